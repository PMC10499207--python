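"""Core containers shared across the pipeline.

A :class:`Recording` is a channels x samples voltage array with per-channel
metadata (participant, ROI, hemisphere).  Derived products — artifact masks,
band-limited analytic envelopes, connectivity matrices — are thin dataclasses
around numpy arrays plus the bookkeeping the downstream statistics need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical frequency bands (Hz).  "broadband" participates only in the
#: channel-rejection rule, not in connectivity.
BANDS: dict[str, tuple[float, float]] = {
    "broadband": (1.0, 110.0),
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 50.0),
    "high_gamma": (70.0, 110.0),
}

#: Bands used for connectivity estimation (broadband and delta excluded).
CONNECTIVITY_BANDS = ("theta", "alpha", "beta", "gamma", "high_gamma")

#: Passband of the slow power-envelope fluctuations used for envelope
#: correlation (Hz).
ENVELOPE_BAND = (0.2, 1.0)

#: Frame rate (Hz) of decimated band envelopes; far above the 1 Hz upper
#: edge of the envelope band.
FRAME_RATE = 50.0


class ConfigurationError(ValueError):
    """Invalid configuration (band edges, durations, coupling ranges)."""


class InsufficientDataError(ValueError):
    """Not enough channels/segments/participants for the requested step."""


def band_edges(band: str | tuple[float, float]) -> tuple[float, float]:
    """Resolve a band name or explicit ``(lo, hi)`` pair to edges in Hz."""
    if isinstance(band, str):
        try:
            return BANDS[band]
        except KeyError:
            raise ConfigurationError(f"unknown band {band!r}") from None
    lo, hi = float(band[0]), float(band[1])
    return lo, hi


@dataclass
class Recording:
    """Continuous multichannel voltage recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Voltage traces (arbitrary gain).
    fs : float
        Sampling rate in Hz.
    channel_meta : pandas.DataFrame
        One row per channel with at least columns ``participant``, ``roi``,
        ``hemisphere``.  A ``dominant`` boolean column marks channels in the
        language-dominant hemisphere when that analysis applies.
    """

    data: np.ndarray
    fs: float
    channel_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ConfigurationError("data must be channels x samples")
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")
        if len(self.channel_meta) != self.data.shape[0]:
            raise ConfigurationError(
                f"channel_meta has {len(self.channel_meta)} rows for "
                f"{self.data.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def select_channels(self, idx) -> "Recording":
        """Sub-recording restricted to the channels in ``idx`` (in order)."""
        idx = np.asarray(idx, dtype=int)
        return Recording(
            data=self.data[idx],
            fs=self.fs,
            channel_meta=self.channel_meta.iloc[idx].reset_index(drop=True),
        )


@dataclass
class ArtifactMask:
    """Boolean contamination mask, channels x samples (True = contaminated).

    ``provenance`` records, per masked run, which rule produced it
    (``"transient"``, ``"high_gamma"``, ...), as tuples
    ``(rule, channel, start_sample, stop_sample)`` with stop exclusive.
    """

    mask: np.ndarray
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def any_channel(self) -> np.ndarray:
        """Per-sample union across channels (masks apply jointly)."""
        return self.mask.any(axis=0)

    def union(self, other: "ArtifactMask") -> "ArtifactMask":
        if self.mask.shape != other.mask.shape:
            raise ValueError("mask shapes differ")
        return ArtifactMask(self.mask | other.mask,
                            self.provenance + other.provenance)

    @classmethod
    def empty(cls, n_channels: int, n_samples: int) -> "ArtifactMask":
        return cls(np.zeros((n_channels, n_samples), dtype=bool))


@dataclass
class BandEnvelope:
    """Band-limited analytic signal decimated to envelope frames.

    ``analytic`` holds the complex analytic band signal sampled at
    ``frame_rate``; ``envelope`` is the log squared amplitude (band log
    power) of those frames.  ``frame_mask`` is True for frames that overlap
    an artifact mask on any channel and must not enter connectivity.
    """

    band: str
    lo: float
    hi: float
    analytic: np.ndarray
    envelope: np.ndarray
    frame_rate: float
    frame_mask: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.analytic.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric pairwise functional-connectivity matrix.

    ``missing`` flags entries with no defining data (e.g., the within-ROI
    diagonal of a single-site ROI); those entries hold NaN in ``values``.
    """

    values: np.ndarray
    node_labels: list
    level: str = "channel"          # "channel" | "roi"
    band: str = ""
    measure: str = "envelope"       # "envelope" | "wpli" | "pearson"
    n_segments_used: int = 0
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("connectivity must be square")
        if len(self.node_labels) != n:
            raise ValueError("node_labels length mismatch")
        if self.missing is None:
            self.missing = np.zeros_like(self.values, dtype=bool)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def off_diagonal(self) -> np.ndarray:
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.values[iu]
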