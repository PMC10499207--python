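"""Synthetic cohorts with planted functional-geometry ground truth.

Each channel is a sum over frequency bands of a band-limited Gaussian
carrier amplitude-modulated by a slow (0.2–1 Hz) log-normal envelope.  The
log-envelope of a channel in ROI ``r`` of community ``c`` mixes three unit
variance slow latents,

    L = sqrt(b) G_global + sqrt(w - b) G_c + sqrt(1 - w) G_private,

so the planted correlation between log-envelopes is ``w`` within a
community and ``b`` between communities.  Hub ROIs instead couple evenly
to every community latent, making them strongly and homogeneously
connected.  Carriers are channel-private (random phase), so envelope
coupling survives orthogonalization, while optional phase-lag entries
share a carrier between two ROIs at a fixed phase offset to drive the
phase-lag index.  A hemispheric effect is planted as a coupling-contrast
change: the "nondominant" half of the cohort has its within/between
contrast multiplied by ``hemisphere_scale``, shrinking planted embedding
distances in that half by approximately the same factor.

Artifacts (transient spikes, high-gamma bursts, a shared broadband
component) are injected at logged positions so detector output can be
checked event by event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.fft import irfft, rfftfreq

from .types import ConfigurationError, Recording

__all__ = [
    "ArtifactSpec",
    "CohortConfig",
    "GroundTruth",
    "band_limited_noise",
    "generate_coupled_signals",
    "inject_artifacts",
    "generate_cohort",
    "planted_hub_connectivity",
    "random_connectivity",
]

DEFAULT_BANDS = (
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 13.0),
    ("beta", 13.0, 30.0),
    ("gamma", 30.0, 50.0),
    ("high_gamma", 70.0, 110.0),
)


@dataclass(frozen=True)
class ArtifactSpec:
    """Rates (events per minute, whole recording) and amplitudes (in
    per-channel SD units) of injected artifacts; ``shared_broadband_amp``
    is the relative amplitude of a common broadband component."""

    transient_rate: float = 0.0
    transient_amp_sd: float = 50.0
    burst_rate: float = 0.0
    burst_amp_sd: float = 20.0
    shared_broadband_amp: float = 0.0


@dataclass(frozen=True)
class CohortConfig:
    """Conditions of a synthetic cohort.

    Defaults define the standard two-community cohort: 8 participants,
    16 ROIs with 1–3 sites each, 600 s at 500 Hz, within/between envelope
    coupling 0.8/0.1.
    """

    n_participants: int = 8
    n_rois: int = 16
    sites_per_roi: tuple[int, int] = (1, 3)
    fs: float = 500.0
    duration: float = 600.0
    bands: tuple = DEFAULT_BANDS
    community_assignment: dict | None = None
    within_coupling: float = 0.8
    between_coupling: float = 0.1
    hub_rois: tuple = ()
    hub_coupling: float = 0.0
    phase_lag_map: dict = field(default_factory=dict)
    hemisphere_scale: float = 1.0
    artifact_spec: ArtifactSpec = ArtifactSpec()
    env_log_sd: float = 1.0
    noise_floor: float = 0.05
    seed: int = 0

    def communities(self) -> dict:
        """ROI -> community id; hubs get community -1.  Default: two
        equal communities over non-hub ROIs."""
        if self.community_assignment is not None:
            comm = dict(self.community_assignment)
        else:
            non_hub = [r for r in range(self.n_rois) if r not in self.hub_rois]
            half = len(non_hub) // 2
            comm = {r: (0 if i < half else 1)
                    for i, r in enumerate(non_hub)}
        for r in self.hub_rois:
            comm[r] = -1
        return comm

    def validate(self) -> None:
        w, b = self.within_coupling, self.between_coupling
        if not (0 <= b <= w < 1):
            raise ConfigurationError(
                "coupling must satisfy 0 <= between <= within < 1")
        if not (0 <= self.hub_coupling < 1):
            raise ConfigurationError("hub_coupling must be in [0, 1)")
        if self.duration < 120:
            raise ConfigurationError(
                "duration must allow >= 2 segments of 60 s")
        if not (0 < self.hemisphere_scale):
            raise ConfigurationError("hemisphere_scale must be positive")
        nyq = self.fs / 2.0
        for name, lo, hi in self.bands:
            if not (0 < lo < hi < nyq):
                raise ConfigurationError(
                    f"band {name} ({lo}, {hi}) invalid for fs={self.fs}")
        comm = self.communities()
        missing = [r for r in range(self.n_rois) if r not in comm]
        if missing:
            raise ConfigurationError(
                f"community assignment misses ROIs {missing}")


@dataclass
class GroundTruth:
    """Planted structure every downstream test checks against."""

    community_labels: dict
    hub_rois: tuple
    envelope_targets: np.ndarray        # ROI x ROI planted log-env corr
    hemisphere_scale: float
    dominant_participants: list
    artifact_events: list = field(default_factory=list)
    roi_lists: dict = field(default_factory=dict)


def band_limited_noise(n_samples: int, fs: float, lo: float, hi: float,
                       rng: np.random.Generator,
                       phase_shift: float = 0.0,
                       base_spectrum: np.ndarray | None = None):
    """Unit-variance Gaussian noise with support in [lo, hi] Hz.

    Synthesized in the frequency domain; ``phase_shift`` rotates every
    in-band component by a constant phase (radians), yielding an exactly
    phase-lagged copy when ``base_spectrum`` is reused.  Returns
    ``(signal, spectrum)``.
    """
    freqs = rfftfreq(n_samples, 1.0 / fs)
    if base_spectrum is None:
        spec = np.zeros(len(freqs), dtype=complex)
        sel = (freqs >= lo) & (freqs <= hi)
        n_in = int(sel.sum())
        if n_in == 0:
            raise ConfigurationError(f"band ({lo}, {hi}) has no FFT bins")
        spec[sel] = rng.standard_normal(n_in) + 1j * rng.standard_normal(n_in)
    else:
        spec = base_spectrum
    if phase_shift:
        spec = spec * np.exp(-1j * phase_shift)
    x = irfft(spec, n=n_samples)
    sd = x.std()
    if sd > 0:
        x = x / sd
    return x, spec


def _latent_weights(config: CohortConfig, roi: int, comm: dict,
                    between: float) -> dict:
    """Mixing weights of the slow latents for channels of one ROI."""
    w = config.within_coupling
    b = between
    if comm[roi] == -1:                      # hub: even coupling to all
        h = config.hub_coupling
        n_comm = len({c for c in comm.values() if c >= 0})
        return {"hub_pool": np.sqrt(h), "private": np.sqrt(1 - h),
                "n_comm": n_comm}
    return {"global": np.sqrt(b), "community": np.sqrt(w - b),
            "private": np.sqrt(1 - w)}


def _participant_rng(config: CohortConfig, participant_index: int
                     ) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, participant_index]))


def _is_dominant(config: CohortConfig, participant_index: int) -> bool:
    return participant_index < (config.n_participants + 1) // 2


def generate_coupled_signals(config: CohortConfig,
                             participant_index: int) -> Recording:
    """One participant's recording with planted envelope coupling.

    Deterministic given ``(config, participant_index)``.  The participant's
    hemisphere follows the cohort split; nondominant participants get the
    reduced coupling contrast.
    """
    config.validate()
    if participant_index >= config.n_participants:
        raise ConfigurationError("participant_index out of range")
    rng = _participant_rng(config, participant_index)
    n = int(round(config.duration * config.fs))
    comm = config.communities()
    dominant = _is_dominant(config, participant_index)
    if dominant:
        between = config.between_coupling
    else:
        between = config.within_coupling - config.hemisphere_scale * (
            config.within_coupling - config.between_coupling)

    n_sites = {r: int(rng.integers(config.sites_per_roi[0],
                                   config.sites_per_roi[1] + 1))
               for r in range(config.n_rois)}
    communities = sorted({c for c in comm.values() if c >= 0})

    def slow(rng_):
        x, _ = band_limited_noise(n, config.fs, 0.2, 1.0, rng_)
        return x

    g_global = slow(rng)
    g_comm = {c: slow(rng) for c in communities}
    g_hub_pool = (np.sum([g_comm[c] for c in communities], axis=0)
                  / np.sqrt(max(len(communities), 1)))

    # shared carriers for phase-lagged ROI pairs
    shared_spec: dict = {}
    lag_of: dict = {}
    for (r1, r2), phi in config.phase_lag_map.items():
        for name, lo, hi in config.bands:
            key = (r1, name)
            if key not in shared_spec:
                _, spec = band_limited_noise(n, config.fs, lo, hi, rng)
                shared_spec[key] = spec
            shared_spec[(r2, name)] = shared_spec[key]
            lag_of[(r2, name)] = phi

    data = []
    meta_rows = []
    sigma = config.env_log_sd
    for r in range(config.n_rois):
        wts = _latent_weights(config, r, comm, between)
        for s in range(n_sites[r]):
            g_priv = slow(rng)
            if comm[r] == -1:
                lat = wts["hub_pool"] * g_hub_pool + wts["private"] * g_priv
            else:
                lat = (wts["global"] * g_global
                       + wts["community"] * g_comm[comm[r]]
                       + wts["private"] * g_priv)
            amp = np.exp(0.5 * sigma * lat)
            sig = np.zeros(n)
            for name, lo, hi in config.bands:
                key = (r, name)
                if key in shared_spec:
                    carrier, _ = band_limited_noise(
                        n, config.fs, lo, hi, rng,
                        phase_shift=lag_of.get(key, 0.0),
                        base_spectrum=shared_spec[key])
                else:
                    carrier, _ = band_limited_noise(n, config.fs, lo, hi, rng)
                sig += amp * carrier
            sig += config.noise_floor * rng.standard_normal(n)
            data.append(sig)
            meta_rows.append({
                "participant": participant_index,
                "roi": f"ROI{r:02d}",
                "roi_id": r,
                "site": s,
                "hemisphere": "L" if dominant else "R",
                "dominant": dominant,
                "community": comm[r],
            })
    return Recording(data=np.array(data), fs=config.fs,
                     channel_meta=pd.DataFrame(meta_rows))


def _envelope_targets(config: CohortConfig) -> np.ndarray:
    """Planted log-envelope correlation between channels of ROI pairs."""
    comm = config.communities()
    communities = sorted({c for c in comm.values() if c >= 0})
    n_c = max(len(communities), 1)
    w, b, h = (config.within_coupling, config.between_coupling,
               config.hub_coupling)
    tgt = np.zeros((config.n_rois, config.n_rois))
    for i in range(config.n_rois):
        for j in range(config.n_rois):
            ci, cj = comm[i], comm[j]
            if ci == -1 and cj == -1:
                tgt[i, j] = h if i != j else 1.0
            elif ci == -1 or cj == -1:
                tgt[i, j] = np.sqrt(h) * np.sqrt(w - b) / np.sqrt(n_c)
            elif ci == cj:
                tgt[i, j] = w if i != j else 1.0
            else:
                tgt[i, j] = b
        tgt[i, i] = w  # distinct same-ROI sites share the community latent
    return tgt


def inject_artifacts(recording: Recording, spec: ArtifactSpec, seed: int
                     ) -> tuple[Recording, list]:
    """Add logged transients, high-gamma bursts, and shared broadband noise.

    Zero rates and amplitude return the input unchanged.  Events are dicts
    with ``channel`` (−1 = all channels), ``onset``/``duration`` in
    samples, and ``kind``.
    """
    if (spec.transient_rate < 0 or spec.burst_rate < 0
            or spec.shared_broadband_amp < 0):
        raise ConfigurationError("artifact rates/amplitudes must be >= 0")
    if (spec.transient_rate == 0 and spec.burst_rate == 0
            and spec.shared_broadband_amp == 0):
        return recording, []
    rng = np.random.default_rng(np.random.SeedSequence([seed, 991]))
    data = recording.data.copy()
    fs = recording.fs
    n_ch, n_s = data.shape
    minutes = n_s / fs / 60.0
    events: list = []
    ch_sd = data.std(axis=1)

    n_trans = rng.poisson(spec.transient_rate * minutes)
    dur = int(round(0.04 * fs))                      # 40 ms biphasic pulse
    shape = np.sin(2 * np.pi * np.arange(dur) / dur) * np.hanning(dur)
    shape /= np.abs(shape).max()
    for _ in range(n_trans):
        ch = int(rng.integers(n_ch))
        onset = int(rng.integers(0, n_s - dur))
        data[ch, onset:onset + dur] += spec.transient_amp_sd * ch_sd[ch] * shape
        events.append({"channel": ch, "onset": onset, "duration": dur,
                       "kind": "transient"})

    n_burst = rng.poisson(spec.burst_rate * minutes)
    bdur = int(round(0.2 * fs))                      # 200 ms 90 Hz burst
    t = np.arange(bdur) / fs
    for _ in range(n_burst):
        ch = int(rng.integers(n_ch))
        onset = int(rng.integers(0, n_s - bdur))
        burst = (spec.burst_amp_sd * ch_sd[ch]
                 * np.sin(2 * np.pi * 90.0 * t) * np.hanning(bdur))
        data[ch, onset:onset + bdur] += burst
        events.append({"channel": ch, "onset": onset, "duration": bdur,
                       "kind": "high_gamma_burst"})

    if spec.shared_broadband_amp > 0:
        common = rng.standard_normal(n_s)
        gains = 1.0 + 0.2 * rng.standard_normal(n_ch)
        data += (spec.shared_broadband_amp
                 * (gains * ch_sd)[:, None] * common[None, :])
        events.append({"channel": -1, "onset": 0, "duration": n_s,
                       "kind": "shared_broadband"})
    return (Recording(data, fs, recording.channel_meta.copy()), events)


def generate_cohort(config: CohortConfig
                    ) -> tuple[list[Recording], GroundTruth]:
    """Generate every participant plus the ground-truth ledger."""
    config.validate()
    recordings = []
    all_events: list = []
    roi_lists: dict = {}
    for p in range(config.n_participants):
        rec = generate_coupled_signals(config, p)
        rec, events = inject_artifacts(rec, config.artifact_spec,
                                       seed=config.seed * 100003 + p)
        for e in events:
            e["participant"] = p
        all_events.extend(events)
        roi_lists[p] = sorted(rec.channel_meta["roi"].unique())
        recordings.append(rec)
    gt = GroundTruth(
        community_labels=config.communities(),
        hub_rois=tuple(config.hub_rois),
        envelope_targets=_envelope_targets(config),
        hemisphere_scale=config.hemisphere_scale,
        dominant_participants=[p for p in range(config.n_participants)
                               if _is_dominant(config, p)],
        artifact_events=all_events,
        roi_lists=roi_lists,
    )
    return recordings, gt


def planted_hub_connectivity(n_nodes: int = 24, n_communities: int = 2,
                             hub_spread: float = 0.7, scale: float = 0.8,
                             noise_sd: float = 0.02,
                             rng: np.random.Generator | None = None
                             ) -> tuple[np.ndarray, int]:
    """Connectivity matrix with a graded hubness structure (hub = node 0).

    Each node carries a community-affinity profile; connectivity is the
    (scaled) inner product of profiles.  A node's *hubness* mixes its
    profile toward the uniform distribution: node 0 is fully uniform (the
    global hub, strongly and homogeneously connected), the rest draw
    hubness from ``[0, hub_spread)``.  Mean connectivity rises and
    embedding centroid distance falls with hubness, planting the inverse
    relation that hub scoring must recover.  Returns ``(matrix,
    hub_index)``.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    labels = np.arange(n_nodes) % n_communities
    h = np.concatenate(([1.0], rng.uniform(0.0, hub_spread, n_nodes - 1)))
    a = np.zeros((n_nodes, n_communities))
    a[np.arange(n_nodes), labels] = 1.0
    a = (1.0 - h[:, None]) * a + h[:, None] / n_communities
    a /= np.linalg.norm(a, axis=1, keepdims=True)
    v = scale * (a @ a.T)
    noise = rng.normal(0.0, noise_sd, (n_nodes, n_nodes))
    v = v + (noise + noise.T) / 2.0
    v = np.clip(v, 0.01, 0.99)
    np.fill_diagonal(v, 0.0)
    return v, 0


def random_connectivity(n_nodes: int, rng: np.random.Generator,
                        sparsity: float = 0.0) -> np.ndarray:
    """Random symmetric nonnegative connectivity (uniform weights)."""
    v = rng.uniform(0.05, 1.0, (n_nodes, n_nodes))
    v = (v + v.T) / 2.0
    if sparsity > 0:
        drop = rng.random((n_nodes, n_nodes)) < sparsity
        drop = np.triu(drop, 1)
        v[drop | drop.T] = 0.0
    np.fill_diagonal(v, 0.0)
    return v
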