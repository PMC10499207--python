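"""Artifact rejection, common-signal removal, and band envelope extraction.

The cleaning cascade for clinical-style multichannel recordings:

1. drop channels whose average log band power is an outlier (> 3.5 SD above
   the across-channel mean) in *any* canonical band;
2. mask transient voltage deflections (> 10 SD) out to the surrounding
   zero crossings plus a 100 ms buffer;
3. mask frames with excessive high-gamma power (> 5 SD above the mean);
4. remove shared broadband noise with a spatial filter built from the SVD
   of the normalized covariance of the > 200 Hz high-passed data, omitting
   the first singular vector.

Masks are applied jointly across channels so that every connectivity
estimate is computed from the same artifact-free time windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal
from scipy.fft import ifft, irfft, rfft, rfftfreq

from .types import (
    ArtifactMask,
    BandEnvelope,
    ConfigurationError,
    InsufficientDataError,
    Recording,
    BANDS,
    FRAME_RATE,
    band_edges,
)

__all__ = [
    "reject_channels_by_band_power",
    "mask_transients",
    "mask_high_gamma_bursts",
    "fit_common_signal_filter",
    "apply_spatial_filter",
    "band_envelopes",
    "optimize_retention",
    "SpatialFilterModel",
    "bandpass_sos",
    "spectral_bandpass",
    "envelope_bandpass",
]

# Log floor relative to the median band power; keeps envelopes finite on
# silent bands.
LOG_FLOOR_REL = 1e-12


def bandpass_sos(lo: float, hi: float, fs: float, order: int = 4) -> np.ndarray:
    """Zero-phase-ready Butterworth bandpass in second-order sections."""
    nyq = fs / 2.0
    if not (0 < lo < hi < nyq):
        raise ConfigurationError(
            f"band ({lo}, {hi}) Hz invalid for fs={fs} (Nyquist {nyq})"
        )
    return signal.butter(order, [lo / nyq, hi / nyq], btype="band", output="sos")


def _filtfilt(sos: np.ndarray, x: np.ndarray) -> np.ndarray:
    return signal.sosfiltfilt(sos, x, axis=-1)


@lru_cache(maxsize=64)
def _butter_power_response(n: int, fs: float, lo: float, hi: float,
                           btype: str) -> np.ndarray:
    """|H|^2 of a 4th-order Butterworth on the rfft grid of length n.

    Matches the magnitude response of forward-backward (zero-phase)
    filtering; applied spectrally for speed on long recordings.
    """
    nyq = fs / 2.0
    if btype == "band":
        sos = bandpass_sos(lo, hi, fs)
    elif btype == "high":
        sos = signal.butter(4, lo / nyq, btype="high", output="sos")
    else:  # pragma: no cover
        raise ValueError(btype)
    freqs = rfftfreq(n, 1.0 / fs)
    _, h = signal.sosfreqz(sos, worN=freqs, fs=fs)
    return np.abs(h) ** 2


def spectral_bandpass(data: np.ndarray, fs: float, lo: float, hi: float,
                      btype: str = "band",
                      analytic: bool = False) -> np.ndarray:
    """Zero-phase Butterworth filtering applied in the frequency domain.

    With ``analytic=True`` the one-sided filtered spectrum is inverted
    directly into the analytic (complex) band signal, fusing the bandpass
    and Hilbert transform into one FFT pair.
    """
    x = np.asarray(data, dtype=float)
    n = x.shape[-1]
    resp = _butter_power_response(n, float(fs), float(lo), float(hi), btype)
    spec = rfft(x, axis=-1) * resp
    if not analytic:
        return irfft(spec, n=n, axis=-1)
    z = np.zeros(x.shape[:-1] + (n,), dtype=complex)
    z[..., : spec.shape[-1]] = 2.0 * spec
    z[..., 0] *= 0.5
    if n % 2 == 0:
        z[..., n // 2] *= 0.5
    return ifft(z, axis=-1)


def envelope_bandpass(env: np.ndarray, frame_rate: float,
                      lo: float = 0.2, hi: float = 1.0) -> np.ndarray:
    """Bandpass slow envelope fluctuations (default 0.2–1 Hz), zero phase."""
    sos = bandpass_sos(lo, hi, frame_rate)
    return _filtfilt(sos, env)


def _mean_log_band_power(data: np.ndarray, fs: float,
                         lo: float, hi: float) -> np.ndarray:
    """Per-channel average log power in the band (channels x samples in)."""
    xb = spectral_bandpass(data, fs, lo, hi)
    p = xb ** 2
    floor = LOG_FLOOR_REL * max(float(np.median(p)), np.finfo(float).tiny)
    return np.log(p + floor).mean(axis=1)


def reject_channels_by_band_power(recording: Recording,
                                  z_thresh: float = 3.5) -> np.ndarray:
    """Indices of channels retained by the any-band power outlier rule.

    A channel is dropped when its average log power in any canonical band
    (broadband, delta, theta, alpha, beta, gamma, high gamma) exceeds the
    across-channel mean by more than ``z_thresh`` standard deviations.
    Bands above Nyquist for this recording are skipped.
    """
    if recording.n_channels < 3:
        raise InsufficientDataError("channel rejection needs >= 3 channels")
    bad = np.zeros(recording.n_channels, dtype=bool)
    for name, (lo, hi) in BANDS.items():
        if hi >= recording.fs / 2:
            continue
        mlp = _mean_log_band_power(recording.data, recording.fs, lo, hi)
        sd = mlp.std()
        if sd == 0:
            continue
        z = (mlp - mlp.mean()) / sd
        bad |= z > z_thresh
    return np.flatnonzero(~bad)


def _zero_crossings(x: np.ndarray) -> np.ndarray:
    """Sample indices i where x changes sign between i and i+1 (or x[i]==0)."""
    s = np.sign(x)
    # treat exact zeros as crossings
    zc = np.flatnonzero((s[:-1] * s[1:] <= 0))
    return zc


def mask_transients(recording: Recording, z_thresh: float = 10.0,
                    buffer_ms: float = 100.0) -> ArtifactMask:
    """Mask transient deflections exceeding ``z_thresh`` SD (strict >).

    Each supra-threshold run is extended backward and forward to the first
    zero crossing of the demeaned trace, then padded by ``buffer_ms`` on
    each side.  A constant channel (SD = 0) is flagged unusable by masking
    it entirely.
    """
    n_ch, n_s = recording.data.shape
    buf = int(round(buffer_ms / 1000.0 * recording.fs))
    mask = np.zeros((n_ch, n_s), dtype=bool)
    prov: list = []
    for ch in range(n_ch):
        x = recording.data[ch] - recording.data[ch].mean()
        sd = x.std()
        if sd == 0:
            mask[ch, :] = True
            prov.append(("unusable", ch, 0, n_s))
            continue
        exceed = np.abs(x) > z_thresh * sd
        if not exceed.any():
            continue
        zc = _zero_crossings(x)
        # runs of consecutive exceedances
        idx = np.flatnonzero(exceed)
        run_breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([idx[0]], idx[run_breaks + 1]))
        stops = np.concatenate((idx[run_breaks], [idx[-1]]))
        for s0, s1 in zip(starts, stops):
            j = np.searchsorted(zc, s0) - 1
            left = zc[j] if j >= 0 else 0
            j = np.searchsorted(zc, s1)
            right = (zc[j] + 1) if j < len(zc) else n_s - 1
            a = max(0, left - buf)
            b = min(n_s, right + buf + 1)
            mask[ch, a:b] = True
            prov.append(("transient", ch, int(a), int(b)))
    return ArtifactMask(mask, prov)


def mask_high_gamma_bursts(recording: Recording,
                           z_thresh: float = 5.0) -> ArtifactMask:
    """Mask frames whose high-gamma power exceeds mean + ``z_thresh`` SD.

    Power is the squared analytic amplitude in 70–110 Hz, decimated to
    envelope frames; supra-threshold frames are expanded back to sample
    spans in the returned mask.
    """
    env = band_envelopes(recording, "high_gamma")
    step = int(round(recording.fs / env.frame_rate))
    power = np.abs(env.analytic) ** 2
    n_ch, n_s = recording.data.shape
    mask = np.zeros((n_ch, n_s), dtype=bool)
    prov: list = []
    for ch in range(n_ch):
        p = power[ch]
        sd = p.std()
        if sd == 0:
            continue
        hot = p > p.mean() + z_thresh * sd
        for f in np.flatnonzero(hot):
            a, b = f * step, min(n_s, (f + 1) * step)
            mask[ch, a:b] = True
            prov.append(("high_gamma", ch, int(a), int(b)))
    return ArtifactMask(mask, prov)


@dataclass
class SpatialFilterModel:
    """SVD-derived spatial filter removing the dominant shared component.

    ``C`` is the normalized covariance of the high-passed data (unit
    diagonal); ``w`` is ``S (I - u1 u1^T) S^-1`` with ``S = diag(1/sigma)``.
    ``w`` is similar to a rank-(M-1) projector: ``S^-1 w S`` has exactly one
    zero eigenvalue, the rest equal one.
    """

    sigma: np.ndarray
    C: np.ndarray
    eigvals: np.ndarray
    eigvecs: np.ndarray
    w: np.ndarray
    hp_cutoff: float


def fit_common_signal_filter(recording: Recording,
                             hp_cutoff: float = 200.0) -> SpatialFilterModel:
    """Derive the common-signal spatial filter from > ``hp_cutoff`` Hz data.

    High-pass filtering before estimating the covariance suppresses
    long-range physiological (low-frequency) correlations while preserving
    the zero-lag correlations of shared reference/equipment noise.
    """
    if recording.n_channels < 2:
        raise InsufficientDataError("spatial filter needs >= 2 channels")
    if recording.fs <= 2 * hp_cutoff:
        raise ConfigurationError(
            f"fs={recording.fs} too low for hp_cutoff={hp_cutoff}")
    x_hp = spectral_bandpass(recording.data, recording.fs, hp_cutoff, 0.0,
                             btype="high")
    sigma = x_hp.std(axis=1)
    if np.any(sigma == 0):
        raise InsufficientDataError("zero-variance channel in high-passed data")
    s = 1.0 / sigma
    n = x_hp.shape[1]
    C = (s[:, None] * (x_hp @ x_hp.T) * s[None, :]) / n
    eigvals, eigvecs = np.linalg.eigh(C)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    u1 = eigvecs[:, [0]]
    m = recording.n_channels
    proj = np.eye(m) - u1 @ u1.T
    w = (s[:, None] * proj) * sigma[None, :]
    return SpatialFilterModel(sigma=sigma, C=C, eigvals=eigvals,
                              eigvecs=eigvecs, w=w, hp_cutoff=hp_cutoff)


def apply_spatial_filter(recording: Recording,
                         model: SpatialFilterModel) -> Recording:
    """Apply ``y_SVD = y W`` to the unfiltered data (metadata preserved)."""
    if model.w.shape[0] != recording.n_channels:
        raise ValueError(
            f"filter built for {model.w.shape[0]} channels, recording has "
            f"{recording.n_channels}")
    filtered = model.w.T @ recording.data
    return Recording(filtered, recording.fs, recording.channel_meta.copy())


def band_envelopes(recording: Recording, band,
                   mask: ArtifactMask | None = None,
                   frame_rate: float = FRAME_RATE) -> BandEnvelope:
    """Band-limited analytic signal and log-power envelope at frame rate.

    The band is isolated with a zero-phase Butterworth bandpass, the
    analytic signal obtained by Hilbert transform, and frames decimated to
    ``frame_rate``.  The envelope is the log squared amplitude with a small
    relative floor.  Frames overlapping an artifact mask on any channel are
    flagged in ``frame_mask`` and excluded downstream.
    """
    lo, hi = band_edges(band)
    name = band if isinstance(band, str) else f"{lo:g}-{hi:g}Hz"
    bandpass_sos(lo, hi, recording.fs)   # validates edges against Nyquist
    step = int(round(recording.fs / frame_rate))
    if step < 1:
        raise ConfigurationError("frame rate exceeds sampling rate")
    actual_rate = recording.fs / step
    n = recording.n_samples
    if n % step == 0:
        # sample the analytic signal at frame rate directly: fold the
        # one-sided filtered spectrum modulo n/step before the inverse FFT
        # (identical to computing the full analytic signal and striding)
        resp = _butter_power_response(n, float(recording.fs), float(lo),
                                      float(hi), "band")
        spec = rfft(recording.data, axis=-1) * (2.0 * resp)
        spec[..., 0] *= 0.5
        if n % 2 == 0:
            spec[..., -1] *= 0.5
        n_f = n // step
        folded = np.zeros(recording.data.shape[:-1] + (n_f,), dtype=complex)
        for q in range((spec.shape[-1] + n_f - 1) // n_f):
            seg = spec[..., q * n_f: (q + 1) * n_f]
            folded[..., : seg.shape[-1]] += seg
        frames = ifft(folded, axis=-1) / step
    else:
        analytic = spectral_bandpass(recording.data, recording.fs, lo, hi,
                                     analytic=True)
        frames = analytic[:, ::step]
    power = np.abs(frames) ** 2
    floor = LOG_FLOOR_REL * max(float(np.median(power)), np.finfo(float).tiny)
    env = np.log(power + floor)
    n_frames = frames.shape[1]
    if mask is not None:
        joint = mask.any_channel
        # frame f covers samples [f*step, (f+1)*step)
        npad = (-len(joint)) % step
        jm = np.pad(joint, (0, npad))
        frame_mask = jm.reshape(-1, step).any(axis=1)[:n_frames]
    else:
        frame_mask = np.zeros(n_frames, dtype=bool)
    return BandEnvelope(band=name, lo=lo, hi=hi, analytic=frames,
                        envelope=env, frame_rate=actual_rate,
                        frame_mask=frame_mask)


def optimize_retention(mask: ArtifactMask) -> np.ndarray:
    """Greedy channel-drop loop maximizing retained channels x time.

    Masks apply jointly: a time sample is usable only if clean on every
    retained channel.  Dropping a channel loses its clean time but can
    recover time on all others; channels are removed while any removal
    increases the retained channels x samples count.
    Returns retained channel indices.
    """
    m = mask.mask
    n_ch = m.shape[0]
    retained = list(range(n_ch))

    def score(chs: list[int]) -> int:
        if not chs:
            return 0
        clean = ~m[chs].any(axis=0)
        return len(chs) * int(clean.sum())

    current = score(retained)
    improved = True
    while improved and len(retained) > 1:
        improved = False
        best_gain, best_ch = 0, None
        for ch in retained:
            trial = [c for c in retained if c != ch]
            gain = score(trial) - current
            if gain > best_gain:
                best_gain, best_ch = gain, ch
        if best_ch is not None:
            retained.remove(best_ch)
            current += best_gain
            improved = True
    return np.asarray(retained, dtype=int)
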