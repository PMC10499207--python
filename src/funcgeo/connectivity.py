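"""Pairwise functional connectivity estimation and ROI aggregation.

Two band-limited measures for electrophysiology, both insensitive to
zero-phase-lag (volume-conducted) coupling:

* **orthogonalized power envelope correlation** — one analytic signal is
  orthogonalized to the other, ``Y_orth = |Im{Y X* / |X|}|``, log-power
  envelopes of the reference and the orthogonalized signal are bandpass
  filtered to 0.2–1 Hz and Pearson-correlated; the two orthogonalization
  directions are averaged;
* **debiased wPLI** — the debiased weighted phase-lag-index square
  estimator built from the imaginary part of short-window cross-spectra,
  averaged across in-band frequencies.

Estimates are formed in 60-second segments and averaged across segments.
Plain Pearson correlation is provided for slow (BOLD-like) ROI series.
Channel-level matrices aggregate to ROI level as the mean over cross-site
pairs, and a cohort coverage rule retains only ROIs whose every pair is
sampled by at least ``min_pairs`` participants.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import signal
from scipy.fft import irfft, rfft, rfftfreq

from .preprocess import band_envelopes, bandpass_sos
from .types import (
    ArtifactMask,
    BandEnvelope,
    ConnectivityMatrix,
    InsufficientDataError,
    Recording,
    ENVELOPE_BAND,
    FRAME_RATE,
    band_edges,
)

__all__ = [
    "orthogonalized_envelope_correlation",
    "envelope_connectivity",
    "debiased_wpli",
    "pearson_connectivity",
    "aggregate_to_rois",
    "coverage_table",
    "select_covered_rois",
    "average_across_participants",
]

_TINY = 1e-30


def _env_sos(frame_rate: float) -> np.ndarray:
    return bandpass_sos(ENVELOPE_BAND[0], ENVELOPE_BAND[1], frame_rate)


@lru_cache(maxsize=16)
def _env_response(n_frames: int, frame_rate: float) -> np.ndarray:
    """Zero-phase 0.2–1 Hz Butterworth magnitude response |H|^2 on the
    rfft grid of a segment.  Applying it in the frequency domain matches
    the forward-backward (filtfilt) magnitude response at a fraction of
    the cost of the recursion."""
    sos = _env_sos(frame_rate)
    freqs = rfftfreq(n_frames, 1.0 / frame_rate)
    _, h = signal.sosfreqz(sos, worN=freqs, fs=frame_rate)
    return np.abs(h) ** 2


def _env_filter(env: np.ndarray, frame_rate: float) -> np.ndarray:
    """Zero-phase envelope bandpass (0.2–1 Hz) applied spectrally."""
    n = env.shape[-1]
    h2 = _env_response(n, frame_rate)
    return irfft(rfft(env, axis=-1) * h2, n=n, axis=-1)


def _log_power(a: np.ndarray, floor: float) -> np.ndarray:
    return np.log(np.abs(a) ** 2 + floor)


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    """Demean rows and scale to unit norm; zero-variance rows become 0."""
    xc = x - x.mean(axis=-1, keepdims=True)
    nrm = np.linalg.norm(xc, axis=-1, keepdims=True)
    good = nrm > _TINY * max(1.0, float(np.abs(x).max(initial=0.0)))
    return np.where(good, xc / np.where(good, nrm, 1.0), 0.0)


def _directed_envelope_corr(a_seg: np.ndarray, frame_rate: float,
                            chunk: int = 8) -> np.ndarray:
    """All-pairs directed envelope correlations for one segment.

    ``r[x, y]`` correlates the filtered log-power envelope of channel ``x``
    (the reference) with that of channel ``y`` orthogonalized to ``x``.
    Degenerate (constant-envelope) rows yield 0.
    """
    n, L = a_seg.shape
    power = np.abs(a_seg) ** 2
    floor = 1e-12 * max(float(np.median(power)), np.finfo(float).tiny)
    env_ref = _log_power(a_seg, floor)
    f_ref = _standardize_rows(_env_filter(env_ref, frame_rate))
    mag = np.abs(a_seg)
    unit_conj = np.conj(a_seg) / np.where(mag > _TINY, mag, 1.0)
    energy = power.mean(axis=-1)
    r = np.zeros((n, n))
    for c0 in range(0, n, chunk):
        c1 = min(c0 + chunk, n)
        # orthogonalize every channel to references c0..c1
        y_orth = np.abs(np.imag(a_seg[None, :, :]
                                * unit_conj[c0:c1, None, :]))
        # a pair that is exactly in phase leaves only numerical noise in
        # y_orth; flag it degenerate rather than standardizing the noise
        degenerate = (y_orth ** 2).mean(axis=-1) < 1e-10 * energy[None, :]
        env_o = _log_power(y_orth, floor).reshape(-1, L)
        g = _standardize_rows(_env_filter(env_o, frame_rate))
        g = g.reshape(c1 - c0, n, L)
        r[c0:c1] = np.einsum("xyl,xl->xy", g, f_ref[c0:c1])
        r[c0:c1][degenerate] = 0.0
    return r


def orthogonalized_envelope_correlation(x_analytic: np.ndarray,
                                        y_analytic: np.ndarray,
                                        frame_rate: float = FRAME_RATE
                                        ) -> float:
    """Orthogonalized power envelope correlation for one signal pair.

    Averages the correlations obtained by orthogonalizing Y to X and X to
    Y.  A pair whose orthogonalized signal is (numerically) constant — for
    example an exactly in-phase scaled copy — carries no orthogonalized
    evidence and returns 0.
    """
    x = np.asarray(x_analytic)
    y = np.asarray(y_analytic)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D analytic series")
    r = _directed_envelope_corr(np.vstack([x, y]), frame_rate)
    return float((r[0, 1] + r[1, 0]) / 2.0)


def _clean_segments(n_frames: int, frames_per_seg: int,
                    frame_mask: np.ndarray) -> list[slice]:
    """Complete segments free of masked frames (trailing partial discarded)."""
    out = []
    for s in range(n_frames // frames_per_seg):
        sl = slice(s * frames_per_seg, (s + 1) * frames_per_seg)
        if not frame_mask[sl].any():
            out.append(sl)
    return out


def envelope_connectivity(recording: Recording, band,
                          segment_s: float = 60.0,
                          mask: ArtifactMask | None = None,
                          env: BandEnvelope | None = None
                          ) -> ConnectivityMatrix:
    """Channel x channel orthogonalized envelope correlation matrix.

    Connectivity is estimated in each complete artifact-free segment of
    ``segment_s`` seconds and averaged across segments.
    """
    if env is None:
        env = band_envelopes(recording, band, mask=mask)
    frames_per_seg = int(round(segment_s * env.frame_rate))
    segs = _clean_segments(env.n_frames, frames_per_seg, env.frame_mask)
    if not segs:
        raise InsufficientDataError(
            f"no complete artifact-free {segment_s:g}-s segment")
    n = env.analytic.shape[0]
    acc = np.zeros((n, n))
    for sl in segs:
        r = _directed_envelope_corr(env.analytic[:, sl], env.frame_rate)
        acc += (r + r.T) / 2.0
    values = acc / len(segs)
    np.fill_diagonal(values, 0.0)
    labels = list(recording.channel_meta.index)
    name = band if isinstance(band, str) else env.band
    return ConnectivityMatrix(values=values, node_labels=labels,
                              level="channel", band=str(name),
                              measure="envelope",
                              n_segments_used=len(segs))


def debiased_wpli(recording: Recording, band,
                  segment_s: float = 60.0,
                  mask: ArtifactMask | None = None,
                  window_s: float = 1.0) -> ConnectivityMatrix:
    """Channel x channel debiased wPLI-square matrix.

    Within each 60-s segment the cross-spectrum is estimated in short
    Hann windows (50% overlap); the debiased square estimator is formed
    from the imaginary parts across windows at each frequency, averaged
    across in-band frequencies, then across segments.  Values may be
    slightly negative by construction of the debiasing.
    """
    lo, hi = band_edges(band)
    fs = recording.fs
    seg_len = int(round(segment_s * fs))
    n_seg_total = recording.n_samples // seg_len
    joint = mask.any_channel if mask is not None else None
    segs = []
    for s in range(n_seg_total):
        sl = slice(s * seg_len, (s + 1) * seg_len)
        if joint is None or not joint[sl].any():
            segs.append(sl)
    if not segs:
        raise InsufficientDataError(
            f"no complete artifact-free {segment_s:g}-s segment")
    nper = int(round(window_s * fs))
    n = recording.n_channels
    acc = np.zeros((n, n))
    for sl in segs:
        f, _, z = signal.stft(recording.data[:, sl], fs=fs, window="hann",
                              nperseg=nper, noverlap=nper // 2,
                              boundary=None, padded=False)
        sel = (f >= lo) & (f <= hi)
        z = z[:, sel, :]                        # (n_ch, n_freq, n_win)
        seg_val = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                im = np.imag(z[i] * np.conj(z[j]))      # (n_freq, n_win)
                s_im = im.sum(axis=1)
                s_sq = (im ** 2).sum(axis=1)
                s_abs = np.abs(im).sum(axis=1)
                num = s_im ** 2 - s_sq
                den = s_abs ** 2 - s_sq
                with np.errstate(invalid="ignore", divide="ignore"):
                    d = np.where(den > 0, num / np.where(den > 0, den, 1.0),
                                 0.0)
                seg_val[i, j] = seg_val[j, i] = d.mean()
        acc += seg_val
    values = acc / len(segs)
    np.fill_diagonal(values, 0.0)
    name = band if isinstance(band, str) else f"{lo:g}-{hi:g}Hz"
    return ConnectivityMatrix(values=values,
                              node_labels=list(recording.channel_meta.index),
                              level="channel", band=str(name),
                              measure="wpli", n_segments_used=len(segs))


def pearson_connectivity(slow_series: np.ndarray,
                         node_labels=None) -> ConnectivityMatrix:
    """Pearson correlation matrix for slow (BOLD-like) node time series."""
    x = np.asarray(slow_series, dtype=float)
    if x.ndim != 2 or x.shape[1] < 3:
        raise InsufficientDataError("need nodes x frames with >= 3 frames")
    n = x.shape[0]
    degenerate = np.ptp(x, axis=1) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.corrcoef(x)
    missing = np.zeros((n, n), dtype=bool)
    if degenerate.any():
        values[degenerate, :] = np.nan
        values[:, degenerate] = np.nan
        missing[degenerate, :] = True
        missing[:, degenerate] = True
    np.fill_diagonal(values, 0.0)
    if node_labels is None:
        node_labels = list(range(n))
    return ConnectivityMatrix(values=values, node_labels=list(node_labels),
                              level="roi", band="slow", measure="pearson",
                              missing=missing)


def aggregate_to_rois(conn: ConnectivityMatrix, roi_map: dict
                      ) -> ConnectivityMatrix:
    """Average channel-level connectivity into ROI-level entries.

    Entry (A, B) is the mean over all cross pairs of sites; the within-ROI
    diagonal uses cross-site pairs only, so a single-site ROI has an
    undefined (missing) diagonal entry.
    """
    labels = conn.node_labels
    unmapped = [l for l in labels if l not in roi_map]
    if unmapped:
        raise ValueError(f"channels without ROI assignment: {unmapped[:5]}")
    rois: list = []
    for l in labels:
        r = roi_map[l]
        if r not in rois:
            rois.append(r)
    idx = {r: np.array([i for i, l in enumerate(labels) if roi_map[l] == r])
           for r in rois}
    n = len(rois)
    values = np.full((n, n), np.nan)
    missing = np.zeros((n, n), dtype=bool)
    for a in range(n):
        ia = idx[rois[a]]
        for b in range(a, n):
            ib = idx[rois[b]]
            if a == b:
                if len(ia) < 2:
                    missing[a, a] = True
                    continue
                sub = conn.values[np.ix_(ia, ia)]
                iu = np.triu_indices(len(ia), k=1)
                values[a, a] = float(np.nanmean(sub[iu]))
            else:
                sub = conn.values[np.ix_(ia, ib)]
                values[a, b] = values[b, a] = float(np.nanmean(sub))
    return ConnectivityMatrix(values=values, node_labels=rois, level="roi",
                              band=conn.band, measure=conn.measure,
                              n_segments_used=conn.n_segments_used,
                              missing=missing)


def coverage_table(roi_lists: dict) -> pd.DataFrame:
    """Participants x ROIs boolean coverage table.

    ``roi_lists`` maps participant id -> iterable of sampled ROI names.
    """
    all_rois = sorted({r for rois in roi_lists.values() for r in rois})
    table = pd.DataFrame(False, index=list(roi_lists), columns=all_rois)
    for p, rois in roi_lists.items():
        table.loc[p, list(rois)] = True
    return table


def select_covered_rois(coverage: pd.DataFrame,
                        min_pairs: int = 2) -> list:
    """Greedy cross-coverage pruning of the ROI set.

    While any retained ROI pair is sampled together by fewer than
    ``min_pairs`` participants, remove the ROI with the fewest sufficiently
    covered partner pairs (ties: fewest sampling participants, then
    lexicographically smallest name).
    """
    if coverage.size == 0:
        raise InsufficientDataError("empty coverage table")
    if min_pairs <= 0:
        return list(coverage.columns)
    retained = list(coverage.columns)
    b = coverage.to_numpy(dtype=int)
    cols = list(coverage.columns)
    pos = {r: i for i, r in enumerate(cols)}
    while True:
        if not retained:
            raise InsufficientDataError(
                "coverage rule removed every ROI; no analyzable set")
        ix = np.array([pos[r] for r in retained])
        sub = b[:, ix]
        pc = sub.T @ sub                       # pair coverage counts
        ok = pc >= min_pairs
        np.fill_diagonal(ok, True)
        if ok.all():
            return retained
        n_ok = ok.sum(axis=1) - 1              # sufficiently covered partners
        n_part = sub.sum(axis=0)
        order = sorted(range(len(retained)),
                       key=lambda i: (n_ok[i], n_part[i], retained[i]))
        retained.pop(order[0])


def average_across_participants(conns: list[ConnectivityMatrix],
                                retained: list,
                                min_pairs: int = 2) -> ConnectivityMatrix:
    """Entrywise mean of ROI matrices over participants sampling each pair.

    Requires every retained off-diagonal pair to be covered by at least
    ``min_pairs`` participants (run :func:`select_covered_rois` first).
    """
    n = len(retained)
    pos = {r: i for i, r in enumerate(retained)}
    total = np.zeros((n, n))
    count = np.zeros((n, n), dtype=int)
    for cm in conns:
        present = [l for l in cm.node_labels if l in pos]
        src = [cm.node_labels.index(l) for l in present]
        dst = [pos[l] for l in present]
        sub = cm.values[np.ix_(src, src)]
        sub_missing = cm.missing[np.ix_(src, src)]
        valid = np.isfinite(sub) & ~sub_missing
        dd = np.ix_(dst, dst)
        total[dd] += np.where(valid, sub, 0.0)
        count[dd] += valid
    off = ~np.eye(n, dtype=bool)
    if np.any(count[off] < min_pairs):
        bad = np.argwhere((count < min_pairs) & off)
        i, j = bad[0]
        raise InsufficientDataError(
            f"pair ({retained[i]}, {retained[j]}) covered by "
            f"{count[i, j]} < {min_pairs} participants; "
            "run select_covered_rois first")
    with np.errstate(invalid="ignore"):
        values = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    missing = count == 0
    np.fill_diagonal(values, np.where(np.diag(count) > 0,
                                      np.diag(values), np.nan))
    bands = {c.band for c in conns}
    measures = {c.measure for c in conns}
    return ConnectivityMatrix(values=values, node_labels=list(retained),
                              level="roi",
                              band=bands.pop() if len(bands) == 1 else "mixed",
                              measure=(measures.pop()
                                       if len(measures) == 1 else "mixed"),
                              n_segments_used=sum(c.n_segments_used
                                                  for c in conns),
                              missing=missing)
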