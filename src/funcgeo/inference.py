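"""Resampling and permutation statistics on embeddings.

Cohort data are hierarchical — recording sites nested in participants —
so uncertainty is estimated with the cluster bootstrap: participants are
resampled with replacement, ROI connectivity re-averaged, the embedding
recomputed and mapped to the group basis.  Group comparisons (set
distances, hemispheric location and scaling differences) use permutation
tests that exchange labels at the participant level; p-values are
``(1 + exceedances) / (n_perm + 1)`` and therefore never zero.  Multiple
comparisons within a family are controlled with Benjamini–Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .connectivity import average_across_participants
from .embedding import (
    DiffusionOperator,
    Embedding,
    change_of_basis,
    embed_connectivity,
    embedding_distances,
    select_dimensions,
)
from .preprocess import band_envelopes
from .types import (
    ArtifactMask,
    ConnectivityMatrix,
    InsufficientDataError,
    Recording,
)

__all__ = [
    "BootstrapEnsemble",
    "PermutationResult",
    "SnrReport",
    "bootstrap_embeddings",
    "embedding_snr",
    "permutation_distance_test",
    "hemisphere_location_test",
    "hemisphere_scaling_test",
    "anatomical_embedding_regression",
    "auditory_responsiveness",
    "benjamini_hochberg",
]

SNR_CAP = 1e6


@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    p_value: float
    n_perm: int
    n_used: int = 0
    excluded: list = field(default_factory=list)


@dataclass
class BootstrapEnsemble:
    """Cluster-bootstrap ensemble of embeddings in the reference basis."""

    coords: np.ndarray          # (n_boot, n_nodes, k)
    distances: np.ndarray       # (n_boot, n_nodes, n_nodes)
    coordinate_sd: np.ndarray   # (n_nodes, k) ellipsoid semiaxes
    distance_sd: np.ndarray     # (n_nodes, n_nodes)
    node_labels: list
    n_redrawn: int = 0


@dataclass
class SnrReport:
    embedding_snr: float
    connectivity_snr: float
    n_segments: int
    capped: bool = False


def _perm_p(observed: float, null: np.ndarray, two_sided: bool = True
            ) -> float:
    if two_sided:
        exceed = int((np.abs(null) >= abs(observed)).sum())
    else:
        exceed = int((null >= observed).sum())
    return (1 + exceed) / (len(null) + 1)


def benjamini_hochberg(pvals, alpha: float = 0.05):
    """BH step-up FDR control; returns ``(reject, p_adjusted)``."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, p_adj


def bootstrap_embeddings(cohort_conns: list[ConnectivityMatrix],
                         reference: DiffusionOperator,
                         n_boot: int = 1000, seed: int = 0,
                         min_pairs: int = 2, fraction: float = 1.0 / 3.0,
                         t: int = 1, k: int | None = None,
                         max_redraw: int = 1000) -> BootstrapEnsemble:
    """Participant-level cluster bootstrap of the group embedding.

    Each iteration resamples participants with replacement, averages their
    ROI connectivity, re-embeds, and maps the result onto the reference
    eigenbasis.  Iterations whose resample breaks the pair-coverage rule
    are redrawn (counted in ``n_redrawn``).
    """
    if len(cohort_conns) < 1:
        raise InsufficientDataError("no participants")
    rng = np.random.default_rng(seed)
    labels = list(reference.node_labels)
    if k is None:
        _, k = select_dimensions(reference.eigvals)
        k = min(k, reference.n_nodes - 1)
    n_p = len(cohort_conns)
    coords, dists = [], []
    redrawn = 0
    for _ in range(n_boot):
        for _attempt in range(max_redraw):
            idx = rng.integers(0, n_p, size=n_p)
            sample = [cohort_conns[i] for i in idx]
            try:
                avg = average_across_participants(sample, labels,
                                                  min_pairs=min_pairs)
            except InsufficientDataError:
                redrawn += 1
                continue
            break
        else:
            raise InsufficientDataError(
                "could not draw a coverage-respecting bootstrap sample")
        _, emb = embed_connectivity(avg, fraction=fraction, t=t, k=k)
        mapped = change_of_basis(emb, reference)
        coords.append(mapped.coords)
        dists.append(embedding_distances(mapped))
    coords = np.array(coords)
    dists = np.array(dists)
    return BootstrapEnsemble(
        coords=coords, distances=dists,
        coordinate_sd=coords.std(axis=0),
        distance_sd=dists.std(axis=0),
        node_labels=labels, n_redrawn=redrawn)


def embedding_snr(recording: Recording, band, segment_s: float = 60.0,
                  mask: ArtifactMask | None = None,
                  fraction: float = 1.0 / 3.0, t: int = 1) -> SnrReport:
    """Signal-to-noise of embedding distances vs raw connectivity.

    Connectivity (and its embedding distance matrix) is computed per
    60-second segment.  Signal = SD of the across-segment mean matrix's
    off-diagonal entries; noise = the per-element SD across segments,
    averaged.  Both SNRs use the same segmentation.  The retained
    dimensionality is fixed across segments (selected on the mean
    spectrum) so that segment-to-segment variation reflects the data, not
    the dimension choice.
    """
    env = band_envelopes(recording, band, mask=mask)
    frames_per_seg = int(round(segment_s * env.frame_rate))
    conns = []
    from .connectivity import _clean_segments, _directed_envelope_corr
    segs = _clean_segments(env.n_frames, frames_per_seg, env.frame_mask)
    if len(segs) < 3:
        raise InsufficientDataError("SNR needs >= 3 complete segments")
    labels = list(recording.channel_meta.index)
    for sl in segs:
        r = _directed_envelope_corr(env.analytic[:, sl], env.frame_rate)
        values = (r + r.T) / 2.0
        np.fill_diagonal(values, 0.0)
        conns.append(ConnectivityMatrix(values=values, node_labels=labels,
                                        band=str(band), measure="envelope",
                                        n_segments_used=1))
    # fixed k from the segment-mean connectivity spectrum
    mean_conn = ConnectivityMatrix(
        values=np.mean([c.values for c in conns], axis=0),
        node_labels=labels, band=str(band), measure="envelope")
    op_mean, _ = embed_connectivity(mean_conn, fraction=fraction, t=t, k=2)
    _, k_fixed = select_dimensions(op_mean.eigvals)
    k_fixed = min(k_fixed, len(labels) - 1)
    dmats = []
    for c in conns:
        _, emb = embed_connectivity(c, fraction=fraction, t=t, k=k_fixed)
        dmats.append(embedding_distances(emb))
    dmats = np.array(dmats)
    cmats = np.array([c.values for c in conns])

    def snr(stack: np.ndarray) -> tuple[float, bool]:
        n = stack.shape[1]
        iu = np.triu_indices(n, k=1)
        mean_mat = stack.mean(axis=0)
        sig = mean_mat[iu].std()
        noise = stack.std(axis=0)[iu].mean()
        if noise == 0:
            return SNR_CAP, True
        return float(sig / noise), False

    e_snr, cap1 = snr(dmats)
    c_snr, cap2 = snr(cmats)
    return SnrReport(embedding_snr=e_snr, connectivity_snr=c_snr,
                     n_segments=len(segs), capped=cap1 or cap2)


def _dist_lookup(emb: Embedding) -> tuple[dict, np.ndarray]:
    return ({l: i for i, l in enumerate(emb.node_labels)},
            embedding_distances(emb))


def permutation_distance_test(per_participant_embeddings: list[Embedding],
                              node_a, node_b, target_set: list,
                              n_perm: int = 10000, seed: int = 0
                              ) -> PermutationResult:
    """Do two nodes sit at different average distances from a target set?

    Per participant, the statistic is the mean over available targets of
    ``dist(node_a, target) - dist(node_b, target)``; the cohort statistic
    is the participant mean.  The null exchanges the A/B labels
    independently per participant (sign flips).  Participants missing
    either node (or every target) are excluded and logged.
    """
    import warnings as _w
    if n_perm < 100:
        _w.warn("n_perm < 100 gives a coarse permutation p-value")
    diffs, excluded = [], []
    for i, emb in enumerate(per_participant_embeddings):
        pos, d = _dist_lookup(emb)
        if node_a not in pos or node_b not in pos:
            excluded.append(i)
            continue
        targets = [t for t in target_set if t in pos
                   and t not in (node_a, node_b)]
        if not targets:
            excluded.append(i)
            continue
        ti = [pos[t] for t in targets]
        diffs.append(d[pos[node_a], ti].mean() - d[pos[node_b], ti].mean())
    if not diffs:
        raise InsufficientDataError("no participant carries both nodes")
    diffs = np.asarray(diffs)
    observed = float(diffs.mean())
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, len(diffs)))
    null = (signs * diffs[None, :]).mean(axis=1)
    return PermutationResult(observed=observed, null=null,
                             p_value=_perm_p(observed, null),
                             n_perm=n_perm, n_used=len(diffs),
                             excluded=excluded)


def hemisphere_location_test(cohort_a_coords: list[np.ndarray],
                             cohort_b_coords: list[np.ndarray],
                             n_perm: int = 10000, seed: int = 0,
                             alpha: float = 0.05,
                             node_labels=None) -> pd.DataFrame:
    """Per-node displacement between two cohorts' average embeddings.

    Coordinates must already live in a common basis (map each participant
    or cohort embedding with :func:`funcgeo.embedding.change_of_basis`
    against the all-participant reference first).  The null redistributes
    participants between cohorts; per-node p-values are BH-FDR adjusted.
    """
    if len(cohort_a_coords) < 2 or len(cohort_b_coords) < 2:
        raise InsufficientDataError("each cohort needs >= 2 participants")
    a = np.array(cohort_a_coords)
    b = np.array(cohort_b_coords)
    n_a = a.shape[0]
    pooled = np.concatenate([a, b], axis=0)
    n_tot = pooled.shape[0]
    obs = np.linalg.norm(a.mean(axis=0) - b.mean(axis=0), axis=1)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, pooled.shape[1]))
    for i in range(n_perm):
        idx = rng.permutation(n_tot)
        ga = pooled[idx[:n_a]].mean(axis=0)
        gb = pooled[idx[n_a:]].mean(axis=0)
        null[i] = np.linalg.norm(ga - gb, axis=1)
    p = (1 + (null >= obs[None, :]).sum(axis=0)) / (n_perm + 1)
    reject, p_adj = benjamini_hochberg(p, alpha=alpha)
    if node_labels is None:
        node_labels = list(range(pooled.shape[1]))
    return pd.DataFrame({"node": node_labels, "displacement": obs,
                         "p": p, "p_adj": p_adj,
                         "significant": reject}).set_index("node")


@dataclass
class ScalingTestResult:
    slope: float
    p_slope: float
    residuals: pd.DataFrame      # per-pair residual difference, p, p_adj
    n_perm: int


def _origin_slope(x: np.ndarray, y: np.ndarray) -> float:
    return float((x * y).sum() / (x * x).sum())


def hemisphere_scaling_test(dists_a: list[np.ndarray],
                            dists_b: list[np.ndarray],
                            n_perm: int = 10000, seed: int = 0,
                            alpha: float = 0.05,
                            node_labels=None) -> ScalingTestResult:
    """Multiplicative scaling between two cohorts' pairwise distances.

    The slope of the regression through the origin of cohort-B group
    distances on cohort-A group distances estimates a global multiplicative
    factor (slope < 1: distances longer in A).  Its deviation from 1 is
    tested by permuting the cohort assignment of participants.  After
    dividing B by the slope, per-pair residual differences are tested the
    same way with BH-FDR.
    """
    a = np.array(dists_a)
    b = np.array(dists_b)
    n_a = a.shape[0]
    n = a.shape[1]
    iu = np.triu_indices(n, k=1)
    av = a[:, iu[0], iu[1]]
    bv = b[:, iu[0], iu[1]]
    ga, gb = av.mean(axis=0), bv.mean(axis=0)
    if ga.std() == 0 or gb.std() == 0:
        raise InsufficientDataError("degenerate (all-equal) distances")
    slope = _origin_slope(ga, gb)
    resid_obs = gb / slope - ga
    pooled = np.concatenate([av, bv], axis=0)
    n_tot = pooled.shape[0]
    rng = np.random.default_rng(seed)
    null_slope = np.empty(n_perm)
    null_resid = np.empty((n_perm, len(ga)))
    for i in range(n_perm):
        idx = rng.permutation(n_tot)
        pa = pooled[idx[:n_a]].mean(axis=0)
        pb = pooled[idx[n_a:]].mean(axis=0)
        s = _origin_slope(pa, pb)
        null_slope[i] = s
        null_resid[i] = pb / s - pa
    p_slope = (1 + (np.abs(null_slope - 1.0)
                    >= abs(slope - 1.0)).sum()) / (n_perm + 1)
    p_pairs = (1 + (np.abs(null_resid) >= np.abs(resid_obs)[None, :])
               .sum(axis=0)) / (n_perm + 1)
    reject, p_adj = benjamini_hochberg(p_pairs, alpha=alpha)
    if node_labels is None:
        node_labels = list(range(n))
    pairs = [(node_labels[i], node_labels[j])
             for i, j in zip(iu[0], iu[1])]
    residuals = pd.DataFrame({"pair": pairs, "residual": resid_obs,
                              "p": p_pairs, "p_adj": p_adj,
                              "significant": reject})
    return ScalingTestResult(slope=slope, p_slope=float(p_slope),
                             residuals=residuals, n_perm=n_perm)


def anatomical_embedding_regression(anat_dist: np.ndarray,
                                    embed_dist: np.ndarray
                                    ) -> tuple[np.ndarray, float]:
    """Per-node adjusted r² of embedding distance on anatomical distance.

    For each node, its embedding distances to all other nodes are
    regressed on the corresponding anatomical distances; returns the
    per-node adjusted r² values and their mean.
    """
    anat = np.asarray(anat_dist, dtype=float)
    emb = np.asarray(embed_dist, dtype=float)
    if anat.shape != emb.shape:
        raise ValueError("distance matrices differ in shape")
    n = anat.shape[0]
    if n < 4:
        raise InsufficientDataError("need >= 4 nodes")
    out = np.empty(n)
    for i in range(n):
        others = np.arange(n) != i
        x, y = anat[i, others], emb[i, others]
        m = len(x)
        r = stats.pearsonr(x, y).statistic if x.std() > 0 and y.std() > 0 else 0.0
        r2 = r ** 2
        out[i] = 1.0 - (1.0 - r2) * (m - 1) / (m - 2)
    return out, float(out.mean())


def auditory_responsiveness(trials: np.ndarray, times: np.ndarray,
                            roi_labels, alpha: float = 0.05,
                            min_trials: int = 10) -> pd.DataFrame:
    """Percent of sites per ROI with significant high-gamma responses.

    ``trials`` is sites x trials x time of high-gamma power; ``times`` is
    seconds relative to stimulus onset.  Per site, the trial-mean power in
    the early (50–350 ms) and late (350–650 ms) windows is compared with
    the prestimulus baseline (−200 to −100 ms) by one-tailed Mann–Whitney
    U (response > baseline), BH-FDR corrected across sites within each
    window family.
    """
    x = np.asarray(trials, dtype=float)
    times = np.asarray(times, dtype=float)
    windows = {"early": (0.050, 0.350), "late": (0.350, 0.650)}
    base_sel = (times >= -0.200) & (times < -0.100)
    sig = {}
    kept = x.shape[1] >= min_trials
    n_sites = x.shape[0]
    if not kept:
        raise InsufficientDataError(
            f"need >= {min_trials} trials per site")
    for wname, (lo, hi) in windows.items():
        sel = (times >= lo) & (times < hi)
        pvals = np.empty(n_sites)
        for s in range(n_sites):
            post = x[s, :, sel].mean(axis=0)
            base = x[s, :, base_sel].mean(axis=0)
            if np.ptp(post) == 0 and np.ptp(base) == 0 and post[0] == base[0]:
                pvals[s] = 1.0
                continue
            pvals[s] = stats.mannwhitneyu(post, base,
                                          alternative="greater").pvalue
        reject, _ = benjamini_hochberg(pvals, alpha=alpha)
        sig[wname] = reject
    df = pd.DataFrame({"roi": list(roi_labels),
                       "early": sig["early"], "late": sig["late"]})
    out = df.groupby("roi").agg(
        n_sites=("early", "size"),
        pct_early=("early", lambda v: 100.0 * v.mean()),
        pct_late=("late", lambda v: 100.0 * v.mean()))
    return out
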