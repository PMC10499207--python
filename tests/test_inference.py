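"""Bootstrap, SNR, permutation tests, regression, FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from funcgeo import embedding as em
from funcgeo import inference as inf
from funcgeo import synthetic as syn
from funcgeo.embedding import Embedding
from funcgeo.types import ConnectivityMatrix, InsufficientDataError


def _embedding(coords, labels=None):
    coords = np.asarray(coords, dtype=float)
    n, k = coords.shape
    if labels is None:
        labels = list(range(n))
    return Embedding(coords=coords, t=1, k_infl=k + 1,
                     spectrum=np.ones(n), basis=np.zeros((n, k)),
                     node_labels=labels)


def _roi_conns(n_participants, n_rois, noise, rng):
    """Per-participant ROI connectivity: common structure + noise."""
    base, _ = syn.planted_hub_connectivity(n_nodes=n_rois,
                                           rng=np.random.default_rng(0))
    out = []
    for _ in range(n_participants):
        e = rng.normal(0, noise, (n_rois, n_rois))
        v = np.clip(base + (e + e.T) / 2, 0.01, 0.99)
        np.fill_diagonal(v, 0.0)
        out.append(ConnectivityMatrix(values=v, level="roi",
                                      node_labels=list(range(n_rois))))
    return out


class TestBootstrap:
    def _reference(self, conns):
        from funcgeo.connectivity import average_across_participants
        avg = average_across_participants(conns, conns[0].node_labels,
                                          min_pairs=1)
        op, _ = em.embed_connectivity(avg, k=3)
        return op

    def test_single_participant_zero_spread(self, rng):
        conns = _roi_conns(1, 10, 0.05, rng)
        ref = self._reference(conns)
        ens = inf.bootstrap_embeddings(conns, ref, n_boot=20, seed=1,
                                       min_pairs=1, k=3)
        assert np.allclose(ens.coordinate_sd, 0.0, atol=1e-12)
        assert np.allclose(ens.distance_sd, 0.0, atol=1e-12)

    def test_seed_determinism(self, rng):
        conns = _roi_conns(5, 10, 0.05, rng)
        ref = self._reference(conns)
        e1 = inf.bootstrap_embeddings(conns, ref, n_boot=15, seed=9,
                                      min_pairs=1, k=3)
        e2 = inf.bootstrap_embeddings(conns, ref, n_boot=15, seed=9,
                                      min_pairs=1, k=3)
        assert np.array_equal(e1.coords, e2.coords)

    def test_log_log_scaling_slope(self):
        """Bootstrap SD vs cohort size has log-log slope near -1/2.

        Run on the dense (unthresholded) graph: the hard top-third rule
        adds a discrete edge-flip component that floors the SD at small
        noise, masking the smooth 1/sqrt(N) behaviour of the mean."""
        rng = np.random.default_rng(4)
        sizes = [6, 12, 24, 48]
        sds = []
        from funcgeo.connectivity import average_across_participants
        for n_p in sizes:
            conns = _roi_conns(n_p, 12, 0.08, rng)
            avg = average_across_participants(
                conns, conns[0].node_labels, min_pairs=1)
            ref, _ = em.embed_connectivity(avg, fraction=1.0, k=2)
            ens = inf.bootstrap_embeddings(conns, ref, n_boot=120, seed=2,
                                           min_pairs=1, fraction=1.0, k=2)
            sds.append(ens.coordinate_sd.mean())
        slope = np.polyfit(np.log(sizes), np.log(sds), 1)[0]
        assert -0.65 < slope < -0.35


class TestSnr:
    def test_embedding_snr_runs(self, tiny_recording):
        rep = inf.embedding_snr(tiny_recording, "gamma", segment_s=30.0)
        assert rep.n_segments == 5
        assert rep.embedding_snr > 0
        assert rep.connectivity_snr > 0

    def test_embedding_snr_beats_connectivity_snr(self):
        """On a default-condition cohort the embedding distance matrix is
        more stable across segments than raw connectivity for the
        majority of participants."""
        cfg = syn.CohortConfig(seed=11,
                               bands=(("gamma", 30.0, 50.0),))
        wins = 0
        for p in range(cfg.n_participants):
            rec = syn.generate_coupled_signals(cfg, p)
            rep = inf.embedding_snr(rec, "gamma")
            wins += rep.embedding_snr > rep.connectivity_snr
        assert wins > cfg.n_participants / 2

    def test_too_few_segments(self, rng):
        from conftest import make_recording
        rec = make_recording(rng.standard_normal((4, int(70 * 250))),
                             fs=250.0)
        with pytest.raises(InsufficientDataError):
            inf.embedding_snr(rec, "gamma")


class TestPermutationDistance:
    def _cohort(self, rng, n_part=8, shift=0.0):
        embs = []
        labels = ["A", "B"] + [f"T{i}" for i in range(6)]
        for _ in range(n_part):
            pts = rng.standard_normal((8, 3))
            pts[0] = pts[1] + shift          # A placed relative to B
            embs.append(_embedding(pts, labels))
        return embs

    def test_identical_nodes_never_significant(self, rng):
        embs = self._cohort(rng, shift=0.0)
        for e in embs:
            e.coords[0] = e.coords[1]        # A == B exactly
        res = inf.permutation_distance_test(
            embs, "A", "B", [f"T{i}" for i in range(6)],
            n_perm=500, seed=0)
        assert res.observed == 0.0
        assert res.p_value == 1.0

    def test_p_value_floor_attained(self):
        rng = np.random.default_rng(0)
        labels = ["A", "B", "T0", "T1", "T2"]
        embs = []
        for _ in range(16):                  # 2^15 sign patterns >> n_perm
            pts = rng.standard_normal((5, 2))
            pts[0] = pts[1] + 5.0            # A consistently farther
            embs.append(_embedding(pts, labels))
        res = inf.permutation_distance_test(embs, "A", "B",
                                            ["T0", "T1", "T2"],
                                            n_perm=2000, seed=3)
        assert res.p_value == pytest.approx(1 / 2001)

    def test_missing_node_excluded(self, rng):
        embs = self._cohort(rng)
        embs.append(_embedding(rng.standard_normal((3, 3)),
                               ["X", "Y", "Z"]))
        res = inf.permutation_distance_test(
            embs, "A", "B", [f"T{i}" for i in range(6)],
            n_perm=200, seed=0)
        assert res.excluded == [len(embs) - 1]
        assert res.n_used == len(embs) - 1


class TestHemisphereLocation:
    def test_null_split_no_survivors(self, rng):
        pooled = [rng.standard_normal((10, 3)) for _ in range(12)]
        out = inf.hemisphere_location_test(pooled[:6], pooled[6:],
                                           n_perm=500, seed=1)
        assert not out["significant"].any()

    def test_displaced_node_detected(self, rng):
        a = [rng.standard_normal((10, 3)) * 0.2 for _ in range(8)]
        b = [x.copy() for x in
             (rng.standard_normal((10, 3)) * 0.2 for _ in range(8))]
        for x in b:
            x[4] += 3.0                      # node 4 displaced in cohort B
        out = inf.hemisphere_location_test(a, b, n_perm=500, seed=1)
        assert out["p"].idxmin() == 4
        assert out.loc[4, "significant"]

    def test_small_cohort_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            inf.hemisphere_location_test([rng.standard_normal((4, 2))],
                                         [rng.standard_normal((4, 2))],
                                         n_perm=10, seed=0)


class TestHemisphereScaling:
    def _dists(self, rng, n_part, n_nodes=10, scale=1.0, noise=0.02,
               pair_bump=None):
        out = []
        base = squareform(pdist(np.random.default_rng(0)
                                .standard_normal((n_nodes, 3))))
        for _ in range(n_part):
            d = scale * base + noise * np.abs(
                rng.standard_normal(base.shape))
            d = (d + d.T) / 2
            if pair_bump is not None:
                i, j = pair_bump
                d[i, j] = d[j, i] = d[i, j] + 1.5
            np.fill_diagonal(d, 0.0)
            out.append(d)
        return out

    def test_identical_cohorts_slope_one(self, rng):
        a = self._dists(rng, 6)
        res = inf.hemisphere_scaling_test(a, [x.copy() for x in a],
                                          n_perm=400, seed=0)
        assert res.slope == pytest.approx(1.0, abs=0.01)
        assert res.p_slope > 0.05

    def test_planted_scaling_recovered(self, rng):
        a = self._dists(rng, 8)
        b = self._dists(rng, 8, scale=0.8)
        res = inf.hemisphere_scaling_test(a, b, n_perm=1000, seed=0)
        assert 0.75 <= res.slope <= 0.85
        assert res.p_slope < 0.05

    def test_planted_pair_flagged_after_scaling(self, rng):
        a = self._dists(rng, 8)
        b = self._dists(rng, 8, scale=0.8, pair_bump=(2, 7))
        res = inf.hemisphere_scaling_test(a, b, n_perm=1000, seed=0)
        sig = res.residuals[res.residuals["significant"]]
        assert (2, 7) in list(sig["pair"])

    def test_degenerate_distances_rejected(self):
        flat = [np.ones((5, 5)) - np.eye(5)] * 4
        with pytest.raises(InsufficientDataError):
            inf.hemisphere_scaling_test(flat, flat, n_perm=10, seed=0)


class TestAnatomicalRegression:
    def test_identity_gives_r2_one(self, rng):
        d = squareform(pdist(rng.standard_normal((10, 3))))
        per_node, mean = inf.anatomical_embedding_regression(d, d)
        assert np.allclose(per_node, 1.0)
        assert mean == pytest.approx(1.0)

    def test_independent_distances_near_zero(self):
        means = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = squareform(pdist(rng.standard_normal((30, 3))))
            b = squareform(pdist(rng.standard_normal((30, 3))))
            means.append(inf.anatomical_embedding_regression(a, b)[1])
        assert abs(np.mean(means)) < 0.05

    def test_planted_linear_relation_recovered(self, rng):
        anat = squareform(pdist(rng.standard_normal((30, 3))))
        noise = rng.standard_normal(anat.shape) * 0.3
        emb_d = 0.4 * anat + np.abs(noise + noise.T) / 2
        np.fill_diagonal(emb_d, 0.0)
        per_node, mean = inf.anatomical_embedding_regression(anat, emb_d)
        # empirical R^2 per node, computed independently
        r2s = []
        for i in range(30):
            o = np.arange(30) != i
            r = np.corrcoef(anat[i, o], emb_d[i, o])[0, 1]
            m = o.sum()
            r2s.append(1 - (1 - r ** 2) * (m - 1) / (m - 2))
        assert mean == pytest.approx(np.mean(r2s), abs=1e-12)
        assert abs(mean - np.mean(r2s)) < 0.05


class TestAuditoryResponsiveness:
    def _trials(self, rng, n_sites=12, n_trials=30, effect_sites=(),
                window="early"):
        """Smooth (autocorrelated) power traces, as band power is."""
        from scipy.ndimage import uniform_filter1d
        times = np.arange(-0.3, 0.8, 0.01)
        raw = rng.standard_normal((n_sites, n_trials, len(times) + 20))
        x = uniform_filter1d(raw, size=5, axis=-1)[..., 20:] ** 2
        lo, hi = (0.05, 0.35) if window == "early" else (0.35, 0.65)
        sel = (times >= lo) & (times < hi)
        for s in effect_sites:
            x[s][:, sel] += 3.0
        return x, times

    def test_null_rarely_flags(self, rng):
        x, times = self._trials(rng)
        out = inf.auditory_responsiveness(
            x, times, roi_labels=["R"] * 12)
        assert out.loc["R", "pct_early"] <= 20.0

    def test_early_effect_flagged_early_not_late(self, rng):
        x, times = self._trials(rng, effect_sites=(0, 1, 2, 3, 4, 5),
                                window="early")
        labels = ["hit"] * 6 + ["miss"] * 6
        out = inf.auditory_responsiveness(x, times, roi_labels=labels)
        assert out.loc["hit", "pct_early"] == 100.0
        assert out.loc["hit", "pct_late"] <= 40.0
        assert out.loc["miss", "pct_early"] <= 40.0

    def test_all_tied_powers_give_p_one(self):
        x = np.ones((3, 15, 110))
        times = np.arange(-0.3, 0.8, 0.01)
        out = inf.auditory_responsiveness(x, times, roi_labels=["R"] * 3)
        assert out.loc["R", "pct_early"] == 0.0

    def test_too_few_trials_rejected(self, rng):
        x, times = self._trials(rng, n_trials=5)
        with pytest.raises(InsufficientDataError):
            inf.auditory_responsiveness(x, times, roi_labels=["R"] * 12)


class TestBenjaminiHochberg:
    def test_hand_worked_step_up(self):
        reject, _ = inf.benjamini_hochberg([0.01, 0.02, 0.03, 0.5],
                                           alpha=0.05)
        assert list(reject) == [True, True, True, False]

    def test_all_ones_none_rejected(self):
        reject, _ = inf.benjamini_hochberg([1.0] * 5)
        assert not reject.any()

    def test_single_p(self):
        assert inf.benjamini_hochberg([0.04], alpha=0.05)[0][0]
        assert not inf.benjamini_hochberg([0.06], alpha=0.05)[0][0]

    def test_matches_exhaustive_step_up(self, rng):
        """Agreement with the closed-form step-up rule on random lists."""
        for _ in range(50):
            m = rng.integers(1, 10)
            p = np.round(rng.random(m), 3)
            reject, _ = inf.benjamini_hochberg(p, alpha=0.05)
            order = np.argsort(p)
            thresh = 0.05 * (np.arange(1, m + 1)) / m
            passed = np.flatnonzero(p[order] <= thresh)
            expected = np.zeros(m, dtype=bool)
            if len(passed):
                expected[order[: passed.max() + 1]] = True
            assert np.array_equal(reject, expected)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            inf.benjamini_hochberg([0.1, 1.4])
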