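"""Ternarize/PCA/K-means clustering, extremum timing, spatial overlap."""

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from tonicpag import calcium, clustering, escape_response as er, synth
from tonicpag.clustering import (
    cluster_k,
    embed_pca,
    extremum_timing,
    spatial_overlap,
    ternarize,
    timing_tests,
)
from tonicpag.spiketrain import InsufficientDataError


class TestTernarize:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.5, 1), (-0.5, -1), (0.1, 0), (0.2, 0), (-0.2, 0), (0.2000001, 1)],
    )
    def test_thresholds(self, value, expected):
        assert ternarize(np.array([value]))[0] == expected

    def test_matrix_shape_preserved(self):
        x = np.linspace(-1, 1, 12).reshape(3, 4)
        assert ternarize(x).shape == (3, 4)

    def test_bad_thresholds_raise(self):
        with pytest.raises(ValueError):
            ternarize(np.zeros(3), lo=0.2, hi=-0.2)


class TestPca:
    def test_rank_one_matrix(self):
        base = np.sin(np.arange(20))
        x = np.outer([1.0, 2.0, 3.0, 4.0, 5.0], base)
        _, evr = embed_pca(x)
        assert evr[0] == pytest.approx(1.0)

    def test_two_motifs_dominate_variance(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 1, 50)
        m1, m2 = np.sin(2 * np.pi * t), np.cos(2 * np.pi * t)
        rows = [m1 + rng.normal(0, 0.05, 50) for _ in range(10)]
        rows += [m2 + rng.normal(0, 0.05, 50) for _ in range(10)]
        _, evr = embed_pca(np.array(rows))
        assert evr[:2].sum() > 0.9

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(12, 30))
        perm = rng.permutation(12)
        s1, _ = embed_pca(x)
        s2, _ = embed_pca(x[perm])
        # scores follow their rows (up to component sign)
        for comp in range(3):
            col = s2[np.argsort(perm), comp]
            assert (
                np.allclose(col, s1[:, comp], atol=1e-8)
                or np.allclose(col, -s1[:, comp], atol=1e-8)
            )

    def test_too_few_neurons_raise(self):
        with pytest.raises(InsufficientDataError):
            embed_pca(np.zeros((3, 30)))


class TestClusterK:
    def blobs(self, seed=0, n=40, sep=8.0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, size=(n, 3))
        b = rng.normal(0, 1, size=(n, 3)) + sep
        return np.vstack([a, b]), np.array([0] * n + [1] * n)

    def test_two_blobs_recovered(self):
        scores, truth = self.blobs()
        wm = np.where(truth == 0, 1.0, -1.0)
        res = cluster_k(scores, window_means=wm, seed=0)
        assert res.chosen_k == 2
        assert adjusted_rand_score(truth, res.labels) > 0.95

    def test_identity_mapping_by_window_sign(self):
        scores, truth = self.blobs(seed=2)
        wm = np.where(truth == 0, 0.8, -0.5)
        res = cluster_k(scores, window_means=wm, seed=0)
        # the positive-response blob must be cluster 1 regardless of k-means labels
        assert np.all(res.labels[truth == 0] == 1)
        assert np.all(res.labels[truth == 1] == 2)

    def test_single_blob_scores_far_below_true_clusters(self):
        # a split isotropic blob cannot reach the silhouette of genuinely
        # separated groups; the clusterable flag compares against the floor
        rng = np.random.default_rng(3)
        single = cluster_k(rng.normal(size=(60, 3)), seed=0)
        scores, _ = self.blobs(seed=3)
        separated = cluster_k(scores, seed=0)
        best_single = max(single.silhouette_by_k.values())
        best_separated = max(separated.silhouette_by_k.values())
        assert best_single < 0.5 * best_separated
        assert separated.clusterable

    def test_identical_rows_fallback(self):
        res = cluster_k(np.ones((10, 3)), seed=0)
        assert res.chosen_k == 1
        assert not res.clusterable

    def test_seed_determinism(self):
        scores, truth = self.blobs(seed=4)
        wm = np.where(truth == 0, 1.0, -1.0)
        r1 = cluster_k(scores, window_means=wm, seed=5)
        r2 = cluster_k(scores, window_means=wm, seed=5)
        np.testing.assert_array_equal(r1.labels, r2.labels)
        assert r1.silhouette_by_k == r2.silhouette_by_k


class TestExtremumTiming:
    def test_peak_at_escape_end_is_zero(self):
        grid = np.arange(0, 5, 1 / 30)
        x = -np.abs(grid - 3.0)
        assert extremum_timing(x, grid, identity=1, escape_stop_time=3.0) == pytest.approx(
            0.0, abs=1 / 30
        )

    def test_tie_breaks_to_earliest(self):
        grid = np.arange(0, 1, 0.1)
        x = np.zeros_like(grid)
        x[[3, 7]] = 1.0
        t = extremum_timing(x, grid, identity=1, escape_stop_time=0.0)
        assert t == pytest.approx(0.3)

    def test_ramp_and_dip_fixture_timing(self, clean_fast_session):
        """Construction check on warped means: ramp peak at escape end, dip
        trough between the reaction and run anchors."""
        s = clean_fast_session
        esc = [t for t in s.trials if t.outcome == "escape"]
        tmpl = er.build_template(
            [{k: v - t.stimulus_onset for k, v in t.events.items()} for t in esc]
        )
        means = {}
        for motif in ("ramp", "dip"):
            i = s.motifs.index(motif)
            trials = []
            for t in esc:
                z = er.baseline_subtract(s.traces[i], s.frame_rate, t.stimulus_onset)
                trials.append((z, t.events, t.outcome))
            means[motif] = er.mean_response(trials, s.frame_rate, tmpl).mean_escape
        stop_t = tmpl.anchor_time("escape_stop")
        peak = extremum_timing(means["ramp"], tmpl.grid, 1, stop_t)
        assert abs(peak) <= 1.5 / tmpl.grid_rate
        trough = extremum_timing(means["dip"], tmpl.grid, 2, stop_t)
        trough_abs = trough + stop_t
        assert tmpl.anchor_time("reaction") - 1 / tmpl.grid_rate <= trough_abs
        assert trough_abs <= tmpl.anchor_time("run") + 1 / tmpl.grid_rate


class TestTimingTests:
    def test_symmetric_times_not_significant(self):
        rng = np.random.default_rng(0)
        times = rng.normal(0.0, 0.5, 30)
        out = timing_tests(times, {"escape_stop": float(times.mean())}, kind="t")
        assert not out["significant"].iloc[0]

    def test_shifted_times_significant(self):
        rng = np.random.default_rng(1)
        times = rng.normal(-2.0, 0.1, 20)
        out = timing_tests(times, {"startle": 0.0, "run": -0.5}, kind="t")
        assert out["significant"].all()

    def test_holm_ordering(self):
        rng = np.random.default_rng(2)
        times = rng.normal(-1.0, 0.2, 15)
        anchors = {"a": 0.0, "b": -1.0, "c": -3.0}
        out = timing_tests(times, anchors, kind="t").set_index("anchor")
        m = len(anchors)
        smallest = out["p_raw"].min()
        # Holm: the smallest raw p is compared against alpha/m, i.e. scaled by m
        row = out[out["p_raw"] == smallest].iloc[0]
        assert row["p_holm"] == pytest.approx(min(1.0, smallest * m))

    def test_sign_test_variant(self):
        times = np.array([-2.1, -1.9, -2.0, -2.2, -1.8, -2.05, -1.95])
        out = timing_tests(times, {"stop": 0.0}, kind="sign")
        assert out["significant"].iloc[0]

    def test_too_few_values_raise(self):
        with pytest.raises(InsufficientDataError):
            timing_tests([0.1, 0.2], {"a": 0.0})


class TestSpatialOverlap:
    def test_identical_point_sets(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 50, size=(6, 2))
        both = np.vstack([pts, pts])
        labels = np.array([1] * 6 + [2] * 6)
        res = spatial_overlap(both, labels, n_permutations=50, seed=0)
        assert res.jaccard == pytest.approx(1.0)

    def test_disjoint_halves(self):
        rng = np.random.default_rng(1)
        left = rng.uniform([0, 0], [20, 100], size=(15, 2))
        right = rng.uniform([80, 0], [100, 100], size=(15, 2))
        labels = np.array([1] * 15 + [2] * 15)
        res = spatial_overlap(np.vstack([left, right]), labels,
                              n_permutations=500, seed=1)
        assert res.jaccard == 0.0
        assert res.permutation_p < 0.05

    def test_label_order_symmetry(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 100, size=(20, 2))
        labels = np.array([1] * 10 + [2] * 10)
        j1, _ = clustering._jaccard(pts, labels)
        j2, _ = clustering._jaccard(pts, 3 - labels)
        assert j1 == pytest.approx(j2)

    def test_null_p_values_uniform(self):
        """Random labels on uniform points: permutation p ~ U(0,1)."""
        rng = np.random.default_rng(3)
        ps = []
        for rep in range(60):
            pts = rng.uniform(0, 100, size=(30, 2))
            labels = np.array([1] * 15 + [2] * 15)
            rng.shuffle(labels)
            res = spatial_overlap(pts, labels, n_permutations=199, seed=rep)
            ps.append(res.permutation_p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_collinear_fallback_flagged(self):
        pts = np.array([[0, 0], [1, 0], [2, 0], [10, 10], [11, 12], [12, 10]], float)
        labels = np.array([1, 1, 1, 2, 2, 2])
        res = spatial_overlap(pts, labels, n_permutations=20, seed=0)
        assert res.hull_fallback

    def test_too_few_per_cluster_raise(self):
        pts = np.zeros((4, 2))
        with pytest.raises(InsufficientDataError):
            spatial_overlap(pts, [1, 1, 2, 2], n_permutations=10)


class TestFullClusteringPipeline:
    def cluster_session(self, session, seed):
        esc = [t for t in session.trials if t.outcome == "escape"]
        tmpl = er.build_template(
            [{k: v - t.stimulus_onset for k, v in t.events.items()} for t in esc]
        )
        means, wms = [], []
        for i in range(session.n_neurons):
            trials = []
            for t in session.trials:
                z = er.baseline_subtract(
                    session.traces[i], session.frame_rate, t.stimulus_onset
                )
                trials.append((z, t.events, t.outcome))
            r = er.mean_response(trials, session.frame_rate, tmpl)
            means.append(r.mean_escape)
            wms.append(r.window_mean_escape)
        filt = np.vstack([calcium.lowpass_fft(m, tmpl.grid_rate) for m in means])
        scores, _ = embed_pca(ternarize(filt))
        return cluster_k(scores, window_means=np.array(wms), seed=seed)

    def test_two_motif_recovery(self, two_motif_session):
        res = self.cluster_session(two_motif_session, seed=0)
        truth = [1 if m == "ramp" else 2 for m in two_motif_session.motifs]
        assert res.chosen_k == 2
        assert adjusted_rand_score(truth, res.labels) > 0.9
        # ramp-like group must carry identity 1
        assert np.all(res.labels[: two_motif_session.spec.n_ramp] == 1)

    def test_recovery_robust_over_seeds(self):
        """Generator replicates at the study's noise level: k = 2 selected
        and motifs recovered (ARI > 0.9) in >= 95% of replicates."""
        ok = 0
        n_rep = 20
        for seed in range(n_rep):
            s = synth.gen_session(
                synth.SessionSpec(n_ramp=72, n_dip=48, n_unmod=0, seed=200 + seed)
            )
            res = self.cluster_session(s, seed=seed)
            truth = [1 if m == "ramp" else 2 for m in s.motifs]
            ok += res.chosen_k == 2 and adjusted_rand_score(truth, res.labels) > 0.9
        assert ok >= 0.95 * n_rep

    def test_pipeline_determinism(self, two_motif_session):
        r1 = self.cluster_session(two_motif_session, seed=3)
        r2 = self.cluster_session(two_motif_session, seed=3)
        np.testing.assert_array_equal(r1.labels, r2.labels)
        assert r1.silhouette_by_k == r2.silhouette_by_k

    def test_explained_variance_monotone(self, two_motif_session):
        res = self.cluster_session(two_motif_session, seed=0)  # warm path
        rng = np.random.default_rng(0)
        _, evr = embed_pca(rng.normal(size=(30, 40)))
        assert evr.sum() <= 1.0 + 1e-9
        assert np.all(np.diff(evr) <= 1e-12)
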