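"""Re-labeling, WSS/K-selection, clustering, control assignment, overlap."""

import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from ramahet.heterogeneity import (SPECTRAL_NECROTIC, SPECTRAL_VITAL,
                                   AssignmentResult, RelabeledSet,
                                   SpectralKMeans, embed, fit_clusters,
                                   necrosis_probability_overlay,
                                   overlap_report, relabel,
                                   rounded_percentages, select_k,
                                   subsample_per_patient, summarize_clusters,
                                   wss_curve)

from conftest import flat_set


class _StubModel:
    """Duck-typed classifier: fixed scores and threshold."""

    grid_hash = None

    def __init__(self, scores, threshold):
        self._scores = np.asarray(scores, dtype=float)
        self.threshold_ = threshold

    def score_samples(self, X):
        return self._scores[:len(X)]


# ---------------------------------------------------------------------------
# relabel / subsample
# ---------------------------------------------------------------------------

class TestRelabel:
    def test_boundary_convention_score_ge_threshold(self, grid_small):
        sset = flat_set(grid_small, np.random.default_rng(0).normal(size=(3, 256)))
        relab = relabel(_StubModel([0.40, 0.452, 0.60], 0.452), sset)
        assert relab.labels.tolist() == [SPECTRAL_VITAL, SPECTRAL_NECROTIC,
                                         SPECTRAL_NECROTIC]

    def test_counts_bookkeeping(self, grid_small):
        rng = np.random.default_rng(1)
        scores = rng.random(40)
        sset = flat_set(grid_small, rng.normal(size=(40, 256)))
        relab = relabel(_StubModel(scores, 0.452), sset)
        n_necro = int((scores >= 0.452).sum())
        assert relab.counts == {SPECTRAL_NECROTIC: n_necro,
                                SPECTRAL_VITAL: 40 - n_necro}
        assert relab.vital_subset().n == 40 - n_necro

    def test_control_spectra_rejected(self, grid_small):
        sset = flat_set(grid_small, np.ones((3, 256)) + np.eye(3, 256))
        sset.meta.loc[sset.spectrum_ids[0], "class_label"] = "control_gray"
        with pytest.raises(ValueError, match="control"):
            relabel(_StubModel([0.1] * 3, 0.5), sset)

    def test_separated_necrosis_scores_high(self, small_study):
        """On the planted cohort nearly all true-necrosis spectra are removed."""
        assert small_study["headline"]["necrosis_profile_removed_fraction"] >= 0.95


def test_subsample_caps_per_patient(nv_standardized):
    std, _, _ = nv_standardized
    sub = subsample_per_patient(std, cap=7, rng=0)
    assert (sub.meta.groupby("patient_id").size() <= 7).all()
    again = subsample_per_patient(std, cap=7, rng=0)
    assert sub.spectrum_ids.tolist() == again.spectrum_ids.tolist()
    all_kept = subsample_per_patient(std, cap=1000, rng=0)
    assert all_kept.n == std.n


# ---------------------------------------------------------------------------
# WSS curve and K selection
# ---------------------------------------------------------------------------

class TestWSS:
    def test_wss_extremes_closed_form(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 4))
        curve = wss_curve(X, kmax=30, n_init=10, seed=0)
        tss = ((X - X.mean(axis=0)) ** 2).sum()
        assert curve.wss[0] == pytest.approx(tss, rel=1e-9)
        assert curve.wss[-1] == pytest.approx(0.0, abs=1e-9)

    def test_wss_non_increasing(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 5))
        curve = wss_curve(X, kmax=20, n_init=10, seed=1)
        diffs = np.diff(curve.wss)
        assert (diffs <= 1e-6 * curve.wss[:-1] + 1e-9).all()

    def test_k2_matches_bruteforce_best_partition(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 1, (10, 2)), rng.normal(5, 1, (10, 2))])
        curve = wss_curve(X, kmax=3, n_init=20, seed=0)

        # independent oracle: enumerate all 2^(n-1) bipartitions
        n = len(X)
        masks = ((np.arange(1, 2 ** (n - 1))[:, None]
                  >> np.arange(n)) & 1).astype(float)
        sq = (X ** 2).sum()
        cnt_a = masks.sum(axis=1)
        cnt_b = n - cnt_a
        sum_a = masks @ X
        sum_b = X.sum(axis=0) - sum_a
        inertia = (sq - (sum_a ** 2).sum(axis=1) / cnt_a
                   - (sum_b ** 2).sum(axis=1) / np.maximum(cnt_b, 1))
        valid = cnt_b > 0
        best = inertia[valid].min()
        assert curve.wss[1] == pytest.approx(best, rel=1e-9)

    def test_kmax_truncated_with_warning(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.warns(UserWarning, match="truncating"):
            curve = wss_curve(X, kmax=50, n_init=5, seed=0)
        assert curve.ks[-1] == 10


class TestSelectK:
    @staticmethod
    def _blobs(k, per, spread, rng):
        centers = rng.normal(0, 20, size=(k, 8))
        return np.vstack([c + rng.normal(0, spread, size=(per, 8))
                          for c in centers])

    def test_three_planted_blobs(self):
        rng = np.random.default_rng(5)
        X = self._blobs(3, 40, 0.5, rng)
        curve = wss_curve(X, kmax=15, n_init=10, seed=0)
        K = select_k(curve, majority_top_m=3, min_minor_clusters=0)
        assert K == 3

    def test_single_blob_falls_back_to_elbow(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(300, 5))
        curve = wss_curve(X, kmax=20, n_init=5, seed=0)
        with pytest.warns(UserWarning, match="elbow"):
            K = select_k(curve)
        assert 1 <= K <= 20

    def test_majority_plus_rare_structure(self, small_study):
        """Planted 7-abundant + 3-rare cohort: K near the planted profile count,
        top-7 coverage above the majority criterion."""
        h = small_study["headline"]
        assert abs(h["selected_k"] - h["planted_nonnecrotic_profiles"]) <= 2
        sizes = np.sort(small_study["clusters"].sizes_)[::-1]
        assert sizes[:7].sum() / sizes.sum() >= 0.9
        assert (sizes < 10).sum() >= 3

    def test_empty_curve_errors(self):
        from ramahet.heterogeneity import WSSCurve
        with pytest.raises(ValueError, match="empty"):
            select_k(WSSCurve(np.array([]), np.array([]), {}, 1, 0))


# ---------------------------------------------------------------------------
# fit_clusters / summarize
# ---------------------------------------------------------------------------

class TestClusters:
    def test_planted_blobs_recovered_exactly(self, grid_small):
        rng = np.random.default_rng(7)
        centers = rng.normal(0, 15, size=(3, grid_small.n_bins))
        X = np.vstack([c + rng.normal(0, 0.3, size=(25, grid_small.n_bins))
                       for c in centers])
        truth = np.repeat([0, 1, 2], 25)
        model = fit_clusters(flat_set(grid_small, X), K=3, seed=0)
        assert adjusted_rand_score(truth, model.labels_) == 1.0

    def test_identical_points_tie_break_to_lowest_id(self):
        X = np.tile([1.0, 2.0, 3.0], (10, 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = SpectralKMeans(n_clusters=2, random_state=0).fit(X)
        assert (model.labels_ == 1).all()

    def test_refit_same_seed_identical(self, grid_small):
        rng = np.random.default_rng(8)
        sset = flat_set(grid_small, rng.normal(size=(50, grid_small.n_bins)))
        a = fit_clusters(sset, K=5, seed=2)
        b = fit_clusters(sset, K=5, seed=2)
        np.testing.assert_array_equal(a.labels_, b.labels_)

    def test_cluster_ids_ordered_by_size(self, small_study):
        sizes = small_study["clusters"].sizes_
        assert (np.diff(sizes) <= 0).all()  # cluster 1 is the largest

    def test_n_below_k_errors(self, grid_small):
        sset = flat_set(grid_small, np.eye(3, grid_small.n_bins))
        with pytest.raises(ValueError, match="< K"):
            fit_clusters(sset, K=5)


class _StubCluster:
    def __init__(self, sizes):
        self.sizes_ = np.asarray(sizes)
        self.n_clusters = len(sizes)


class TestSummary:
    def test_taxonomy_arithmetic(self):
        s = summarize_clusters(_StubCluster([500, 300, 100, 5, 1, 1]))
        assert (len(s.major), len(s.small), len(s.singletons)) == (3, 1, 2)
        assert s.major_coverage == pytest.approx(900 / 908, abs=0.01)
        assert s.major_coverage == pytest.approx(900 / sum([500, 300, 100, 5, 1, 1]))

    def test_all_singletons(self):
        s = summarize_clusters(_StubCluster([1, 1, 1, 1]))
        assert s.major == [] and s.major_coverage == 0.0

    def test_sizes_partition_taxonomy(self, small_study):
        s = small_study["summary"]
        assert sorted(s.major + s.small + s.singletons) == \
            sorted(s.sizes.index.tolist())
        assert int(s.sizes.sum()) == small_study["vital_sub"].n


# ---------------------------------------------------------------------------
# external assignment / overlap bookkeeping
# ---------------------------------------------------------------------------

class TestAssignment:
    def test_centroid_identity_assignment(self, grid_small):
        rng = np.random.default_rng(9)
        sset = flat_set(grid_small, rng.normal(size=(40, grid_small.n_bins)))
        model = fit_clusters(sset, K=4, seed=0)
        external = flat_set(grid_small, model.centroids_[2][None, :], prefix="e")
        from ramahet.heterogeneity import assign_external
        res = assign_external(model, external)
        assert res.table["cluster"].iloc[0] == 3
        assert res.table["distance"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_printed_count_percentages(self):
        table = pd.DataFrame({
            "class_label": ["control_gray"] * 55,
            "cluster": [2] * 47 + [1] * 6 + [9] * 2,
            "distance": 0.0,
        }, index=[f"g{i}" for i in range(55)])
        dist = AssignmentResult(table).class_distribution("control_gray")
        assert dist.loc[2, "percent"] == 85
        assert dist.loc[1, "percent"] == 11
        assert dist.loc[9, "percent"] == 4
        assert dist["count"].sum() == 55

    def test_controls_assigned_to_generating_clusters(self, small_study):
        assert small_study["headline"]["control_assignment_concordance"] >= 0.95

    def test_percentages_sum_to_about_100(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            counts = rng.integers(0, 40, size=rng.integers(2, 8))
            if counts.sum() == 0:
                continue
            pct = rounded_percentages(counts)
            assert abs(pct.sum() - 100) <= len(counts) // 2 + 1


class TestOverlap:
    def test_printed_infiltration_overlap(self):
        labels = np.array([1] * 89 + [2] * 25 + [5] * 67)
        tags = [{"infiltration_zone"}] * 181
        rep = overlap_report(labels, tags, designated_clusters=(1, 2))
        ov = rep.overlap["infiltration_zone"]
        assert (ov["count"], ov["total"], ov["percent"]) == (114, 181, 63)

    def test_designated_all_clusters_is_total(self):
        labels = np.array([1, 2, 3, 3])
        rep = overlap_report(labels, [{"hemorrhage"}] * 4, (1, 2, 3))
        assert rep.overlap["hemorrhage"]["percent"] == 100

    def test_empty_intersection_zero_percent(self):
        labels = np.array([4, 4, 5])
        rep = overlap_report(labels, [{"infiltration_zone"}] * 3, (1, 2))
        assert rep.overlap["infiltration_zone"]["percent"] == 0

    def test_no_tags_empty_report(self):
        rep = overlap_report(np.array([1, 2]), [set(), set()], (1,))
        assert rep.overlap == {} and rep.per_tag == {}


# ---------------------------------------------------------------------------
# embedding & overlay
# ---------------------------------------------------------------------------

class TestEmbedding:
    def test_separates_planted_structure_and_agrees_with_clusters(self, small_study):
        emb = small_study["embedding"]
        clusters = small_study["clusters"]
        xy = emb.coords.to_numpy()
        # independent methods agree: k-means labels (spectral space) form
        # coherent groups in the UMAP plane
        keep = np.isin(clusters.labels_,
                       np.flatnonzero(clusters.sizes_ >= 10) + 1)
        sil = silhouette_score(xy[keep], clusters.labels_[keep])
        assert sil > 0

    def test_deterministic_for_fixed_seed(self, nv_standardized):
        std, _, _ = nv_standardized
        sub = std.subset(std.spectrum_ids[:60].tolist())
        a = embed(sub, n_neighbors=10, seed=4)
        b = embed(sub, n_neighbors=10, seed=4)
        np.testing.assert_array_equal(a.coords.to_numpy(), b.coords.to_numpy())

    def test_too_few_spectra_error(self, grid_small):
        sset = flat_set(grid_small, np.eye(5, grid_small.n_bins))
        with pytest.raises(ValueError, match="n_neighbors"):
            embed(sset, n_neighbors=15)


class TestOverlay:
    def test_join_preserves_scores(self, grid_small):
        rng = np.random.default_rng(11)
        sset = flat_set(grid_small, rng.normal(size=(8, grid_small.n_bins)))
        scores = rng.random(8)
        relab = RelabeledSet(sset, scores, 0.452)
        from ramahet.heterogeneity import EmbeddingResult
        coords = pd.DataFrame(rng.normal(size=(8, 2)), columns=["x", "y"],
                              index=sset.meta.index)
        out = necrosis_probability_overlay(
            relab, EmbeddingResult(coords, 15, 0.1, "euclidean", 0))
        assert len(out) == 8
        np.testing.assert_array_equal(out["necrosis_score"].to_numpy(), scores)

    def test_mismatched_ids_error(self, grid_small):
        rng = np.random.default_rng(12)
        sset = flat_set(grid_small, rng.normal(size=(4, grid_small.n_bins)))
        relab = RelabeledSet(sset, rng.random(4), 0.5)
        coords = pd.DataFrame(rng.normal(size=(2, 2)), columns=["x", "y"],
                              index=["sX", "sY"])
        from ramahet.heterogeneity import EmbeddingResult
        with pytest.raises(ValueError, match="missing"):
            necrosis_probability_overlay(
                relab, EmbeddingResult(coords, 15, 0.1, "euclidean", 0))
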