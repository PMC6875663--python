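"""Cohort selection and function-space clustering statistics: mean
nearest-neighbor distance, centroid displacement from pairwise distances,
and random-subset null percentiles."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from cooclust import cohorts as coh


def _dm(points, ids=None):
    """Euclidean distance matrix from coordinates (an exact-geometry oracle)."""
    pts = np.asarray(points, dtype=float)
    ids = ids or [f"p{i}" for i in range(len(pts))]
    return pd.DataFrame(cdist(pts, pts), index=ids, columns=ids), pts, ids


def _pairs(rows):
    return pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "p_lt", "p_gt"])


class TestSelectCohorts:
    COVS = ["euk1", "euk2"]
    BACT = [f"b{i}" for i in range(8)]

    def test_single_interacting_otu_excluded(self):
        pairs = _pairs([("euk1", "b0", 1.0, 0.001)])
        assert coh.select_cohorts(pairs, self.COVS, self.BACT) == []

    def test_membership_looser_than_selection(self):
        rows = [("euk1", "b0", 1.0, 0.005), ("euk1", "b1", 1.0, 0.009)]
        rows += [("euk1", f"b{i}", 1.0, 0.04) for i in range(2, 7)]
        rows += [("euk1", "b7", 1.0, 0.2)]
        out = coh.select_cohorts(_pairs(rows), self.COVS, self.BACT, 0.01, 0.05)
        assert len(out) == 1 and len(out[0].members) == 7

    def test_equal_thresholds_coincide(self):
        rows = [("euk1", "b0", 1.0, 0.005), ("euk1", "b1", 1.0, 0.009),
                ("euk1", "b2", 1.0, 0.04)]
        out = coh.select_cohorts(_pairs(rows), self.COVS, self.BACT, 0.01, 0.01)
        assert out[0].members == frozenset({"b0", "b1"})

    def test_pooled_direction_accepts_both_tails(self):
        rows = [("euk1", "b0", 0.004, 1.0), ("b1", "euk1", 1.0, 0.004)]
        out = coh.select_cohorts(_pairs(rows), self.COVS, self.BACT)
        assert out[0].members == frozenset({"b0", "b1"})
        only_pos = coh.select_cohorts(
            _pairs(rows), self.COVS, self.BACT, direction="positive"
        )
        assert only_pos == []  # just one positive partner

    def test_non_bacterial_partners_ignored(self):
        rows = [("euk1", "euk2", 1.0, 0.001), ("euk1", "b0", 1.0, 0.001)]
        assert coh.select_cohorts(_pairs(rows), self.COVS, self.BACT) == []


class TestMeanNearestNeighbor:
    def test_hand_computed_triangle(self):
        dm = pd.DataFrame(
            [[0, 1, 3], [1, 0, 2], [3, 2, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        assert coh.mean_nearest_neighbor(dm, ["A", "B", "C"]) == pytest.approx(4 / 3)

    def test_pair_subset_equals_their_distance(self):
        dm, _, ids = _dm([[0, 0], [3, 4]])
        assert coh.mean_nearest_neighbor(dm, ids) == pytest.approx(5.0)

    def test_duplicated_profiles_contribute_zero(self):
        dm = pd.DataFrame(
            [[0, 0, 2], [0, 0, 2], [2, 2, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        assert coh.mean_nearest_neighbor(dm, list("ABC")) == pytest.approx(2 / 3)

    def test_requires_two_members(self):
        dm, _, _ = _dm([[0, 0], [1, 1]])
        with pytest.raises(ValueError):
            coh.mean_nearest_neighbor(dm, ["p0"])


class TestCentroidDisplacement:
    def test_subset_equal_to_background_is_zero(self):
        dm, _, ids = _dm([[0, 0], [1, 2], [3, 1]])
        assert coh.centroid_displacement(dm, ids, ids) == pytest.approx(0.0, abs=1e-12)

    def test_square_example(self):
        dm, _, ids = _dm([[0, 0], [2, 0], [0, 2], [2, 2]])
        # subset centroid (1, 0); background centroid (1, 1) -> displacement 1
        assert coh.centroid_displacement(dm, ids[:2], ids) == pytest.approx(1.0)

    def test_matches_direct_centroids_on_random_clouds(self):
        """The pairwise-distance formula reproduces |c_A - c_B| exactly for
        Euclidean point clouds."""
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = rng.integers(4, 15)
            k = rng.integers(1, n)
            pts = rng.normal(size=(n, rng.integers(2, 5)))
            dm, _, ids = _dm(pts)
            direct = np.linalg.norm(pts[:k].mean(axis=0) - pts.mean(axis=0))
            assert coh.centroid_displacement(dm, ids[:k], ids) == pytest.approx(
                direct, abs=1e-9
            )

    def test_negative_square_clamped_and_flagged(self):
        # an ultra-metric violating Euclidean embedding in this configuration
        dm = pd.DataFrame(
            [[0, 1, 1], [1, 0, 0.1], [1, 0.1, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        value, clamped = coh.centroid_displacement(
            dm, ["B"], list("ABC"), return_clamped=True
        )
        assert value >= 0.0
        assert isinstance(clamped, (bool, np.bool_))


class TestNullPercentiles:
    def test_deterministic_given_seed(self):
        dm, _, ids = _dm(np.random.default_rng(0).normal(size=(20, 3)))
        a = coh.null_percentiles(dm, 5, ids, reps=200, seed=11, observed_mnn=0.5,
                                 observed_displacement=0.2)
        b = coh.null_percentiles(dm, 5, ids, reps=200, seed=11, observed_mnn=0.5,
                                 observed_displacement=0.2)
        assert a.frac_tighter == b.frac_tighter
        assert np.array_equal(a.null_mnn, b.null_mnn)

    def test_full_size_subset_degenerate(self):
        dm, _, ids = _dm([[0, 0], [1, 0], [0, 1]])
        res = coh.null_percentiles(dm, len(ids), ids, reps=100, seed=0,
                                   observed_mnn=1.0, observed_displacement=0.0)
        assert np.allclose(res.null_displacement, 0.0, atol=1e-6)
        assert res.frac_less_displaced == 0.0  # no draw strictly smaller than 0

    def test_fraction_converges_across_seeds(self):
        dm, _, ids = _dm(np.random.default_rng(3).normal(size=(30, 2)))
        fr = [
            coh.null_percentiles(dm, 6, ids, reps=400, seed=s,
                                 observed_mnn=0.6).frac_tighter
            for s in (1, 2)
        ]
        assert abs(fr[0] - fr[1]) < 2 / np.sqrt(400)

    def test_statistics_invariant_under_relabeling(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(12, 3))
        dm, _, ids = _dm(pts)
        perm = list(rng.permutation(ids))
        dm_perm = dm.loc[perm, perm]
        subset = ids[:4]
        assert coh.mean_nearest_neighbor(dm, subset) == pytest.approx(
            coh.mean_nearest_neighbor(dm_perm, subset)
        )
        assert coh.centroid_displacement(dm, subset, ids) == pytest.approx(
            coh.centroid_displacement(dm_perm, subset, perm)
        )


class TestCohortReport:
    def test_cross_product_and_zero_fraction_clamping(self):
        rng = np.random.default_rng(9)
        # a deliberately ultra-tight pair in an otherwise diffuse cloud
        pts = np.vstack([[[0, 0], [1e-6, 0]], rng.normal(5, 3, size=(20, 2))])
        dm, _, ids = _dm(pts)
        cohorts = [coh.Cohort("covX", frozenset(ids[:2]))]
        spaces = {"catA": dm, "catB": dm}
        rep = coh.cohort_report(cohorts, spaces, reps=100, seed=0)
        assert len(rep) == 2
        assert (rep["status"] == "ok").all()
        assert (rep["frac_tighter"] >= 1 / 100).all()
        assert rep.loc[rep["frac_tighter"] == 1 / 100, "below_resolution"].all()

    def test_cohort_absent_from_space_dropped_with_note(self):
        dm, _, ids = _dm([[0, 0], [1, 1], [2, 0]])
        cohorts = [coh.Cohort("covX", frozenset({"zz1", "zz2"}))]
        rep = coh.cohort_report(cohorts, {"catA": dm}, reps=100, seed=0)
        assert rep.iloc[0]["status"].startswith("dropped")

    def test_empty_cohort_list_gives_empty_table(self):
        dm, _, ids = _dm([[0, 0], [1, 1]])
        rep = coh.cohort_report([], {"catA": dm}, reps=100, seed=0)
        assert rep.empty
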