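"""Functional distance geometry: Bray-Curtis on binary profiles, ontology
subsetting, and the deviation-vs-similarity permutation regression."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cooclust import function_space as fspace


def _fm(rows, categories=None, otus=None):
    rows = np.asarray(rows, dtype=bool)
    otus = otus or [f"o{i}" for i in range(rows.shape[0])]
    fns = [f"f{i}" for i in range(rows.shape[1])]
    cats = categories or ["c0"] * rows.shape[1]
    return fspace.FunctionMatrix(
        pd.DataFrame(rows, index=otus, columns=fns), pd.Series(cats, index=fns)
    )


class TestBrayCurtis:
    def test_hand_computed_distances(self):
        fm = _fm([[1, 1, 0, 0], [1, 0, 1, 0], [1, 1, 0, 0], [0, 0, 1, 1]])
        d = fspace.bray_curtis(fm)
        assert d.loc["o0", "o1"] == pytest.approx(0.5)   # 2 mismatches / 4 carried
        assert d.loc["o0", "o2"] == 0.0                   # identical profiles
        assert d.loc["o0", "o3"] == 1.0                   # disjoint profiles

    def test_all_zero_profile_undefined(self):
        fm = _fm([[1, 1], [0, 0]])
        with pytest.warns(UserWarning, match="all-zero"):
            d = fspace.bray_curtis(fm)
        assert np.isnan(d.loc["o1", "o0"]) and np.isnan(d.loc["o1", "o1"])

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_distance_matrix_invariants(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.random((rng.integers(2, 8), rng.integers(1, 12))) < 0.5
        X[:, 0] = True  # guarantee non-empty profiles
        d = fspace.bray_curtis(_fm(X)).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert ((d >= 0) & (d <= 1)).all()


class TestSimilarity:
    def test_one_minus_mode(self):
        dm = pd.DataFrame([[0.0, 0.5], [0.5, 0.0]])
        s = fspace.similarity(dm, "one_minus")
        assert s.iloc[0, 1] == 0.5 and s.iloc[0, 0] == 1.0

    def test_reciprocal_needs_cap_at_zero(self):
        dm = pd.DataFrame([[0.0, 0.5], [0.5, 0.0]])
        with pytest.raises(ValueError, match="cap"):
            fspace.similarity(dm, "reciprocal")
        s = fspace.similarity(dm, "reciprocal", cap=10.0)
        assert s.iloc[0, 0] == 10.0 and s.iloc[0, 1] == 2.0

    def test_both_modes_monotone_decreasing(self):
        d = pd.DataFrame([np.linspace(0.1, 1.0, 10)])
        for mode in ("one_minus", "reciprocal"):
            s = fspace.similarity(d, mode, cap=99.0).to_numpy().ravel()
            assert (np.diff(s) < 0).all()


class TestSubsetCategories:
    def test_small_category_dropped_at_default_threshold(self):
        cats = ["big"] * 8 + ["small"] * 7
        fm = _fm(np.ones((3, 15)), categories=cats)
        with pytest.warns(UserWarning, match="small"):
            out = fspace.subset_categories(fm, 8)
        assert set(out) == {"big"}
        assert out["big"].presence.shape == (3, 8)

    def test_threshold_one_keeps_all_nonempty(self):
        cats = ["a"] * 2 + ["b"] * 3
        fm = _fm(np.ones((2, 5)), categories=cats)
        assert set(fspace.subset_categories(fm, 1)) == {"a", "b"}

    def test_twelve_categories_survive(self):
        cats = [f"c{i:02d}" for i in range(12) for _ in range(9)]
        fm = _fm(np.ones((4, 108)), categories=cats)
        assert len(fspace.subset_categories(fm, 8)) == 12

    def test_no_qualifying_category_raises(self):
        fm = _fm(np.ones((2, 3)))
        with pytest.raises(ValueError, match="no ontology category"):
            fspace.subset_categories(fm, 8)


class TestDeviationSimilarityRegression:
    @staticmethod
    def _scenario(slope_signal, n=16, seed=0):
        """Pairs whose similarity tracks pct_dev (plus noise) when signalled."""
        rng = np.random.default_rng(seed)
        otus = [f"o{i}" for i in range(n)]
        # latent trait: similarity = 1 - |trait_i - trait_j|
        trait = rng.random(n)
        S = 1 - np.abs(trait[:, None] - trait[None, :])
        sim = pd.DataFrame(S, index=otus, columns=otus)
        rows = []
        for i in range(n):
            for j in range(i + 1, n):
                x = 100 * (S[i, j] - 0.5) if slope_signal else rng.normal(0, 30)
                rows.append({"taxon_a": otus[i], "taxon_b": otus[j], "pct_dev": x})
        pairs = pd.DataFrame(rows)
        groups = pd.Series(["P"] * n, index=otus)
        return pairs, sim, groups

    def test_constant_similarity_gives_flat_fit(self):
        pairs, sim, groups = self._scenario(False)
        const = pd.DataFrame(0.5, index=sim.index, columns=sim.columns)
        out = fspace.deviation_similarity_regression(
            pairs, const, groups, n_perm=99, seed=0
        )
        row = out[out["group"] == "P"].iloc[0]
        assert row["slope"] == 0.0 and row["p_perm"] == 1.0

    def test_signal_detected_and_null_not(self):
        pairs, sim, groups = self._scenario(True)
        out = fspace.deviation_similarity_regression(pairs, sim, groups, 199, seed=1)
        row = out[out["group"] == "P"].iloc[0]
        assert row["slope"] > 0 and row["p_perm"] <= 0.05

        pairs0, sim0, groups0 = self._scenario(False, seed=7)
        out0 = fspace.deviation_similarity_regression(pairs0, sim0, groups0, 199, seed=1)
        assert out0[out0["group"] == "P"].iloc[0]["p_perm"] > 0.05

    def test_deterministic_given_seed(self):
        pairs, sim, groups = self._scenario(True)
        a = fspace.deviation_similarity_regression(pairs, sim, groups, 99, seed=3)
        b = fspace.deviation_similarity_regression(pairs, sim, groups, 99, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_small_group_skipped(self):
        pairs, sim, groups = self._scenario(True)
        groups = groups.copy()
        groups.iloc[:2] = "tiny"
        with pytest.warns(UserWarning, match="tiny"):
            out = fspace.deviation_similarity_regression(pairs, sim, groups, 99, seed=0)
        assert "tiny" not in set(out["group"])

    def test_null_calibration_near_nominal(self):
        """Under no association the permutation p is approximately uniform:
        rejection rate at alpha=.1 stays near nominal over 200 null draws."""
        rng = np.random.default_rng(42)
        n = 10
        otus = [f"o{i}" for i in range(n)]
        groups = pd.Series(["P"] * n, index=otus)
        rejections = 0
        trials = 200
        for t in range(trials):
            trait = rng.random(n)
            S = 1 - np.abs(trait[:, None] - trait[None, :])
            sim = pd.DataFrame(S, index=otus, columns=otus)
            rows = [
                {"taxon_a": otus[i], "taxon_b": otus[j], "pct_dev": rng.normal(0, 30)}
                for i in range(n) for j in range(i + 1, n)
            ]
            out = fspace.deviation_similarity_regression(
                pd.DataFrame(rows), sim, groups, n_perm=99, seed=t
            )
            if out[out["group"] == "P"].iloc[0]["p_perm"] <= 0.1:
                rejections += 1
        rate = rejections / trials
        assert rate < 0.1 + 3 * np.sqrt(0.1 * 0.9 / trials)


def test_function_matrix_io_roundtrip(tmp_path):
    cats = ["met"] * 3 + ["env"] * 2
    fm = _fm(np.eye(5, 5), categories=cats)
    path = tmp_path / "functions.tsv"
    fspace.write_function_matrix(fm, path)
    back = fspace.read_function_matrix(path)
    pd.testing.assert_frame_equal(back.presence, fm.presence)
    pd.testing.assert_series_equal(back.categories, fm.categories)


def test_header_without_category_label_rejected(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("otu\tjustafunction\no1\t1\n")
    with pytest.raises(ValueError, match="category:function"):
        fspace.read_function_matrix(path)
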