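"""KS statistic, connectivity scores, running sums, and the connect pipeline."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from kinconn import (
    ActivityMatrix,
    ConnectivityMapper,
    connect,
    connectivity_scores,
    ks_statistic,
    normalize_scores,
    rank_profiles,
    running_sum,
)
from conftest import brute_ab, brute_ks, brute_running_sum


class TestKSStatistic:
    @pytest.mark.parametrize(
        "ranks,n,a,b,ks",
        [
            ({1, 2}, 10, 0.8, 0.1, 0.8),          # top-enriched query
            ({9, 10}, 10, 0.0, 0.9, -0.9),        # bottom-enriched query
            (set(range(1, 11)), 10, 0.0, 0.1, -0.1),  # query = whole panel
        ],
    )
    def test_hand_derived_values(self, ranks, n, a, b, ks):
        res = ks_statistic(ranks, n)
        assert res.a == pytest.approx(a, abs=1e-12)
        assert res.b == pytest.approx(b, abs=1e-12)
        assert res.ks == pytest.approx(ks, abs=1e-12)
        assert res.n_matched == len(ranks)
        assert res.n_ref == n

    def test_exhaustive_oracle_equivalence_small_n(self):
        """Every nonempty subset of ranks for N <= 6 matches the exact
        rational brute-force enumeration of both maxima."""
        for n in range(1, 7):
            for m in range(1, n + 1):
                for subset in itertools.combinations(range(1, n + 1), m):
                    res = ks_statistic(subset, n)
                    a, b = brute_ab(subset, n)
                    assert res.a == pytest.approx(float(a), abs=1e-12)
                    assert res.b == pytest.approx(float(b), abs=1e-12)
                    assert res.ks == pytest.approx(
                        float(brute_ks(subset, n)), abs=1e-12
                    )

    def test_a_and_b_nonnegative_and_ks_bounded(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(2, 40))
            m = int(rng.integers(1, n + 1))
            ranks = rng.choice(n, size=m, replace=False) + 1
            res = ks_statistic(ranks, n)
            assert res.a >= 0.0 and res.b > 0.0
            assert -1.0 <= res.ks <= 1.0

    def test_location_monotonicity(self):
        """Promoting any single query kinase to a better rank never
        decreases the KS score."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(3, 25))
            m = int(rng.integers(1, n))
            ranks = set((rng.choice(n, size=m, replace=False) + 1).tolist())
            ks0 = ks_statistic(ranks, n).ks
            movable = [r for r in ranks if r > 1 and (r - 1) not in ranks]
            for r in movable:
                better = (ranks - {r}) | {r - 1}
                assert ks_statistic(better, n).ks >= ks0 - 1e-12

    def test_input_validation(self):
        with pytest.raises(ValueError, match="empty"):
            ks_statistic([], 5)
        with pytest.raises(ValueError, match="duplicate"):
            ks_statistic([2, 2], 5)
        with pytest.raises(ValueError, match="outside"):
            ks_statistic([0, 3], 5)
        with pytest.raises(ValueError, match="outside"):
            ks_statistic([6], 5)


class TestRunningSum:
    def test_hand_derived_curve(self):
        d = running_sum({1, 2}, 10)
        expected = [0.4, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1, 0.0]
        np.testing.assert_allclose(d, expected, atol=1e-12)

    def test_max_equals_a_exhaustively(self):
        for n in range(1, 7):
            for m in range(1, n + 1):
                for subset in itertools.combinations(range(1, n + 1), m):
                    d = running_sum(subset, n)
                    res = ks_statistic(subset, n)
                    assert d.max() == pytest.approx(res.a, abs=1e-12)
                    assert d[-1] == pytest.approx(0.0, abs=1e-12)
                    np.testing.assert_allclose(
                        d,
                        [float(x) for x in brute_running_sum(subset, n)],
                        atol=1e-12,
                    )

    def test_min_before_first_hit_for_bottom_query(self):
        d = running_sum({9, 10}, 10)
        assert d.max() == pytest.approx(0.0, abs=1e-12)
        assert np.argmin(d) == 7  # r = 8, just before the first hit


class TestScores:
    def test_rescaling_by_extremes(self):
        assert connectivity_scores([0.8, -0.9, 0.4]) == pytest.approx(
            [1.0, -1.0, 0.5]
        )

    def test_all_equal_positive_all_one(self):
        assert connectivity_scores([0.3, 0.3, 0.3]) == pytest.approx(
            [1.0, 1.0, 1.0]
        )

    def test_zero_and_all_zero(self):
        assert connectivity_scores([0.0]) == [0.0]
        assert connectivity_scores([0.0, 0.0]) == [0.0, 0.0]

    def test_nan_sentinel_passthrough(self):
        out = connectivity_scores([0.5, float("nan"), -0.2])
        assert out[0] == pytest.approx(1.0)
        assert math.isnan(out[1])
        assert out[2] == pytest.approx(-1.0)

    @pytest.mark.parametrize(
        "s,expected", [(1.0, 1.0), (-1.0, 0.0), (0.0, 0.5), (0.8, 0.9)]
    )
    def test_normalization_affine_map(self, s, expected):
        assert normalize_scores([s]) == pytest.approx([expected])

    def test_normalization_preserves_order(self):
        rng = np.random.default_rng(0)
        s = rng.uniform(-1, 1, size=50)
        norm = normalize_scores(s)
        assert np.all(np.diff(np.argsort(s)) == np.diff(np.argsort(norm)))


class TestConnect:
    def test_spiked_drug_first_with_normalized_one(self, tiny_kd_matrix):
        ref = rank_profiles(tiny_kd_matrix)
        res = connect(ref, ["ABL1", "KIT"], n_permutations=0)
        top = res.table.iloc[0]
        assert top["drug"] == "drugX"
        assert top["normalized_score"] == pytest.approx(1.0)
        assert res.table["normalized_score"].is_monotonic_decreasing

    def test_single_drug_reference_extreme_score(self):
        df = pd.DataFrame({"A": [0.1], "B": [1.0], "C": [2.0]}, index=["d"])
        ref = rank_profiles(ActivityMatrix(values=df, assay_type="kd"))
        res = connect(ref, ["A"], n_permutations=0)
        assert res.table.iloc[0]["score"] in (1.0, -1.0, 0.0)

    def test_partial_match_and_unscored_section(self, tiny_kd_matrix):
        m = tiny_kd_matrix.values.copy()
        m.loc["drugW"] = [np.nan, np.nan, 1.0, 2.0]
        ref = rank_profiles(ActivityMatrix(values=m, assay_type="kd"))
        res = connect(ref, ["ABL1", "KIT"], n_permutations=0)
        assert res.unscored == ["drugW"]
        assert set(res.table["drug"]) == {"drugX", "drugY", "drugZ"}
        assert res.dropped_per_drug["drugW"] == 2

    def test_no_overlap_raises(self, tiny_kd_matrix):
        ref = rank_profiles(tiny_kd_matrix)
        with pytest.raises(ValueError, match="shares no kinase"):
            connect(ref, ["EGFR"], n_permutations=0)

    def test_scale_invariance(self, tiny_kd_matrix):
        """Multiplying all Kd values by a positive constant leaves the
        connectivity table unchanged: only ranks matter."""
        ref1 = rank_profiles(tiny_kd_matrix)
        scaled = ActivityMatrix(
            values=tiny_kd_matrix.values * 37.5, assay_type="kd"
        )
        ref2 = rank_profiles(scaled)
        t1 = connect(ref1, ["ABL1", "KIT"], n_permutations=50, seed=3)
        t2 = connect(ref2, ["ABL1", "KIT"], n_permutations=50, seed=3)
        pd.testing.assert_frame_equal(t1.table, t2.table)

    def test_sort_ties_broken_by_drug_id(self):
        df = pd.DataFrame(
            {"A": [0.1, 0.1], "B": [1.0, 1.0]}, index=["zeta", "alpha"]
        )
        ref = rank_profiles(ActivityMatrix(values=df, assay_type="kd"))
        res = connect(ref, ["A"], n_permutations=0)
        assert list(res.table["drug"]) == ["alpha", "zeta"]


class TestEstimator:
    def test_fit_sets_sklearn_style_attributes(self, tiny_kd_matrix):
        est = ConnectivityMapper(n_permutations=0).fit(tiny_kd_matrix)
        assert est.drugs_ == ["drugX", "drugY", "drugZ"]
        assert est.n_features_in_ == 4
        assert "ABL1" in est.kinases_

    def test_unfitted_raises(self):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            ConnectivityMapper().connect(["ABL1"])

    def test_get_set_params_roundtrip(self):
        est = ConnectivityMapper(n_permutations=100, random_state=9)
        params = est.get_params()
        assert params["n_permutations"] == 100
        est2 = ConnectivityMapper().set_params(**params)
        assert est2.random_state == 9

    def test_transform_shape_and_nan_for_unscored(self, tiny_kd_matrix):
        m = tiny_kd_matrix.values.copy()
        m.loc["drugW"] = [np.nan, np.nan, 1.0, 2.0]
        est = ConnectivityMapper(n_permutations=0).fit(
            ActivityMatrix(values=m, assay_type="kd")
        )
        out = est.transform([["ABL1", "KIT"], ["MET"]])
        assert out.shape == (2, 4)
        w = est.drugs_.index("drugW")
        assert math.isnan(out[0, w]) and not math.isnan(out[1, w])

    def test_fit_accepts_plain_dataframe(self, tiny_kd_matrix):
        est = ConnectivityMapper(assay_type="kd", n_permutations=0)
        est.fit(tiny_kd_matrix.values)
        res = est.connect(["ABL1", "KIT"])
        assert res.table.iloc[0]["drug"] == "drugX"
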