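"""Permutation-test inference, BH correction, fold changes and overlaps."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from sagelnc.diffexp import (
    DiffExpResult,
    bh_adjust,
    differential_expression,
    overlap_sets,
    permutation_test,
    signed_fold_change,
    significant_set,
    up_down_split,
)
from sagelnc.matrix_ops import TPM, ExpressionMatrix


def _tpm(rows: dict) -> ExpressionMatrix:
    df = pd.DataFrame(rows).T.astype(float)
    df.columns = [f"L{i}" for i in range(df.shape[1])]
    totals = pd.Series([100_000.0] * df.shape[1], index=df.columns)
    return ExpressionMatrix(df, totals, unit=TPM)


def enumeration_oracle(values, labels):
    """Exact p by brute-force enumeration of all label arrangements."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    k = sum(1 for l in labels if l == "cancer")
    observed_idx = [i for i, l in enumerate(labels) if l == "cancer"]

    def stat(cancer_idx):
        cancer = values[list(cancer_idx)]
        normal = values[[i for i in range(n) if i not in set(cancer_idx)]]
        return abs(cancer.mean() - normal.mean())

    observed = stat(observed_idx)
    arrangements = list(combinations(range(n), k))
    n_ge = sum(stat(c) >= observed - 1e-12 for c in arrangements)
    return n_ge / len(arrangements)


class TestPermutationTest:
    def test_2v2_exact_p_equals_enumeration_oracle(self):
        rows = {"G_max": [10, 11, 30, 31], "G_mid": [10, 30, 11, 29],
                "G_flat": [5, 5, 5, 5]}
        labels = {"L0": "normal", "L1": "normal", "L2": "cancer", "L3": "cancer"}
        p = permutation_test(_tpm(rows), labels, n_permutations=1000,
                             allow_small_groups=True)
        lab_list = ["normal", "normal", "cancer", "cancer"]
        for gene, values in rows.items():
            assert p[gene] == pytest.approx(
                enumeration_oracle(values, lab_list)), gene

    def test_uniquely_maximal_arrangement_gives_two_sixths(self):
        # observed split separates cleanly; only it and its complement reach
        # the observed statistic among the 6 arrangements of 2 from 4
        rows = {"G": [1, 2, 100, 101]}
        labels = {"L0": "normal", "L1": "normal", "L2": "cancer", "L3": "cancer"}
        p = permutation_test(_tpm(rows), labels, n_permutations=1000,
                             allow_small_groups=True)
        assert p["G"] == pytest.approx(2 / 6)

    def test_identical_groups_give_p_one(self):
        rows = {"G": [7, 7, 7, 7, 7, 7, 7, 7, 7, 7]}
        labels = {f"L{i}": ("normal" if i < 5 else "cancer") for i in range(10)}
        p = permutation_test(_tpm(rows), labels, n_permutations=1000)
        assert p["G"] == 1.0

    def test_sampled_mode_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        rows = {f"G{i}": rng.uniform(0, 100, 12) for i in range(20)}
        labels = {f"L{i}": ("normal" if i < 6 else "cancer") for i in range(12)}
        m = _tpm(rows)
        # C(12,6) = 924 > 500 forces sampling
        p1 = permutation_test(m, labels, n_permutations=500, seed=9,
                              min_group_size=5)
        p2 = permutation_test(m, labels, n_permutations=500, seed=9,
                              min_group_size=5)
        assert p1 == p2

    def test_sampled_p_close_to_exact_p(self):
        rng = np.random.default_rng(12)
        rows = {f"G{i}": rng.uniform(0, 100, 10) for i in range(30)}
        labels = {f"L{i}": ("normal" if i < 5 else "cancer") for i in range(10)}
        m = _tpm(rows)
        exact = permutation_test(m, labels, n_permutations=252)  # exhaustive
        sampled = permutation_test(m, labels, n_permutations=4000, seed=1)
        for g in rows:
            tol = 3 * math.sqrt(exact[g] * (1 - exact[g]) / 4000) + 1e-3
            assert abs(exact[g] - sampled[g]) < tol

    def test_label_swap_preserves_p_and_flips_fold_sign(self):
        rng = np.random.default_rng(6)
        rows = {f"G{i}": rng.uniform(1, 100, 10) for i in range(10)}
        m = _tpm(rows)
        labels = {f"L{i}": ("normal" if i < 5 else "cancer") for i in range(10)}
        swapped = {k: ("cancer" if v == "normal" else "normal")
                   for k, v in labels.items()}
        r1 = differential_expression(m, labels, n_permutations=252)
        r2 = differential_expression(m, swapped, n_permutations=252)
        for a, b in zip(r1, r2):
            assert a.p_raw == pytest.approx(b.p_raw)  # exhaustive: exact
            assert a.signed_fc == pytest.approx(-b.signed_fc)

    def test_small_groups_rejected_without_override(self):
        rows = {"G": [1, 2, 3, 4]}
        labels = {"L0": "normal", "L1": "normal", "L2": "cancer", "L3": "cancer"}
        with pytest.raises(ValueError, match="minimum"):
            permutation_test(_tpm(rows), labels, n_permutations=100)

    def test_requires_tpm_unit(self):
        m = _tpm({"G": [1, 2, 3, 4]})
        m.unit = "raw_counts"
        with pytest.raises(ValueError, match="TPM"):
            permutation_test(m, {"L0": "normal", "L1": "cancer"},
                             allow_small_groups=True)


def bh_step_up_oracle(p):
    """Independent step-up implementation of the BH adjustment."""
    p = list(p)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adjusted = [0.0] * n
    running_min = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * n / rank)
        adjusted[i] = running_min
    return adjusted


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.05]) == [pytest.approx(0.05)]

    def test_step_up_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_all_equal_p_unchanged(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_matches_independent_oracle_on_random_vectors(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 40)))
            assert bh_adjust(p) == pytest.approx(bh_step_up_oracle(p))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestSignedFoldChange:
    @pytest.mark.parametrize(
        "cancer,normal,expected",
        [(6, 2, 3.0), (2, 6, -3.0), (5, 5, 1.0), (7.5, 5, 1.5)],
    )
    def test_sign_convention(self, cancer, normal, expected):
        assert signed_fold_change(cancer, normal) == pytest.approx(expected)

    def test_zero_normal_is_up_sentinel(self):
        assert signed_fold_change(5, 0) == math.inf

    def test_zero_cancer_is_down_sentinel(self):
        assert signed_fold_change(0, 5) == -math.inf

    def test_both_zero_is_undefined(self):
        assert math.isnan(signed_fold_change(0, 0))

    def test_negative_mean_rejected(self):
        with pytest.raises(ValueError):
            signed_fold_change(-1, 5)


def _result(row_id, fc, p_bh):
    return DiffExpResult(row_id=row_id, mean_normal=1.0, mean_cancer=1.0,
                         signed_fc=fc, p_raw=p_bh, p_bh=p_bh,
                         n_permutations=100)


class TestSignificantSet:
    @pytest.mark.parametrize(
        "p_bh,fc,included",
        [(0.04, 2.5, True), (0.04, 1.5, False), (0.06, 3.0, False),
         (0.04, -2.5, True), (0.05, 2.5, False)],  # alpha boundary is strict
    )
    def test_threshold_semantics(self, p_bh, fc, included):
        s = significant_set([_result("G", fc, p_bh)], alpha=0.05, min_fold=2.0)
        assert ("G" in s) is included

    def test_undefined_fold_never_significant(self):
        assert significant_set([_result("G", math.nan, 0.001)]) == set()

    def test_up_down_split(self):
        results = [_result("U", 3.0, 0.01), _result("D", -2.5, 0.01),
                   _result("N", 1.2, 0.01)]
        up, down = up_down_split(results)
        assert up == {"U"} and down == {"D"}


class TestOverlapSets:
    def test_three_set_example(self):
        regions = overlap_sets({"X": {"a", "b"}, "Y": {"b", "c"}, "Z": {"b"}})
        assert regions["X&Y&Z"] == {"b"}
        assert regions["X"] == {"a"}
        assert regions["Y"] == {"c"}
        assert regions["Z"] == set()

    def test_disjoint_sets_have_empty_intersections(self):
        regions = overlap_sets({"X": {"a"}, "Y": {"b"}})
        assert regions["X&Y"] == set()
        assert regions["X"] == {"a"} and regions["Y"] == {"b"}

    def test_region_sizes_sum_to_union(self):
        rng = np.random.default_rng(9)
        universe = [f"g{i}" for i in range(50)]
        sets = {
            name: set(rng.choice(universe, size=20, replace=False))
            for name in ("A", "B", "C")
        }
        regions = overlap_sets(sets)
        union = set().union(*sets.values())
        assert sum(len(m) for m in regions.values()) == len(union)
        assert set().union(*regions.values()) == union

    def test_more_than_three_sets_rejected(self):
        with pytest.raises(ValueError):
            overlap_sets({n: set() for n in "ABCD"})
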