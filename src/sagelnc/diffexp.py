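"""Permutation-test differential expression between normal and cancer groups.

The test is non-parametric: per gene the statistic is the absolute
difference of group mean TPM, and the null distribution is built by
permuting the normal/cancer labels across libraries (the same label
arrangements are reused for every gene).  Small designs are enumerated
exhaustively, giving exact p-values; larger designs are sampled with the
add-one estimator.  Benjamini-Hochberg correction is applied per cancer
type, and fold changes are reported in the signed convention where a
down-regulated gene with cancer:normal ratio r < 1 is printed as -1/r.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .matrix_ops import TPM, ExpressionMatrix

logger = logging.getLogger(__name__)

NORMAL = "normal"
CANCER = "cancer"

#: Sentinel fold changes when one (or both) group mean is zero.
FC_UP_UNDEFINED = math.inf      # cancer > 0, normal = 0
FC_DOWN_UNDEFINED = -math.inf   # cancer = 0, normal > 0
FC_UNDEFINED = math.nan         # both means zero


@dataclass
class DiffExpResult:
    """Per-gene differential-expression summary."""

    row_id: str
    mean_normal: float
    mean_cancer: float
    signed_fc: float
    p_raw: float
    p_bh: float
    n_permutations: int

    def __post_init__(self) -> None:
        for p in (self.p_raw, self.p_bh):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"p-value out of [0,1]: {p}")


def _mean_diff_stat(cancer_means: np.ndarray, normal_means: np.ndarray) -> np.ndarray:
    return np.abs(cancer_means - normal_means)


def permutation_test(
    matrix: ExpressionMatrix,
    labels: Mapping[str, str],
    n_permutations: int = 10_000,
    seed: int | None = None,
    min_group_size: int = 5,
    allow_small_groups: bool = False,
    statistic: Callable[[np.ndarray, np.ndarray], np.ndarray] = _mean_diff_stat,
) -> dict[str, float]:
    """Label-permutation p-values for every gene in ``matrix``.

    ``labels`` maps library_id -> 'normal' | 'cancer'; unlisted libraries
    are ignored.  If the number of distinct label arrangements is at most
    ``n_permutations`` the null is enumerated exhaustively and the p-value
    is exact (#{arrangement stat >= observed} / #arrangements, observed
    arrangement included); otherwise ``n_permutations`` random
    arrangements are drawn and p = (1 + #{>= observed}) / (1 + n).
    Deterministic under a fixed seed.
    """
    if matrix.unit != TPM:
        raise ValueError("permutation_test expects TPM values")
    libs = [l for l in matrix.library_ids if l in labels]
    lab = np.array([labels[l] for l in libs])
    bad = set(lab) - {NORMAL, CANCER}
    if bad:
        raise ValueError(f"labels must be normal/cancer, got {sorted(bad)}")
    n_cancer = int((lab == CANCER).sum())
    n_normal = int((lab == NORMAL).sum())
    if min(n_cancer, n_normal) < min_group_size and not allow_small_groups:
        raise ValueError(
            f"groups of {n_normal} normal / {n_cancer} cancer libraries are "
            f"below the minimum of {min_group_size} per group "
            "(pass allow_small_groups=True to override)"
        )
    if min(n_cancer, n_normal) < 1:
        raise ValueError("both groups must be non-empty")

    X = matrix.values[libs].to_numpy(dtype=float)  # genes x libraries
    n_libs = len(libs)
    n_arrangements = math.comb(n_libs, n_cancer)

    if n_arrangements <= n_permutations:
        masks = np.zeros((n_arrangements, n_libs), dtype=bool)
        for i, combo in enumerate(combinations(range(n_libs), n_cancer)):
            masks[i, list(combo)] = True
        exact = True
    else:
        rng = np.random.default_rng(seed)
        masks = np.zeros((n_permutations, n_libs), dtype=bool)
        for i in range(n_permutations):
            masks[i, rng.choice(n_libs, size=n_cancer, replace=False)] = True
        exact = False

    observed_mask = (lab == CANCER)[None, :]
    # Single code path for observed and permuted statistics so that float
    # ties (observed arrangement vs itself) compare exactly equal.
    def stats_for(mask_block: np.ndarray) -> np.ndarray:
        cancer_means = X @ mask_block.T / n_cancer
        normal_means = X @ (~mask_block).T / n_normal
        return statistic(cancer_means, normal_means)  # genes x arrangements

    observed = stats_for(observed_mask)[:, 0]
    n_ge = np.zeros(len(X), dtype=np.int64)
    chunk = max(1, int(2e6 // max(1, len(X))))
    for start in range(0, len(masks), chunk):
        block = masks[start: start + chunk]
        n_ge += (stats_for(block) >= observed[:, None]).sum(axis=1)

    if exact:
        p = n_ge / n_arrangements
    else:
        p = (1 + n_ge) / (1 + len(masks))
    return dict(zip(matrix.row_ids, p.astype(float)))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def signed_fold_change(mean_cancer: float, mean_normal: float) -> float:
    """Cancer/normal fold change in the signed reporting convention.

    Ratios >= 1 are returned as-is; ratios < 1 as -1/ratio, so a halving
    prints as -2.0.  Zero means yield sentinels: +inf (up from zero),
    -inf (down to zero), NaN (undetected in both groups).
    """
    if mean_cancer < 0 or mean_normal < 0:
        raise ValueError("group means must be >= 0")
    if mean_normal == 0 and mean_cancer == 0:
        return FC_UNDEFINED
    if mean_normal == 0:
        return FC_UP_UNDEFINED
    if mean_cancer == 0:
        return FC_DOWN_UNDEFINED
    r = mean_cancer / mean_normal
    return r if r >= 1 else -1.0 / r


def differential_expression(
    matrix: ExpressionMatrix,
    labels: Mapping[str, str],
    n_permutations: int = 10_000,
    seed: int | None = None,
    min_group_size: int = 5,
    allow_small_groups: bool = False,
) -> list[DiffExpResult]:
    """Full per-gene analysis: group means, signed fold change, permutation
    p, and BH-adjusted p (corrected within this gene set)."""
    p_raw = permutation_test(
        matrix, labels, n_permutations=n_permutations, seed=seed,
        min_group_size=min_group_size, allow_small_groups=allow_small_groups,
    )
    libs = [l for l in matrix.library_ids if l in labels]
    lab = pd.Series({l: labels[l] for l in libs})
    normal_libs = lab.index[lab == NORMAL]
    cancer_libs = lab.index[lab == CANCER]
    mean_n = matrix.values[normal_libs].mean(axis=1)
    mean_c = matrix.values[cancer_libs].mean(axis=1)
    genes = matrix.row_ids
    p_bh = bh_adjust([p_raw[g] for g in genes])
    return [
        DiffExpResult(
            row_id=g,
            mean_normal=float(mean_n[g]),
            mean_cancer=float(mean_c[g]),
            signed_fc=signed_fold_change(float(mean_c[g]), float(mean_n[g])),
            p_raw=float(p_raw[g]),
            p_bh=float(adj),
            n_permutations=n_permutations,
        )
        for g, adj in zip(genes, p_bh)
    ]


def significant_set(
    results: Iterable[DiffExpResult],
    alpha: float = 0.05,
    min_fold: float = 2.0,
) -> set[str]:
    """Genes with BH p < alpha and |signed fold change| >= min_fold.

    Sentinel folds count as satisfying the magnitude criterion in their
    direction (inf: up from zero; -inf: down to zero); genes undetected in
    both groups (NaN fold) never qualify.
    """
    out = set()
    for r in results:
        if math.isnan(r.signed_fc):
            continue
        if r.p_bh < alpha and abs(r.signed_fc) >= min_fold:
            out.add(r.row_id)
    return out


def up_down_split(
    results: Iterable[DiffExpResult],
    alpha: float = 0.05,
    min_fold: float = 2.0,
) -> tuple[set[str], set[str]]:
    """Significant genes split into up- and down-regulated in cancer."""
    results = list(results)
    sig = significant_set(results, alpha=alpha, min_fold=min_fold)
    up = {r.row_id for r in results if r.row_id in sig and r.signed_fc > 0}
    down = {r.row_id for r in results if r.row_id in sig and r.signed_fc < 0}
    return up, down


def overlap_sets(named_sets: Mapping[str, set[str]]) -> dict[str, set[str]]:
    """Venn-region membership for 2 or 3 named sets.

    Each region key is a '&'-joined sorted tuple of the set names whose
    intersection it represents, *exclusive* of all other sets, so region
    sizes sum to the union size.  Full member lists are returned.
    """
    names = sorted(named_sets)
    if not (2 <= len(names) <= 3):
        raise ValueError("overlap_sets supports 2 or 3 sets")
    regions: dict[str, set[str]] = {}
    for r in range(1, len(names) + 1):
        for inside in combinations(names, r):
            members = set.intersection(*(named_sets[n] for n in inside))
            for n in names:
                if n not in inside:
                    members = members - named_sets[n]
            regions["&".join(inside)] = members
    return regions


def results_to_frame(results: Sequence[DiffExpResult]) -> pd.DataFrame:
    """Tabulate results for TSV export (sorted by BH p, then gene)."""
    df = pd.DataFrame(
        [
            {
                "row_id": r.row_id,
                "mean_normal": r.mean_normal,
                "mean_cancer": r.mean_cancer,
                "signed_fc": r.signed_fc,
                "p_raw": r.p_raw,
                "p_bh": r.p_bh,
            }
            for r in results
        ]
    )
    return df.sort_values(["p_bh", "row_id"]).reset_index(drop=True)
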