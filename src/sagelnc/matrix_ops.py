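"""Expression-matrix operations: filtering, collapsing, TPM, atlas calls.

These are the steps between the raw unique-tag matrix and the analysis
matrices: the low-count tag filter, the tag-to-gene collapse (summing all
tags of a gene to capture transcript variants), tags-per-million
normalisation against the *full* library totals, tissue averaging,
ubiquitous / tissue-exclusive detection, and mean/CV rankings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .reference import TagAssignment
from .sage_io import TagMatrix

logger = logging.getLogger(__name__)

RAW_COUNTS = "raw_counts"
TPM = "TPM"


@dataclass
class ExpressionMatrix:
    """Gene (or tag) by library expression matrix.

    ``library_totals`` are raw per-library totals of the *complete*
    libraries, so TPM normalisation of any row subset uses the same
    denominator a whole-library normalisation would.
    """

    values: pd.DataFrame
    library_totals: pd.Series
    unit: str = RAW_COUNTS

    def __post_init__(self) -> None:
        if self.unit not in (RAW_COUNTS, TPM):
            raise ValueError(f"unknown unit {self.unit!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be >= 0")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate row_ids")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate library_ids")
        self.library_totals = self.library_totals.reindex(self.values.columns)
        if self.library_totals.isna().any() or (self.library_totals <= 0).any():
            raise ValueError("library_totals must be present and > 0")

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def library_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_libraries(self, library_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = set(library_ids) - set(self.values.columns)
        if missing:
            raise KeyError(f"unknown libraries {sorted(missing)}")
        return ExpressionMatrix(
            self.values[list(library_ids)].copy(),
            self.library_totals[list(library_ids)].copy(),
            unit=self.unit,
        )

    def drop_undetected(self) -> "ExpressionMatrix":
        """Remove rows with no detected expression in any retained library."""
        keep = self.values.sum(axis=1) > 0
        return ExpressionMatrix(
            self.values.loc[keep].copy(), self.library_totals.copy(), unit=self.unit
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# unit: {self.unit}\n")
            self.values.sort_index().to_csv(fh, sep="\t", index_label="row_id")

    @classmethod
    def from_tsv(cls, path: str | Path, library_totals: pd.Series,
                 unit: str | None = None) -> "ExpressionMatrix":
        with open(path) as fh:
            first = fh.readline()
            header_unit = None
            if first.startswith("# unit:"):
                header_unit = first.split(":", 1)[1].strip()
            else:
                fh.seek(0)
            values = pd.read_csv(fh, sep="\t", index_col="row_id")
        return cls(values, library_totals, unit=unit or header_unit or RAW_COUNTS)


def filter_tags_min_counts(
    matrix: TagMatrix, min_count: int = 2, min_libraries: int = 3
) -> TagMatrix:
    """Keep tags with >= ``min_count`` raw counts in >= ``min_libraries``
    distinct libraries."""
    n_libs = len(matrix.library_ids)
    if min_libraries > n_libs:
        logger.warning(
            "min_libraries=%d exceeds the %d libraries; result is empty",
            min_libraries, n_libs,
        )
    ok = (matrix.counts >= min_count).sum(axis=1) >= min_libraries
    kept = matrix.counts.loc[ok]
    logger.info(
        "tag filter (>=%d in >=%d libraries): kept %d of %d tags",
        min_count, min_libraries, len(kept), len(matrix.counts),
    )
    return TagMatrix(kept.copy(), matrix.library_totals.copy())


def collapse_tags_to_genes(
    matrix: TagMatrix, assignments: Sequence[TagAssignment]
) -> tuple[ExpressionMatrix, pd.Series]:
    """Sum member-tag counts per gene (capturing all transcript variants).

    Assignments referencing tags absent from the matrix are ignored with
    a warning.  Returns the gene-level count matrix and the member-tag
    count per gene.
    """
    present = set(matrix.tags)
    usable = [a for a in assignments if a.tag in present]
    n_missing = len(assignments) - len(usable)
    if n_missing:
        logger.warning(
            "%d assignments reference tags absent from the matrix", n_missing
        )
    if not usable:
        empty = pd.DataFrame(
            np.zeros((0, len(matrix.library_ids))), columns=matrix.library_ids
        )
        return (
            ExpressionMatrix(empty, matrix.library_totals.copy(), unit=RAW_COUNTS),
            pd.Series(dtype=int),
        )
    tag_to_gene = pd.Series({a.tag: a.ensembl_id for a in usable})
    sub = matrix.counts.loc[tag_to_gene.index]
    collapsed = sub.groupby(tag_to_gene).sum().sort_index()
    members = tag_to_gene.groupby(tag_to_gene).size().sort_index()
    members.index.name = None
    return (
        ExpressionMatrix(collapsed, matrix.library_totals.copy(), unit=RAW_COUNTS),
        members.rename("n_tags"),
    )


def tpm_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Convert raw counts to tags per million of the full library total."""
    if matrix.unit != RAW_COUNTS:
        raise ValueError("tpm_normalize expects raw counts")
    if (matrix.library_totals == 0).any():
        raise ValueError("library total of 0; cannot normalize")
    tpm = matrix.values.div(matrix.library_totals, axis=1) * 1e6
    return ExpressionMatrix(tpm, matrix.library_totals.copy(), unit=TPM)


def average_by_group(
    matrix: ExpressionMatrix,
    grouping: Mapping[str, str],
    drop_undetected: bool = False,
) -> ExpressionMatrix:
    """Average TPM columns within groups (e.g. libraries of one tissue).

    ``grouping`` maps library_id -> group label; libraries absent from the
    mapping are dropped.  Group totals are set to the mean member total so
    the result remains a valid matrix (they have no analysis role once the
    values are TPM).
    """
    if matrix.unit != TPM:
        raise ValueError("average_by_group expects TPM values")
    groups: dict[str, list[str]] = {}
    for lib in matrix.library_ids:
        g = grouping.get(lib)
        if g is not None:
            groups.setdefault(g, []).append(lib)
    if not groups:
        raise ValueError("no libraries matched the grouping")
    for g, members in groups.items():
        if not members:
            raise ValueError(f"empty group {g!r}")
    names = sorted(groups)
    averaged = pd.DataFrame(
        {g: matrix.values[groups[g]].mean(axis=1) for g in names}
    )
    totals = pd.Series(
        {g: float(matrix.library_totals[groups[g]].mean()) for g in names}
    )
    out = ExpressionMatrix(averaged, totals, unit=TPM)
    return out.drop_undetected() if drop_undetected else out


def detect_ubiquitous(
    matrix: ExpressionMatrix, fraction: float = 0.90
) -> list[str]:
    """Rows detected (nonzero) in strictly more than ``fraction`` of libraries."""
    n_libs = len(matrix.library_ids)
    detected = (matrix.values > 0).sum(axis=1)
    return sorted(matrix.values.index[detected > fraction * n_libs])


def detect_exclusive(
    tissue_matrix: ExpressionMatrix,
    min_tpm: float = 10.0,
    tolerance: float = 0.0,
) -> dict[str, str]:
    """Rows expressed >= ``min_tpm`` in exactly one tissue and (up to
    ``tolerance`` TPM) nowhere else, mapped to that tissue."""
    out: dict[str, str] = {}
    vals = tissue_matrix.values
    high = vals.ge(min_tpm)
    low_elsewhere = vals.le(tolerance)
    for row_id in vals.index:
        h = high.loc[row_id]
        if h.sum() == 1:
            tissue = h.idxmax()
            others = low_elsewhere.loc[row_id].drop(tissue)
            if others.all():
                out[row_id] = tissue
    return out


def rank_rows(
    matrix: ExpressionMatrix, by: str = "mean", top_n: int | None = None
) -> list[tuple[str, float]]:
    """Rank rows by mean expression or by coefficient of variation.

    CV = sample (n-1) standard deviation / mean over the columns; rows
    with zero mean are excluded from CV ranking with a warning.  Ties are
    broken by row_id for determinism; descending order.
    """
    if by not in ("mean", "cv"):
        raise ValueError("by must be 'mean' or 'cv'")
    means = matrix.values.mean(axis=1)
    if by == "mean":
        scores = means
    else:
        zero = means == 0
        if zero.any():
            logger.warning("excluding %d all-zero rows from CV ranking", zero.sum())
        sub = matrix.values.loc[~zero]
        scores = sub.std(axis=1, ddof=1) / means[~zero]
    order = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_n is not None:
        order = order[:top_n]
    return [(rid, float(s)) for rid, s in order]


def cap_values(matrix: ExpressionMatrix, cap: float = 300.0) -> ExpressionMatrix:
    """Clip values above ``cap`` (display matrices for heatmaps only)."""
    if cap <= 0:
        raise ValueError("cap must be > 0")
    return ExpressionMatrix(
        matrix.values.clip(upper=cap), matrix.library_totals.copy(), unit=matrix.unit
    )


def plot_heatmap(
    matrix: ExpressionMatrix,
    path: str | Path,
    cap: float = 300.0,
    row_ids: Iterable[str] | None = None,
) -> None:
    """Render a basic expression heatmap (values capped at ``cap``)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    disp = cap_values(matrix, cap).values
    if row_ids is not None:
        disp = disp.loc[list(row_ids)]
    fig, ax = plt.subplots(
        figsize=(max(4, 0.4 * disp.shape[1]), max(3, 0.25 * disp.shape[0]))
    )
    im = ax.imshow(disp.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(disp.shape[1]), disp.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(disp.shape[0]), disp.index, fontsize=6)
    fig.colorbar(im, ax=ax, label=matrix.unit)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
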