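"""Chromosome gene-density profiles and their rank correlation.

Gene classes (lncRNAs, miRNAs, protein-coding genes) are summarised as
genes per 100 Mb of chromosome; similarity of two classes' genomic
distributions is assessed with a Spearman rank correlation over the
shared chromosome set.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

DENSITY_WINDOW = 1e8  # bp per density unit (100 Mb)

#: Default chromosome universe: 22 autosomes plus the sex chromosomes.
AUTOSOMES_XY = tuple(str(i) for i in range(1, 23)) + ("X", "Y")


@dataclass
class ChromosomeDensity:
    chromosome: str
    length: int
    gene_count: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.chromosome}: length must be > 0")
        if self.gene_count < 0:
            raise ValueError(f"{self.chromosome}: negative gene count")

    @property
    def density(self) -> float:
        """Genes per 100 Mb."""
        return self.gene_count / self.length * DENSITY_WINDOW


def read_chromosome_lengths(path: str | Path) -> dict[str, int]:
    """Read a two-column (chromosome, length) TSV."""
    tbl = pd.read_csv(path, sep="\t", dtype={0: str}, comment="#")
    cols = list(tbl.columns)
    return dict(zip(tbl[cols[0]].astype(str), tbl[cols[1]].astype(int)))


def density_profile(
    gene_chromosomes: Sequence[str], chrom_lengths: Mapping[str, int]
) -> list[ChromosomeDensity]:
    """Per-chromosome gene density for one gene class.

    Every chromosome in ``chrom_lengths`` appears in the output (zero
    counts included); genes on chromosomes absent from the length table
    raise an error naming the offenders.
    """
    unknown = sorted(set(gene_chromosomes) - set(chrom_lengths))
    if unknown:
        raise ValueError(
            f"genes on chromosomes not in the length table: {unknown}"
        )
    counts = pd.Series(gene_chromosomes).value_counts()
    return [
        ChromosomeDensity(
            chromosome=str(chrom),
            length=int(length),
            gene_count=int(counts.get(chrom, 0)),
        )
        for chrom, length in chrom_lengths.items()
    ]


def density_correlation(
    a: Sequence[ChromosomeDensity],
    b: Sequence[ChromosomeDensity],
    exact: bool = False,
) -> tuple[float, float]:
    """Spearman correlation of two density profiles over the same chromosomes.

    Uses average ranks for ties and a two-sided p-value (large-sample t
    approximation; with ``exact=True`` an exhaustive pairing-permutation
    p is computed instead, practical for ~10 chromosomes or fewer).
    """
    chroms_a = [d.chromosome for d in a]
    chroms_b = [d.chromosome for d in b]
    if set(chroms_a) != set(chroms_b):
        raise ValueError("density profiles cover different chromosome sets")
    if len(chroms_a) < 3:
        raise ValueError("need at least 3 chromosomes")
    da = pd.Series({d.chromosome: d.density for d in a})
    db = pd.Series({d.chromosome: d.density for d in b}).reindex(da.index)
    if exact:
        res = stats.permutation_test(
            (da.to_numpy(), db.to_numpy()),
            lambda x, y: stats.spearmanr(x, y).statistic,
            permutation_type="pairings",
            n_resamples=math_inf_resamples(len(da)),
            alternative="two-sided",
        )
        rho = stats.spearmanr(da, db).statistic
        return float(rho), float(res.pvalue)
    rho, p = stats.spearmanr(da, db)
    return float(rho), float(p)


def math_inf_resamples(n: int) -> int:
    """Resample budget forcing exhaustive enumeration of n! pairings."""
    import math

    return math.factorial(n)


def densities_to_frame(profile: Sequence[ChromosomeDensity]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chromosome": d.chromosome,
                "length": d.length,
                "gene_count": d.gene_count,
                "density_per_100mb": d.density,
            }
            for d in profile
        ]
    )
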