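"""Reading, writing and assembling short-SAGE tag-count libraries.

A short-SAGE library is a table of 10-base tags (the bases immediately
3' of the 3'-most NlaIII site, CATG) with their observed counts.  The
on-disk dialect is a two-column TSV (``<tag><TAB><count>``) with optional
``#`` comment lines, the format typically obtained from GEO supplementary
files.  Libraries carry tissue/phenotype metadata from a catalog table.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

TAG_LENGTH = 10
TAG_PATTERN = re.compile(r"^[ACGT]{10}$")

#: Allowed library phenotypes. ``precancer`` covers metaplasia/dysplasia/
#: inflammatory samples, which are excluded from tumour-vs-normal contrasts.
PHENOTYPES = ("normal", "cancer", "precancer", "cell_line")


class SageIOError(ValueError):
    """Raised for malformed library files or inconsistent metadata."""


def _validate_tag(tag: str) -> None:
    if not TAG_PATTERN.match(tag):
        raise SageIOError(
            f"invalid SAGE tag {tag!r}: expected exactly {TAG_LENGTH} "
            "characters over A/C/G/T"
        )


@dataclass
class SageLibrary:
    """One SAGE library: tag counts plus sample metadata.

    ``total_raw_tags`` is always the sum of ``tag_counts`` and is the
    denominator later used for tags-per-million normalisation.
    """

    library_id: str
    tissue: str
    phenotype: str
    tag_counts: dict[str, int]
    accession: str = ""
    total_raw_tags: int = field(init=False)

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise SageIOError(
                f"library {self.library_id!r}: unknown phenotype "
                f"{self.phenotype!r} (expected one of {PHENOTYPES})"
            )
        for tag, count in self.tag_counts.items():
            _validate_tag(tag)
            if not isinstance(count, (int,)) or count < 1:
                raise SageIOError(
                    f"library {self.library_id!r}: tag {tag} has "
                    f"non-positive or non-integer count {count!r}"
                )
        self.total_raw_tags = int(sum(self.tag_counts.values()))

    @property
    def n_unique_tags(self) -> int:
        return len(self.tag_counts)


def read_sage_library(
    path: str | Path, metadata: Mapping[str, str]
) -> SageLibrary:
    """Read one two-column tag/count file into a :class:`SageLibrary`.

    Lowercase tags are uppercased; duplicate tag lines are merged by
    summation with a warning (a dialect quirk seen in real GEO exports).
    ``metadata`` must provide ``library_id``, ``tissue`` and ``phenotype``
    (``accession`` optional), typically one catalog row.
    """
    path = Path(path)
    counts: dict[str, int] = {}
    n_data_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise SageIOError(
                    f"{path}:{lineno}: expected '<tag><TAB><count>', got {line!r}"
                )
            tag, count_str = parts[0].strip().upper(), parts[1].strip()
            if not TAG_PATTERN.match(tag):
                raise SageIOError(
                    f"{path}:{lineno}: invalid tag {parts[0]!r} (need "
                    f"{TAG_LENGTH}-mer over A/C/G/T)"
                )
            try:
                count = int(count_str)
            except ValueError:
                raise SageIOError(
                    f"{path}:{lineno}: non-integer count {count_str!r}"
                ) from None
            if count < 1:
                raise SageIOError(f"{path}:{lineno}: count must be >= 1, got {count}")
            if tag in counts:
                logger.warning(
                    "%s:%d: duplicate tag %s merged additively", path, lineno, tag
                )
            counts[tag] = counts.get(tag, 0) + count
            n_data_lines += 1
    if n_data_lines == 0:
        raise SageIOError(f"{path}: no tag records found (empty library file)")
    return SageLibrary(
        library_id=str(metadata["library_id"]),
        tissue=str(metadata["tissue"]),
        phenotype=str(metadata["phenotype"]),
        accession=str(metadata.get("accession", "") or ""),
        tag_counts=counts,
    )


def write_sage_library(library: SageLibrary, path: str | Path) -> None:
    """Write a library in the two-column dialect, tags sorted for determinism."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# library_id={library.library_id}\n")
        for tag in sorted(library.tag_counts):
            fh.write(f"{tag}\t{library.tag_counts[tag]}\n")


# ---------------------------------------------------------------------------
# Library catalog


def read_catalog(path: str | Path) -> pd.DataFrame:
    """Read a library catalog (CSV, TSV or YAML) into a DataFrame.

    Required columns: library_id, tissue, phenotype; optional: accession,
    plus free-form grouping columns used by downstream analyses.
    """
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path) as fh:
            rows = yaml.safe_load(fh)
        cat = pd.DataFrame(rows)
    else:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        cat = pd.read_csv(path, sep=sep, dtype=str, comment="#")
    required = {"library_id", "tissue", "phenotype"}
    missing = required - set(cat.columns)
    if missing:
        raise SageIOError(f"{path}: catalog missing columns {sorted(missing)}")
    if "accession" not in cat.columns:
        cat["accession"] = ""
    if cat["library_id"].duplicated().any():
        dups = cat.loc[cat["library_id"].duplicated(), "library_id"].tolist()
        raise SageIOError(f"{path}: duplicate library_ids {dups}")
    bad = set(cat["phenotype"]) - set(PHENOTYPES)
    if bad:
        raise SageIOError(f"{path}: unknown phenotypes {sorted(bad)}")
    return cat.reset_index(drop=True)


def read_libraries(
    catalog: pd.DataFrame, libdir: str | Path, suffix: str = ".tsv"
) -> list[SageLibrary]:
    """Read every catalogued library from ``libdir/<library_id><suffix>``."""
    libdir = Path(libdir)
    return [
        read_sage_library(libdir / f"{row.library_id}{suffix}", row._asdict())
        for row in catalog.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Depth filter and tag matrix


def filter_libraries_by_depth(
    libraries: Sequence[SageLibrary], min_depth: int = 50_000
) -> list[SageLibrary]:
    """Keep libraries whose raw tag total is strictly greater than ``min_depth``.

    The strict inequality follows the protocol of retaining libraries with
    more than 50,000 raw tags; order is preserved.
    """
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    kept = [lib for lib in libraries if lib.total_raw_tags > min_depth]
    n_dropped = len(libraries) - len(kept)
    logger.info(
        "depth filter (> %d): kept %d libraries, dropped %d",
        min_depth, len(kept), n_dropped,
    )
    if not kept and libraries:
        logger.warning("depth filter removed every library")
    return kept


@dataclass
class TagMatrix:
    """Unique-tag count matrix: rows are tags, columns are libraries.

    ``library_totals`` are the *full* per-library raw totals, kept separate
    from the matrix so subsetting rows never changes the TPM denominator.
    """

    counts: pd.DataFrame
    library_totals: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise SageIOError("TagMatrix has duplicate tag rows")
        if self.counts.columns.duplicated().any():
            raise SageIOError("TagMatrix has duplicate library columns")
        if list(self.library_totals.index) != list(self.counts.columns):
            self.library_totals = self.library_totals.reindex(self.counts.columns)
        if self.library_totals.isna().any():
            raise SageIOError("library_totals missing for some columns")
        col_sums = self.counts.sum(axis=0)
        if (col_sums > self.library_totals).any():
            raise SageIOError("column sum exceeds library total")

    @property
    def tags(self) -> list[str]:
        return list(self.counts.index)

    @property
    def library_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset_tags(self, tags: Iterable[str]) -> "TagMatrix":
        keep = [t for t in self.tags if t in set(tags)]
        return TagMatrix(self.counts.loc[keep].copy(), self.library_totals.copy())

    def to_tsv(self, path: str | Path, totals_path: str | Path | None = None) -> None:
        """Write the matrix (tags sorted) and a sidecar totals file."""
        out = self.counts.sort_index()
        out.to_csv(path, sep="\t", index_label="tag")
        if totals_path is not None:
            self.library_totals.rename("total_raw_tags").to_csv(
                totals_path, sep="\t", index_label="library_id"
            )


def build_tag_matrix(libraries: Sequence[SageLibrary]) -> TagMatrix:
    """Assemble the unique-tag expression matrix across libraries.

    Rows are the union of all tags (sorted); absent cells are zero; columns
    follow library input order.  Column sums equal each library's raw total.
    """
    if not libraries:
        raise SageIOError("build_tag_matrix requires at least one library")
    ids = [lib.library_id for lib in libraries]
    if len(set(ids)) != len(ids):
        raise SageIOError(f"duplicate library_ids in input: {ids}")
    all_tags = sorted(set().union(*(lib.tag_counts.keys() for lib in libraries)))
    counts = pd.DataFrame(0, index=all_tags, columns=ids, dtype=int)
    for lib in libraries:
        col = pd.Series(lib.tag_counts)
        counts.loc[col.index, lib.library_id] = col.astype(int)
    totals = pd.Series(
        [lib.total_raw_tags for lib in libraries], index=ids, dtype=int
    )
    return TagMatrix(counts, totals)


def read_tag_matrix(path: str | Path, totals_path: str | Path) -> TagMatrix:
    counts = pd.read_csv(path, sep="\t", index_col="tag")
    totals = pd.read_csv(totals_path, sep="\t", index_col="library_id")[
        "total_raw_tags"
    ]
    return TagMatrix(counts, totals)
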