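"""Tag-to-Unigene mapping and descriptor-based lncRNA candidate calling.

Short SAGE tags can be linked to Unigene clusters through a curated
two-column mapping file (the ``Hs_short`` style table).  Tags that map are
then classified by their gene annotation: an exact name match against a
reference lncRNA name set marks a *known* lncRNA, while empty names or
annotation descriptors characteristic of unannotated transcripts
("transcribed locus", "hypothetical", FLJ/KIAA identifiers, ...) mark
*candidate* lncRNAs that are sent on to sequence-level matching.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .sage_io import TAG_PATTERN, TagMatrix

logger = logging.getLogger(__name__)

KNOWN_LNCRNA = "known_lncRNA"
CANDIDATE_LNCRNA = "candidate_lncRNA"
OTHER = "other"

# Gene-name patterns indicating provisional/unannotated identifiers.
_NAME_PATTERNS = [
    re.compile(r"^c(?:hr)?\d+orf\d+$", re.IGNORECASE),   # C#orf# / chr#orf#
    re.compile(r"^FLJ\d+$", re.IGNORECASE),
    re.compile(r"^KIAA\d+$", re.IGNORECASE),
]

# Case-insensitive substrings of the description indicating an ambiguous,
# likely non-protein-coding annotation.
_DESCRIPTION_SUBSTRINGS = [
    "non-coding",
    "non-protein",
    "cdna",
    "transcribed locus",
    "clone image",
    "hypothetical",
    "family with sequence similarity",
]


@dataclass
class UnigeneMapping:
    """Resolved tag -> Unigene cluster ID mapping."""

    tag_to_id: dict[str, str]

    def __post_init__(self) -> None:
        for tag in self.tag_to_id:
            if not TAG_PATTERN.match(tag):
                raise ValueError(f"invalid tag in mapping: {tag!r}")

    def __len__(self) -> int:
        return len(self.tag_to_id)

    def __contains__(self, tag: str) -> bool:
        return tag in self.tag_to_id


@dataclass
class GeneAnnotation:
    """Annotation of one Unigene cluster plus the reference lncRNA name set."""

    unigene_id: str
    gene_name: str = ""
    description: str = ""
    lncRNA_names: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.unigene_id:
            raise ValueError("unigene_id must be non-empty")


def load_tag_mapping(path: str | Path) -> UnigeneMapping:
    """Load a two-column (tag, Unigene ID) mapping file.

    A tag listed more than once with *conflicting* IDs is dropped entirely
    (with a warning) rather than resolved arbitrarily; consistent repeats
    are kept.
    """
    path = Path(path)
    mapping: dict[str, str] = {}
    conflicted: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected '<tag><TAB><id>'")
            tag, uid = parts[0].strip().upper(), parts[1].strip()
            if not TAG_PATTERN.match(tag):
                raise ValueError(f"{path}:{lineno}: invalid tag {parts[0]!r}")
            if tag in mapping and mapping[tag] != uid:
                conflicted.add(tag)
            else:
                mapping[tag] = uid
    for tag in conflicted:
        del mapping[tag]
    if conflicted:
        logger.warning(
            "%s: dropped %d tags with conflicting Unigene IDs", path, len(conflicted)
        )
    return UnigeneMapping(mapping)


def load_annotation(
    path: str | Path, lncRNA_names: frozenset[str] = frozenset()
) -> dict[str, GeneAnnotation]:
    """Load an annotation TSV (unigene_id, gene_name, description)."""
    tbl = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"unigene_id", "gene_name", "description"}
    missing = required - set(tbl.columns)
    if missing:
        raise ValueError(f"{path}: annotation missing columns {sorted(missing)}")
    return {
        row.unigene_id: GeneAnnotation(
            unigene_id=row.unigene_id,
            gene_name=row.gene_name,
            description=row.description,
            lncRNA_names=lncRNA_names,
        )
        for row in tbl.itertuples(index=False)
    }


def split_mapped_unmapped(
    matrix: TagMatrix, mapping: UnigeneMapping
) -> tuple[TagMatrix, TagMatrix]:
    """Partition a tag matrix into Unigene-mapped and unmapped matrices.

    The two outputs are disjoint, jointly exhaustive over the input tags,
    and share the input's columns and library totals.
    """
    mapped_tags = [t for t in matrix.tags if t in mapping]
    unmapped_tags = [t for t in matrix.tags if t not in mapping]
    return matrix.subset_tags(mapped_tags), matrix.subset_tags(unmapped_tags)


def classify_descriptor(annotation: GeneAnnotation) -> str:
    """Classify one annotation as known lncRNA, candidate lncRNA, or other.

    Known takes priority: an exact case-insensitive gene-name match against
    the reference lncRNA name set wins over any candidate descriptor.
    """
    name = annotation.gene_name.strip()
    if name and name.upper() in {n.upper() for n in annotation.lncRNA_names}:
        return KNOWN_LNCRNA
    if not name:
        return CANDIDATE_LNCRNA
    for pat in _NAME_PATTERNS:
        if pat.match(name):
            return CANDIDATE_LNCRNA
    desc = annotation.description.lower()
    for sub in _DESCRIPTION_SUBSTRINGS:
        if sub in desc:
            return CANDIDATE_LNCRNA
    return OTHER


def classify_tags(
    tags: list[str],
    mapping: UnigeneMapping,
    annotations: dict[str, GeneAnnotation],
) -> dict[str, str]:
    """Classify each Unigene-mapped tag via its cluster's annotation.

    Tags whose Unigene ID has no annotation row are treated as candidates
    (no confirmed association with a known gene).
    """
    out: dict[str, str] = {}
    for tag in tags:
        uid = mapping.tag_to_id.get(tag)
        if uid is None:
            continue
        ann = annotations.get(uid)
        out[tag] = classify_descriptor(ann) if ann is not None else CANDIDATE_LNCRNA
    return out
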