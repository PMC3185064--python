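"""LncRNA reference handling and exact, strand-aware tag matching.

The reference is a gene table (ID, name, coordinates, strand, biotype:
lincRNA or processed_transcript) paired with transcript sequences in
FASTA.  Short-SAGE tags are matched to transcripts as the anchored 14-mer
``CATG`` + tag: a *forward* match (the 14-mer on the transcript's own
strand) is evidence that the transcript is expressed, whereas a *reverse*
match (the 14-mer's reverse complement) is not and is excluded.  Tags
whose forward matches hit more than one distinct gene are discarded as
multi-mapping.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import reverse_complement

from .sage_io import TAG_LENGTH, TAG_PATTERN

logger = logging.getLogger(__name__)

ANCHOR = "CATG"
BIOTYPES = ("lincRNA", "processed_transcript")

FORWARD = "forward"
REVERSE = "reverse"


@dataclass
class LncRNARecord:
    """One reference lncRNA gene with its transcript sequence(s).

    Coordinates are 1-based inclusive; ``strand`` is +1 or -1.  A record
    with no sequence is loadable but cannot take part in tag matching.
    """

    ensembl_id: str
    gene_name: str
    chromosome: str
    start: int
    end: int
    strand: int
    biotype: str
    transcript_sequences: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.ensembl_id}: start > end")
        if self.strand not in (1, -1):
            raise ValueError(f"{self.ensembl_id}: strand must be +1/-1")
        if self.biotype not in BIOTYPES:
            raise ValueError(
                f"{self.ensembl_id}: biotype {self.biotype!r} not in {BIOTYPES}"
            )
        self.transcript_sequences = [s.upper() for s in self.transcript_sequences]

    @property
    def matchable(self) -> bool:
        return len(self.transcript_sequences) > 0


@dataclass
class TagAssignment:
    """A tag's resolved link to one lncRNA gene.

    Only forward, single-target assignments are retained downstream;
    ``source`` records whether the link came from Unigene annotation or
    from sequence matching.
    """

    tag: str
    ensembl_id: str
    orientation: str = FORWARD
    n_targets: int = 1
    source: str = "sequence_match"

    def __post_init__(self) -> None:
        if not TAG_PATTERN.match(self.tag):
            raise ValueError(f"invalid tag {self.tag!r}")
        if self.orientation not in (FORWARD, REVERSE):
            raise ValueError(f"orientation must be forward/reverse")
        if self.n_targets < 1:
            raise ValueError("n_targets must be >= 1")
        if self.source not in ("unigene", "sequence_match"):
            raise ValueError(f"unknown source {self.source!r}")


def _parse_strand(value) -> int:
    s = str(value).strip()
    if s in ("1", "+1", "+"):
        return 1
    if s in ("-1", "−1", "-"):
        return -1
    raise ValueError(f"cannot parse strand {value!r}")


def load_reference(
    gene_table: str | Path,
    fasta: str | Path,
    transcript_map: str | Path | None = None,
    id_remap: str | Path | None = None,
) -> list[LncRNARecord]:
    """Load the lncRNA reference: gene table TSV + transcript FASTA.

    FASTA IDs (first whitespace-delimited header token) are gene IDs, or
    transcript IDs resolved through the optional two-column
    ``transcript_map`` (transcript_id, gene_id).  Records without any
    sequence are loaded but flagged unmatchable with a warning.  An
    optional two-column ``id_remap`` table (old_id, new_id), in the spirit
    of an assembly/release ID lift, is applied last: genes absent from it
    are dropped.
    """
    tbl = pd.read_csv(gene_table, sep="\t", dtype=str, keep_default_na=False)
    required = {"ensembl_id", "gene_name", "chromosome", "start", "end",
                "strand", "biotype"}
    missing = required - set(tbl.columns)
    if missing:
        raise ValueError(f"{gene_table}: missing columns {sorted(missing)}")
    if tbl["ensembl_id"].duplicated().any():
        raise ValueError(f"{gene_table}: duplicate ensembl_ids")

    tx_to_gene: dict[str, str] = {}
    if transcript_map is not None:
        tmap = pd.read_csv(
            transcript_map, sep="\t", header=None, names=["tx", "gene"], dtype=str
        )
        tx_to_gene = dict(zip(tmap["tx"], tmap["gene"]))

    sequences: dict[str, list[str]] = defaultdict(list)
    n_fasta = 0
    for rec in SeqIO.parse(str(fasta), "fasta"):
        n_fasta += 1
        gene_id = tx_to_gene.get(rec.id, rec.id)
        sequences[gene_id].append(str(rec.seq).upper())

    known_ids = set(tbl["ensembl_id"])
    matched_ids = known_ids & set(sequences)
    if n_fasta > 0 and not matched_ids:
        raise ValueError(
            f"no FASTA sequence ID matches any gene-table ID; "
            f"check the {fasta} / {gene_table} pairing"
        )

    records = [
        LncRNARecord(
            ensembl_id=row.ensembl_id,
            gene_name=row.gene_name,
            chromosome=row.chromosome,
            start=int(row.start),
            end=int(row.end),
            strand=_parse_strand(row.strand),
            biotype=row.biotype,
            transcript_sequences=sequences.get(row.ensembl_id, []),
        )
        for row in tbl.itertuples(index=False)
    ]
    n_unmatchable = sum(not r.matchable for r in records)
    if n_unmatchable:
        logger.warning(
            "%d of %d reference genes have no transcript sequence and are "
            "excluded from tag matching", n_unmatchable, len(records),
        )

    if id_remap is not None:
        rmap = pd.read_csv(
            id_remap, sep="\t", header=None, names=["old", "new"], dtype=str
        )
        lift = dict(zip(rmap["old"], rmap["new"]))
        lifted = []
        for rec in records:
            new_id = lift.get(rec.ensembl_id)
            if new_id is None:
                continue
            rec.ensembl_id = new_id
            lifted.append(rec)
        logger.info(
            "ID remap: kept %d of %d genes", len(lifted), len(records)
        )
        records = lifted
    return records


def extract_canonical_tag(sequence: str) -> str | None:
    """Extract the canonical short-SAGE tag from a transcript sequence.

    The canonical tag is the 10 bases immediately 3' of the 3'-most CATG
    occurrence that still has >= 10 downstream bases.  Returns ``None``
    when no such site exists or the tag at that site contains N.
    """
    seq = sequence.upper()
    # anchor start must leave room for the 4-base site plus a full 10-mer
    pos = seq.rfind(ANCHOR, 0, len(seq) - TAG_LENGTH)
    if pos == -1:
        return None
    tag = seq[pos + len(ANCHOR): pos + len(ANCHOR) + TAG_LENGTH]
    if not TAG_PATTERN.match(tag):
        return None
    return tag


class TagIndex:
    """Exact-match index of anchored tag windows over a reference set.

    For every transcript sequence (and its reverse complement) each
    occurrence of CATG with >= 10 downstream bases contributes one 10-mer
    window; a query tag matches a gene forward if its window occurs on the
    transcript's own strand, reverse if on the complement.  Matching is
    position-unconstrained: any anchored site qualifies, not only the
    3'-most one.  With ``require_catg_prefix=False`` every 10-mer window
    (anchored or not) is indexed instead, i.e. plain substring matching.
    """

    def __init__(
        self,
        records: Sequence[LncRNARecord],
        require_catg_prefix: bool = True,
    ) -> None:
        self._index: dict[str, set[tuple[str, str]]] = defaultdict(set)
        for rec in records:
            if not rec.matchable:
                continue
            for seq in rec.transcript_sequences:
                for tag in self._windows(seq, require_catg_prefix):
                    self._index[tag].add((rec.ensembl_id, FORWARD))
                for tag in self._windows(
                    reverse_complement(seq), require_catg_prefix
                ):
                    self._index[tag].add((rec.ensembl_id, REVERSE))

    @staticmethod
    def _windows(seq: str, anchored: bool) -> Iterable[str]:
        if anchored:
            start = seq.find(ANCHOR)
            while start != -1:
                tag = seq[start + len(ANCHOR): start + len(ANCHOR) + TAG_LENGTH]
                if len(tag) == TAG_LENGTH and TAG_PATTERN.match(tag):
                    yield tag
                start = seq.find(ANCHOR, start + 1)
        else:
            for i in range(len(seq) - TAG_LENGTH + 1):
                tag = seq[i: i + TAG_LENGTH]
                if TAG_PATTERN.match(tag):
                    yield tag

    def lookup(self, tag: str) -> list[tuple[str, str]]:
        """All (gene_id, orientation) hits for a tag, sorted for determinism."""
        return sorted(self._index.get(tag.upper(), ()))


def match_tag(
    tag: str,
    records: Sequence[LncRNARecord],
    require_catg_prefix: bool = True,
) -> list[tuple[str, str]]:
    """Match one tag against a reference set (exact, 0 mismatches).

    Convenience wrapper that builds a one-shot :class:`TagIndex`; for many
    tags build the index once and use :func:`assign_tags`.
    """
    return TagIndex(records, require_catg_prefix).lookup(tag)


@dataclass
class AssignmentResult:
    """Outcome of assigning a tag set to the reference.

    ``assignments`` holds the retained (forward, single-gene) links;
    multi-mapping, reverse-only and unmatched tags are reported so that
    every input tag lands in exactly one tally (forward takes precedence
    for tags matching in both orientations).
    """

    assignments: list[TagAssignment]
    multi_mapped: dict[str, list[str]]
    reverse_only: list[str]
    unmatched: list[str]

    @property
    def n_forward(self) -> int:
        return len(self.assignments) + len(self.multi_mapped)

    def tallies(self) -> dict[str, int]:
        return {
            "forward_retained": len(self.assignments),
            "forward_multi_mapped": len(self.multi_mapped),
            "reverse_only": len(self.reverse_only),
            "unmatched": len(self.unmatched),
        }


def assign_tags(
    tags: Sequence[str],
    records: Sequence[LncRNARecord],
    require_catg_prefix: bool = True,
) -> AssignmentResult:
    """Assign tags to lncRNAs, keeping forward single-target matches.

    A tag with forward matches to exactly one distinct gene yields one
    retained :class:`TagAssignment`; forward matches to more than one gene
    are discarded as multi-mapping; reverse-only matches are excluded but
    tallied (they do not corroborate expression of the matched gene).
    """
    index = TagIndex(records, require_catg_prefix)
    assignments: list[TagAssignment] = []
    multi: dict[str, list[str]] = {}
    reverse_only: list[str] = []
    unmatched: list[str] = []
    seen: set[str] = set()
    for tag in tags:
        tag = tag.upper()
        if tag in seen:
            continue
        seen.add(tag)
        hits = index.lookup(tag)
        fwd_genes = sorted({g for g, o in hits if o == FORWARD})
        if fwd_genes:
            if len(fwd_genes) == 1:
                assignments.append(
                    TagAssignment(
                        tag=tag,
                        ensembl_id=fwd_genes[0],
                        orientation=FORWARD,
                        n_targets=1,
                        source="sequence_match",
                    )
                )
            else:
                multi[tag] = fwd_genes
        elif hits:  # reverse matches only
            reverse_only.append(tag)
        else:
            unmatched.append(tag)
    return AssignmentResult(assignments, multi, reverse_only, unmatched)


def merge_assignments(
    sequence_assignments: Iterable[TagAssignment],
    unigene_assignments: Iterable[TagAssignment],
) -> tuple[list[TagAssignment], dict[str, list[str]]]:
    """Pool sequence-match and Unigene-derived tag assignments.

    When both sources assign the same tag to the same gene the sequence
    match is kept; when they point to different genes the tag is discarded
    as multi-mapping (returned in the conflict report).
    """
    by_tag: dict[str, TagAssignment] = {a.tag: a for a in sequence_assignments}
    conflicts: dict[str, list[str]] = {}
    merged = dict(by_tag)
    for a in unigene_assignments:
        prior = by_tag.get(a.tag)
        if prior is None:
            merged[a.tag] = a
        elif prior.ensembl_id != a.ensembl_id:
            conflicts[a.tag] = sorted({prior.ensembl_id, a.ensembl_id})
            merged.pop(a.tag, None)
    if conflicts:
        logger.warning(
            "%d tags discarded: Unigene and sequence matching disagree",
            len(conflicts),
        )
    return [merged[t] for t in sorted(merged)], conflicts


def write_assignments(
    result: AssignmentResult, path: str | Path
) -> None:
    """Write the retained assignment table as TSV."""
    rows = [
        {
            "tag": a.tag,
            "ensembl_id": a.ensembl_id,
            "orientation": a.orientation,
            "n_targets": a.n_targets,
            "source": a.source,
        }
        for a in sorted(result.assignments, key=lambda a: a.tag)
    ]
    pd.DataFrame(
        rows, columns=["tag", "ensembl_id", "orientation", "n_targets", "source"]
    ).to_csv(path, sep="\t", index=False)
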