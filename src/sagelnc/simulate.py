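"""Synthetic SAGE studies with known ground truth.

The generator emulates the data the discovery pipeline consumes: a
reference transcriptome whose transcripts carry extractable anchored
tags, tissue-structured expression profiles with planted housekeeping,
tissue-exclusive and differentially expressed genes, and SAGE libraries
drawn multinomially at a configurable sequencing depth.  A configurable
share of each library's mass goes to decoy tags absent from the
reference, standing in for the bulk of real SAGE tags that derive from
protein-coding transcripts.

Everything is deterministic under a seed, and the planted truth is
returned alongside the data so recovery can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .reference import (
    ANCHOR,
    LncRNARecord,
    TagIndex,
    extract_canonical_tag,
)
from .sage_io import TAG_LENGTH, SageLibrary, write_sage_library

BASES = np.array(list("ACGT"))

#: Toy karyotype used for synthetic gene coordinates (chromosome -> bp).
TOY_KARYOTYPE = {"1": 200_000_000, "2": 150_000_000, "3": 100_000_000,
                 "4": 80_000_000, "X": 60_000_000}

ROLE_HOUSEKEEPING = "housekeeping"
ROLE_DE_UP = "de_up"
ROLE_DE_DOWN = "de_down"
ROLE_NULL = "null"


def role_exclusive(tissue: str) -> str:
    return f"tissue_exclusive:{tissue}"


@dataclass
class SyntheticDesign:
    """Study design for a synthetic SAGE experiment.

    Defaults describe a modest cancer-vs-normal atlas: six tissues of
    which three have matched cancer groups, five libraries per group at a
    depth of 100,000 tags, 200 reference genes with ~30% planted
    differential expression at four-fold, log-normal baseline abundances,
    and 20% of each library's mass on non-reference decoy tags.
    """

    tissues: tuple[str, ...] = ("brain", "breast", "lung", "liver", "heart",
                                "kidney")
    cancer_tissues: tuple[str, ...] = ("brain", "breast", "lung")
    n_genes: int = 200
    n_housekeeping: int = 20
    n_exclusive_per_tissue: int = 2
    n_de_up: int = 30
    n_de_down: int = 30
    de_fold: float = 4.0
    lognormal_sigma: float = 0.8
    noise_fraction: float = 0.20
    n_decoy_tags: int = 300
    tag_collision_rate: float = 0.0
    libraries_per_group: int = 5
    depth: int = 100_000

    def __post_init__(self) -> None:
        if len(self.tissues) < 2:
            raise ValueError("need at least 2 tissues")
        if set(self.cancer_tissues) - set(self.tissues):
            raise ValueError("cancer_tissues must be a subset of tissues")
        if self.de_fold < 1:
            raise ValueError("planted fold changes must be >= 1")
        if not (0 <= self.noise_fraction < 1):
            raise ValueError("noise_fraction must be in [0, 1)")
        n_special = (self.n_housekeeping
                     + self.n_exclusive_per_tissue * len(self.tissues)
                     + self.n_de_up + self.n_de_down)
        if n_special > self.n_genes:
            raise ValueError(
                f"design plants {n_special} special genes but has only "
                f"{self.n_genes} genes"
            )


@dataclass
class SyntheticTruth:
    """Planted ground truth of a synthetic study.

    ``expected_tpm[(tissue, phenotype)]`` is the per-gene expected TPM of
    a library from that condition; ``roles`` partitions the gene set.
    """

    roles: dict[str, str]
    de_fold: float
    expected_tpm: dict[tuple[str, str], pd.Series]
    canonical_tags: dict[str, str]
    decoy_tags: list[str]
    collision_groups: list[list[str]] = field(default_factory=list)

    def genes_with_role(self, role: str) -> list[str]:
        return sorted(g for g, r in self.roles.items() if r == role)

    @property
    def exclusive_genes(self) -> dict[str, str]:
        """Planted tissue-exclusive genes mapped to their tissue."""
        return {
            g: r.split(":", 1)[1]
            for g, r in self.roles.items()
            if r.startswith("tissue_exclusive:")
        }

    def baseline_tpm(self, gene: str) -> float:
        """Expected TPM of a gene under normal phenotype where expressed."""
        excl = self.exclusive_genes
        tissue = excl.get(gene, None)
        if tissue is None:
            tissue = sorted(self.expected_tpm)[0][0]
        return float(self.expected_tpm[(tissue, "normal")][gene])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def _random_tag(rng: np.random.Generator) -> str:
    return "".join(rng.choice(BASES, size=TAG_LENGTH))


def _plant_tag(seq: str, tag: str) -> str:
    """Overwrite the 3' end so the canonical (3'-most eligible) tag is ``tag``.

    Planting CATG+tag as the final 14 bases guarantees no later anchored
    site can have 10 downstream bases, so the canonical tag is fixed.
    """
    return seq[:-(len(ANCHOR) + TAG_LENGTH)] + ANCHOR + tag


def generate_reference(
    n_genes: int,
    seed: int,
    tag_collision_rate: float = 0.0,
    chrom_lengths: Mapping[str, int] | None = None,
    min_length: int = 300,
    max_length: int = 3000,
) -> tuple[list[LncRNARecord], dict[str, str], list[list[str]]]:
    """Generate a synthetic lncRNA reference with extractable tags.

    Returns (records, canonical tag per gene, collision groups).  A
    fraction ``tag_collision_rate`` of genes is placed in groups of two
    sharing an identical planted tag, to exercise the multi-map discard.
    Tags of non-collision genes are re-planted until each matches only
    its own gene, so accidental 14-mer repeats cannot blur the truth.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    chrom_lengths = dict(chrom_lengths or TOY_KARYOTYPE)
    chroms = sorted(chrom_lengths)

    gene_ids = [f"SYNG{i:05d}" for i in range(n_genes)]
    lengths = rng.integers(min_length, max_length + 1, size=n_genes)
    seqs = [_random_seq(rng, int(L)) for L in lengths]

    n_collision_genes = int(round(tag_collision_rate * n_genes))
    n_collision_genes -= n_collision_genes % 2  # groups of two
    collision_groups = [
        [gene_ids[i], gene_ids[i + 1]]
        for i in range(n_genes - n_collision_genes, n_genes, 2)
    ]

    tags: dict[str, str] = {}
    used: set[str] = set()
    for gid in gene_ids:
        tag = _random_tag(rng)
        while tag in used:
            tag = _random_tag(rng)
        used.add(tag)
        tags[gid] = tag
    for pair in collision_groups:
        tags[pair[1]] = tags[pair[0]]

    def build_records() -> list[LncRNARecord]:
        records = []
        for i, gid in enumerate(gene_ids):
            chrom = chroms[i % len(chroms)]
            start = int(rng.integers(1, chrom_lengths[chrom] - int(lengths[i])))
            records.append(
                LncRNARecord(
                    ensembl_id=gid,
                    gene_name=f"SYNLNC{i:04d}",
                    chromosome=chrom,
                    start=start,
                    end=start + int(lengths[i]) - 1,
                    strand=int(rng.choice([1, -1])),
                    biotype=str(
                        rng.choice(
                            ["lincRNA", "processed_transcript"], p=[0.125, 0.875]
                        )
                    ),
                    transcript_sequences=[_plant_tag(seqs[i], tags[gid])],
                )
            )
        return records

    # Re-plant any non-collision tag that accidentally matches another gene.
    collision_members = {g for grp in collision_groups for g in grp}
    for _ in range(20):
        records = build_records()
        index = TagIndex(records)
        dirty = []
        for gid in gene_ids:
            if gid in collision_members:
                continue
            fwd = {g for g, o in index.lookup(tags[gid]) if o == "forward"}
            if fwd != {gid}:
                dirty.append(gid)
        if not dirty:
            break
        for gid in dirty:
            tag = _random_tag(rng)
            while tag in used:
                tag = _random_tag(rng)
            used.add(tag)
            tags[gid] = tag
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("could not resolve accidental tag collisions")

    for rec in records:
        assert extract_canonical_tag(rec.transcript_sequences[0]) == tags[rec.ensembl_id]
    return records, tags, collision_groups


def _make_decoys(
    rng: np.random.Generator,
    n: int,
    records: Sequence[LncRNARecord],
    forbidden: set[str],
) -> list[str]:
    """Random tags matching no reference gene in either orientation."""
    index = TagIndex(records)
    decoys: list[str] = []
    while len(decoys) < n:
        tag = _random_tag(rng)
        if tag in forbidden or index.lookup(tag):
            continue
        forbidden.add(tag)
        decoys.append(tag)
    return decoys


def generate_profiles(
    design: SyntheticDesign,
    records: Sequence[LncRNARecord],
    canonical_tags: dict[str, str],
    collision_groups: list[list[str]],
    seed: int,
) -> SyntheticTruth:
    """Assign roles and per-condition expected TPM to a reference set.

    Baseline abundances are log-normal; tissue-exclusive genes are
    nonzero in exactly one tissue; planted DE genes have an exact
    cancer:normal expected-TPM ratio of ``de_fold``.  All conditions are
    scaled by one common factor so that the heaviest condition's gene
    mass equals ``1 - noise_fraction`` of a library; the decoy mass
    absorbs the remainder per condition.  Scaling every condition equally
    keeps the planted fold ratios exact.
    """
    rng = np.random.default_rng(seed)
    gene_ids = [r.ensembl_id for r in records]
    if len(gene_ids) != design.n_genes:
        raise ValueError("records do not match design.n_genes")

    roles: dict[str, str] = {}
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        out = gene_ids[cursor: cursor + n]
        cursor += n
        return out

    for g in take(design.n_housekeeping):
        roles[g] = ROLE_HOUSEKEEPING
    for tissue in design.tissues:
        for g in take(design.n_exclusive_per_tissue):
            roles[g] = role_exclusive(tissue)
    for g in take(design.n_de_up):
        roles[g] = ROLE_DE_UP
    for g in take(design.n_de_down):
        roles[g] = ROLE_DE_DOWN
    for g in gene_ids[cursor:]:
        roles[g] = ROLE_NULL

    weights = rng.lognormal(mean=0.0, sigma=design.lognormal_sigma,
                            size=len(gene_ids))
    baseline = pd.Series(weights / weights.sum() * 1e6, index=gene_ids)

    expected: dict[tuple[str, str], pd.Series] = {}
    exclusive = {g: r.split(":", 1)[1] for g, r in roles.items()
                 if r.startswith("tissue_exclusive:")}
    for tissue in design.tissues:
        normal = baseline.copy()
        for g, t in exclusive.items():
            if t != tissue:
                normal[g] = 0.0
        expected[(tissue, "normal")] = normal
        if tissue in design.cancer_tissues:
            cancer = normal.copy()
            for g, r in roles.items():
                if r == ROLE_DE_UP:
                    cancer[g] = normal[g] * design.de_fold
                elif r == ROLE_DE_DOWN:
                    cancer[g] = normal[g] / design.de_fold
            expected[(tissue, "cancer")] = cancer

    heaviest = max(float(v.sum()) for v in expected.values())
    scale = (1 - design.noise_fraction) * 1e6 / heaviest
    expected = {k: v * scale for k, v in expected.items()}

    decoys = _make_decoys(
        rng, design.n_decoy_tags, records, set(canonical_tags.values())
    )
    return SyntheticTruth(
        roles=roles,
        de_fold=design.de_fold,
        expected_tpm=expected,
        canonical_tags=canonical_tags,
        decoy_tags=decoys,
        collision_groups=collision_groups,
    )


def sample_library(
    truth: SyntheticTruth,
    tissue: str,
    phenotype: str,
    depth: int,
    seed: int,
    library_id: str | None = None,
) -> SageLibrary:
    """Draw one SAGE library multinomially from a condition's expectation.

    Tag probabilities are proportional to expected TPM (genes sharing a
    planted tag pool their mass on it); the remaining mass is spread
    uniformly over the decoy tags.  ``total_raw_tags`` equals ``depth``
    exactly.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    key = (tissue, phenotype)
    if key not in truth.expected_tpm:
        raise KeyError(f"no expected profile for {key}")
    tpm = truth.expected_tpm[key]

    tag_mass: dict[str, float] = {}
    for gene, value in tpm.items():
        if value > 0:
            tag = truth.canonical_tags[gene]
            tag_mass[tag] = tag_mass.get(tag, 0.0) + float(value)
    gene_mass = sum(tag_mass.values())
    decoy_total = 1e6 - gene_mass
    if decoy_total < 0:
        raise ValueError("expected TPM exceeds 1e6; invalid profile")
    for tag in truth.decoy_tags:
        tag_mass[tag] = decoy_total / len(truth.decoy_tags)

    tags = sorted(tag_mass)
    probs = np.array([tag_mass[t] for t in tags], dtype=float)
    if probs.sum() <= 0:
        raise ValueError("empty probability vector")
    probs = probs / probs.sum()

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(depth, probs)
    tag_counts = {t: int(c) for t, c in zip(tags, counts) if c > 0}
    return SageLibrary(
        library_id=library_id or f"LIB_{tissue}_{phenotype}_{seed}",
        tissue=tissue,
        phenotype=phenotype,
        tag_counts=tag_counts,
        accession="",
    )


@dataclass
class SimulatedStudy:
    """A complete synthetic experiment: reference, truth, libraries, catalog."""

    records: list[LncRNARecord]
    truth: SyntheticTruth
    libraries: list[SageLibrary]
    catalog: pd.DataFrame
    design: SyntheticDesign


def simulate_study(design: SyntheticDesign, seed: int) -> SimulatedStudy:
    """Generate reference + profiles and sample every catalogued library.

    One normal group per tissue and one cancer group per cancer tissue,
    each of ``design.libraries_per_group`` libraries at ``design.depth``.
    """
    ss = np.random.SeedSequence(seed)
    ref_seed, prof_seed, lib_seed = (int(s.generate_state(1)[0] % (2**31))
                                     for s in ss.spawn(3))
    records, tags, collisions = generate_reference(
        design.n_genes, ref_seed, tag_collision_rate=design.tag_collision_rate
    )
    truth = generate_profiles(design, records, tags, collisions, prof_seed)

    conditions = [(t, "normal") for t in design.tissues]
    conditions += [(t, "cancer") for t in design.cancer_tissues]
    lib_rng = np.random.default_rng(lib_seed)
    libraries: list[SageLibrary] = []
    rows = []
    for tissue, phenotype in conditions:
        for i in range(design.libraries_per_group):
            lid = f"LIB_{tissue}_{phenotype}_{i}"
            lib = sample_library(
                truth, tissue, phenotype, design.depth,
                seed=int(lib_rng.integers(0, 2**31)), library_id=lid,
            )
            libraries.append(lib)
            rows.append(
                {"library_id": lid, "accession": "", "tissue": tissue,
                 "phenotype": phenotype}
            )
    catalog = pd.DataFrame(rows)
    return SimulatedStudy(records, truth, libraries, catalog, design)


# ---------------------------------------------------------------------------
# Fixture emission (file-based pipeline inputs)

#: Descriptor phrases used for synthetic "ambiguous" Unigene annotations.
_CANDIDATE_DESCRIPTIONS = (
    "transcribed locus",
    "hypothetical protein",
    "cDNA clone IMAGE:1234567",
    "non-coding transcript",
    "family with sequence similarity 99",
)


def synthetic_unigene_tables(
    study: SimulatedStudy,
    known_fraction: float = 0.10,
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Build a synthetic tag->Unigene mapping plus annotation table.

    A ``known_fraction`` of reference genes get Unigene coverage whose
    gene name matches the reference (the known-lncRNA path); a share of
    decoy tags gets ambiguous candidate-style annotations and another
    share gets protein-coding-style annotations (the 'other' class).
    """
    rng = np.random.default_rng(seed)
    mapping: dict[str, str] = {}
    ann_rows = []
    uid = 1
    by_id = {r.ensembl_id: r for r in study.records}
    collision_members = {g for grp in study.truth.collision_groups for g in grp}
    known_genes = [
        g for g in sorted(by_id) if g not in collision_members
    ][: int(round(known_fraction * len(by_id)))]
    for g in known_genes:
        tag = study.truth.canonical_tags[g]
        mapping[tag] = f"Syn.{uid}"
        ann_rows.append(
            {"unigene_id": f"Syn.{uid}", "gene_name": by_id[g].gene_name,
             "description": "long non-coding RNA"}
        )
        uid += 1
    decoys = study.truth.decoy_tags
    n_candidate = len(decoys) // 4
    n_other = len(decoys) // 4
    for tag in decoys[:n_candidate]:
        mapping[tag] = f"Syn.{uid}"
        ann_rows.append(
            {"unigene_id": f"Syn.{uid}", "gene_name": "",
             "description": str(rng.choice(_CANDIDATE_DESCRIPTIONS))}
        )
        uid += 1
    for i, tag in enumerate(decoys[n_candidate: n_candidate + n_other]):
        mapping[tag] = f"Syn.{uid}"
        ann_rows.append(
            {"unigene_id": f"Syn.{uid}", "gene_name": f"SYNPC{i:04d}",
             "description": "synthetic protein-coding gene"}
        )
        uid += 1
    annotation = pd.DataFrame(
        ann_rows, columns=["unigene_id", "gene_name", "description"]
    )
    return mapping, annotation


def write_fixtures(study: SimulatedStudy, outdir: str | Path,
                   seed: int = 0) -> dict[str, Path]:
    """Write a complete file-based fixture set for the pipeline.

    Emits per-library TSVs, the catalog, reference gene table + FASTA,
    synthetic Unigene mapping + annotation, chromosome lengths and the
    ground-truth JSON.  Returns the path of each artifact.
    """
    outdir = Path(outdir)
    (outdir / "libraries").mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    for lib in study.libraries:
        write_sage_library(lib, outdir / "libraries" / f"{lib.library_id}.tsv")
    paths["libdir"] = outdir / "libraries"

    paths["catalog"] = outdir / "catalog.tsv"
    study.catalog.to_csv(paths["catalog"], sep="\t", index=False)

    paths["gene_table"] = outdir / "reference_genes.tsv"
    pd.DataFrame(
        [
            {"ensembl_id": r.ensembl_id, "gene_name": r.gene_name,
             "chromosome": r.chromosome, "start": r.start, "end": r.end,
             "strand": r.strand, "biotype": r.biotype}
            for r in study.records
        ]
    ).to_csv(paths["gene_table"], sep="\t", index=False)

    paths["fasta"] = outdir / "reference_transcripts.fa"
    with open(paths["fasta"], "w") as fh:
        for r in study.records:
            for j, seq in enumerate(r.transcript_sequences):
                fh.write(f">{r.ensembl_id} transcript={j}\n")
                for k in range(0, len(seq), 70):
                    fh.write(seq[k: k + 70] + "\n")

    mapping, annotation = synthetic_unigene_tables(study, seed=seed)
    paths["unigene_mapping"] = outdir / "unigene_mapping.tsv"
    with open(paths["unigene_mapping"], "w") as fh:
        for tag in sorted(mapping):
            fh.write(f"{tag}\t{mapping[tag]}\n")
    paths["annotation"] = outdir / "unigene_annotation.tsv"
    annotation.to_csv(paths["annotation"], sep="\t", index=False)

    paths["chrom_lengths"] = outdir / "chrom_lengths.tsv"
    with open(paths["chrom_lengths"], "w") as fh:
        fh.write("chromosome\tlength\n")
        for chrom in sorted(TOY_KARYOTYPE):
            fh.write(f"{chrom}\t{TOY_KARYOTYPE[chrom]}\n")

    paths["truth"] = outdir / "truth.json"
    truth_doc = {
        "roles": study.truth.roles,
        "de_fold": study.truth.de_fold,
        "canonical_tags": study.truth.canonical_tags,
        "decoy_tags": study.truth.decoy_tags,
        "collision_groups": study.truth.collision_groups,
        "design": asdict(study.design),
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth_doc, fh, indent=1, sort_keys=True)
    return paths
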