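"""End-to-end orchestration of the lncRNA discovery pipeline.

Stage order: library depth filter -> unique-tag matrix -> Unigene split
-> per-matrix low-count filter -> descriptor classification -> pooling of
candidate and unmapped tags -> exact sequence matching -> forward /
single-target filter -> merge with Unigene-derived lncRNA tags ->
collapse to genes -> TPM.  Every stage's input/output tally is recorded
in a machine-readable run report and checked for conservation (no tag
silently vanishes: each is retained, filtered, or reported).
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import unigene as ug
from .config import PipelineConfig
from .matrix_ops import (
    ExpressionMatrix,
    collapse_tags_to_genes,
    filter_tags_min_counts,
    tpm_normalize,
)
from .reference import (
    AssignmentResult,
    LncRNARecord,
    TagAssignment,
    assign_tags,
    load_reference,
    merge_assignments,
)
from .sage_io import (
    SageLibrary,
    TagMatrix,
    build_tag_matrix,
    filter_libraries_by_depth,
    read_catalog,
    read_libraries,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a stage fails or a tally is inconsistent."""


@dataclass
class RunReport:
    """Per-stage tallies of one pipeline run, plus the config snapshot."""

    n_libraries_input: int = 0
    n_libraries_retained: int = 0
    n_unique_tags: int = 0
    n_mapped_tags: int = 0
    n_unmapped_tags: int = 0
    n_mapped_filtered: int = 0
    n_unmapped_filtered: int = 0
    n_known_lncrna_tags: int = 0
    n_candidate_tags: int = 0
    n_other_tags: int = 0
    n_candidate_pool: int = 0
    n_seq_forward_retained: int = 0
    n_seq_multi_mapped: int = 0
    n_seq_reverse_only: int = 0
    n_seq_unmatched: int = 0
    n_merge_conflicts: int = 0
    n_merged_tags: int = 0
    n_final_genes: int = 0
    mean_raw_tags_per_library: float = 0.0
    config: dict = field(default_factory=dict)
    timestamp: str = ""

    def validate(self) -> None:
        """Assert internal consistency of the tally chain."""
        checks = [
            ("unigene split partitions the unique tags",
             self.n_mapped_tags + self.n_unmapped_tags == self.n_unique_tags),
            ("classification partitions the filtered mapped tags",
             self.n_known_lncrna_tags + self.n_candidate_tags + self.n_other_tags
             == self.n_mapped_filtered),
            ("pool = candidate + filtered unmapped tags",
             self.n_candidate_pool
             == self.n_candidate_tags + self.n_unmapped_filtered),
            ("matching partitions the candidate pool",
             self.n_seq_forward_retained + self.n_seq_multi_mapped
             + self.n_seq_reverse_only + self.n_seq_unmatched
             == self.n_candidate_pool),
            ("all tallies non-negative",
             all(v >= 0 for k, v in self.__dict__.items()
                 if isinstance(v, int))),
        ]
        for label, ok in checks:
            if not ok:
                raise PipelineError(f"inconsistent run report: {label}")

    def to_dict(self, include_timestamp: bool = True) -> dict:
        d = dict(self.__dict__)
        if not include_timestamp:
            d.pop("timestamp", None)
        return d

    def to_json(self, path: str | Path, include_timestamp: bool = True) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(include_timestamp), fh, indent=1,
                      sort_keys=True)
            fh.write("\n")


@dataclass
class PipelineResult:
    """Everything a run produces: report, matrices and assignments."""

    report: RunReport
    lncrna_counts: ExpressionMatrix
    lncrna_tpm: ExpressionMatrix
    assignments: list[TagAssignment]
    tag_matrix: TagMatrix
    sequence_result: AssignmentResult
    catalog: pd.DataFrame


def run_pipeline_objects(
    libraries: Sequence[SageLibrary],
    catalog: pd.DataFrame,
    mapping: ug.UnigeneMapping,
    annotations: Mapping[str, ug.GeneAnnotation],
    records: Sequence[LncRNARecord],
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the discovery pipeline on in-memory inputs."""
    config = config or PipelineConfig()
    report = RunReport(config=config.to_dict(),
                       timestamp=datetime.datetime.now().isoformat())
    report.n_libraries_input = len(libraries)

    kept = filter_libraries_by_depth(libraries, config.min_library_depth)
    report.n_libraries_retained = len(kept)
    if not kept:
        raise PipelineError(
            "depth filter: no library exceeds "
            f"{config.min_library_depth} raw tags"
        )
    report.mean_raw_tags_per_library = float(
        sum(lib.total_raw_tags for lib in kept) / len(kept)
    )

    matrix = build_tag_matrix(kept)
    report.n_unique_tags = len(matrix.tags)

    mapped, unmapped = ug.split_mapped_unmapped(matrix, mapping)
    report.n_mapped_tags = len(mapped.tags)
    report.n_unmapped_tags = len(unmapped.tags)

    mapped_f = filter_tags_min_counts(
        mapped, config.tag_min_count, config.tag_min_libraries
    )
    unmapped_f = filter_tags_min_counts(
        unmapped, config.tag_min_count, config.tag_min_libraries
    )
    report.n_mapped_filtered = len(mapped_f.tags)
    report.n_unmapped_filtered = len(unmapped_f.tags)

    classes = ug.classify_tags(mapped_f.tags, mapping, dict(annotations))
    known_tags = sorted(t for t, c in classes.items() if c == ug.KNOWN_LNCRNA)
    candidate_tags = sorted(
        t for t, c in classes.items() if c == ug.CANDIDATE_LNCRNA
    )
    report.n_known_lncrna_tags = len(known_tags)
    report.n_candidate_tags = len(candidate_tags)
    report.n_other_tags = len(classes) - len(known_tags) - len(candidate_tags)

    name_to_gene: dict[str, str] = {}
    for rec in records:
        if rec.gene_name:
            name_to_gene.setdefault(rec.gene_name.upper(), rec.ensembl_id)
    unigene_assignments = []
    for tag in known_tags:
        uid = mapping.tag_to_id[tag]
        name = annotations[uid].gene_name.upper()
        gene = name_to_gene.get(name)
        if gene is None:
            logger.warning(
                "known-lncRNA tag %s: name %r not in reference; skipped",
                tag, name,
            )
            continue
        unigene_assignments.append(
            TagAssignment(tag=tag, ensembl_id=gene, orientation="forward",
                          n_targets=1, source="unigene")
        )

    pool = sorted(set(candidate_tags) | set(unmapped_f.tags))
    report.n_candidate_pool = len(pool)

    seq_result = assign_tags(pool, records, config.require_catg_prefix)
    t = seq_result.tallies()
    report.n_seq_forward_retained = t["forward_retained"]
    report.n_seq_multi_mapped = t["forward_multi_mapped"]
    report.n_seq_reverse_only = t["reverse_only"]
    report.n_seq_unmatched = t["unmatched"]

    merged, conflicts = merge_assignments(
        seq_result.assignments, unigene_assignments
    )
    report.n_merge_conflicts = len(conflicts)
    report.n_merged_tags = len(merged)

    combined = pd.concat([mapped_f.counts, unmapped_f.counts])
    combined_matrix = TagMatrix(combined, matrix.library_totals.copy())
    counts, _members = collapse_tags_to_genes(combined_matrix, merged)
    counts = counts.drop_undetected()
    tpm = tpm_normalize(counts) if len(counts.row_ids) else counts
    report.n_final_genes = len(counts.row_ids)

    report.validate()
    retained_ids = {lib.library_id for lib in kept}
    cat = catalog[catalog["library_id"].isin(retained_ids)].reset_index(drop=True)
    return PipelineResult(
        report=report,
        lncrna_counts=counts,
        lncrna_tpm=tpm,
        assignments=merged,
        tag_matrix=matrix,
        sequence_result=seq_result,
        catalog=cat,
    )


def run_pipeline(
    catalog_path: str | Path,
    libdir: str | Path,
    unigene_mapping_path: str | Path,
    annotation_path: str | Path,
    gene_table_path: str | Path,
    fasta_path: str | Path,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
    transcript_map: str | Path | None = None,
    id_remap: str | Path | None = None,
) -> PipelineResult:
    """Run the discovery pipeline from files; optionally write outputs.

    Outputs (when ``outdir`` is given): lncrna_counts.tsv, lncrna_tpm.tsv,
    assignments.tsv and run_report.json.
    """
    config = config or PipelineConfig()
    catalog = read_catalog(catalog_path)
    libraries = read_libraries(catalog, libdir)
    records = load_reference(
        gene_table_path, fasta_path,
        transcript_map=transcript_map, id_remap=id_remap,
    )
    mapping = ug.load_tag_mapping(unigene_mapping_path)
    names = frozenset(r.gene_name for r in records if r.gene_name)
    annotations = ug.load_annotation(annotation_path, lncRNA_names=names)

    result = run_pipeline_objects(
        libraries, catalog, mapping, annotations, records, config
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        result.lncrna_counts.to_tsv(outdir / "lncrna_counts.tsv")
        result.lncrna_tpm.to_tsv(outdir / "lncrna_tpm.tsv")
        from .reference import write_assignments

        write_assignments(
            AssignmentResult(result.assignments, {}, [], []),
            outdir / "assignments.tsv",
        )
        result.report.to_json(outdir / "run_report.json")
    return result


def tissue_average_tpm(
    result: PipelineResult, phenotype: str = "normal"
) -> ExpressionMatrix:
    """Tissue-averaged TPM for libraries of one phenotype."""
    from .matrix_ops import average_by_group

    cat = result.catalog
    sel = cat[cat["phenotype"] == phenotype]
    grouping = dict(zip(sel["library_id"], sel["tissue"]))
    sub = result.lncrna_tpm.subset_libraries(list(grouping))
    return average_by_group(sub, grouping)


def cancer_vs_normal_labels(
    catalog: pd.DataFrame, tissue: str
) -> dict[str, str]:
    """Normal/cancer labels for one tissue's contrast.

    Precancerous libraries (metaplasia/dysplasia/inflammatory phenotypes)
    and cell lines are excluded.
    """
    sel = catalog[
        (catalog["tissue"] == tissue)
        & (catalog["phenotype"].isin(["normal", "cancer"]))
    ]
    return dict(zip(sel["library_id"], sel["phenotype"]))
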