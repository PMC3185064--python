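"""Simulation experiments scoring the pipeline against planted truth.

Each experiment generates synthetic studies, runs the relevant pipeline
stages, and scores recovery of the planted signal.  They are used both
by the validation suite and by the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .diffexp import differential_expression, permutation_test, significant_set
from .matrix_ops import (
    average_by_group,
    collapse_tags_to_genes,
    detect_exclusive,
    tpm_normalize,
)
from .reference import TagAssignment
from .sage_io import build_tag_matrix
from .simulate import (
    ROLE_DE_DOWN,
    ROLE_DE_UP,
    ROLE_HOUSEKEEPING,
    ROLE_NULL,
    SyntheticDesign,
    SyntheticTruth,
    generate_profiles,
    generate_reference,
    sample_library,
    simulate_study,
)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _truth_assignments(truth: SyntheticTruth) -> list[TagAssignment]:
    """Ground-truth tag assignments (single-target genes only)."""
    shared = {g for grp in truth.collision_groups for g in grp}
    return [
        TagAssignment(tag=tag, ensembl_id=gene)
        for gene, tag in truth.canonical_tags.items()
        if gene not in shared
    ]


def _contrast_tpm(truth, design, tissue, seed):
    """Sample one 5v5-style contrast and return its gene TPM matrix."""
    seeds = _spawn_seeds(seed, 2 * design.libraries_per_group)
    libraries = []
    for i in range(design.libraries_per_group):
        libraries.append(sample_library(
            truth, tissue, "normal", design.depth, seeds[i],
            library_id=f"N{i}",
        ))
        libraries.append(sample_library(
            truth, tissue, "cancer", design.depth,
            seeds[design.libraries_per_group + i], library_id=f"C{i}",
        ))
    matrix = build_tag_matrix(libraries)
    # restrict to tags present: genes exclusive to other tissues are
    # legitimately absent from a single-tissue contrast
    present = set(matrix.tags)
    assignments = [a for a in _truth_assignments(truth) if a.tag in present]
    counts, _ = collapse_tags_to_genes(matrix, assignments)
    labels = {lib.library_id: lib.phenotype for lib in libraries}
    return tpm_normalize(counts), labels


@dataclass
class RecoveryOutcome:
    """Aggregated planted-DE recovery over simulation replicates."""

    n_replicates: int
    n_planted_scored: int
    n_planted_recovered: int
    n_null_scored: int
    n_null_flagged: int

    @property
    def sensitivity(self) -> float:
        return self.n_planted_recovered / self.n_planted_scored

    @property
    def null_false_positive_rate(self) -> float:
        return self.n_null_flagged / self.n_null_scored


def de_recovery_experiment(
    n_replicates: int = 50,
    seed: int = 0,
    design: SyntheticDesign | None = None,
    min_baseline_tpm: float = 50.0,
    n_permutations: int = 2000,
    alpha: float = 0.05,
    min_fold: float = 2.0,
) -> RecoveryOutcome:
    """Score recovery of planted fold changes in repeated 5v5 contrasts.

    Each replicate draws a fresh reference, profiles and libraries, runs
    the permutation test with BH correction, and scores the significant
    set: sensitivity over planted DE genes whose baseline is at least
    ``min_baseline_tpm``, and the flagged fraction of null genes.
    """
    design = design or SyntheticDesign()
    tissue = design.cancer_tissues[0]
    planted_scored = planted_recovered = null_scored = null_flagged = 0
    for rep_seed in _spawn_seeds(seed, n_replicates):
        s1, s2, s3, s4 = _spawn_seeds(rep_seed, 4)
        records, tags, groups = generate_reference(
            design.n_genes, s1, tag_collision_rate=design.tag_collision_rate
        )
        truth = generate_profiles(design, records, tags, groups, s2)
        tpm, labels = _contrast_tpm(truth, design, tissue, s3)
        results = differential_expression(
            tpm, labels, n_permutations=n_permutations, seed=s4,
            min_group_size=design.libraries_per_group,
        )
        sig = significant_set(results, alpha=alpha, min_fold=min_fold)
        baseline = truth.expected_tpm[(tissue, "normal")]
        planted = [
            g for g in (truth.genes_with_role(ROLE_DE_UP)
                        + truth.genes_with_role(ROLE_DE_DOWN))
            if baseline[g] >= min_baseline_tpm
        ]
        nulls = truth.genes_with_role(ROLE_NULL)
        planted_scored += len(planted)
        planted_recovered += sum(g in sig for g in planted)
        null_scored += len(nulls)
        null_flagged += sum(g in sig for g in nulls)
    return RecoveryOutcome(
        n_replicates=n_replicates,
        n_planted_scored=planted_scored,
        n_planted_recovered=planted_recovered,
        n_null_scored=null_scored,
        n_null_flagged=null_flagged,
    )


def calibration_experiment(
    n_genes: int = 500,
    seed: int = 0,
    n_permutations: int = 2000,
    alpha: float = 0.05,
    depth: int = 100_000,
    libraries_per_group: int = 5,
) -> tuple[float, int]:
    """Type-I error of the permutation test on all-null data.

    Returns (fraction of genes with raw p below ``alpha``, n genes).
    Both groups are drawn from identical expected profiles, so the raw
    p-values should be (sub)uniform.
    """
    design = SyntheticDesign(
        tissues=("brain", "liver"), cancer_tissues=("brain",),
        n_genes=n_genes, n_housekeeping=0, n_exclusive_per_tissue=0,
        n_de_up=0, n_de_down=0, depth=depth,
        libraries_per_group=libraries_per_group,
    )
    s1, s2, s3 = _spawn_seeds(seed, 3)
    records, tags, groups = generate_reference(n_genes, s1)
    truth = generate_profiles(design, records, tags, groups, s2)
    tpm, labels = _contrast_tpm(truth, design, "brain", s3)
    p = permutation_test(
        tpm, labels, n_permutations=n_permutations, seed=s3,
        min_group_size=libraries_per_group,
    )
    values = np.array(list(p.values()))
    return float((values < alpha).mean()), len(values)


def exclusive_recovery_experiment(
    seed: int = 0, design: SyntheticDesign | None = None
) -> dict[str, object]:
    """Recovery of planted tissue-exclusive genes from a full study.

    Builds the tissue-averaged normal TPM matrix and compares the
    tissue-exclusive calls (>= 10 TPM in exactly one tissue, zero
    elsewhere) against the planted truth.  Sampling zeros can in
    principle hide a planted gene; the outcome reports any misses
    explicitly alongside false calls.
    """
    design = design or SyntheticDesign()
    study = simulate_study(design, seed)
    truth = study.truth
    matrix = build_tag_matrix(study.libraries)
    counts, _ = collapse_tags_to_genes(matrix, _truth_assignments(truth))
    tpm = tpm_normalize(counts)
    cat = study.catalog
    normal = cat[cat["phenotype"] == "normal"]
    grouping = dict(zip(normal["library_id"], normal["tissue"]))
    averaged = average_by_group(tpm.subset_libraries(list(grouping)), grouping)
    called = detect_exclusive(averaged, min_tpm=10.0)
    expected = truth.exclusive_genes
    housekeeping = set(truth.genes_with_role(ROLE_HOUSEKEEPING))
    return {
        "expected": expected,
        "called": called,
        "missed": sorted(set(expected) - set(called)),
        "false_calls": sorted(set(called) - set(expected)),
        "housekeeping_false_calls": sorted(set(called) & housekeeping),
    }


def multimap_leakage_experiment(
    seed: int = 0, tag_collision_rate: float = 0.10
) -> dict[str, int]:
    """Run the full pipeline on a collision study; count shared-tag genes
    that leak into the final expression matrix (should be zero)."""
    from .pipeline import run_pipeline_objects
    from .simulate import synthetic_unigene_tables
    from .unigene import GeneAnnotation, UnigeneMapping

    design = replace(SyntheticDesign(), tag_collision_rate=tag_collision_rate)
    study = simulate_study(design, seed)
    mapping, ann = synthetic_unigene_tables(study, seed=seed)
    names = frozenset(r.gene_name for r in study.records)
    annotations = {
        row.unigene_id: GeneAnnotation(row.unigene_id, row.gene_name,
                                       row.description, names)
        for row in ann.itertuples(index=False)
    }
    result = run_pipeline_objects(
        study.libraries, study.catalog, UnigeneMapping(mapping),
        annotations, study.records,
    )
    shared = {g for grp in study.truth.collision_groups for g in grp}
    leaked = shared & set(result.lncrna_counts.row_ids)
    return {
        "n_shared_tag_genes": len(shared),
        "n_leaked": len(leaked),
        "n_final_genes": result.report.n_final_genes,
    }
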