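# Methods

## The measurement model

Short SAGE sequences the 10 bases immediately 3' of the 3'-most NlaIII
site (CATG) of each polyadenylated transcript. A library is therefore a
multinomial sample of tags: a transcript expressed at relative abundance
*q* contributes its canonical tag with probability ≈ *q* per sequenced
tag, and a library of depth *N* yields counts that are binomial(*N*, *q*)
marginally. Tags-per-million, `TPM = count / N × 10⁶`, is the natural
depth-free abundance scale; the denominator is always the *full* library
total, never the total of a row subset, so TPM values are comparable
across any gene selection and a complete library sums to exactly 10⁶ TPM.

Two consequences of the chemistry drive the pipeline's design:

- **Anchoring.** A 10-mer alone does not represent a SAGE tag; the tag is
  defined by an adjacent CATG. Matching therefore uses the 14-mer
  `CATG + tag` (configurable via `require_catg_prefix`). Matching is
  position-unconstrained — any anchored site on the transcript qualifies,
  not only the 3'-most one — which tolerates alternative 3' ends and
  incomplete digestion; the canonical-tag extractor (3'-most eligible
  site) exists for simulation and diagnostics.
- **Strand sense.** A tag occurring on a transcript's own strand
  (*forward*) is evidence that this transcript was sequenced; the reverse
  complement occurring is not, regardless of which genomic strand the
  gene occupies. Reverse-only matches are counted and excluded. A tag
  with both orientations is processed under the forward rules, since the
  forward evidence stands on its own.

## Filtering cascade

Thresholds live in `PipelineConfig`, with the strictness of each boundary
fixed and the value configurable:

| parameter | default | meaning |
|---|---|---|
| `min_library_depth` | 50,000 | keep libraries with **strictly more** raw tags |
| `tag_min_count` / `tag_min_libraries` | 2 / 3 | keep tags with ≥ 2 counts in ≥ 3 libraries, applied separately to the Unigene-mapped and unmapped matrices before pooling |
| `ubiquitous_fraction` | 0.90 | detected (≥ 1 tag) in strictly more than 90% of libraries |
| `exclusive_min_tpm` | 10 TPM | tissue-exclusive: ≥ 10 TPM in exactly one tissue and ≤ `exclusive_tolerance` (default 0) elsewhere |
| `heatmap_cap` | 300 TPM | display-only clipping; analysis matrices untouched |
| `de_alpha` / `de_min_fold` / `de_min_group_size` | 0.05 / 2 / 5 | significance calls |

Tag-to-gene collapse sums all member tags of a gene, capturing transcript
variants that produce different tags; tags assigned to more than one gene
are discarded outright rather than fractionally allocated, trading a
small loss of sensitivity for unambiguous attribution. When Unigene
annotation and sequence matching assign the same tag to different genes,
the tag is likewise discarded.

The descriptor classification mechanises what is in practice a manual
curation step: *known* means an exact case-insensitive gene-name match
against the reference lncRNA names; *candidate* means an empty gene name
or an annotation matching provisional-identifier patterns
(`^C(hr)?\d+orf\d+$`, `^FLJ\d+$`, `^KIAA\d+$` on the name; "non-coding",
"non-protein", "cDNA", "transcribed locus", "clone IMAGE",
"hypothetical", "family with sequence similarity" as case-insensitive
description substrings). Known takes priority over candidate.

## Permutation test

Per gene the statistic is `|mean_cancer − mean_normal|` on TPM — two-sided
by construction, since both directions of change are of interest. The
null is generated by permuting the normal/cancer labels across libraries;
the same arrangements are reused for all genes, which preserves the
between-gene correlation structure. With *n* libraries and *k* in the
cancer group there are C(*n*, *k*) distinct arrangements; when that
number is at most `n_permutations` the test enumerates them all and
returns the exact p-value `#{stat ≥ observed} / #arrangements` (the
observed arrangement is included, so p ≥ 1/C(*n*, *k*) and the test is
valid). Larger designs are sampled with the add-one estimator
`(1 + #{≥ observed}) / (1 + B)`. Observed and permuted statistics go
through one code path so floating-point ties resolve exactly.

Discreteness matters for downstream correction: a 5v5 design has 252
arrangements and, because an arrangement and its complement give the same
statistic, the smallest attainable p is 2/252 ≈ 0.0079. After
Benjamini–Hochberg correction over *m* genes of which *m₁* sit at the
floor, the smallest adjusted value is ≈ 0.0079·*m*/*m₁*; calls at
α = 0.05 are therefore only possible when true signal is a non-trivial
fraction of the tested genes. This is a property of any exact test at
small group sizes, not of the implementation.

Fold changes divide the cancer group mean by the normal group mean and
are reported in the signed convention (r if r ≥ 1, else −1/r), so a
halving prints as −2.00. Zero group means produce sentinels (±∞ for
up-from-zero / down-to-zero, NaN when undetected in both groups); the
±∞ sentinels satisfy any fold threshold in their direction, NaN never
qualifies. BH correction is applied within each contrast (each cancer
type is analysed independently). Libraries with phenotype `precancer`
(metaplasia/dysplasia/inflammation) or `cell_line` are excluded from
contrasts by the label builder.

## Chromosome densities

Gene-class distributions are summarised as genes per 100 Mb per
chromosome, over whichever chromosome universe the length table supplies
(for human data: the 22 autosomes plus X and Y; mitochondrial and patch
contigs are excluded). Similarity between classes is quantified by
Spearman correlation with average ranks for ties; the default p-value is
the large-sample two-sided t approximation, with an exhaustive
pairing-permutation p available for small chromosome sets. The package
reports ρ and p without encoding a direction of inference — a
non-significant p is *absence of evidence* for distributional difference,
not evidence of similarity.

## Synthetic studies

The generator emulates what the pipeline consumes, with known truth:

- **Reference** — per gene one random transcript of 300–3,000 nt with
  `CATG + tag` planted as the final 14 bases, which pins the canonical
  tag (no later anchored site can have 10 downstream bases). Tags are
  re-planted if they accidentally match a second gene, so the truth is
  unambiguous; a configurable fraction of genes is deliberately paired on
  a shared tag to exercise the multi-map discard. Coordinates are drawn
  on a five-chromosome toy karyotype (60–200 Mb), biotypes at a 1:7
  lincRNA : processed-transcript ratio.
- **Profiles** — baseline abundances are log-normal (σ = 0.8). The
  default design has 200 genes: 20 housekeeping, 2 tissue-exclusive genes
  per tissue, 30 up- and 30 down-regulated at 4-fold in cancer, the
  remainder null. Six tissues, three with matched cancer groups, five
  libraries per group. The 4-fold / 5v5 / depth-100,000 setting is the
  regime the inference is designed for (exact 252-arrangement test); the
  ~30% DE fraction is within the range seen in cancer-vs-normal bulk
  contrasts and, per the discreteness analysis above, is what makes
  BH-corrected calls attainable at all in a 5v5 exact test. All
  conditions are scaled by one common factor so the heaviest condition's
  gene mass is `1 − noise_fraction` (default 80%) of a library; equal
  scaling keeps planted cancer:normal expectation ratios exactly equal to
  the planted fold, with the decoy mass absorbing per-condition
  differences.
- **Libraries** — multinomial draws at the configured depth (default
  100,000 tags — a typical archived-library size). The decoy mass
  (default 20%) goes to random tags verified to match no reference gene,
  so the unmapped/candidate pathway is exercised. A synthetic Unigene
  mapping covers 10% of genes as known lncRNAs plus shares of the decoys
  with candidate-style and protein-coding-style annotations.

What the generator does **not** model: realistic base composition or GC
bias, sequencing error (tags are sampled exactly), inter-library
biological variability beyond multinomial noise, partial digestion, and
the extreme sparsity of real tag space (~716k unique tags in a real
272-library compilation vs hundreds here). Passing recovery tests
therefore demonstrates correctness of the pipeline's logic and the
calibration of its inference under the stated sampling model — not
robustness to artefacts of real SAGE chemistry.

## Numerical and policy choices

- Strict inequalities at the depth (> 50,000) and ubiquity (> 90%)
  boundaries; inclusive at tag-count (≥ 2 in ≥ 3), exclusivity (≥ 10
  TPM) and fold (≥ 2) thresholds.
- CV uses the sample (n−1) standard deviation over tissue-averaged
  columns; all-zero rows are excluded from CV ranking with a warning.
  Rankings break ties by row identifier for determinism.
- Tissue exclusivity requires exact zeros elsewhere by default; a TPM
  tolerance is available because genuinely exclusive genes can show
  trace counts in deep real libraries.
- Duplicate tag lines in a library file merge additively (observed in
  real exports); conflicting rows in a tag→Unigene mapping drop the tag
  rather than pick a winner.
- BH adjustment delegates to `statsmodels` (`fdr_bh`); Spearman to
  `scipy.stats`. The permutation test, matcher and all pipeline logic
  are implemented here and validated against independent oracles
  (enumeration, brute-force substring search, a hand-written step-up).
- Reported experiment sizes — 50 recovery replicates, 500 calibration
  genes, 2,000 permutations (⇒ exhaustive mode for 5v5) — keep the whole
  validation suite and the reproduction script to a few seconds while
  leaving the binomial scoring intervals tight.

## Known limitations

- Genome-level mapping (intronic, antisense, novel loci) is out of
  scope: only matches to the supplied transcript sequences are
  considered, and reverse-orientation tags are deliberately not used for
  novel-gene discovery.
- Mismatch-tolerant matching is not implemented (the protocol is exact,
  0-mismatch matching); sequencing errors in real tags therefore lower
  sensitivity rather than creating false assignments.
- The permutation test treats libraries as exchangeable under the null;
  batch structure between archived libraries from different sources
  violates this and is not modelled.
- The reference-list ID lift between annotation releases is supported
  only as a user-supplied two-column remap table.
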