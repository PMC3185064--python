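"""Ingest SAGE tag-count libraries and build a TPM matrix.

Builds two tiny in-memory libraries, applies the sequencing-depth filter
(here with a toy threshold), assembles the unique-tag matrix and
normalises to tags per million.
"""

from sagelnc import (
    SageLibrary,
    build_tag_matrix,
    filter_libraries_by_depth,
    tpm_normalize,
)
from sagelnc.matrix_ops import ExpressionMatrix

deep = SageLibrary(
    library_id="L_deep", tissue="brain", phenotype="normal",
    tag_counts={"AAAAAAAAAA": 60, "CCCCCCCCCC": 30, "GGGGGGGGGG": 10},
)
shallow = SageLibrary(
    library_id="L_shallow", tissue="brain", phenotype="normal",
    tag_counts={"AAAAAAAAAA": 4},
)

kept = filter_libraries_by_depth([deep, shallow], min_depth=50)
print(f"libraries passing depth > 50 raw tags: "
      f"{[lib.library_id for lib in kept]}")

matrix = build_tag_matrix(kept)
print("\nraw unique-tag matrix:")
print(matrix.counts)

tpm = tpm_normalize(
    ExpressionMatrix(matrix.counts.astype(float),
                     matrix.library_totals.astype(float))
)
print("\nTPM (count / library total x 1e6):")
print(tpm.values)
print(f"\ncolumn sum = {tpm.values['L_deep'].sum():.0f} "
      "(a full library always sums to one million TPM)")
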