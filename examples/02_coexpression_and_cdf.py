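"""Cosine co-expression and the designated-vs-background CDF comparison.

The co-expression of two genes is the cosine similarity of their voxel
expression-energy vectors, in [0, 1]. If a designated gene set co-expresses
more tightly than chance, its pairwise value distribution deviates from the
background's; the two-sample Kolmogorov-Smirnov test quantifies this and
the deviation argmax suggests a threshold that delineates the set's
co-expression structure.
"""

import numpy as np

from voxcoex import (
    SyntheticSpec,
    background_values,
    coexpression_matrix,
    compare_cdfs,
    generate_synthetic_brain,
    offdiagonal_values,
    submatrix,
)

dataset, atlas, designated, truth = generate_synthetic_brain(SyntheticSpec(seed=0))

C = coexpression_matrix(dataset)
sub = submatrix(C, designated)
set_values = offdiagonal_values(sub)
bg_values = background_values(C, designated)

print(f"co-expression matrix: {C.n_genes} x {C.n_genes}")
print(f"designated pairs: {set_values.size}, background pairs: {bg_values.size}")
print(f"background median co-expression: {np.median(bg_values):.3f}")

out = compare_cdfs(set_values, bg_values)
print(f"KS statistic D = {out.ks_statistic:.3f}, p = {out.ks_pvalue:.2e}")
print(f"largest set-enrichment deviation at co-expression "
      f"{100 * out.argmax_set_excess:.2f}%")
# A tiny p says the designated set's co-expression distribution differs
# from the background; the percentage is the natural seed threshold for
# clique delineation (the planted cliques live above it).
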