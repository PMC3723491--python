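"""Cosine co-expression matrices and distribution comparison.

The co-expression of two genes is the cosine similarity of their masked-voxel
expression-energy vectors,

    C(g, g') = sum_v E(v,g) E(v,g') / (||E(.,g)||_2 ||E(.,g')||_2),

which lies in [0, 1] because energies are nonnegative. For unit-normalized
profiles e, e' it is equivalent to the squared energy of the difference:
||e - e'||^2 = 2 (1 - C). A designated gene set's co-expression distribution
is compared to the background via the two-sample Kolmogorov-Smirnov
statistic, recording the co-expression value at which the empirical CDFs
deviate most.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from .types import ExpressionDataset, GeneSet, ValidationError

__all__ = [
    "CoexpressionMatrix",
    "CdfComparison",
    "coexpression_matrix",
    "submatrix",
    "offdiagonal_values",
    "compare_cdfs",
    "background_values",
]


@dataclass
class CoexpressionMatrix:
    """Symmetric gene x gene cosine-similarity matrix with entries in [0, 1].

    The diagonal is exactly 1 for genes with a nonzero profile; zero-profile
    genes get an all-zero row/column (diagonal stored as 0, flagged at
    construction).
    """

    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.gene_ids)
        if len(set(self.gene_ids)) != n:
            raise ValidationError("duplicate gene ids in co-expression matrix")
        if self.values.shape != (n, n):
            raise ValidationError("co-expression matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("co-expression matrix must be symmetric")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValidationError("co-expression entries must lie in [0, 1]")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def indices(self, gene_ids) -> np.ndarray:
        missing = [g for g in gene_ids if g not in self._index]
        if missing:
            raise KeyError(f"gene ids absent from co-expression matrix: {missing}")
        return np.asarray([self._index[g] for g in gene_ids], dtype=np.intp)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.gene_ids, columns=self.gene_ids).to_csv(
            path, sep="\t", float_format="%.17g"
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CoexpressionMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(gene_ids=[str(g) for g in frame.index], values=frame.to_numpy())


def coexpression_matrix(dataset: ExpressionDataset) -> CoexpressionMatrix:
    """Compute the gene-by-gene cosine co-expression matrix.

    Zero-profile genes receive an all-zero row/column with a warning; at
    least two genes are required.
    """
    if dataset.n_genes < 2:
        raise ValidationError("co-expression needs at least 2 genes")
    energies = dataset.energies
    norms = np.linalg.norm(energies, axis=1)
    zero = norms == 0
    if zero.any():
        warnings.warn(
            "zero-expression genes get undefined co-expression (stored as 0): "
            f"{[g for g, z in zip(dataset.gene_ids, zero) if z][:10]}"
        )
    unit = energies / np.where(zero, 1.0, norms)[:, None]
    values = unit @ unit.T
    np.clip(values, 0.0, 1.0, out=values)
    np.fill_diagonal(values, 1.0)
    values[zero, :] = 0.0
    values[:, zero] = 0.0
    values = (values + values.T) / 2.0
    return CoexpressionMatrix(gene_ids=list(dataset.gene_ids), values=values)


def submatrix(C: CoexpressionMatrix, genes: GeneSet) -> CoexpressionMatrix:
    """Extract the sub-matrix for ``genes``, preserving the set's order."""
    idx = C.indices(list(genes))
    return CoexpressionMatrix(
        gene_ids=list(genes), values=C.values[np.ix_(idx, idx)].copy()
    )


def offdiagonal_values(C: CoexpressionMatrix) -> np.ndarray:
    """The n(n-1)/2 upper-triangle co-expression values."""
    if C.n_genes < 2:
        raise ValidationError("need at least 2 genes for off-diagonal values")
    iu = np.triu_indices(C.n_genes, k=1)
    return C.values[iu]


def background_values(
    C: CoexpressionMatrix, genes: GeneSet, exclude_set_pairs: bool = True
) -> np.ndarray:
    """Off-diagonal entries of the full matrix forming the comparison
    background.

    With ``exclude_set_pairs`` (default) the set-vs-set pairs are removed, so
    the background is "all other pairs"; with it False the full matrix's
    off-diagonal is used (both readings of the background are useful).
    """
    values = offdiagonal_values(C)
    if not exclude_set_pairs:
        return values
    idx = set(C.indices(list(genes)).tolist())
    iu, ju = np.triu_indices(C.n_genes, k=1)
    in_set = np.fromiter(
        ((i in idx) and (j in idx) for i, j in zip(iu, ju)),
        dtype=bool,
        count=len(iu),
    )
    return values[~in_set]


@dataclass
class CdfComparison:
    """Two-sample KS comparison of co-expression value distributions.

    ``argmax_coexpression`` locates the largest absolute CDF deviation (the
    KS statistic); ``argmax_set_excess`` locates the largest *signed*
    deviation CDF_background - CDF_set, i.e. the co-expression value above
    which the set is maximally enriched relative to the background. The two
    coincide when the set's distribution is shifted up as a whole; they
    differ when the set is a heterogeneous mixture with extra mass at low
    values.
    """

    ks_statistic: float
    ks_pvalue: float
    argmax_coexpression: float
    set_excess: float
    argmax_set_excess: float
    n_set_pairs: int
    n_background_pairs: int
    extra: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "ks_statistic": self.ks_statistic,
            "ks_pvalue": self.ks_pvalue,
            "argmax_coexpression": self.argmax_coexpression,
            "set_excess": self.set_excess,
            "argmax_set_excess": self.argmax_set_excess,
            "n_set_pairs": self.n_set_pairs,
            "n_background_pairs": self.n_background_pairs,
            **self.extra,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def compare_cdfs(set_values, background_values) -> CdfComparison:
    """Compare the empirical CDFs of two co-expression value samples.

    D is the supremum over observed values of the absolute CDF difference;
    ``argmax_coexpression`` is the (smallest, on ties) value attaining it.
    The signed analogue (background CDF minus set CDF, the direction in
    which the set is over-represented at high co-expression) is reported as
    ``set_excess`` / ``argmax_set_excess``. The p-value comes from the
    asymptotic two-sample KS distribution.
    """
    sv = np.sort(np.asarray(set_values, dtype=np.float64))
    bv = np.sort(np.asarray(background_values, dtype=np.float64))
    if sv.size == 0 or bv.size == 0:
        raise ValidationError("compare_cdfs requires nonempty value lists")
    grid = np.union1d(sv, bv)
    count_s = np.searchsorted(sv, grid, side="right").astype(np.int64)
    count_b = np.searchsorted(bv, grid, side="right").astype(np.int64)
    # exact integer arithmetic over the common denominator n*m, so ties at
    # the supremum resolve to the smallest co-expression value exactly
    signed_int = count_b * sv.size - count_s * bv.size
    abs_int = np.abs(signed_int)
    denom = sv.size * bv.size
    d = float(abs_int.max() / denom)
    argmax = float(grid[int(np.argmax(abs_int))])  # argmax takes the first
    ks = scipy.stats.ks_2samp(sv, bv, alternative="two-sided", method="asymp")
    return CdfComparison(
        ks_statistic=d,
        ks_pvalue=float(ks.pvalue),
        argmax_coexpression=argmax,
        set_excess=float(signed_int.max() / denom),
        argmax_set_excess=float(grid[int(np.argmax(signed_int))]),
        n_set_pairs=int(sv.size),
        n_background_pairs=int(bv.size),
    )
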