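"""Threshold graphs, connected-component size curves and clique discovery.

Cutting the co-expression matrix at a threshold rho yields an unweighted
graph with an edge wherever C(g, g') >= rho (inclusive, matching the
">= 70%" convention). Per threshold, N_rho(k) counts connected components of
exactly k genes; the maximum component size is M(rho) = max{k : N_rho(k) > 0}
and the average is A(rho) = sum_k k N_rho(k) / sum_k N_rho(k). A clique is a
gene set in which every pair is connected at rho.

Clique discovery proceeds in two stages: exhaustive maximal-clique
enumeration (Bron-Kerbosch) inside the small designated gene set at a seed
threshold, then greedy maximin extension of each seed over the full gene
universe at the seed's own minimum pairwise co-expression. An exhaustive
extension mode exists for small universes to validate the greedy rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse
import scipy.sparse.csgraph

from .coexpression import CoexpressionMatrix
from .types import GeneSet, ValidationError

__all__ = [
    "ThresholdGraph",
    "ComponentSizeCurve",
    "Clique",
    "threshold_graph",
    "connected_components",
    "component_size_curves",
    "seed_cliques",
    "extend_clique",
    "is_clique",
    "clique_min_coexpression",
    "write_clique_table",
]


@dataclass
class ThresholdGraph:
    """Unweighted graph with an edge iff co-expression >= rho."""

    gene_ids: list[str]
    rho: float
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        n = len(self.gene_ids)
        if self.adjacency.shape != (n, n):
            raise ValidationError("adjacency shape mismatch")
        if self.adjacency.diagonal().any():
            raise ValidationError("threshold graph must be irreflexive")
        if (self.adjacency != self.adjacency.T).any():
            raise ValidationError("threshold graph must be symmetric")

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


def threshold_graph(C: CoexpressionMatrix, rho: float) -> ThresholdGraph:
    """Cut the co-expression matrix at ``rho`` (edges where C >= rho)."""
    if not 0.0 <= rho <= 1.0:
        raise ValidationError(f"rho={rho} outside [0, 1]")
    adjacency = C.values >= rho
    np.fill_diagonal(adjacency, False)
    return ThresholdGraph(gene_ids=list(C.gene_ids), rho=float(rho), adjacency=adjacency)


def _component_labels(adjacency: np.ndarray) -> np.ndarray:
    n_comp, labels = scipy.sparse.csgraph.connected_components(
        scipy.sparse.csr_matrix(adjacency), directed=False
    )
    return labels


def connected_components(graph: ThresholdGraph) -> list[list[str]]:
    """Partition genes into maximal connected sets.

    Components are ordered by their smallest member index; members keep the
    matrix's gene order.
    """
    labels = _component_labels(graph.adjacency)
    first_seen: dict[int, int] = {}
    members: dict[int, list[str]] = {}
    for i, lab in enumerate(labels):
        lab = int(lab)
        if lab not in first_seen:
            first_seen[lab] = i
            members[lab] = []
        members[lab].append(graph.gene_ids[i])
    order = sorted(first_seen, key=first_seen.get)
    return [members[lab] for lab in order]


@dataclass
class ComponentSizeCurve:
    """Component-size census over a grid of thresholds."""

    rho_grid: np.ndarray
    counts: list[dict[int, int]]  # per rho: k -> N_rho(k)
    max_size: np.ndarray  # M(rho)
    avg_size: np.ndarray  # A(rho)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rho": self.rho_grid, "max_size": self.max_size, "avg_size": self.avg_size}
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def component_size_curves(
    C: CoexpressionMatrix, rho_grid
) -> ComponentSizeCurve:
    """Tabulate N_rho(k) and derive M(rho), A(rho) over ``rho_grid``."""
    rho_grid = np.asarray(rho_grid, dtype=np.float64)
    if rho_grid.size == 0:
        raise ValidationError("rho grid is empty")
    if rho_grid.min() < 0 or rho_grid.max() > 1:
        raise ValidationError("rho grid must lie within [0, 1]")
    counts: list[dict[int, int]] = []
    max_size = np.empty(rho_grid.size)
    avg_size = np.empty(rho_grid.size)
    base = C.values.copy()
    np.fill_diagonal(base, -1.0)  # never a self-edge regardless of rho
    for j, rho in enumerate(rho_grid):
        labels = _component_labels(base >= rho)
        sizes = np.bincount(labels)
        sizes = sizes[sizes > 0]
        census: dict[int, int] = {}
        for k in sizes:
            census[int(k)] = census.get(int(k), 0) + 1
        counts.append(census)
        max_size[j] = sizes.max()
        avg_size[j] = sizes.sum() / sizes.size
    return ComponentSizeCurve(
        rho_grid=rho_grid, counts=counts, max_size=max_size, avg_size=avg_size
    )


@dataclass
class Clique:
    """A gene set mutually co-expressed at level >= rho.

    ``rho`` is the seed's internal minimum pairwise co-expression (the level
    at which the clique was delineated); ``min_coexpression`` is the realized
    minimum over all member pairs after extension. ``ng`` (designated genes
    among members) is filled once a designated set is supplied.
    """

    member_ids: list[str]
    seed_ids: list[str]
    rho: float
    min_coexpression: float | None = None
    ng: int | None = None
    clique_id: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.member_ids) < 2:
            raise ValidationError("a clique needs at least 2 members")
        if not set(self.seed_ids) <= set(self.member_ids):
            raise ValidationError("seed genes must be clique members")

    @property
    def n(self) -> int:
        return len(self.member_ids)

    def count_designated(self, designated: GeneSet) -> int:
        self.ng = sum(1 for g in self.member_ids if g in designated)
        return self.ng


def is_clique(C: CoexpressionMatrix, genes, rho: float) -> bool:
    """True iff every pair among ``genes`` has co-expression >= rho."""
    idx = C.indices(list(genes))
    if idx.size < 2:
        raise ValidationError("is_clique needs at least 2 genes")
    sub = C.values[np.ix_(idx, idx)]
    iu = np.triu_indices(idx.size, k=1)
    return bool((sub[iu] >= rho).all())


def clique_min_coexpression(C: CoexpressionMatrix, genes) -> float:
    """Minimum pairwise co-expression over all pairs in ``genes``."""
    idx = C.indices(list(genes))
    if idx.size < 2:
        raise ValidationError("need at least 2 genes")
    sub = C.values[np.ix_(idx, idx)]
    iu = np.triu_indices(idx.size, k=1)
    return float(sub[iu].min())


def seed_cliques(C_set: CoexpressionMatrix, rho0: float) -> list[list[str]]:
    """All maximal cliques of size >= 2 within the designated set at rho0.

    Exhaustive maximal-clique enumeration (Bron-Kerbosch via networkx) is
    feasible because the designated set is small. Output is deterministic:
    each clique sorted by position in ``C_set`` and the list sorted
    lexicographically by member ids.
    """
    graph = threshold_graph(C_set, rho0)
    g = nx.Graph()
    g.add_nodes_from(range(len(graph.gene_ids)))
    g.add_edges_from(zip(*np.nonzero(np.triu(graph.adjacency))))
    out = []
    for clique in nx.find_cliques(g):
        if len(clique) >= 2:
            out.append([graph.gene_ids[i] for i in sorted(clique)])
    out.sort()
    return out


def _greedy_extend(
    C: CoexpressionMatrix, seed_idx: np.ndarray, universe_idx: np.ndarray, rho: float
) -> list[int]:
    members = list(seed_idx)
    in_members = np.zeros(C.n_genes, dtype=bool)
    in_members[seed_idx] = True
    allowed = np.zeros(C.n_genes, dtype=bool)
    allowed[universe_idx] = True
    # min co-expression of each gene to the current members
    minvec = C.values[members].min(axis=0)
    while True:
        candidate_mask = allowed & ~in_members & (minvec >= rho)
        if not candidate_mask.any():
            break
        cand = np.nonzero(candidate_mask)[0]
        best = minvec[cand].max()
        # ties broken by gene order in the matrix (stable, documented)
        pick = int(cand[minvec[cand] == best][0])
        members.append(pick)
        in_members[pick] = True
        minvec = np.minimum(minvec, C.values[pick])
    return members


def _exhaustive_extend(
    C: CoexpressionMatrix, seed_idx: np.ndarray, universe_idx: np.ndarray, rho: float
) -> list[int]:
    """Largest clique at ``rho`` containing the seed, by exhaustive search.

    Only for small universes (validation of the greedy rule); ties broken by
    lexicographically smallest index tuple.
    """
    extras = [int(i) for i in universe_idx if i not in set(seed_idx.tolist())]
    if len(extras) > 25:
        raise ValidationError("exhaustive extension limited to small universes")
    # candidates must connect to every seed member
    extras = [
        i for i in extras if (C.values[i, seed_idx] >= rho).all()
    ]
    best: tuple[int, tuple] = (len(seed_idx), tuple(sorted(seed_idx.tolist())))
    for r in range(1, len(extras) + 1):
        for combo in combinations(extras, r):
            pairs_ok = all(
                C.values[a, b] >= rho for a, b in combinations(combo, 2)
            )
            if pairs_ok:
                members = tuple(sorted(list(seed_idx) + list(combo)))
                # first max-size hit wins: combinations() is lexicographic
                if len(members) > best[0]:
                    best = (len(members), members)
    return list(best[1])


def extend_clique(
    C: CoexpressionMatrix,
    seed: list[str],
    universe: GeneSet | None = None,
    mode: str = "greedy",
    recompute_rho: bool = False,
) -> Clique:
    """Grow a seed clique over the universe at the seed's internal threshold.

    The threshold rho is frozen at the minimum pairwise co-expression within
    the seed. Greedy maximin rule: repeatedly admit the universe gene whose
    minimum co-expression to all current members is largest, provided that
    minimum is >= rho; ties broken by gene order. ``mode='exhaustive'``
    instead finds the true maximum clique containing the seed (small
    universes only). With ``recompute_rho`` the reported rho is re-derived
    from the extended members (sensitivity option).
    """
    seed_idx = C.indices(seed)
    if seed_idx.size < 2:
        raise ValidationError("seed must contain at least 2 genes")
    rho = clique_min_coexpression(C, seed)
    if not is_clique(C, seed, rho):  # pragma: no cover - rho is the seed min
        raise ValidationError("seed is not a clique at its own minimum")
    universe_idx = (
        np.arange(C.n_genes, dtype=np.intp)
        if universe is None
        else C.indices(list(universe))
    )
    if mode == "greedy":
        members_idx = _greedy_extend(C, seed_idx, universe_idx, rho)
    elif mode == "exhaustive":
        members_idx = _exhaustive_extend(C, seed_idx, universe_idx, rho)
    else:
        raise ValidationError(f"unknown extension mode {mode!r}")
    member_ids = [C.gene_ids[i] for i in sorted(members_idx)]
    realized = clique_min_coexpression(C, member_ids)
    return Clique(
        member_ids=member_ids,
        seed_ids=[C.gene_ids[i] for i in sorted(seed_idx.tolist())],
        rho=realized if recompute_rho else rho,
        min_coexpression=realized,
    )


def write_clique_table(cliques: list[Clique], path: str | Path) -> None:
    """Clique table TSV: id, rho, min co-expression, n, ng, members, seeds."""
    rows = []
    for i, clique in enumerate(cliques):
        rows.append(
            {
                "clique_id": clique.clique_id or f"clique_{i + 1:03d}",
                "rho": clique.rho,
                "min_coexpression": clique.min_coexpression,
                "n": clique.n,
                "ng": clique.ng,
                "member_ids": ",".join(clique.member_ids),
                "seed_ids": ",".join(clique.seed_ids),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "clique_id", "rho", "min_coexpression", "n", "ng",
            "member_ids", "seed_ids",
        ],
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")
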