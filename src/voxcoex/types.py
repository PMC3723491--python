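"""Core in-memory containers for voxelized expression analysis.

An :class:`ExpressionDataset` holds the gene x masked-voxel matrix of
nonnegative expression energies E(v, g) together with the integer grid
coordinates of each masked voxel. A :class:`RegionAtlas` holds the voxel ->
region labeling and the region hierarchy with its coarse "main region"
grouping. Masked voxels are always kept in raster order: x fastest, then y,
then z — a pure function of the mask, so serialized artifacts are
reproducible regardless of input file order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The 12 coarse anatomical groups used to organize region-level results:
#: cerebral cortex, olfactory areas, hippocampal and retrohippocampal
#: regions, striatum, pallidum, thalamus, hypothalamus, midbrain, pons,
#: medulla and cerebellum.
MAIN_GROUPS = (
    "COR", "OLF", "Hi", "RHi", "STR", "PAL",
    "THA", "HYP", "MID", "PON", "MED", "CER",
)


class ValidationError(ValueError):
    """Raised when a container's invariants are violated."""


def mask_to_coords(mask: np.ndarray) -> np.ndarray:
    """Coordinates of set voxels in raster order (x fastest, then y, then z).

    Returns an ``(n_voxels, 3)`` integer array of 0-based (x, y, z) indices.
    """
    mask = np.asarray(mask) > 0
    z, y, x = np.nonzero(mask.transpose(2, 1, 0))
    return np.stack([x, y, z], axis=1)


def flatten_volume(volume: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Extract the masked-voxel vector of ``volume`` at ``coords``."""
    return np.asarray(volume)[coords[:, 0], coords[:, 1], coords[:, 2]]


@dataclass
class ExpressionDataset:
    """Gene x masked-voxel matrix of nonnegative expression energies.

    Parameters
    ----------
    gene_ids
        Ordered unique gene identifiers, one per row of ``energies``.
    energies
        ``(n_genes, n_voxels)`` float array, all entries >= 0 (arbitrary
        energy units).
    voxel_coords
        ``(n_voxels, 3)`` 0-based integer (x, y, z) grid indices, one per
        masked voxel, in raster order.
    grid_shape
        Full grid dimensions ``(nx, ny, nz)``.
    voxel_size_um
        Edge length of a voxel in micrometres.
    """

    gene_ids: list[str]
    energies: np.ndarray
    voxel_coords: np.ndarray
    grid_shape: tuple[int, int, int]
    voxel_size_um: float = 200.0

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.energies = np.asarray(self.energies, dtype=np.float64)
        self.voxel_coords = np.asarray(self.voxel_coords, dtype=np.intp)
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValidationError(f"duplicate gene ids: {dupes}")
        if self.energies.ndim != 2 or self.energies.shape[0] != len(self.gene_ids):
            raise ValidationError("energies must be (n_genes, n_voxels)")
        if self.n_voxels == 0:
            raise ValidationError("dataset must contain at least one masked voxel")
        if self.voxel_coords.shape != (self.n_voxels, 3):
            raise ValidationError("voxel_coords must be (n_voxels, 3)")
        if np.isnan(self.energies).any():
            bad = [self.gene_ids[i] for i in
                   np.unique(np.nonzero(np.isnan(self.energies))[0])]
            raise ValidationError(f"NaN expression energies for genes: {bad}")
        if (self.energies < 0).any():
            bad = [self.gene_ids[i] for i in
                   np.unique(np.nonzero((self.energies < 0).any(axis=1))[0])]
            raise ValidationError(f"negative expression energies for genes: {bad}")
        if (self.voxel_coords < 0).any() or (
            self.voxel_coords >= np.asarray(self.grid_shape)
        ).any():
            raise ValidationError("voxel coordinates outside grid_shape")
        flat = np.ravel_multi_index(self.voxel_coords.T, self.grid_shape)
        if len(np.unique(flat)) != self.n_voxels:
            raise ValidationError("duplicate voxel coordinates")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_voxels(self) -> int:
        return self.energies.shape[1]

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene id {gene_id!r}") from None

    def profile(self, gene_id: str) -> np.ndarray:
        """The masked-voxel expression vector of one gene."""
        return self.energies[self.gene_index(gene_id)]

    def zero_expression_genes(self) -> list[str]:
        """Genes whose profile is identically zero (retained at load,
        excluded by downstream analyses)."""
        zero = ~self.energies.any(axis=1)
        return [g for g, z in zip(self.gene_ids, zero) if z]

    def subset(self, gene_ids: list[str]) -> "ExpressionDataset":
        """Restrict to ``gene_ids``, preserving the given order."""
        idx = [self.gene_index(g) for g in gene_ids]
        return ExpressionDataset(
            gene_ids=list(gene_ids),
            energies=self.energies[idx],
            voxel_coords=self.voxel_coords,
            grid_shape=self.grid_shape,
            voxel_size_um=self.voxel_size_um,
        )

    def to_volume(self, values: np.ndarray) -> np.ndarray:
        """Scatter a masked-voxel vector back onto the full 3-D grid
        (unmasked voxels are zero)."""
        volume = np.zeros(self.grid_shape, dtype=np.float64)
        volume[
            self.voxel_coords[:, 0], self.voxel_coords[:, 1], self.voxel_coords[:, 2]
        ] = values
        return volume


@dataclass
class RegionAtlas:
    """Voxel -> region labeling plus region hierarchy and main-region grouping.

    ``labels`` assigns each masked voxel an integer region id (0 =
    unassigned). ``regions`` is a table with columns ``region_id``,
    ``parent_id`` (0 for roots), ``acronym`` and ``main_group``; parent links
    must form a forest and every region belongs to exactly one main group.
    """

    labels: np.ndarray
    regions: pd.DataFrame
    main_region_groups: tuple[str, ...] = MAIN_GROUPS

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        required = {"region_id", "parent_id", "acronym", "main_group"}
        missing = required - set(self.regions.columns)
        if missing:
            raise ValidationError(f"region table missing columns: {sorted(missing)}")
        self.regions = self.regions.reset_index(drop=True)
        ids = self.regions["region_id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise ValidationError("duplicate region ids in hierarchy")
        if (ids == 0).any():
            raise ValidationError("region id 0 is reserved for unassigned voxels")
        known = set(ids.tolist())
        present = set(np.unique(self.labels).tolist()) - {0}
        orphan = sorted(present - known)
        if orphan:
            raise ValidationError(
                f"labels present in volume but absent from hierarchy: {orphan}"
            )
        parent = dict(zip(
            self.regions["region_id"].tolist(), self.regions["parent_id"].tolist()
        ))
        for rid in parent:
            seen = set()
            node = rid
            while node not in (0, None) and node in parent:
                if node in seen:
                    raise ValidationError(f"cyclic parent links involving region {rid}")
                seen.add(node)
                node = parent[node]
        bad_group = self.regions.loc[
            ~self.regions["main_group"].isin(self.main_region_groups), "region_id"
        ].tolist()
        if bad_group:
            raise ValidationError(
                f"regions with unknown main group: {bad_group} "
                f"(known groups: {list(self.main_region_groups)})"
            )
        self._children: dict[int, list[int]] = {}
        for rid, pid in parent.items():
            self._children.setdefault(int(pid), []).append(int(rid))

    @property
    def n_voxels(self) -> int:
        return len(self.labels)

    @property
    def region_ids(self) -> list[int]:
        return [int(r) for r in self.regions["region_id"]]

    def region_row(self, region_id: int) -> pd.Series:
        rows = self.regions[self.regions["region_id"] == region_id]
        if rows.empty:
            raise KeyError(f"unknown region id {region_id}")
        return rows.iloc[0]

    def descendants(self, region_id: int) -> list[int]:
        """All regions below ``region_id`` (excluding itself)."""
        self.region_row(region_id)
        out: list[int] = []
        stack = list(self._children.get(int(region_id), []))
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(self._children.get(node, []))
        return sorted(out)

    def empty_regions(self) -> list[int]:
        """Regions with no directly labeled voxel (accepted, flagged)."""
        present = set(np.unique(self.labels).tolist())
        return [r for r in self.region_ids if r not in present]

    def main_group_of(self, region_id: int) -> str:
        return str(self.region_row(region_id)["main_group"])


@dataclass
class RegionMask:
    """Indicator (characteristic function) of one region over masked voxels."""

    region_id: int
    indicator: np.ndarray

    def __post_init__(self) -> None:
        self.indicator = np.asarray(self.indicator)
        if not np.isin(self.indicator, (0, 1)).all():
            raise ValidationError("region indicator must be 0/1")
        self.indicator = self.indicator.astype(np.float64)

    @property
    def n_set(self) -> int:
        return int(self.indicator.sum())


@dataclass
class GeneSet:
    """A named list of gene identifiers (e.g. the designated autism set)."""

    name: str
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        if not self.gene_ids:
            raise ValidationError(f"gene set {self.name!r} is empty")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError(f"gene set {self.name!r} has duplicate ids")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __iter__(self):
        return iter(self.gene_ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in set(self.gene_ids)


def warn_zero_expression(gene_ids: list[str], context: str) -> None:
    if gene_ids:
        warnings.warn(
            f"{context}: {len(gene_ids)} zero-expression gene(s) excluded: "
            f"{gene_ids[:10]}{'...' if len(gene_ids) > 10 else ''}",
            stacklevel=3,
        )
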