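"""Loading, validation and serialization of expression volumes and atlases.

Two carrier formats are supported for expression data:

* volumetric — one NRRD scalar grid per gene plus a manifest TSV
  (``gene_id<TAB>path``) and a brain-mask NRRD;
* tabular — a MatrixMarket gene x voxel matrix with TSV sidecars for gene
  ids and voxel coordinates, convenient for desk-scale synthetic runs.

Region annotation comes as an integer NRRD plus a hierarchy CSV
(``region_id,parent_id,acronym,main_group``). All loaders produce masked
voxels in raster order (x fastest), a pure function of the mask.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .nrrdio import read_nrrd, write_nrrd
from .types import (
    ExpressionDataset,
    GeneSet,
    RegionAtlas,
    RegionMask,
    ValidationError,
    flatten_volume,
    mask_to_coords,
)

__all__ = [
    "load_expression_dataset",
    "write_expression_dataset",
    "load_dataset_tabular",
    "write_dataset_tabular",
    "load_region_atlas",
    "write_region_atlas",
    "characteristic_function",
    "filter_consistent_genes",
    "consistency_correlations",
    "load_gene_set",
    "write_gene_set",
]


# ---------------------------------------------------------------------------
# volumetric carrier

def load_expression_dataset(
    manifest_path: str | Path,
    mask_path: str | Path,
    voxel_size_um: float = 200.0,
) -> ExpressionDataset:
    """Load per-gene NRRD volumes listed in a manifest TSV, masked.

    The manifest has columns ``gene_id`` and ``path`` (relative paths are
    resolved against the manifest's directory). Voxels with mask > 0 become
    the masked-voxel axis in raster order. Volumes must share the mask's
    grid; NaNs or negative energies are rejected naming the gene.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, sep="\t")
    if not {"gene_id", "path"} <= set(manifest.columns):
        raise ValidationError("manifest must have columns: gene_id, path")
    genes = manifest["gene_id"].astype(str).tolist()
    if len(set(genes)) != len(genes):
        dupes = sorted({g for g in genes if genes.count(g) > 1})
        raise ValidationError(f"manifest names duplicate gene ids: {dupes}")

    mask, _ = read_nrrd(mask_path)
    coords = mask_to_coords(mask)
    if coords.shape[0] == 0:
        raise ValidationError("mask selects no voxels")

    energies = np.empty((len(genes), coords.shape[0]), dtype=np.float64)
    for i, (gene, rel) in enumerate(zip(genes, manifest["path"].astype(str))):
        path = Path(rel)
        if not path.is_absolute():
            path = manifest_path.parent / path
        volume, _ = read_nrrd(path)
        if volume.shape != mask.shape:
            raise ValidationError(
                f"gene {gene!r}: volume shape {volume.shape} does not match "
                f"mask shape {mask.shape}"
            )
        vec = flatten_volume(volume, coords).astype(np.float64)
        if np.isnan(vec).any():
            raise ValidationError(f"gene {gene!r}: NaN expression energy")
        if (vec < 0).any():
            raise ValidationError(f"gene {gene!r}: negative expression energy")
        energies[i] = vec

    dataset = ExpressionDataset(
        gene_ids=genes,
        energies=energies,
        voxel_coords=coords,
        grid_shape=mask.shape,
        voxel_size_um=voxel_size_um,
    )
    zero = dataset.zero_expression_genes()
    if zero:
        warnings.warn(
            f"{len(zero)} gene(s) with all-zero expression retained at load: "
            f"{zero[:10]}{'...' if len(zero) > 10 else ''}"
        )
    return dataset


def write_expression_dataset(
    dataset: ExpressionDataset, outdir: str | Path, encoding: str = "gzip"
) -> Path:
    """Write one NRRD per gene plus ``manifest.tsv`` and ``mask.nrrd``.

    Returns the manifest path. Round-trips bit-exactly with
    :func:`load_expression_dataset` for raw/gzip encodings.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mask = np.zeros(dataset.grid_shape, dtype=np.uint8)
    mask[
        dataset.voxel_coords[:, 0],
        dataset.voxel_coords[:, 1],
        dataset.voxel_coords[:, 2],
    ] = 1
    write_nrrd(outdir / "mask.nrrd", mask, encoding=encoding)
    rows = []
    for i, gene in enumerate(dataset.gene_ids):
        fname = f"gene_{i:05d}.nrrd"
        write_nrrd(
            outdir / fname, dataset.to_volume(dataset.energies[i]), encoding=encoding
        )
        rows.append((gene, fname))
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows, columns=["gene_id", "path"]).to_csv(
        manifest, sep="\t", index=False
    )
    return manifest


# ---------------------------------------------------------------------------
# tabular carrier (MatrixMarket + TSV sidecars)

def write_dataset_tabular(dataset: ExpressionDataset, prefix: str | Path) -> None:
    """Write ``<prefix>.mtx`` (gene x voxel), ``<prefix>.genes.tsv``,
    ``<prefix>.voxels.tsv`` and ``<prefix>.meta.json``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        str(prefix) + ".mtx",
        scipy.sparse.csr_matrix(dataset.energies),
        precision=17,
    )
    pd.DataFrame({"gene_id": dataset.gene_ids}).to_csv(
        str(prefix) + ".genes.tsv", sep="\t", index=False
    )
    pd.DataFrame(dataset.voxel_coords, columns=["x", "y", "z"]).to_csv(
        str(prefix) + ".voxels.tsv", sep="\t", index=False
    )
    Path(str(prefix) + ".meta.json").write_text(
        json.dumps(
            {
                "grid_shape": list(dataset.grid_shape),
                "voxel_size_um": dataset.voxel_size_um,
            },
            indent=2,
        )
        + "\n"
    )


def load_dataset_tabular(prefix: str | Path) -> ExpressionDataset:
    """Inverse of :func:`write_dataset_tabular`."""
    prefix = str(prefix)
    energies = np.asarray(scipy.io.mmread(prefix + ".mtx").todense(), dtype=np.float64)
    genes = pd.read_csv(prefix + ".genes.tsv", sep="\t")["gene_id"].astype(str).tolist()
    coords = pd.read_csv(prefix + ".voxels.tsv", sep="\t")[["x", "y", "z"]].to_numpy()
    meta = json.loads(Path(prefix + ".meta.json").read_text())
    return ExpressionDataset(
        gene_ids=genes,
        energies=energies,
        voxel_coords=coords,
        grid_shape=tuple(meta["grid_shape"]),
        voxel_size_um=float(meta["voxel_size_um"]),
    )


# ---------------------------------------------------------------------------
# region atlas

def load_region_atlas(
    annotation_path: str | Path,
    hierarchy_path: str | Path,
    mask_path: str | Path | None = None,
) -> RegionAtlas:
    """Load an integer annotation NRRD and its hierarchy CSV, masked.

    When ``mask_path`` is None, every voxel with a nonzero annotation label
    is treated as masked. Empty regions (present in the hierarchy, zero
    voxels) are accepted and flagged with a warning.
    """
    annotation, _ = read_nrrd(annotation_path)
    if mask_path is not None:
        mask, _ = read_nrrd(mask_path)
        if mask.shape != annotation.shape:
            raise ValidationError(
                f"annotation shape {annotation.shape} does not match mask "
                f"shape {mask.shape}"
            )
    else:
        mask = annotation != 0
    coords = mask_to_coords(mask)
    labels = flatten_volume(annotation, coords).astype(np.int64)
    hierarchy = pd.read_csv(hierarchy_path)
    atlas = RegionAtlas(labels=labels, regions=hierarchy)
    empty = atlas.empty_regions()
    if empty:
        warnings.warn(f"{len(empty)} region(s) with no labeled voxel: {empty[:10]}")
    return atlas


def write_region_atlas(
    atlas: RegionAtlas,
    dataset: ExpressionDataset,
    annotation_path: str | Path,
    hierarchy_path: str | Path,
    encoding: str = "gzip",
) -> None:
    """Write the annotation volume (using the dataset's voxel geometry) and
    the hierarchy CSV."""
    volume = np.zeros(dataset.grid_shape, dtype=np.int32)
    volume[
        dataset.voxel_coords[:, 0],
        dataset.voxel_coords[:, 1],
        dataset.voxel_coords[:, 2],
    ] = atlas.labels
    write_nrrd(annotation_path, volume, encoding=encoding)
    atlas.regions.to_csv(hierarchy_path, index=False)


def characteristic_function(
    atlas: RegionAtlas,
    region_id: int,
    include_descendants: bool = True,
    require_nonempty: bool = False,
) -> RegionMask:
    """Indicator of a region over masked voxels.

    chi(v) = 1 iff voxel v is labeled ``region_id`` (or any descendant when
    ``include_descendants``), else 0.
    """
    atlas.region_row(region_id)
    wanted = {int(region_id)}
    if include_descendants:
        wanted.update(atlas.descendants(region_id))
    indicator = np.isin(atlas.labels, sorted(wanted)).astype(np.float64)
    if require_nonempty and not indicator.any():
        raise ValidationError(f"region {region_id} covers no masked voxel")
    return RegionMask(region_id=int(region_id), indicator=indicator)


# ---------------------------------------------------------------------------
# coronal/sagittal consistency filter

def consistency_correlations(
    dataset_a: ExpressionDataset, dataset_b: ExpressionDataset
) -> pd.Series:
    """Pearson correlation between each shared gene's two profiles.

    Zero-variance profiles get correlation 0 (flagged by warning), never NaN.
    """
    shared = [g for g in dataset_a.gene_ids if g in set(dataset_b.gene_ids)]
    if not shared:
        raise ValidationError("datasets share no gene ids")
    a = dataset_a.subset(shared).energies
    b = dataset_b.subset(shared).energies
    if a.shape[1] != b.shape[1]:
        raise ValidationError("datasets have different voxel counts")
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    na = np.linalg.norm(ac, axis=1)
    nb = np.linalg.norm(bc, axis=1)
    flat = (na == 0) | (nb == 0)
    denom = np.where(flat, 1.0, na * nb)
    corr = (ac * bc).sum(axis=1) / denom
    corr[flat] = 0.0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} gene(s) with zero-variance profile assigned "
            "correlation 0"
        )
    return pd.Series(corr, index=shared, name="correlation")


def filter_consistent_genes(
    dataset_a: ExpressionDataset, dataset_b: ExpressionDataset, keep_n: int
) -> GeneSet:
    """Keep the ``keep_n`` shared genes whose two replicate profiles (e.g.
    coronal vs sagittal acquisitions) correlate best.

    Ranking is by Pearson correlation, ties broken by gene id order in
    ``dataset_a``; deterministic.
    """
    corr = consistency_correlations(dataset_a, dataset_b)
    if keep_n < 1 or keep_n > len(corr):
        raise ValidationError(
            f"keep_n={keep_n} out of range for {len(corr)} shared genes"
        )
    order = dict((g, i) for i, g in enumerate(corr.index))
    ranked = sorted(corr.index, key=lambda g: (-corr[g], order[g]))
    return GeneSet(name=f"consistent_top{keep_n}", gene_ids=ranked[:keep_n])


# ---------------------------------------------------------------------------
# gene sets

def load_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a one-id-per-line TSV (blank lines and ``#`` comments skipped)."""
    path = Path(path)
    ids = [
        line.strip()
        for line in path.read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    return GeneSet(name=name or path.stem, gene_ids=ids)


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    Path(path).write_text("\n".join(gene_set.gene_ids) + "\n")
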