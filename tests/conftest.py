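import numpy as np
import pytest

from voxcoex import (
    ExpressionDataset,
    SyntheticSpec,
    coexpression_matrix,
    generate_synthetic_brain,
)


def make_dataset(energies, grid_shape=None, gene_ids=None):
    """Small helper: wrap a (n_genes, n_voxels) array as a dataset on a
    1-D ribbon of voxels."""
    energies = np.asarray(energies, dtype=float)
    n_voxels = energies.shape[1]
    if grid_shape is None:
        grid_shape = (n_voxels, 1, 1)
    coords = np.stack(
        [np.arange(n_voxels), np.zeros(n_voxels, int), np.zeros(n_voxels, int)],
        axis=1,
    )
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(energies.shape[0])]
    return ExpressionDataset(
        gene_ids=gene_ids,
        energies=energies,
        voxel_coords=coords,
        grid_shape=grid_shape,
    )


@pytest.fixture(scope="session")
def default_brain():
    """One default synthetic brain, shared across tests (seed-pinned)."""
    spec = SyntheticSpec(seed=0)
    return generate_synthetic_brain(spec)


@pytest.fixture(scope="session")
def default_coexpression(default_brain):
    dataset, _, _, _ = default_brain
    return coexpression_matrix(dataset)
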