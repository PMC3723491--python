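import numpy as np
import pandas as pd
import pytest

from voxcoex import (
    RegionMask,
    ValidationError,
    clique_expression_sum,
    fitting_permutation_pvalues,
    fitting_profile,
    fitting_score,
    maximal_intensity_projection,
)
from voxcoex.anatomy import CliqueExpressionProfile
from voxcoex.types import RegionAtlas

from conftest import make_dataset


def profile_from(values):
    return CliqueExpressionProfile(
        clique_id="toy", values=np.asarray(values, float),
        member_ids=["g0"], excluded_zero_norm=[],
    )


# summed normalized expression ------------------------------------------------

def test_single_gene_gives_unit_profile():
    ds = make_dataset([[3.0, 4.0], [1.0, 1.0]])
    out = clique_expression_sum(ds, ["g0"])
    np.testing.assert_allclose(out.values, [0.6, 0.8])
    assert np.linalg.norm(out.values) == pytest.approx(1.0)


def test_two_identical_genes_double_the_unit_profile():
    ds = make_dataset([[3.0, 4.0], [6.0, 8.0]])
    out = clique_expression_sum(ds, ["g0", "g1"])
    np.testing.assert_allclose(out.values, [1.2, 1.6])


def test_orthogonal_unit_genes_sum_to_sqrt2_norm():
    ds = make_dataset([[1.0, 0.0], [0.0, 5.0]])
    out = clique_expression_sum(ds, ["g0", "g1"])
    assert np.linalg.norm(out.values) == pytest.approx(np.sqrt(2))


def test_zero_norm_member_skipped_with_warning():
    ds = make_dataset([[1.0, 1.0], [0.0, 0.0]])
    with pytest.warns(UserWarning, match="zero-norm"):
        out = clique_expression_sum(ds, ["g0", "g1"])
    assert out.excluded_zero_norm == ["g1"]
    with pytest.raises(ValidationError):
        clique_expression_sum(ds, ["g1"])


# fitting score ---------------------------------------------------------------

def test_score_one_for_proportional_profile():
    chi = RegionMask(region_id=1, indicator=np.array([1, 0, 1, 0]))
    s = profile_from([2.5, 0, 2.5, 0])  # proportional to chi
    assert fitting_score(s, chi) == pytest.approx(1.0, abs=1e-12)


def test_score_zero_outside_region():
    chi = RegionMask(region_id=1, indicator=np.array([1, 1, 0, 0]))
    s = profile_from([0, 0, 3.0, 1.0])
    assert fitting_score(s, chi) == pytest.approx(0.0, abs=1e-12)


def test_uniform_profile_score_is_sqrt_region_fraction():
    indicator = np.zeros(100)
    indicator[:25] = 1
    chi = RegionMask(region_id=1, indicator=indicator)
    s = profile_from(np.full(100, 0.7))
    assert fitting_score(s, chi) == pytest.approx(0.5, abs=1e-12)


def test_score_invariant_to_positive_rescaling():
    rng = np.random.default_rng(0)
    indicator = (rng.random(50) > 0.6).astype(float)
    chi = RegionMask(region_id=1, indicator=indicator)
    values = rng.random(50)
    assert fitting_score(profile_from(values), chi) == pytest.approx(
        fitting_score(profile_from(values * 123.0), chi), abs=1e-12
    )


def test_empty_region_and_zero_profile_rejected():
    chi = RegionMask(region_id=1, indicator=np.zeros(4))
    with pytest.raises(ValidationError):
        fitting_score(profile_from([1, 1, 1, 1]), chi)
    chi2 = RegionMask(region_id=1, indicator=np.array([1, 0, 0, 0]))
    with pytest.raises(ValidationError):
        fitting_score(profile_from([0, 0, 0, 0]), chi2)


# per-region profiles ---------------------------------------------------------

def two_region_atlas():
    labels = np.array([1, 1, 2, 2, 2])
    regions = pd.DataFrame(
        [(1, 0, "L", "COR"), (2, 0, "R", "CER")],
        columns=["region_id", "parent_id", "acronym", "main_group"],
    )
    return RegionAtlas(labels=labels, regions=regions)


def test_disjoint_regions_score_support_only():
    atlas = two_region_atlas()
    s = profile_from([1.0, 2.0, 0.0, 0.0, 0.0])
    out = fitting_profile(s, atlas)
    scores = out.rows.set_index("region_id")["fitting_score"]
    assert scores[1] > 0
    assert scores[2] == pytest.approx(0.0, abs=1e-12)
    assert list(out.rows["main_group"]) == ["COR", "CER"]


def test_whole_brain_closed_form_and_uniform_limit():
    atlas = two_region_atlas()
    rng = np.random.default_rng(1)
    values = rng.random(5)
    whole = RegionMask(region_id=1, indicator=np.ones(5))
    expected = values.sum() / (np.linalg.norm(values) * np.sqrt(5))
    assert fitting_score(profile_from(values), whole) == pytest.approx(expected)
    assert fitting_score(profile_from(np.full(5, 2.0)), whole) == pytest.approx(1.0)


def test_planted_clique_localizes_to_host_region(default_brain):
    dataset, atlas, _, truth = default_brain
    for members, host in zip(truth.clique_memberships, truth.host_regions):
        s = clique_expression_sum(dataset, members)
        out = fitting_profile(s, atlas)
        top = out.rows.sort_values("fitting_score", ascending=False).iloc[0]
        assert int(top["region_id"]) == host


# permutation null ------------------------------------------------------------

def test_permutation_pvalues_reproducible_and_bounded(default_brain):
    dataset, atlas, _, truth = default_brain
    members = truth.clique_memberships[0]
    s = clique_expression_sum(dataset, members)
    observed = fitting_profile(s, atlas)
    region_ids = observed.rows["region_id"].tolist()
    kwargs = dict(
        dataset=dataset, atlas=atlas, clique_size=len(members),
        region_ids=region_ids, observed=observed, n_perm=500,
    )
    a = fitting_permutation_pvalues(seed=9, **kwargs)
    b = fitting_permutation_pvalues(seed=9, **kwargs)
    pd.testing.assert_frame_equal(a.rows, b.rows)
    p = a.rows.set_index("region_id")["permutation_p"]
    assert ((p >= 1 / 501) & (p <= 1.0)).all()
    host = truth.host_regions[0]
    assert p[host] == pytest.approx(1 / 501)


def test_permutation_pvalues_valid_for_random_observed(default_brain):
    """When the 'observed' clique is itself a random draw, host-region
    p-values are not systematically small."""
    dataset, atlas, _, _ = default_brain
    rng = np.random.default_rng(3)
    ps = []
    for rep in range(20):
        members = [dataset.gene_ids[i]
                   for i in rng.choice(dataset.n_genes, size=6, replace=False)]
        s = clique_expression_sum(dataset, members)
        observed = fitting_profile(s, atlas)
        out = fitting_permutation_pvalues(
            dataset, atlas, clique_size=6,
            region_ids=observed.rows["region_id"].tolist(),
            observed=observed, n_perm=99, seed=int(rng.integers(2**31)),
        )
        ps.extend(out.rows["permutation_p"].tolist())
    assert np.mean(np.array(ps) <= 0.05) < 0.15


# maximal-intensity projection ------------------------------------------------

def test_single_voxel_projection():
    ds = make_dataset([[0.0, 0.0, 2.0, 0.0]], grid_shape=(4, 1, 1))
    s = clique_expression_sum(ds, ["g0"])
    image = maximal_intensity_projection(s, ds, axis="z")
    assert image.shape == (4, 1)
    assert image[2, 0] == pytest.approx(1.0)
    assert image.sum() == pytest.approx(1.0)


def test_toy_grid_projection_by_hand():
    coords = np.array(
        [[x, y, z] for z in range(2) for y in range(2) for x in range(2)]
    )
    values = np.arange(8, dtype=float)
    from voxcoex.types import ExpressionDataset

    ds = ExpressionDataset(
        gene_ids=["g0"], energies=values[None, :], voxel_coords=coords,
        grid_shape=(2, 2, 2),
    )
    s = CliqueExpressionProfile(
        clique_id="t", values=values, member_ids=["g0"], excluded_zero_norm=[]
    )
    image = maximal_intensity_projection(s, ds, axis="x")
    # volume[x,y,z] = x + 2y + 4z; max over x leaves 1 + 2y + 4z
    np.testing.assert_allclose(image, [[1, 5], [3, 7]])
    with pytest.raises(ValidationError):
        maximal_intensity_projection(s, ds, axis="w")


def test_uniform_profile_projects_mask_silhouette(default_brain):
    dataset, _, _, _ = default_brain
    s = CliqueExpressionProfile(
        clique_id="u", values=np.ones(dataset.n_voxels),
        member_ids=["x"], excluded_zero_norm=[],
    )
    image = maximal_intensity_projection(s, dataset, axis="y")
    assert image.shape == (10, 10)
    np.testing.assert_allclose(image, 1.0)
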