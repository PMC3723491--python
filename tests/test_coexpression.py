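import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from voxcoex import (
    GeneSet,
    ValidationError,
    background_values,
    coexpression_matrix,
    compare_cdfs,
    offdiagonal_values,
    submatrix,
)
from voxcoex.coexpression import CoexpressionMatrix

from conftest import make_dataset


def test_parallel_disjoint_and_halfway_profiles():
    ds = make_dataset(
        [
            [1.0, 0.0, 2.0, 0.0],
            [0.5, 0.0, 1.0, 0.0],  # parallel to g0
            [0.0, 3.0, 0.0, 0.0],  # disjoint support
        ]
    )
    C = coexpression_matrix(ds)
    assert C.values[0, 1] == pytest.approx(1.0, abs=1e-12)
    assert C.values[0, 2] == pytest.approx(0.0, abs=1e-12)

    ds2 = make_dataset([[1.0, 0.0], [1.0, 1.0]])
    C2 = coexpression_matrix(ds2)
    assert C2.values[0, 1] == pytest.approx(1 / np.sqrt(2), abs=1e-12)


def test_zero_profile_gene_row_zeroed_with_warning():
    ds = make_dataset([[1.0, 2.0], [0.0, 0.0], [2.0, 1.0]])
    with pytest.warns(UserWarning, match="zero-expression"):
        C = coexpression_matrix(ds)
    assert C.values[1].sum() == 0.0
    assert C.values[:, 1].sum() == 0.0
    assert C.values[0, 0] == 1.0


def test_fewer_than_two_genes_rejected():
    ds = make_dataset([[1.0, 2.0]])
    with pytest.raises(ValidationError):
        coexpression_matrix(ds)


def test_submatrix_identity_single_and_permutation():
    rng = np.random.default_rng(0)
    ds = make_dataset(rng.random((5, 12)))
    C = coexpression_matrix(ds)
    full = submatrix(C, GeneSet("all", list(C.gene_ids)))
    np.testing.assert_array_equal(full.values, C.values)

    single = submatrix(C, GeneSet("one", ["g2"]))
    np.testing.assert_array_equal(single.values, [[1.0]])

    rev = submatrix(C, GeneSet("rev", list(reversed(C.gene_ids))))
    np.testing.assert_array_equal(rev.values, C.values[::-1, ::-1])

    with pytest.raises(KeyError, match="nope"):
        submatrix(C, GeneSet("bad", ["g0", "nope"]))


@pytest.mark.parametrize("n,expected", [(2, 1), (26, 325)])
def test_offdiagonal_pair_count(n, expected):
    values = np.eye(n)
    C = CoexpressionMatrix(gene_ids=[f"g{i}" for i in range(n)], values=values)
    assert offdiagonal_values(C).size == expected


def test_scale_invariance_of_cosine_rows():
    rng = np.random.default_rng(1)
    energies = rng.random((6, 30))
    C1 = coexpression_matrix(make_dataset(energies))
    scaled = energies.copy()
    scaled[2] *= 37.5
    C2 = coexpression_matrix(make_dataset(scaled))
    np.testing.assert_allclose(C1.values, C2.values, atol=1e-12)


def test_permutation_equivariance():
    rng = np.random.default_rng(2)
    energies = rng.random((5, 20))
    perm = [4, 2, 0, 3, 1]
    C = coexpression_matrix(make_dataset(energies))
    Cp = coexpression_matrix(
        make_dataset(energies[perm], gene_ids=[f"g{i}" for i in perm])
    )
    np.testing.assert_allclose(
        Cp.values, C.values[np.ix_(perm, perm)], atol=1e-12
    )


def test_unit_profile_distance_equivalence():
    """For unit-normalized profiles, ||e - e'||^2 = 2 (1 - C)."""
    rng = np.random.default_rng(3)
    energies = rng.random((10, 50))
    C = coexpression_matrix(make_dataset(energies))
    unit = energies / np.linalg.norm(energies, axis=1, keepdims=True)
    for i in range(10):
        for j in range(i + 1, 10):
            dist_sq = np.sum((unit[i] - unit[j]) ** 2)
            assert dist_sq == pytest.approx(2 * (1 - C.values[i, j]), abs=1e-12)


# ---------------------------------------------------------------------------
# CDF comparison

def _brute_force_cdf_comparison(set_values, bg_values):
    """Independent oracle: evaluate both step functions at every observed
    point with a double loop."""
    points = sorted(set(set_values) | set(bg_values))
    best_d, best_x = -1.0, None
    best_excess, best_excess_x = -np.inf, None
    for x in points:
        cdf_s = sum(v <= x for v in set_values) / len(set_values)
        cdf_b = sum(v <= x for v in bg_values) / len(bg_values)
        if abs(cdf_b - cdf_s) > best_d + 1e-15:
            best_d, best_x = abs(cdf_b - cdf_s), x
        if (cdf_b - cdf_s) > best_excess + 1e-15:
            best_excess, best_excess_x = cdf_b - cdf_s, x
    return best_d, best_x, best_excess, best_excess_x


def test_identical_lists_zero_deviation():
    values = [0.1, 0.4, 0.9]
    out = compare_cdfs(values, values)
    assert out.ks_statistic == 0.0


def test_disjoint_supports_full_deviation():
    out = compare_cdfs([0.9] * 5, [0.1] * 7)
    assert out.ks_statistic == 1.0


def test_small_example_matches_brute_force():
    sv, bv = [0.2, 0.8], [0.1, 0.3, 0.9]
    out = compare_cdfs(sv, bv)
    d, x, excess, excess_x = _brute_force_cdf_comparison(sv, bv)
    assert out.ks_statistic == pytest.approx(d, abs=1e-15)
    assert out.argmax_coexpression == pytest.approx(x, abs=1e-15)
    assert out.set_excess == pytest.approx(excess, abs=1e-15)
    assert out.argmax_set_excess == pytest.approx(excess_x, abs=1e-15)


@pytest.mark.filterwarnings("ignore:divide by zero")
@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    sv=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50),
    bv=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50),
)
def test_deviation_matches_brute_force_oracle(sv, bv):
    out = compare_cdfs(sv, bv)
    d, x, _, _ = _brute_force_cdf_comparison(sv, bv)
    assert out.ks_statistic == pytest.approx(d, abs=1e-12)
    assert out.argmax_coexpression == pytest.approx(x, abs=1e-12)
    # statistic agrees with the reference two-sample implementation
    assert out.ks_statistic == pytest.approx(
        scipy.stats.ks_2samp(sv, bv).statistic, abs=1e-12
    )


def test_upshifted_set_signed_and_absolute_argmax_agree():
    rng = np.random.default_rng(4)
    bg = rng.random(400)
    shifted = np.clip(bg[:80] + 0.3, 0, 1)
    out = compare_cdfs(shifted, bg)
    assert out.argmax_set_excess == out.argmax_coexpression


def test_empty_input_rejected():
    with pytest.raises(ValidationError):
        compare_cdfs([], [0.1])


def test_background_values_excludes_set_pairs(default_coexpression, default_brain):
    _, _, designated, _ = default_brain
    C = default_coexpression
    n = C.n_genes
    total_pairs = n * (n - 1) // 2
    g = len(designated)
    set_pairs = g * (g - 1) // 2
    excl = background_values(C, designated, exclude_set_pairs=True)
    full = background_values(C, designated, exclude_set_pairs=False)
    assert full.size == total_pairs
    assert excl.size == total_pairs - set_pairs
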