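"""Anatomical localization of clique expression.

A clique's spatial signature is the sum of its members' L2-normalized
expression profiles,

    S_clique(v) = sum_{g in clique} E(v, g) / ||E(., g)||_2 ,

and its affinity for a brain region omega is the fitting score

    Phi(omega) = sum_v S(v) chi_omega(v) / (||S||_2 ||chi_omega||_2),

the cosine similarity between the summed profile and the region's
characteristic function: 1 when S is proportional to chi_omega, 0 when S is
supported entirely outside the region. Significance comes from a
permutation null that repeatedly draws random gene sets of the same size,
recomputes their summed profile and scores it in every region (one shared
set of draws per clique, scored across regions).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import characteristic_function
from .types import (
    ExpressionDataset,
    RegionAtlas,
    RegionMask,
    ValidationError,
)

__all__ = [
    "CliqueExpressionProfile",
    "FittingProfile",
    "clique_expression_sum",
    "fitting_score",
    "fitting_profile",
    "fitting_permutation_pvalues",
    "maximal_intensity_projection",
    "save_projection_text",
    "save_projection_png",
]


@dataclass
class CliqueExpressionProfile:
    """Summed normalized expression of a clique over masked voxels."""

    clique_id: str
    values: np.ndarray
    member_ids: list[str]
    excluded_zero_norm: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if (self.values < 0).any():
            raise ValidationError("clique expression profile must be nonnegative")


def clique_expression_sum(
    dataset: ExpressionDataset, members, clique_id: str = "clique"
) -> CliqueExpressionProfile:
    """Sum of unit-normalized member profiles; zero-norm members skipped
    with a warning, all-zero membership is an error."""
    members = list(members)
    idx = [dataset.gene_index(g) for g in members]
    energies = dataset.energies[idx]
    norms = np.linalg.norm(energies, axis=1)
    zero = norms == 0
    excluded = [g for g, z in zip(members, zero) if z]
    if zero.all():
        raise ValidationError(f"{clique_id}: every member has a zero profile")
    if excluded:
        warnings.warn(f"{clique_id}: zero-norm members skipped: {excluded}")
    unit = energies[~zero] / norms[~zero][:, None]
    return CliqueExpressionProfile(
        clique_id=clique_id,
        values=unit.sum(axis=0),
        member_ids=members,
        excluded_zero_norm=excluded,
    )


def fitting_score(profile: CliqueExpressionProfile, region: RegionMask) -> float:
    """Cosine similarity between the summed clique profile and a region's
    characteristic function; in [0, 1]."""
    s = profile.values
    chi = region.indicator
    if s.shape != chi.shape:
        raise ValidationError("profile and region mask have different voxel counts")
    s_norm = np.linalg.norm(s)
    chi_norm = np.linalg.norm(chi)
    if chi_norm == 0:
        raise ValidationError(f"region {region.region_id} is empty")
    if s_norm == 0:
        raise ValidationError("clique expression profile is identically zero")
    return float(np.clip((s @ chi) / (s_norm * chi_norm), 0.0, 1.0))


@dataclass
class FittingProfile:
    """Per-region fitting scores of one clique, optionally with a
    permutation null (p-values, null mean/sd)."""

    clique_id: str
    rows: pd.DataFrame  # region_id, acronym, main_group, fitting_score, ...
    n_perm: int | None = None
    seed: int | None = None

    def to_tsv(self, path: str | Path) -> None:
        self.rows.to_csv(path, sep="\t", index=False, float_format="%.17g")
        sidecar = {"clique_id": self.clique_id, "n_perm": self.n_perm,
                   "seed": self.seed}
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def _region_masks(
    atlas: RegionAtlas, region_ids, include_descendants: bool
) -> tuple[list[int], np.ndarray]:
    kept: list[int] = []
    masks: list[np.ndarray] = []
    for rid in region_ids:
        mask = characteristic_function(
            atlas, rid, include_descendants=include_descendants
        )
        if mask.n_set == 0:
            warnings.warn(f"region {rid} is empty; skipped")
            continue
        kept.append(int(rid))
        masks.append(mask.indicator)
    if not kept:
        raise ValidationError("no nonempty regions to score")
    return kept, np.stack(masks)


def fitting_profile(
    profile: CliqueExpressionProfile,
    atlas: RegionAtlas,
    region_ids=None,
    include_descendants: bool = True,
) -> FittingProfile:
    """Score the clique profile in each region (empty regions skipped)."""
    if region_ids is None:
        region_ids = atlas.region_ids
    kept, chi = _region_masks(atlas, region_ids, include_descendants)
    s = profile.values
    s_norm = np.linalg.norm(s)
    if s_norm == 0:
        raise ValidationError("clique expression profile is identically zero")
    scores = np.clip((chi @ s) / (s_norm * np.linalg.norm(chi, axis=1)), 0.0, 1.0)
    rows = pd.DataFrame(
        {
            "region_id": kept,
            "acronym": [atlas.region_row(r)["acronym"] for r in kept],
            "main_group": [atlas.main_group_of(r) for r in kept],
            "fitting_score": scores,
        }
    )
    return FittingProfile(clique_id=profile.clique_id, rows=rows)


def fitting_permutation_pvalues(
    dataset: ExpressionDataset,
    atlas: RegionAtlas,
    clique_size: int,
    region_ids,
    observed: FittingProfile,
    n_perm: int,
    seed: int,
    include_descendants: bool = True,
) -> FittingProfile:
    """Permutation null for per-region fitting scores.

    Each permutation draws ``clique_size`` genes uniformly from the dataset
    (zero-profile genes excluded), forms their summed normalized profile and
    scores it in every region; the one-sided p-value per region is
    (1 + #{null >= observed}) / (1 + n_perm). One shared set of draws is
    scored across all regions. Scores are computed algebraically from the
    genes' unit-profile Gram matrix, which avoids materializing null
    profiles.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    norms = np.linalg.norm(dataset.energies, axis=1)
    usable = np.nonzero(norms > 0)[0]
    if clique_size > usable.size:
        raise ValidationError(
            f"clique_size={clique_size} exceeds {usable.size} usable genes"
        )
    unit = dataset.energies[usable] / norms[usable][:, None]
    kept, chi = _region_masks(atlas, region_ids, include_descendants)
    obs = observed.rows.set_index("region_id")["fitting_score"]
    missing = [r for r in kept if r not in obs.index]
    if missing:
        raise ValidationError(f"observed scores missing for regions: {missing}")

    chi_norm = np.linalg.norm(chi, axis=1)
    gene_dot_chi = unit @ chi.T  # (n_usable, n_regions)
    gram = unit @ unit.T  # ||S||^2 = sum of the members' Gram block

    rng = np.random.default_rng(seed)
    draws = np.empty((n_perm, clique_size), dtype=np.intp)
    for p in range(n_perm):
        draws[p] = rng.choice(usable.size, size=clique_size, replace=False)
    numerator = gene_dot_chi[draws].sum(axis=1)  # (n_perm, n_regions)
    s_sq = gram[draws[:, :, None], draws[:, None, :]].sum(axis=(1, 2))
    null_scores = numerator / (np.sqrt(s_sq)[:, None] * chi_norm[None, :])

    obs_vec = obs.loc[kept].to_numpy()
    exceed = (null_scores >= obs_vec[None, :]).sum(axis=0)
    rows = observed.rows.copy()
    rows = rows[rows["region_id"].isin(kept)].reset_index(drop=True)
    rows["permutation_p"] = (1 + exceed) / (1 + n_perm)
    rows["null_mean"] = null_scores.mean(axis=0)
    rows["null_sd"] = null_scores.std(axis=0, ddof=1) if n_perm > 1 else np.nan
    return FittingProfile(
        clique_id=observed.clique_id, rows=rows, n_perm=int(n_perm), seed=int(seed)
    )


_AXES = {"x": 0, "y": 1, "z": 2}


def maximal_intensity_projection(
    profile: CliqueExpressionProfile, dataset: ExpressionDataset, axis: str = "y"
) -> np.ndarray:
    """Maximum of the profile along one grid axis (unmasked voxels are 0)."""
    if axis not in _AXES:
        raise ValidationError(f"axis must be one of {sorted(_AXES)}")
    volume = dataset.to_volume(profile.values)
    return volume.max(axis=_AXES[axis])


def save_projection_text(image: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, image, fmt="%.17g", delimiter="\t")


def save_projection_png(image: np.ndarray, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    plt.imsave(path, image.T, origin="lower", cmap="inferno")
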