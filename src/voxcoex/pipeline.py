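"""End-to-end orchestration: inputs -> co-expression -> CDF/KS -> component
curves and random-set envelope -> seed cliques -> extension -> enrichment ->
anatomical fitting, driven by one :class:`RunConfig`.

Each stage writes plain-text artifacts into the run directory and can be
resumed from them; a run manifest records the configuration, per-stage
seeds and a SHA-256 digest of every output, so end-to-end determinism under
a fixed master seed is checkable by digest comparison.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as vio
from .anatomy import (
    clique_expression_sum,
    fitting_permutation_pvalues,
    fitting_profile,
    maximal_intensity_projection,
    save_projection_png,
    save_projection_text,
)
from .cliques import (
    Clique,
    component_size_curves,
    extend_clique,
    seed_cliques,
    write_clique_table,
)
from .coexpression import (
    CoexpressionMatrix,
    background_values,
    coexpression_matrix,
    compare_cdfs,
    offdiagonal_values,
    submatrix,
)
from .enrichment import (
    bonferroni,
    mc_overlap_pvalue,
    random_component_envelope,
    write_enrichment_table,
)
from .synthetic import SyntheticSpec, generate_synthetic_brain
from .types import ExpressionDataset, GeneSet, RegionAtlas, ValidationError

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "report_summary", "STAGES"]

logger = logging.getLogger("voxcoex.pipeline")

STAGES = (
    "inputs", "coexpr", "cdf", "curves", "cliques", "enrich", "anatomy",
)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input mode: a synthetic spec, or paths to on-disk inputs
    (expression manifest + mask, annotation + hierarchy, designated set).
    ``rho_policy`` is either the string ``"argmax"`` (seed threshold taken
    at the co-expression value of largest CDF deviation) or a fixed float.
    """

    synthetic: SyntheticSpec | None = None
    input_paths: dict | None = None
    rho_policy: str | float = "argmax"
    exclude_set_pairs: bool = True
    n_draws: int = 10000
    n_perm: int = 10000
    n_sets: int = 1000
    rho_grid_points: int = 101
    anatomy_p_threshold: float = 0.01
    max_anatomy_cliques: int = 5
    write_png: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.input_paths is None):
            raise ValidationError(
                "exactly one of synthetic spec or input paths must be set"
            )
        if isinstance(self.rho_policy, str):
            if self.rho_policy != "argmax":
                raise ValidationError("rho_policy must be 'argmax' or a float")
        else:
            self.rho_policy = float(self.rho_policy)
            if not 0 <= self.rho_policy <= 1:
                raise ValidationError("fixed rho must lie in [0, 1]")
        for name in ("n_draws", "n_perm", "n_sets", "rho_grid_points"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")

    @property
    def rho_grid(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.rho_grid_points)

    def to_dict(self) -> dict:
        return {
            "synthetic": self.synthetic.to_dict() if self.synthetic else None,
            "input_paths": self.input_paths,
            "rho_policy": self.rho_policy,
            "exclude_set_pairs": self.exclude_set_pairs,
            "n_draws": self.n_draws,
            "n_perm": self.n_perm,
            "n_sets": self.n_sets,
            "rho_grid_points": self.rho_grid_points,
            "anatomy_p_threshold": self.anatomy_p_threshold,
            "max_anatomy_cliques": self.max_anatomy_cliques,
            "write_png": self.write_png,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload)
        if payload.get("synthetic") is not None:
            payload["synthetic"] = SyntheticSpec.from_dict(payload["synthetic"])
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed, so a
    stage reruns identically when resumed in isolation (< 2^31)."""
    idx = STAGES.index(stage)
    return int(
        np.random.SeedSequence([int(master_seed), idx]).generate_state(1)[0]
        % (2**31)
    )


@dataclass
class RunManifest:
    """Echo of the configuration plus per-stage seeds and output digests."""

    config: dict
    stage_seeds: dict
    files: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "config": self.config,
                    "stage_seeds": self.stage_seeds,
                    "files": self.files,
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RunManifest":
        payload = json.loads(Path(path).read_text())
        return cls(**payload)

    def verify(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        for rel, digest in self.files.items():
            path = outdir / rel
            if not path.exists():
                raise ValidationError(f"manifest output missing: {rel}")
            if _sha256(path) != digest:
                raise ValidationError(f"manifest digest mismatch: {rel}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# stage I/O helpers

def _load_inputs(outdir: Path) -> tuple[ExpressionDataset, RegionAtlas, GeneSet]:
    dataset = vio.load_dataset_tabular(outdir / "dataset")
    labels = pd.read_csv(outdir / "labels.tsv", sep="\t")["region_id"].to_numpy()
    hierarchy = pd.read_csv(outdir / "hierarchy.csv")
    atlas = RegionAtlas(labels=labels, regions=hierarchy)
    designated = vio.load_gene_set(outdir / "designated.tsv", name="designated")
    return dataset, atlas, designated


def _stage_inputs(config: RunConfig, outdir: Path) -> list[Path]:
    if config.synthetic is not None:
        spec = SyntheticSpec.from_dict(config.synthetic.to_dict())
        spec.seed = stage_seed(config.seed, "inputs")
        dataset, atlas, designated, truth = generate_synthetic_brain(spec)
        truth.to_json(outdir / "ground_truth.json")
    else:
        paths = config.input_paths
        dataset = vio.load_expression_dataset(paths["manifest"], paths["mask"])
        atlas = vio.load_region_atlas(
            paths["annotation"], paths["hierarchy"], paths.get("mask")
        )
        designated = vio.load_gene_set(paths["designated"], name="designated")
    vio.write_dataset_tabular(dataset, outdir / "dataset")
    pd.DataFrame({"region_id": atlas.labels}).to_csv(
        outdir / "labels.tsv", sep="\t", index=False
    )
    atlas.regions.to_csv(outdir / "hierarchy.csv", index=False)
    vio.write_gene_set(designated, outdir / "designated.tsv")
    produced = [
        outdir / "dataset.mtx", outdir / "dataset.genes.tsv",
        outdir / "dataset.voxels.tsv", outdir / "dataset.meta.json",
        outdir / "labels.tsv", outdir / "hierarchy.csv",
        outdir / "designated.tsv",
    ]
    if config.synthetic is not None:
        produced.append(outdir / "ground_truth.json")
    return produced


def _stage_coexpr(config: RunConfig, outdir: Path) -> list[Path]:
    dataset, _, _ = _load_inputs(outdir)
    C = coexpression_matrix(dataset)
    C.to_tsv(outdir / "coexpression.tsv")
    return [outdir / "coexpression.tsv"]


def _stage_cdf(config: RunConfig, outdir: Path) -> list[Path]:
    _, _, designated = _load_inputs(outdir)
    C = CoexpressionMatrix.from_tsv(outdir / "coexpression.tsv")
    set_values = offdiagonal_values(submatrix(C, designated))
    bg_values = background_values(
        C, designated, exclude_set_pairs=config.exclude_set_pairs
    )
    comparison = compare_cdfs(set_values, bg_values)
    if config.rho_policy == "argmax":
        # delineation threshold: where the designated set is maximally
        # enriched above the background (signed deviation), which equals the
        # two-sided argmax for a homogeneously up-shifted set
        rho0 = comparison.argmax_set_excess
    else:
        rho0 = float(config.rho_policy)
    comparison.extra = {
        "rho_policy": config.rho_policy,
        "rho0": rho0,
        "exclude_set_pairs": config.exclude_set_pairs,
    }
    comparison.to_json(outdir / "cdf.json")
    return [outdir / "cdf.json"]


def _stage_curves(config: RunConfig, outdir: Path) -> list[Path]:
    _, _, designated = _load_inputs(outdir)
    C = CoexpressionMatrix.from_tsv(outdir / "coexpression.tsv")
    curve = component_size_curves(submatrix(C, designated), config.rho_grid)
    curve.to_tsv(outdir / "component_curves.tsv")
    envelope = random_component_envelope(
        C,
        set_size=len(designated),
        rho_grid=config.rho_grid,
        n_sets=config.n_sets,
        seed=stage_seed(config.seed, "curves"),
    )
    envelope.to_tsv(outdir / "random_envelope.tsv")
    return [outdir / "component_curves.tsv", outdir / "random_envelope.tsv"]


def _read_rho0(outdir: Path) -> float:
    return float(json.loads((outdir / "cdf.json").read_text())["rho0"])


def _read_cliques(outdir: Path) -> list[Clique]:
    table = pd.read_csv(outdir / "cliques.tsv", sep="\t")
    out = []
    for _, row in table.iterrows():
        out.append(
            Clique(
                member_ids=str(row["member_ids"]).split(","),
                seed_ids=str(row["seed_ids"]).split(","),
                rho=float(row["rho"]),
                min_coexpression=float(row["min_coexpression"]),
                ng=int(row["ng"]),
                clique_id=str(row["clique_id"]),
            )
        )
    return out


def _stage_cliques(config: RunConfig, outdir: Path) -> list[Path]:
    _, _, designated = _load_inputs(outdir)
    C = CoexpressionMatrix.from_tsv(outdir / "coexpression.tsv")
    rho0 = _read_rho0(outdir)
    seeds = seed_cliques(submatrix(C, designated), rho0)
    cliques = []
    seen: set[tuple] = set()
    for i, seed in enumerate(seeds):
        clique = extend_clique(C, seed)
        key = tuple(clique.member_ids)
        if key in seen:  # identical member sets collapse; overlaps are kept
            continue
        seen.add(key)
        clique.clique_id = f"clique_{len(cliques) + 1:03d}"
        clique.count_designated(designated)
        cliques.append(clique)
    write_clique_table(cliques, outdir / "cliques.tsv")
    return [outdir / "cliques.tsv"]


def _stage_enrich(config: RunConfig, outdir: Path) -> list[Path]:
    dataset, _, designated = _load_inputs(outdir)
    cliques = _read_cliques(outdir)
    universe = GeneSet(name="universe", gene_ids=list(dataset.gene_ids))
    base = stage_seed(config.seed, "enrich")
    results = []
    for i, clique in enumerate(cliques):
        results.append(
            mc_overlap_pvalue(
                clique.member_ids,
                universe,
                set_size=len(designated),
                ng_threshold=clique.ng,
                n_draws=config.n_draws,
                seed=(base + i) % (2**31),  # independent stream per clique
                clique_id=clique.clique_id,
            )
        )
    corrected = bonferroni([r.p_mc for r in results], n_tests=max(1, len(results)))
    for r, p in zip(results, corrected):
        r.p_bonferroni = p
    write_enrichment_table(results, outdir / "enrichment.tsv")
    return [outdir / "enrichment.tsv"]


def _stage_anatomy(config: RunConfig, outdir: Path) -> list[Path]:
    dataset, atlas, _ = _load_inputs(outdir)
    cliques = {c.clique_id: c for c in _read_cliques(outdir)}
    enrich = pd.read_csv(outdir / "enrichment.tsv", sep="\t")
    selected = enrich[enrich["p_mc"] < config.anatomy_p_threshold]
    selected = selected.sort_values(["p_mc", "clique_id"]).head(
        config.max_anatomy_cliques
    )
    produced: list[Path] = []
    base = stage_seed(config.seed, "anatomy")
    for i, clique_id in enumerate(selected["clique_id"]):
        clique = cliques[str(clique_id)]
        profile = clique_expression_sum(
            dataset, clique.member_ids, clique_id=str(clique_id)
        )
        observed = fitting_profile(profile, atlas)
        scored = fitting_permutation_pvalues(
            dataset,
            atlas,
            clique_size=len(profile.member_ids) - len(profile.excluded_zero_norm),
            region_ids=observed.rows["region_id"].tolist(),
            observed=observed,
            n_perm=config.n_perm,
            seed=(base + i) % (2**31),
        )
        fit_path = outdir / f"fitting_{clique_id}.tsv"
        scored.to_tsv(fit_path)
        produced += [fit_path, Path(str(fit_path) + ".json")]
        image = maximal_intensity_projection(profile, dataset, axis="y")
        text_path = outdir / f"projection_{clique_id}_y.tsv"
        save_projection_text(image, text_path)
        produced.append(text_path)
        if config.write_png:
            png_path = outdir / f"projection_{clique_id}_y.png"
            save_projection_png(image, png_path)
            produced.append(png_path)
    (outdir / "anatomy_index.json").write_text(
        json.dumps({"cliques": [str(c) for c in selected["clique_id"]]}, indent=2)
        + "\n"
    )
    produced.append(outdir / "anatomy_index.json")
    return produced


_STAGE_FUNCS = {
    "inputs": _stage_inputs,
    "coexpr": _stage_coexpr,
    "cdf": _stage_cdf,
    "curves": _stage_curves,
    "cliques": _stage_cliques,
    "enrich": _stage_enrich,
    "anatomy": _stage_anatomy,
}

_STAGE_SENTINELS = {
    "inputs": "dataset.mtx",
    "coexpr": "coexpression.tsv",
    "cdf": "cdf.json",
    "curves": "random_envelope.tsv",
    "cliques": "cliques.tsv",
    "enrich": "enrichment.tsv",
    "anatomy": "anatomy_index.json",
}


def run_pipeline(
    config: RunConfig,
    outdir: str | Path,
    resume: bool = False,
    stages=STAGES,
) -> RunManifest:
    """Execute the pipeline stages, writing artifacts and a manifest.

    With ``resume=True`` a stage whose sentinel output already exists is
    skipped, so deleted downstream artifacts are regenerated bit-identically
    (stage seeds derive from the master seed, not from execution order). A
    stage failure aborts with the stage name; previously produced files stay
    on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config.to_dict(),
        stage_seeds={s: stage_seed(config.seed, s) for s in STAGES},
    )
    produced: dict[str, str] = {}
    for stage in stages:
        if stage not in _STAGE_FUNCS:
            raise ValidationError(f"unknown stage {stage!r}")
        if resume and (outdir / _STAGE_SENTINELS[stage]).exists():
            logger.info("stage %s: resumed from existing outputs", stage)
            continue
        logger.info("stage %s: running", stage)
        try:
            files = _STAGE_FUNCS[stage](config, outdir)
        except Exception as exc:
            manifest.files = produced
            manifest.to_json(outdir / "run_manifest.json")
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        for path in files:
            produced[str(path.relative_to(outdir))] = _sha256(path)
    # include resumed stages' artifacts in the digest table
    for path in sorted(outdir.iterdir()):
        if path.is_file() and path.name != "run_manifest.json":
            produced.setdefault(path.name, _sha256(path))
    manifest.files = dict(sorted(produced.items()))
    manifest.to_json(outdir / "run_manifest.json")
    return manifest


def report_summary(outdir: str | Path) -> dict:
    """Condense a finished run into a small JSON-able summary (no
    recomputation): clique count, top enrichment, top region per scored
    clique. Raises if a manifest output is missing or altered."""
    outdir = Path(outdir)
    manifest = RunManifest.from_json(outdir / "run_manifest.json")
    manifest.verify(outdir)
    summary: dict = {"n_cliques": 0, "cliques": []}
    cdf = json.loads((outdir / "cdf.json").read_text())
    summary["ks_statistic"] = cdf["ks_statistic"]
    summary["ks_pvalue"] = cdf["ks_pvalue"]
    summary["rho0"] = cdf["rho0"]
    cliques_path = outdir / "cliques.tsv"
    if cliques_path.exists():
        table = pd.read_csv(cliques_path, sep="\t")
        summary["n_cliques"] = int(len(table))
    enrich_path = outdir / "enrichment.tsv"
    if enrich_path.exists() and summary["n_cliques"] > 0:
        enrich = pd.read_csv(enrich_path, sep="\t")
        best = enrich.sort_values(["p_mc", "clique_id"]).iloc[0]
        summary["top_clique"] = {
            "clique_id": str(best["clique_id"]),
            "p_mc": float(best["p_mc"]),
            "p_bonferroni": float(best["p_bonferroni"]),
        }
    index_path = outdir / "anatomy_index.json"
    if index_path.exists():
        for clique_id in json.loads(index_path.read_text())["cliques"]:
            rows = pd.read_csv(outdir / f"fitting_{clique_id}.tsv", sep="\t")
            top = rows.sort_values(
                ["fitting_score", "region_id"], ascending=[False, True]
            ).iloc[0]
            summary["cliques"].append(
                {
                    "clique_id": clique_id,
                    "top_region": int(top["region_id"]),
                    "top_region_acronym": str(top["acronym"]),
                    "top_main_group": str(top["main_group"]),
                    "fitting_score": float(top["fitting_score"]),
                    "permutation_p": float(top["permutation_p"]),
                }
            )
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary
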