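"""One-command orchestration of the full community-assembly analysis.

Runs the analysis graph — diversity, latitudinal diversity gradient,
distance decay, multivariate group tests, environmental-driver attribution,
PCNM + variation partitioning, and null-model stochasticity — on either a
synthetic community or user-supplied tables, writing one JSON artifact per
stage plus a manifest with configuration echo, derived seeds and output
checksums. A single global seed is fanned out to per-stage child seeds by
stable derivation so any stage can be re-run in isolation reproducibly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assembly import anosim, environment_distance, factor_importance, mantel, mrpp, partial_mantel, permanova
from .biogeography import ddr, geo_distance, ldg
from .diversity import alpha_diversity, bray_curtis, ordinate, similarity_from
from .spatial import forward_select, pcnm, variation_partition
from .stochasticity import run_stochasticity
from .synth import SyntheticConfig, make_community
from .tables import AbundanceTable, SampleMetadata, normalize_depth, read_metadata, read_table, write_metadata, write_table

__all__ = ["STAGES", "RunConfig", "PipelineError", "run_pipeline"]

STAGES = ("diversity", "ldg", "ddr", "tests", "drivers", "vpa", "stochasticity")


class PipelineError(RuntimeError):
    """Raised when one or more pipeline stages fail."""


@dataclass
class RunConfig:
    """Validated configuration of a pipeline run.

    Inputs are either a synthetic-community spec (``synth`` holding
    :class:`~ncycomm.synth.SyntheticConfig` keywords) or paths to existing
    taxon/trait/metadata tables. Validation is fail-fast: every enabled
    stage's inputs must be resolvable before execution starts.
    """

    out_dir: str | Path = "ncycomm_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    n_perm: int = 999
    n_null: int = 200
    normalization_target: float | None = None
    synth: dict | None = None
    taxon_table: str | None = None
    trait_table: str | None = None
    metadata: str | None = None

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}; known: {STAGES}")
        if self.synth is None:
            paths = {"taxon_table": self.taxon_table, "trait_table": self.trait_table,
                     "metadata": self.metadata}
            missing = [k for k, v in paths.items() if v is None]
            if missing:
                raise ValueError(f"no synth config and no input path for: {missing}")
            absent = [v for v in paths.values() if not Path(v).exists()]
            if absent:
                raise FileNotFoundError(f"input files not found: {absent}")
        if self.n_perm < 1 or self.n_null < 1:
            raise ValueError("n_perm and n_null must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _jsonable(obj):
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else str(v)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Stable per-stage child generator from the global seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(STAGES.index(stage),)))


def _fit_dict(fit) -> dict:
    return {
        "slope": fit.slope, "intercept": fit.intercept, "r2": fit.r2,
        "p_value": fit.p_value, "p_permutation": fit.p_permutation,
        "n": fit.n, "n_excluded": fit.n_excluded,
    }


def _test_dict(res) -> dict:
    return {
        "statistic": res.statistic, "p_value": res.p_value,
        "n_permutations": res.n_permutations,
        "perm_mean": res.perm_mean, "perm_sd": res.perm_sd,
        **(res.extra or {}),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the run manifest.

    Per-stage JSON files and a ``manifest.json`` are written to
    ``config.out_dir``. A stage failure is recorded and independent stages
    continue; :class:`PipelineError` is raised at the end if anything
    failed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- inputs ---------------------------------------------------------
    if config.synth is not None:
        synth_cfg = SyntheticConfig(**{**config.synth, "seed": config.synth.get("seed", config.seed)})
        metadata, taxon, trait, truth = make_community(synth_cfg)
        write_metadata(metadata, out / "metadata.tsv")
        write_table(taxon, out / "taxa.tsv")
        write_table(trait, out / "traits.tsv")
        (out / "truth.json").write_text(json.dumps(_jsonable(truth.as_dict()), indent=1))
    else:
        taxon = read_table(config.taxon_table, feature_kind="taxon")
        trait = read_table(config.trait_table, feature_kind="trait")
        metadata = read_metadata(config.metadata)
    if config.normalization_target:
        taxon = normalize_depth(taxon, config.normalization_target)
        trait = normalize_depth(trait, config.normalization_target)
    metadata = metadata.align_to(taxon.sample_ids)
    tables = {"taxon": taxon, "trait": trait}

    geo = geo_distance(metadata)
    bc = {k: bray_curtis(t) for k, t in tables.items()}
    sim = {k: similarity_from(d) for k, d in bc.items()}
    alpha = {k: alpha_diversity(t) for k, t in tables.items()}
    zone = metadata.zone()

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": _jsonable(dataclasses.asdict(config)),
        "stages": {},
    }
    failures: list[str] = []

    def _run_stage(name: str, fn) -> None:
        if name not in config.stages:
            manifest["stages"][name] = {"status": "disabled"}
            return
        try:
            payload = fn(_stage_rng(config.seed, name))
            path = out / f"{name}.json"
            text = json.dumps(_jsonable(payload), indent=1, sort_keys=True)
            path.write_text(text)
            manifest["stages"][name] = {
                "status": "ok",
                "output": path.name,
                "sha256": hashlib.sha256(text.encode()).hexdigest(),
            }
        except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
            failures.append(name)
            manifest["stages"][name] = {
                "status": "failed",
                "error": f"{type(exc).__name__}: {exc}",
                "traceback": traceback.format_exc(limit=5),
            }

    # ---- stages ---------------------------------------------------------
    def stage_diversity(rng):
        payload = {}
        for kind, a in alpha.items():
            ordn = ordinate(bc[kind], "pcoa_on_distance")
            payload[kind] = {
                "alpha_mean": a.mean().to_dict(),
                "alpha_sd": a.std().to_dict(),
                "pcoa_variance_explained": ordn.proportion_explained[:2],
                "mean_bray_curtis": float(np.mean(bc[kind].condensed_form())),
            }
        return payload

    def stage_ldg(rng):
        payload = {}
        for kind, a in alpha.items():
            payload[kind] = {}
            for subset in ("all", "SRF", "DCM", "MES"):
                try:
                    payload[kind][subset] = _fit_dict(ldg(a["richness"], metadata, subset))
                except ValueError as exc:
                    payload[kind][subset] = {"error": str(exc)}
        return payload

    def stage_ddr(rng):
        payload = {}
        for kind in tables:
            payload[kind] = {
                "all": _fit_dict(ddr(sim[kind], geo, n_perm=config.n_perm, rng=rng))
            }
            for layer in ("SRF", "DCM", "MES"):
                ids = [s for s in taxon.sample_ids if metadata.frame.loc[s, "layer"] == layer]
                if len(ids) < 3:
                    continue
                try:
                    payload[kind][layer] = _fit_dict(
                        ddr(sim[kind], geo, subset_ids=ids, n_perm=config.n_perm, rng=rng)
                    )
                except ValueError as exc:
                    payload[kind][layer] = {"error": str(exc)}
        return payload

    def stage_tests(rng):
        env_d = environment_distance(metadata)
        payload = {}
        for kind in tables:
            payload[kind] = {
                "permanova_epi_vs_meso": _test_dict(permanova(bc[kind], zone, config.n_perm, rng)),
                "anosim_epi_vs_meso": _test_dict(anosim(bc[kind], zone, config.n_perm, rng)),
                "mrpp_epi_vs_meso": _test_dict(mrpp(bc[kind], zone, config.n_perm, rng)),
                "mantel_env": _test_dict(mantel(bc[kind], env_d, config.n_perm, rng=rng)),
                "partial_mantel_env_given_geo": _test_dict(
                    partial_mantel(bc[kind], env_d, geo, config.n_perm, rng=rng)
                ),
            }
        return payload

    def stage_drivers(rng):
        env = metadata.env
        payload = {}
        for kind, a in alpha.items():
            imp = factor_importance(a["shannon"], env, n_trees=200, rng=rng)
            from scipy.stats import spearmanr

            rho = {
                col: float(spearmanr(env[col], a["shannon"]).statistic)
                for col in env.columns
            }
            payload[kind] = {
                "importance": imp["importance"].to_dict(),
                "univariate_r2": imp["univariate_r2"].to_dict(),
                "best_factor": imp.attrs["best_factor"],
                "spearman_rho_shannon": rho,
            }
        return payload

    def stage_vpa(rng):
        basis = pcnm(geo)
        env = metadata.env
        payload = {"pcnm": {"threshold_km": basis.threshold_km, "n_axes": basis.n_axes}}
        for kind, t in tables.items():
            env_sel = forward_select(t, env, alpha=0.05, n_perm=199, rng=rng)
            spa_sel = forward_select(t, basis.scores, alpha=0.05, n_perm=199, rng=rng)
            if not env_sel and not spa_sel:
                payload[kind] = {"error": "no variable survived forward selection"}
                continue
            res = variation_partition(
                t,
                env[env_sel] if env_sel else None,
                basis.scores[spa_sel] if spa_sel else None,
            )
            payload[kind] = res.as_dict()
        return payload

    def stage_stochasticity(rng):
        payload = {}
        for kind, t in tables.items():
            results = run_stochasticity(t, metadata, n_null=config.n_null, rng=rng)
            payload[kind] = {
                grp: {"st": r.st, "n_a": r.n_a, "n_b": r.n_b, "n_pairs": len(r.pairs)}
                for grp, r in results.items()
            }
        return payload

    _run_stage("diversity", stage_diversity)
    _run_stage("ldg", stage_ldg)
    _run_stage("ddr", stage_ddr)
    _run_stage("tests", stage_tests)
    _run_stage("drivers", stage_drivers)
    _run_stage("vpa", stage_vpa)
    _run_stage("stochasticity", stage_stochasticity)

    (out / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=1, sort_keys=True))
    if failures:
        raise PipelineError(f"stages failed: {failures} (see manifest.json)")
    return manifest
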