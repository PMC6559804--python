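"""End-to-end screen orchestration with reproducible manifests.

Stage order: read model → candidate filter → expression mapping /
discretization / consensus / GPR propagation per condition → iMAT per
condition → ACHR sampling of the source flux space → change sets →
knockout screen → dual-criterion selection → optional enrichment.

Every run writes a manifest (resolved configuration, software version,
per-stage wall time, solver statuses, input/output checksums) — also on
failure, naming the failing stage.  Two runs from one configuration are
identical apart from timestamps.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import candidate_reactions
from .enrichment import hypergeometric_test, read_gene_list
from .expression import (consensus_state, discretize_matrix,
                         map_expression_to_model, read_expression,
                         reaction_states_from_gpr)
from .imat import IMAT
from .io import read_model
from .mta import MTAScreen, derive_change_sets, reaction_gene_map
from .sampling import achr_sample, mean_metabolic_state

__all__ = ["RunConfig", "ConfigError", "PipelineError", "validate_config",
           "run_pipeline", "screen_scenario"]


def screen_scenario(scenario, n_samples: int = 2000, seed: int | None = None,
                    **mta_kwargs):
    """In-memory screen of a synthetic scenario (disease → healthy).

    Runs discretization → consensus → iMAT → ACHR → change sets →
    knockout screen on the scenario's own model and expression data and
    returns the :class:`fluxshift.mta.MTAResults`.  ``seed`` (default:
    the scenario's seed) drives the ACHR chain.
    """
    model = scenario.model
    src, _ = map_expression_to_model(scenario.disease_expr, model)
    tgt, _ = map_expression_to_model(scenario.healthy_expr, model)
    assignment = reaction_states_from_gpr(
        consensus_state(discretize_matrix(src)), model)
    imat_res = IMAT(model, assignment).fit()
    if imat_res.v is None:
        raise RuntimeError(f"iMAT infeasible: {imat_res.diagnostic}")
    samples = achr_sample(imat_res.activity_polytope(), n_samples=n_samples,
                          seed=scenario.seed if seed is None else seed)
    v_source = mean_metabolic_state(samples)
    change_sets = derive_change_sets(src, tgt, model)
    return MTAScreen(model, v_source, change_sets, **mta_kwargs).fit()


class ConfigError(ValueError):
    """Invalid or unknown configuration."""


class PipelineError(RuntimeError):
    """A stage failed; the manifest names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Fully-resolved pipeline configuration; every default materialized."""

    model: str
    source_expr: str
    target_expr: str
    out_dir: str
    model_format: str = "json_tabular"
    reference_genes: str | None = None
    q_low: float = 0.25
    q_high: float = 0.25
    agreement: float = 2.0 / 3.0
    epsilon_active: float = 1.0
    epsilon_zero: float = 1e-4
    de_alpha: float = 0.05
    min_samples: int = 3
    alpha_weight: float = 0.66
    epsilon_change_rel: float = 0.1
    epsilon_change_floor: float = 1.0
    delta: float = 0.1
    gamma: float = 0.01
    achievement_bonus: float = 1e-6
    top_fraction: float = 0.10
    n_samples: int = 2000
    thinning: int = 10
    seed: int = 0
    time_limit: float = 300.0

    def validate(self) -> None:
        for key in ("q_low", "q_high", "agreement", "top_fraction"):
            val = getattr(self, key)
            if not 0 < val < 1:
                raise ConfigError(f"{key} must be in (0, 1), got {val}")
        if self.q_low + self.q_high >= 1:
            raise ConfigError("q_low + q_high must be < 1")
        for key in ("model", "source_expr", "target_expr"):
            if not Path(getattr(self, key)).exists():
                raise ConfigError(f"{key} file not found: {getattr(self, key)}")
        if self.reference_genes and not Path(self.reference_genes).exists():
            raise ConfigError(f"reference_genes file not found: {self.reference_genes}")


_REQUIRED = ("model", "source_expr", "target_expr", "out_dir")


def validate_config(source: str | Path | dict, strict: bool = True,
                    check_files: bool = True) -> RunConfig:
    """Parse a flat TOML-like key=value config into a RunConfig.

    Unknown keys raise in strict mode (warn otherwise); string-typed
    numbers are coerced with a warning.  All defaults are materialized
    on the returned object.
    """
    import warnings

    if isinstance(source, dict):
        raw = dict(source)
    else:
        import tomllib
        with open(source, "rb") as fh:
            try:
                raw = tomllib.load(fh)
            except tomllib.TOMLDecodeError as exc:
                raise ConfigError(f"{source}: {exc}") from exc
    known = set(RunConfig.__dataclass_fields__)
    unknown = sorted(set(raw) - known)
    if unknown:
        if strict:
            raise ConfigError(f"unknown config keys: {unknown}")
        warnings.warn(f"ignoring unknown config keys: {unknown}")
        for k in unknown:
            raw.pop(k)
    missing = [k for k in _REQUIRED if k not in raw]
    if missing:
        raise ConfigError(f"missing required config keys: {missing}")
    coerced = {}
    for key, val in raw.items():
        want_float = key in ("q_low", "q_high", "agreement", "epsilon_active",
                             "epsilon_zero", "de_alpha", "alpha_weight",
                             "epsilon_change_rel", "epsilon_change_floor",
                             "delta", "gamma", "achievement_bonus", "top_fraction",
                             "time_limit")
        want_int = key in ("min_samples", "n_samples", "thinning", "seed")
        if isinstance(val, str) and (want_float or want_int):
            warnings.warn(f"coercing config key {key}={val!r} to a number")
            val = float(val) if want_float else int(val)
        elif want_float:
            val = float(val)
        elif want_int:
            if isinstance(val, float) and val != int(val):
                raise ConfigError(f"{key} must be an integer, got {val}")
            val = int(val)
        coerced[key] = val
    cfg = RunConfig(**coerced)
    for key in ("q_low", "q_high", "agreement", "top_fraction"):
        if not 0 < getattr(cfg, key) < 1:
            raise ConfigError(f"{key} must be in (0, 1), got {getattr(cfg, key)}")
    if check_files:
        cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full screen; returns the manifest dictionary."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "stages": {},
        "solver_statuses": {},
        "inputs": {},
        "outputs": {},
        "status": "running",
    }
    for key in ("model", "source_expr", "target_expr", "reference_genes"):
        p = getattr(config, key)
        if p:
            manifest["inputs"][key] = {"path": str(p), "sha256": _sha256(Path(p))}

    stage = "read_model"
    t_start = time.perf_counter()

    def tick(name: str) -> None:
        nonlocal stage, t_start
        manifest["stages"][stage] = round(time.perf_counter() - t_start, 4)
        stage = name
        t_start = time.perf_counter()

    try:
        model = read_model(config.model, config.model_format)

        tick("candidate_filter")
        candidates = candidate_reactions(model)
        if not candidates:
            raise ValueError("no candidate reactions after filtering")
        manifest["n_candidates"] = len(candidates)

        tick("expression")
        states = {}
        exprs = {}
        for cond, path in (("source", config.source_expr),
                           ("target", config.target_expr)):
            expr = read_expression(path)
            mapped, report = map_expression_to_model(expr, model)
            exprs[cond] = mapped
            per_sample = discretize_matrix(mapped, config.q_low, config.q_high)
            consensus = consensus_state(per_sample, config.agreement)
            states[cond] = reaction_states_from_gpr(consensus, model)
            manifest.setdefault("mapping", {})[cond] = {
                "n_mapped": int(mapped.shape[0]),
                "n_unmapped": len(report.unmapped),
                "n_uncovered": len(report.uncovered),
            }

        tick("imat")
        imat_res = {}
        for cond in ("source", "target"):
            res = IMAT(model, states[cond],
                       epsilon_active=config.epsilon_active,
                       epsilon_zero=config.epsilon_zero,
                       time_limit=config.time_limit).fit()
            if res.v is None:
                raise RuntimeError(f"iMAT infeasible for {cond}: {res.diagnostic}")
            imat_res[cond] = res
            manifest["solver_statuses"][f"imat_{cond}"] = res.status
            manifest.setdefault("imat_objective", {})[cond] = res.objective
        imat_res["source"].to_frame().to_csv(out_dir / "imat_source.tsv", sep="\t")

        tick("sampling")
        polytope = imat_res["source"].activity_polytope()
        samples = achr_sample(polytope, n_samples=config.n_samples,
                              seed=config.seed, thinning=config.thinning)
        v_source = mean_metabolic_state(samples)
        v_source.as_series().to_csv(out_dir / "source_state.tsv", sep="\t",
                                    index_label="reaction_id",
                                    header=["mean_flux"])
        manifest["sampling"] = {"n_samples": samples.n_samples,
                                "thinning": samples.thinning,
                                "n_warmup": samples.n_warmup,
                                "seed": config.seed,
                                "alternate_optima_note":
                                    "sampled from the single frozen iMAT optimum"}

        tick("change_sets")
        change_sets = derive_change_sets(exprs["source"], exprs["target"], model,
                                         alpha=config.de_alpha,
                                         min_samples=config.min_samples)
        manifest["change_sets"] = {"R_F": len(change_sets.R_F),
                                   "R_B": len(change_sets.R_B),
                                   "R_S": len(change_sets.R_S),
                                   "conflicts": sorted(change_sets.conflicts)}

        tick("mta")
        screen = MTAScreen(model, v_source, change_sets, candidates=candidates,
                           alpha_weight=config.alpha_weight,
                           epsilon_change_rel=config.epsilon_change_rel,
                           epsilon_change_floor=config.epsilon_change_floor,
                           delta=config.delta, gamma=config.gamma,
                           achievement_bonus=config.achievement_bonus,
                           time_limit=config.time_limit)
        results = screen.fit()
        ranking = results.to_frame()
        null_row = pd.DataFrame([{
            "ts": results.null_score.ts, "rank": 0, "percentile": np.nan,
            "achieved_F_count": len(results.null_score.achieved_F),
            "achieved_B_count": len(results.null_score.achieved_B),
            "steady_deviation": results.null_score.steady_deviation,
            "passes_c1": False, "passes_c2": False,
            "status": results.null_score.status,
        }], index=pd.Index(["null"], name="candidate"))
        pd.concat([null_row, ranking]).to_csv(
            out_dir / "ranking.tsv", sep="\t", float_format="%.10g")

        tick("select")
        selection = results.select(config.top_fraction)
        sel_df = ranking.loc[selection.passing]
        sel_df.to_csv(out_dir / "selection.tsv", sep="\t", float_format="%.10g")
        manifest["selection"] = {
            "n_passing": len(selection.passing),
            "n_criterion1": len(selection.criterion1_pass),
            "n_criterion2": len(selection.criterion2_pass),
            "top_fraction": config.top_fraction,
        }

        if config.reference_genes:
            tick("enrichment")
            gene_map = reaction_gene_map(model)
            universe = sorted(frozenset().union(
                *(gene_map.get(r, frozenset()) for r in candidates), frozenset()))
            predicted = sorted(frozenset().union(
                *(gene_map.get(r, frozenset()) for r in selection.passing),
                frozenset()))
            reference = read_gene_list(config.reference_genes)
            enr = hypergeometric_test(predicted, reference, universe)
            with open(out_dir / "enrichment.json", "w") as fh:
                json.dump(enr.as_dict(), fh, indent=1)

        tick("finalize")
        for name in ("ranking.tsv", "selection.tsv", "source_state.tsv",
                     "imat_source.tsv", "enrichment.json"):
            p = out_dir / name
            if p.exists():
                manifest["outputs"][name] = {"sha256": _sha256(p)}
        manifest["stages"][stage] = round(time.perf_counter() - t_start, 4)
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["diagnostic"] = str(exc)
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        raise PipelineError(stage, str(exc)) from exc
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
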