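"""Synthetic test bed: toy networks with a known causal knockout.

The generator builds a layered network — one shared uptake, several
parallel linear pathways with cross-links between neighbours, one
shared secretion — and two ground-truth flux states:

* the *source* ("disease") state: an LP routes the available uptake
  through the reward-maximal path of the unperturbed network;
* the *target* ("healthy"/protected) state: the same LP re-solved with
  one admissible reaction knocked out, so the knockout **reproduces the
  target state by construction** — exactly the situation a
  transformation screen should recover when run source → target.

Expression matrices for both conditions are tiered by the ground-truth
flux (genes of flux-carrying reactions high, genes of silent reactions
low, decoys in between) plus i.i.d. Gaussian noise, giving the
discretize → consensus → GPR chain realistic two-condition input whose
per-sample ranks support quantile trichotomization.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._optimize import OPTIMAL, solve_lp
from .core import FluxVector, MetabolicModel, candidate_reactions
from .expression import write_expression
from .gpr import parse_gpr
from .io import read_model, write_model

__all__ = [
    "ScenarioConfig",
    "SyntheticScenario",
    "make_toy_network",
    "simulate_reference_flux",
    "simulate_expression",
    "make_scenario",
    "load_scenario",
]

TIER_LOW = 2.0
TIER_MID = 4.0
TIER_HIGH = 6.0
NOISE_SD_DEFAULT = 0.3
DECOY_FRACTION = 0.2
UPTAKE_BOUND = 10.0
INTERNAL_BOUND = 1000.0
ACTIVE_FLUX_THRESHOLD = 1e-3


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions of one synthetic screen."""

    n_parallel_pathways: int = 4
    pathway_length: int = 5
    cross_link_prob: float = 0.9
    n_samples: int = 5            # samples per condition
    noise_sd: float = NOISE_SD_DEFAULT
    epsilon_change: float = 1.0   # minimum flux difference a knockout must cause
    uptake_bound: float = UPTAKE_BOUND


def make_toy_network(n_parallel_pathways: int, pathway_length: int,
                     seed: int, cross_link_prob: float = 0.9,
                     uptake_bound: float = UPTAKE_BOUND) -> MetabolicModel:
    """Layered toy network: uptake → parallel pathways + cross-links → secretion.

    Every internal reaction carries a unique 1–2 gene GPR (AND/OR chosen
    at random); exchanges carry none.  By construction no metabolite is
    a dead end.  Deterministic given the seed.
    """
    if n_parallel_pathways < 2 or pathway_length < 2:
        raise ValueError("need >= 2 pathways of length >= 2")
    rng = np.random.default_rng(seed)
    P, L = n_parallel_pathways, pathway_length
    mets = ["U"] + [f"M{p}_{k}" for p in range(1, P + 1)
                    for k in range(1, L)] + ["W"]
    reactions: list[tuple[str, dict[str, float], float, float, bool]] = []

    def met_of(p: int, k: int) -> str:
        return "U" if k == 0 else ("W" if k == L else f"M{p}_{k}")

    reactions.append(("EX_in", {"U": 1.0}, 0.0, uptake_bound, True))
    for p in range(1, P + 1):
        for k in range(1, L + 1):
            stoich = {met_of(p, k - 1): -1.0, met_of(p, k): 1.0}
            reactions.append((f"P{p}_{k}", stoich, 0.0, INTERNAL_BOUND, False))
    for p in range(1, P):
        for k in range(1, L):
            if rng.random() < cross_link_prob:
                stoich = {f"M{p}_{k}": -1.0, f"M{p + 1}_{k}": 1.0}
                reactions.append((f"C{p}_{k}", stoich, 0.0, INTERNAL_BOUND, False))
    reactions.append(("EX_out", {"W": -1.0}, 0.0, INTERNAL_BOUND, True))

    n = len(reactions)
    S = np.zeros((len(mets), n))
    met_index = {m: i for i, m in enumerate(mets)}
    gpr = {}
    gene_counter = 0
    rxn_ids, lb, ub, exch = [], [], [], []
    for j, (rid, stoich, lo, hi, is_ex) in enumerate(reactions):
        rxn_ids.append(rid)
        lb.append(lo)
        ub.append(hi)
        exch.append(is_ex)
        for m, coef in stoich.items():
            S[met_index[m], j] = coef
        if not is_ex:
            if rng.random() < 0.5:
                rule = f"G{gene_counter}"
                gene_counter += 1
            else:
                op = "and" if rng.random() < 0.5 else "or"
                rule = f"G{gene_counter} {op} G{gene_counter + 1}"
                gene_counter += 2
            gpr[rid] = parse_gpr(rule)
    return MetabolicModel(
        metabolite_ids=mets, reaction_ids=rxn_ids, S=S,
        v_min=np.array(lb), v_max=np.array(ub), gpr=gpr,
        exchange=np.array(exch, dtype=bool),
        name=f"toy_P{P}_L{L}_s{seed}",
    )


def simulate_reference_flux(model: MetabolicModel, knockout: str | None,
                            seed: int) -> FluxVector:
    """Ground-truth flux state: maximize a random positive reward.

    Each internal reaction gets a weight ~ U(0.5, 1.5); the LP pushes
    the bounded uptake through the reward-maximal route (generically a
    unique vertex), optionally with one reaction forced to zero.
    """
    if knockout is not None and knockout not in model.reaction_ids:
        raise KeyError(f"unknown reaction {knockout!r}")
    rng = np.random.default_rng(seed)
    c = np.where(model.exchange, 0.0, -rng.uniform(0.5, 1.5, model.n_reactions))
    lb = model.v_min.copy()
    ub = model.v_max.copy()
    if knockout is not None:
        j = model.reaction_index(knockout)
        lb[j] = ub[j] = 0.0
    res = solve_lp(c, lb, ub, A_eq=model.S,
                   b_eq=np.zeros(model.n_metabolites))
    if res.status != OPTIMAL:
        raise RuntimeError(f"reference flux LP {res.status}")
    return FluxVector.from_array(res.x, model)


def simulate_expression(model: MetabolicModel, v_ref: FluxVector,
                        n_samples: int, noise_sd: float, seed: int,
                        decoy_fraction: float = DECOY_FRACTION,
                        sample_prefix: str = "S") -> pd.DataFrame:
    """Tiered expression coupled to a flux state, plus decoy genes.

    A gene sits at the high tier when some reaction citing it carries
    flux above ``ACTIVE_FLUX_THRESHOLD``, at the low tier when all its
    reactions are silent.  Decoys (absent from the model) sit mid-tier.
    Per-sample values add i.i.d. N(0, noise_sd) noise.
    """
    if n_samples < 3:
        raise ValueError("need >= 3 samples per condition")
    rng = np.random.default_rng(seed)
    gene_rxn: dict[str, list[str]] = {}
    for rid, rule in model.gpr.items():
        for g in rule.genes:
            gene_rxn.setdefault(g, []).append(rid)
    genes = sorted(model.genes)
    base = []
    for g in genes:
        fluxes = [abs(v_ref[r]) for r in gene_rxn.get(g, [])]
        if not fluxes:
            base.append(TIER_MID)
        elif max(fluxes) > ACTIVE_FLUX_THRESHOLD:
            base.append(TIER_HIGH)
        else:
            base.append(TIER_LOW)
    n_decoys = int(np.ceil(decoy_fraction * len(genes)))
    genes = genes + [f"DECOY{i}" for i in range(n_decoys)]
    base = np.array(base + [TIER_MID] * n_decoys)
    values = base[:, None] + rng.normal(0.0, noise_sd, (len(genes), n_samples))
    cols = [f"{sample_prefix}{i + 1}" for i in range(n_samples)]
    return pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=cols)


@dataclass
class SyntheticScenario:
    """A toy network, two-condition expression, and the causal knockout.

    ``v_disease`` is the unperturbed (source) flux state; ``v_healthy``
    is the state after knocking out ``true_knockout`` — the protected
    state the screen should steer toward, so the knockout reproduces
    the target state by construction and carries flux in the source.
    """

    model: MetabolicModel
    disease_expr: pd.DataFrame
    healthy_expr: pd.DataFrame
    true_knockout: str
    v_disease: FluxVector
    v_healthy: FluxVector
    seed: int
    config: ScenarioConfig = field(default_factory=ScenarioConfig)

    def reference_genes(self, threshold: float | None = None) -> list[str]:
        """Genes of reactions silenced by the causal knockout.

        The synthetic analogue of an externally curated predisposition
        list, for exercising the enrichment test.
        """
        thr = threshold if threshold is not None else self.config.epsilon_change
        out: set[str] = set()
        for rid, rule in self.model.gpr.items():
            if abs(self.v_disease[rid]) >= thr and \
                    abs(self.v_healthy[rid]) <= ACTIVE_FLUX_THRESHOLD:
                out.update(rule.genes)
        return sorted(out)

    # -- persistence ----------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_model(self.model, directory / "model.json")
        write_expression(self.disease_expr, directory / "disease_expr.tsv")
        write_expression(self.healthy_expr, directory / "healthy_expr.tsv")
        truth = {
            "true_knockout": self.true_knockout,
            "v_disease": list(self.v_disease.values),
            "v_healthy": list(self.v_healthy.values),
            "seed": self.seed,
            "config": asdict(self.config),
        }
        with open(directory / "ground_truth.json", "w") as fh:
            json.dump(truth, fh, indent=1)


def load_scenario(directory: str | Path) -> SyntheticScenario:
    directory = Path(directory)
    model = read_model(directory / "model.json")
    with open(directory / "ground_truth.json") as fh:
        truth = json.load(fh)
    from .expression import read_expression
    return SyntheticScenario(
        model=model,
        disease_expr=read_expression(directory / "disease_expr.tsv"),
        healthy_expr=read_expression(directory / "healthy_expr.tsv"),
        true_knockout=truth["true_knockout"],
        v_disease=FluxVector.from_array(np.array(truth["v_disease"]), model),
        v_healthy=FluxVector.from_array(np.array(truth["v_healthy"]), model),
        seed=truth["seed"],
        config=ScenarioConfig(**truth["config"]),
    )


def make_scenario(config: ScenarioConfig | None = None,
                  seed: int = 0) -> SyntheticScenario:
    """Build a complete scenario with an admissible causal knockout.

    A knockout is admissible when its reaction carries flux in the
    source state and forcing it to zero changes at least one flux by
    ``config.epsilon_change``.  Topologies without one are regenerated
    (up to 50 attempts).
    """
    cfg = config or ScenarioConfig()
    for attempt in range(50):
        net_seed = seed + 7919 * attempt
        model = make_toy_network(cfg.n_parallel_pathways, cfg.pathway_length,
                                 seed=net_seed,
                                 cross_link_prob=cfg.cross_link_prob,
                                 uptake_bound=cfg.uptake_bound)
        v_base = simulate_reference_flux(model, None, seed=net_seed + 1)
        rng = np.random.default_rng(net_seed + 2)
        admissible = []
        for rid in candidate_reactions(model):
            if abs(v_base[rid]) < cfg.epsilon_change:
                continue
            v_ko = simulate_reference_flux(model, rid, seed=net_seed + 1)
            if np.max(np.abs(v_ko.values - v_base.values)) >= cfg.epsilon_change:
                admissible.append((rid, v_ko))
        if not admissible:
            continue
        true_ko, v_ko = admissible[rng.integers(len(admissible))]
        disease = simulate_expression(model, v_base, cfg.n_samples, cfg.noise_sd,
                                      seed=net_seed + 3, sample_prefix="D")
        healthy = simulate_expression(model, v_ko, cfg.n_samples, cfg.noise_sd,
                                      seed=net_seed + 4, sample_prefix="H")
        return SyntheticScenario(model, disease, healthy, true_ko,
                                 v_base, v_ko, seed, cfg)
    raise RuntimeError("no admissible knockout found in 50 topologies")
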