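"""The metabolic transformation screen (MTA).

Given a *source* flux state (e.g. a disease condition's sampled mean
metabolic state) and expression data for source and *target* conditions,
the screen asks, for every candidate reaction knockout: does forcing
this reaction's flux to zero shift the network from the source state
toward the target state?

Concretely:

1. :func:`derive_change_sets` compares expression between conditions
   (two-sided rank-sum test per gene) and propagates gene verdicts
   through the GPRs into three reaction sets — R_F (flux should
   increase), R_B (should decrease), R_S (should stay unchanged).
2. For each candidate, a MILP fixes ``v_candidate = 0`` and predicts
   the network's response as the *minimal weighted rearrangement* of
   the source state: steady-set L1 deviation is expensive (weight
   1 − α), movement of expression-changed reactions is cheap (weight
   ``gamma``), and binary "achievement" indicators (flux moved ≥ ε
   beyond the source value in the desired direction) carry a tiny bonus
   that breaks ties toward the target.  An unperturbed network has no
   driving force to rearrange, so the null problem's optimum is the
   source state itself; knockouts score by the movement they *force*.
3. The transformation score ``ts`` is the signed ratio of realized flux
   movement among achieved versus unachieved changed reactions to the
   steady-set deviation (floored at one minimal meaningful movement);
   candidates are ranked by it.
4. The dual selection criterion keeps candidates that (1) beat the
   no-perturbation (null) score and (2) sit in the top decile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._optimize import INFEASIBLE, solve_milp
from .core import FluxVector, MetabolicModel, candidate_reactions
from .expression import ReactionStateAssignment  # noqa: F401  (re-export convenience)

__all__ = [
    "ChangeSets",
    "MTAScore",
    "MTAResults",
    "SelectionResult",
    "MTAScreen",
    "derive_change_sets",
    "reaction_gene_map",
    "overlap_across_datasets",
]

ALPHA_WEIGHT_DEFAULT = 0.66
EPS_CHANGE_REL_DEFAULT = 0.1
EPS_CHANGE_FLOOR_DEFAULT = 1.0
# floor = one minimal meaningful movement (rel * floor of a unit-flux reaction)
DELTA_DEFAULT = EPS_CHANGE_REL_DEFAULT * EPS_CHANGE_FLOOR_DEFAULT
GAMMA_DEFAULT = 0.01
ACHIEVEMENT_BONUS_DEFAULT = 1e-6
TOP_FRACTION_DEFAULT = 0.10
NULL_ID = "null"


# ---------------------------------------------------------------------------
# change sets from differential expression
# ---------------------------------------------------------------------------

@dataclass
class ChangeSets:
    """Reaction sets the transformation should move, and how.

    R_F: flux should increase source → target; R_B: decrease;
    R_S: stay unchanged.  ``conflicts`` lists reactions whose GPR mixes
    significantly up- and down-regulated genes (excluded from all
    three).  ``gene_table`` records the per-gene test evidence.
    """

    R_F: frozenset[str]
    R_B: frozenset[str]
    R_S: frozenset[str]
    conflicts: frozenset[str] = frozenset()
    gene_table: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        pairs = [(self.R_F, self.R_B), (self.R_F, self.R_S), (self.R_B, self.R_S)]
        for a, b in pairs:
            if a & b:
                raise ValueError(f"change sets overlap: {sorted(a & b)}")


def derive_change_sets(
    source_expr: pd.DataFrame,
    target_expr: pd.DataFrame,
    model: MetabolicModel,
    alpha: float = 0.05,
    min_samples: int = 3,
) -> ChangeSets:
    """Differential expression (rank-sum) → R_F / R_B / R_S reaction sets.

    Per mapped gene a two-sided Wilcoxon rank-sum test compares the two
    conditions; genes with ``p < alpha`` are "changed" with direction
    ``sign(median(target) − median(source))``, the rest are "constant".
    A reaction joins R_F (R_B) when some rule gene is significantly up
    (down) and none the other way; conflicting reactions are excluded
    and reported; R_S holds reactions all of whose rule genes have data
    and are constant.
    """
    for name, df in (("source", source_expr), ("target", target_expr)):
        if df.shape[1] < min_samples:
            raise ValueError(
                f"{name} condition has {df.shape[1]} samples; need >= {min_samples}")
    genes = [g for g in source_expr.index
             if g in set(target_expr.index) and g in model.genes]
    records = []
    for g in genes:
        x = source_expr.loc[g].to_numpy(dtype=float)
        y = target_expr.loc[g].to_numpy(dtype=float)
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
        diff = float(np.median(y) - np.median(x))
        direction = int(np.sign(diff)) if p < alpha else 0
        records.append((g, p, diff, direction))
    table = pd.DataFrame(records, columns=["gene", "p_value", "median_diff",
                                           "direction"]).set_index("gene")
    verdict = table["direction"].to_dict()

    R_F, R_B, R_S, conflicts = set(), set(), set(), set()
    for rid, rule in model.gpr.items():
        rule_genes = rule.genes
        with_data = [g for g in rule_genes if g in verdict]
        if not with_data:
            continue  # no evidence: unconstrained
        up = any(verdict[g] > 0 for g in with_data)
        down = any(verdict[g] < 0 for g in with_data)
        if up and down:
            conflicts.add(rid)
        elif up:
            R_F.add(rid)
        elif down:
            R_B.add(rid)
        elif len(with_data) == len(rule_genes):
            R_S.add(rid)
        # partially-covered constant rules stay unconstrained
    return ChangeSets(frozenset(R_F), frozenset(R_B), frozenset(R_S),
                      frozenset(conflicts), table)


# ---------------------------------------------------------------------------
# knockout scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MTAScore:
    """One candidate's transformation score and its audit components."""

    candidate: str                 # reaction id, or "null"
    ts: float
    achieved_F: frozenset[str]
    achieved_B: frozenset[str]
    steady_deviation: float
    sum_achieved_dev: float
    sum_unachieved_dev: float
    status: str
    objective: float = math.nan

    @property
    def n_achieved(self) -> int:
        return len(self.achieved_F) + len(self.achieved_B)


class MTAScreen:
    """Score every candidate knockout's ability to shift source → target.

    Parameters
    ----------
    model, v_source
        Network and source-condition metabolic state (typically the
        ACHR mean of the iMAT source flux space).
    change_sets
        Output of :func:`derive_change_sets`.
    candidates
        Reactions to knock out; defaults to
        :func:`fluxshift.core.candidate_reactions` (GPR-bearing,
        non-dead-end).
    alpha_weight
        α ∈ (0, 1); the steady set's deviation is penalised at weight
        1 − α, so larger α makes the response more willing to disturb
        steady reactions when forced.
    epsilon_change_rel, epsilon_change_floor
        Required movement ε_i = rel · max(|v_source_i|, floor).
    delta
        Denominator floor of the transformation score (default: one
        minimal meaningful movement, rel · floor).
    gamma
        Cost of moving expression-changed reactions (≪ 1 − α): forced
        flux prefers rerouting along the desired directions over
        disturbing the steady set.
    achievement_bonus
        Tiny reward on achievement binaries; breaks ties toward the
        target without ever paying for spontaneous movement.
    """

    def __init__(
        self,
        model: MetabolicModel,
        v_source: FluxVector,
        change_sets: ChangeSets,
        candidates: Sequence[str] | None = None,
        alpha_weight: float = ALPHA_WEIGHT_DEFAULT,
        epsilon_change_rel: float = EPS_CHANGE_REL_DEFAULT,
        epsilon_change_floor: float = EPS_CHANGE_FLOOR_DEFAULT,
        delta: float = DELTA_DEFAULT,
        gamma: float = GAMMA_DEFAULT,
        achievement_bonus: float = ACHIEVEMENT_BONUS_DEFAULT,
        time_limit: float = 300.0,
    ):
        if not 0 < alpha_weight < 1:
            raise ValueError("alpha_weight must be in (0, 1)")
        self.model = model
        self.v_source = v_source
        self.change_sets = change_sets
        self.candidates = list(candidates) if candidates is not None \
            else candidate_reactions(model)
        if not self.candidates:
            raise ValueError("candidate list is empty")
        self.alpha_weight = float(alpha_weight)
        self.epsilon_change_rel = float(epsilon_change_rel)
        self.epsilon_change_floor = float(epsilon_change_floor)
        self.delta = float(delta)
        self.gamma = float(gamma)
        self.achievement_bonus = float(achievement_bonus)
        self.time_limit = float(time_limit)
        idx = model.reaction_index
        self._forward = sorted(change_sets.R_F, key=idx)
        self._backward = sorted(change_sets.R_B, key=idx)
        self._steady = sorted(change_sets.R_S, key=idx)

    def epsilon_change(self, rid: str) -> float:
        vs = abs(self.v_source[rid])
        return self.epsilon_change_rel * max(vs, self.epsilon_change_floor)

    # -- single-candidate MILP ------------------------------------------
    def _solve(self, knockouts: tuple[str, ...], label: str | None = None) -> MTAScore:
        model = self.model
        n = model.n_reactions
        vs = self.v_source.values
        lb = model.v_min.copy()
        ub = model.v_max.copy()
        for rid in knockouts:
            j = model.reaction_index(rid)
            lb[j] = ub[j] = 0.0

        changed = self._forward + self._backward
        n_b = len(changed)
        n_d = len(self._steady)
        # columns: v (n) | b (n_b) | d_steady (n_d) | e_changed (n_b)
        n_var = n + n_b + n_d + n_b
        lo = np.concatenate([lb, np.zeros(n_b), np.zeros(n_d), np.zeros(n_b)])
        hi = np.concatenate([ub, np.ones(n_b), np.full(n_d + n_b, np.inf)])
        c = np.zeros(n_var)
        c[n:n + n_b] = -self.achievement_bonus
        c[n + n_b:n + n_b + n_d] = 1.0 - self.alpha_weight
        c[n + n_b + n_d:] = self.gamma
        integrality = np.zeros(n_var)
        integrality[n:n + n_b] = 1

        A_eq = np.zeros((model.n_metabolites, n_var))
        A_eq[:, :n] = model.S
        b_eq = np.zeros(model.n_metabolites)

        rows, rhs = [], []

        def add(coefs: dict[int, float], bound: float) -> None:
            row = np.zeros(n_var)
            for col, val in coefs.items():
                row[col] = val
            rows.append(row)
            rhs.append(bound)

        for k, rid in enumerate(changed):
            j = model.reaction_index(rid)
            bcol = n + k
            ecol = n + n_b + n_d + k
            eps = self.epsilon_change(rid)
            if rid in self.change_sets.R_F:
                t = min(vs[j] + eps, model.v_max[j])  # clipped to bounds
                if t > ub[j] + 1e-12:
                    hi[bcol] = 0.0  # knockout makes the increase unreachable
                else:
                    # b=1 ⇒ v_j ≥ t:  −v_j + (t − lb_j)·b ≤ −lb_j
                    add({j: -1.0, bcol: t - lb[j]}, -lb[j])
            else:
                t = max(vs[j] - eps, model.v_min[j])
                if t < lb[j] - 1e-12:
                    hi[bcol] = 0.0  # knockout makes the decrease unreachable
                else:
                    # b=1 ⇒ v_j ≤ t:  v_j + (ub_j − t)·b ≤ ub_j
                    add({j: 1.0, bcol: ub[j] - t}, ub[j])
            # e ≥ |v_j − vs_j|
            add({j: 1.0, ecol: -1.0}, vs[j])
            add({j: -1.0, ecol: -1.0}, -vs[j])
        for k, rid in enumerate(self._steady):
            j = model.reaction_index(rid)
            dcol = n + n_b + k
            add({j: 1.0, dcol: -1.0}, vs[j])
            add({j: -1.0, dcol: -1.0}, -vs[j])

        A_ub = np.array(rows) if rows else np.zeros((0, n_var))
        b_ub = np.array(rhs)
        res = solve_milp(c, integrality, lo, hi, A_eq, b_eq, A_ub, b_ub,
                         time_limit=self.time_limit)
        cand_id = label if label is not None else \
            (knockouts[0] if knockouts else NULL_ID)
        if res.status == INFEASIBLE or res.x is None:
            return MTAScore(cand_id, -math.inf, frozenset(), frozenset(),
                            math.nan, math.nan, math.nan, status=res.status)
        x = res.x
        v = x[:n]
        achieved_F, achieved_B = set(), set()
        for k, rid in enumerate(changed):
            if round(x[n + k]) == 1:
                (achieved_F if rid in self.change_sets.R_F else achieved_B).add(rid)
        dev = np.abs(v - vs)
        ach = achieved_F | achieved_B
        sum_ach = float(sum(dev[model.reaction_index(r)] for r in ach))
        sum_unach = float(sum(dev[model.reaction_index(r)]
                              for r in changed if r not in ach))
        steady_dev = float(sum(dev[model.reaction_index(r)] for r in self._steady))
        ts = (sum_ach - sum_unach) / max(steady_dev, self.delta)
        return MTAScore(cand_id, ts, frozenset(achieved_F), frozenset(achieved_B),
                        steady_dev, sum_ach, sum_unach, status=res.status,
                        objective=float(-res.fun))

    def score_knockout(self, candidate: str) -> MTAScore:
        if candidate not in self.model.reaction_ids:
            raise KeyError(f"unknown reaction {candidate!r}")
        return self._solve((candidate,))

    def score_null(self) -> MTAScore:
        """Score without any perturbation — the criterion-1 threshold."""
        return self._solve(())

    def reactions_disabled_by_gene(self, gene: str) -> list[str]:
        """Reactions whose GPR evaluates false with ``gene`` absent."""
        if gene not in self.model.genes:
            raise KeyError(f"unknown gene {gene!r}")
        return [rid for rid, rule in self.model.gpr.items()
                if not rule.evaluate_bool({gene: False})]

    def score_gene_knockout(self, gene: str) -> MTAScore:
        """Gene-level knockout: silence every reaction the gene's loss
        disables (an isozyme in an OR rule disables nothing and scores
        at the null)."""
        disabled = tuple(sorted(self.reactions_disabled_by_gene(gene),
                                key=self.model.reaction_index))
        return self._solve(disabled, label=f"gene:{gene}")

    def fit(self) -> "MTAResults":
        """Score the null and every candidate; rank by ts (descending)."""
        null = self.score_null()
        scores = []
        for rid in self.candidates:
            try:
                scores.append(self.score_knockout(rid))
            except Exception as exc:  # pragma: no cover - solver failure path
                scores.append(MTAScore(rid, -math.inf, frozenset(), frozenset(),
                                       math.nan, math.nan, math.nan,
                                       status=f"error: {exc}"))
        scores.sort(key=lambda s: (-s.ts, s.candidate))
        return MTAResults(self, scores, null)


@dataclass
class SelectionResult:
    """Candidates passing the dual selection criterion, in rank order."""

    passing: list[str]
    criterion1_pass: frozenset[str]   # ts > null ts
    criterion2_pass: frozenset[str]   # top decile
    top_fraction: float


@dataclass
class MTAResults:
    """Ranked knockout screen: scores, percentiles, selection."""

    screen: MTAScreen
    scores: list[MTAScore]
    null_score: MTAScore

    def __post_init__(self) -> None:
        n = len(self.scores)
        self.percentile = {s.candidate: 100.0 * (i + 1) / n
                           for i, s in enumerate(self.scores)}

    def rank_of(self, candidate: str) -> int:
        """1-based rank of a candidate (1 = best)."""
        for i, s in enumerate(self.scores):
            if s.candidate == candidate:
                return i + 1
        raise KeyError(candidate)

    def to_frame(self) -> pd.DataFrame:
        sel = self.select()
        rows = []
        for i, s in enumerate(self.scores):
            rows.append({
                "candidate": s.candidate,
                "ts": s.ts,
                "rank": i + 1,
                "percentile": self.percentile[s.candidate],
                "achieved_F_count": len(s.achieved_F),
                "achieved_B_count": len(s.achieved_B),
                "steady_deviation": s.steady_deviation,
                "passes_c1": s.candidate in sel.criterion1_pass,
                "passes_c2": s.candidate in sel.criterion2_pass,
                "status": s.status,
            })
        return pd.DataFrame(rows).set_index("candidate")

    def select(self, top_fraction: float = TOP_FRACTION_DEFAULT) -> SelectionResult:
        """Dual criterion: ts above the null score AND in the top decile."""
        if not 0 < top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        n_top = int(math.floor(top_fraction * len(self.scores)))
        c2 = frozenset(s.candidate for s in self.scores[:n_top])
        c1 = frozenset(s.candidate for s in self.scores
                       if s.ts > self.null_score.ts)
        passing = [s.candidate for s in self.scores
                   if s.candidate in c1 and s.candidate in c2]
        return SelectionResult(passing, c1, c2, top_fraction)

    def summary(self) -> str:
        sel = self.select()
        best = self.scores[0]
        lines = [
            "MTA knockout screen",
            "=" * 44,
            f"candidates screened:     {len(self.scores)}",
            f"R_F / R_B / R_S sizes:   {len(self.screen.change_sets.R_F)} / "
            f"{len(self.screen.change_sets.R_B)} / {len(self.screen.change_sets.R_S)}",
            f"null score (ts):         {self.null_score.ts:.6g}",
            f"best candidate:          {best.candidate} (ts = {best.ts:.6g})",
            f"beat the null score:     {len(sel.criterion1_pass)}",
            f"top-decile size:         {len(sel.criterion2_pass)}",
            f"passing dual criterion:  {len(sel.passing)}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# cross-dataset overlap
# ---------------------------------------------------------------------------

def reaction_gene_map(model: MetabolicModel) -> dict[str, frozenset[str]]:
    return {rid: rule.genes for rid, rule in model.gpr.items()}


def overlap_across_datasets(
    selections: Mapping[str, SelectionResult | Iterable[str]],
    gene_map: Mapping[str, Iterable[str]],
) -> dict:
    """Gene-level Venn table across datasets' selected reactions.

    Each dataset's selected reactions are translated to the union of
    their GPR genes; the table reports, for every nonempty dataset
    subset, the number of genes exclusive to exactly that subset, plus
    the membership of the full intersection.
    """
    if len(selections) < 2:
        raise ValueError("need at least two datasets to intersect")
    gene_sets: dict[str, frozenset[str]] = {}
    for name, sel in selections.items():
        rids = sel.passing if isinstance(sel, SelectionResult) else list(sel)
        gene_sets[name] = frozenset().union(
            *(frozenset(gene_map.get(r, ())) for r in rids), frozenset())
    names = sorted(gene_sets)
    membership: dict[str, tuple[str, ...]] = {}
    for g in frozenset().union(*gene_sets.values(), frozenset()):
        membership[g] = tuple(nm for nm in names if g in gene_sets[nm])
    exclusive: dict[tuple[str, ...], int] = {}
    for subset in membership.values():
        exclusive[subset] = exclusive.get(subset, 0) + 1
    full = frozenset(g for g, subset in membership.items()
                     if len(subset) == len(names))
    return {
        "gene_sets": gene_sets,
        "exclusive_counts": exclusive,
        "full_intersection": full,
        "full_intersection_count": len(full),
    }
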