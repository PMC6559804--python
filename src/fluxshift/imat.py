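"""iMAT: integrate expression states into a steady-state flux space.

Given reaction states from expression data — RH reactions expected to
carry flux, RL reactions expected to be silent — iMAT solves a mixed
integer linear program over the feasible flux space:

    max   Σ_{i∈RH} (y⁺ᵢ + y⁻ᵢ)  +  Σ_{i∈RL} zᵢ
    s.t.  S·v = 0,  v_min ≤ v ≤ v_max
          y⁺ᵢ = 1 ⇒ vᵢ ≥ ε_active        (forward activation)
          y⁻ᵢ = 1 ⇒ vᵢ ≤ −ε_active       (backward activation, reversible)
          zᵢ  = 1 ⇒ |vᵢ| ≤ ε_zero        (silencing)
          y⁺ᵢ + y⁻ᵢ ≤ 1

i.e. it finds a feasible flux distribution maximizing the number of
reactions whose activity is consistent with their expression.  The
implications are encoded with per-reaction big-M coefficients sized from
that reaction's own bounds, so the relaxation is as tight as the bounds
allow.

Freezing the binaries at their optimal values turns the mixed-integer
feasible set into a convex polytope — the expression-consistent flux
space that is then explored by ACHR sampling.

Usage follows the model/results convention::

    res = IMAT(model, assignment).fit()
    res.objective        # number of expression-consistent reactions
    poly = res.activity_polytope()
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._optimize import INFEASIBLE, OPTIMAL, TIME_LIMIT, solve_lp, solve_milp
from .core import FluxVector, MetabolicModel, check_steady_state
from .expression import ReactionStateAssignment
from .sampling import Polytope

__all__ = ["IMAT", "IMATResults", "ConfigurationError"]

EPS_ACTIVE_DEFAULT = 1.0
EPS_ZERO_DEFAULT = 1e-4
TIME_LIMIT_DEFAULT = 300.0

ACTIVE_FWD = "active_forward"
ACTIVE_BWD = "active_backward"
INACTIVE = "inactive"
UNCONSTRAINED = "unconstrained"


class ConfigurationError(ValueError):
    """Parameters incompatible with the model's bounds."""


class IMAT:
    """The iMAT optimization for one condition.

    Parameters
    ----------
    model
        The metabolic network.
    assignment
        Per-reaction expression states; ``RH`` (+1) and ``RL`` (−1)
        drive the objective.
    epsilon_active
        Minimum |flux| for a reaction to count as active (flux units;
        default 1.0 with the conventional ±1000 bounds).
    epsilon_zero
        Maximum |flux| for a reaction to count as silenced.
    time_limit
        Branch-and-bound wall-clock limit in seconds.
    """

    def __init__(self, model: MetabolicModel, assignment: ReactionStateAssignment,
                 epsilon_active: float = EPS_ACTIVE_DEFAULT,
                 epsilon_zero: float = EPS_ZERO_DEFAULT,
                 time_limit: float = TIME_LIMIT_DEFAULT):
        if epsilon_active <= 0:
            raise ConfigurationError("epsilon_active must be > 0")
        self.model = model
        self.assignment = assignment
        self.epsilon_active = float(epsilon_active)
        self.epsilon_zero = float(epsilon_zero)
        self.time_limit = float(time_limit)
        self.RH = sorted(assignment.RH, key=model.reaction_index)
        self.RL = sorted(assignment.RL, key=model.reaction_index)
        for rid in self.RH:
            j = model.reaction_index(rid)
            reach = max(abs(model.v_min[j]), model.v_max[j])
            if epsilon_active > reach:
                raise ConfigurationError(
                    f"epsilon_active={epsilon_active} exceeds the attainable "
                    f"|flux| {reach} of RH reaction {rid!r}")

    # -- MILP assembly --------------------------------------------------
    def _build(self):
        model, eps, epz = self.model, self.epsilon_active, self.epsilon_zero
        n = model.n_reactions
        lb = list(model.v_min)
        ub = list(model.v_max)
        c = [0.0] * n
        integrality = [0] * n
        rows, row_lb, row_ub = [], [], []
        binaries: list[tuple[str, str, int]] = []  # (rid, kind, column)

        def new_binary(rid: str, kind: str) -> int:
            col = len(lb)
            lb.append(0.0)
            ub.append(1.0)
            c.append(-1.0)  # maximize Σ binaries
            integrality.append(1)
            binaries.append((rid, kind, col))
            return col

        def add_row(coefs: dict[int, float], lo: float, hi: float) -> None:
            rows.append(coefs)
            row_lb.append(lo)
            row_ub.append(hi)

        for rid in self.RH:
            j = model.reaction_index(rid)
            cols = []
            if model.v_max[j] >= eps:
                yp = new_binary(rid, "y+")
                cols.append(yp)
                # y+=1 ⇒ v_j ≥ eps:  v_j + (v_min_j − eps)·y+ ≥ v_min_j
                add_row({j: 1.0, yp: model.v_min[j] - eps}, model.v_min[j], np.inf)
            if model.v_min[j] <= -eps:
                ym = new_binary(rid, "y-")
                cols.append(ym)
                # y−=1 ⇒ v_j ≤ −eps:  v_j + (v_max_j + eps)·y− ≤ v_max_j
                add_row({j: 1.0, ym: model.v_max[j] + eps}, -np.inf, model.v_max[j])
            if len(cols) == 2:
                add_row({cols[0]: 1.0, cols[1]: 1.0}, -np.inf, 1.0)
        for rid in self.RL:
            j = model.reaction_index(rid)
            z = new_binary(rid, "z")
            # z=1 ⇒ v_j ≤ eps_zero and v_j ≥ −eps_zero
            add_row({j: 1.0, z: model.v_max[j] - epz}, -np.inf, model.v_max[j])
            add_row({j: 1.0, z: model.v_min[j] + epz}, model.v_min[j], np.inf)

        n_var = len(lb)
        A_eq = np.zeros((model.n_metabolites, n_var))
        A_eq[:, :n] = model.S
        b_eq = np.zeros(model.n_metabolites)
        # split two-sided rows into ≤ rows
        A_ub, b_ub = [], []
        for coefs, lo, hi in zip(rows, row_lb, row_ub):
            row = np.zeros(n_var)
            for col, val in coefs.items():
                row[col] = val
            if np.isfinite(hi):
                A_ub.append(row)
                b_ub.append(hi)
            if np.isfinite(lo):
                A_ub.append(-row)
                b_ub.append(-lo)
        A_ub = np.array(A_ub) if A_ub else np.zeros((0, n_var))
        b_ub = np.array(b_ub)
        return (np.array(c), np.array(integrality), np.array(lb), np.array(ub),
                A_eq, b_eq, A_ub, b_ub, binaries)

    # -- fitting --------------------------------------------------------
    def fit(self) -> "IMATResults":
        """Solve the MILP and return the optimal activity assignment."""
        c, integrality, lb, ub, A_eq, b_eq, A_ub, b_ub, binaries = self._build()
        res = solve_milp(c, integrality, lb, ub, A_eq, b_eq, A_ub, b_ub,
                         time_limit=self.time_limit)
        model = self.model
        if res.status == INFEASIBLE or res.x is None:
            diagnostic = self._diagnose_infeasibility()
            return IMATResults(self, status=INFEASIBLE, v=None, objective=0,
                               indicators={}, diagnostic=diagnostic)
        x = res.x
        v = FluxVector.from_array(x[:model.n_reactions], model)
        indicators: dict[str, str] = {}
        binary_values: dict[str, dict[str, int]] = {}
        for rid, kind, col in binaries:
            binary_values.setdefault(rid, {})[kind] = int(round(x[col]))
        for rid in self.RH:
            b = binary_values.get(rid, {})
            if b.get("y+"):
                indicators[rid] = ACTIVE_FWD
            elif b.get("y-"):
                indicators[rid] = ACTIVE_BWD
            else:
                indicators[rid] = UNCONSTRAINED
        for rid in self.RL:
            indicators[rid] = INACTIVE if binary_values[rid].get("z") else UNCONSTRAINED
        objective = int(round(-res.fun)) if res.fun is not None else 0
        status = OPTIMAL if res.status == OPTIMAL else TIME_LIMIT
        return IMATResults(self, status=status, v=v, objective=objective,
                           indicators=indicators, binary_values=binary_values)

    def _diagnose_infeasibility(self) -> str:
        """Name a metabolite whose mass balance cannot be satisfied."""
        model = self.model
        m, n = model.n_metabolites, model.n_reactions
        # elastic LP: S·v + s⁺ − s⁻ = 0, minimize Σ(s⁺+s⁻)
        lb = np.concatenate([model.v_min, np.zeros(2 * m)])
        ub = np.concatenate([model.v_max, np.full(2 * m, np.inf)])
        A_eq = np.hstack([model.S, np.eye(m), -np.eye(m)])
        c = np.concatenate([np.zeros(n), np.ones(2 * m)])
        res = solve_lp(c, lb, ub, A_eq=A_eq, b_eq=np.zeros(m))
        if res.status == OPTIMAL and res.fun is not None and res.fun > 1e-9:
            slack = res.x[n:n + m] + res.x[n + m:]
            worst = int(np.argmax(slack))
            return (f"no steady-state flux exists; metabolite "
                    f"{model.metabolite_ids[worst]!r} cannot be balanced")
        return "MILP infeasible"


@dataclass
class IMATResults:
    """Optimal expression-consistent flux distribution and activity calls."""

    problem: IMAT
    status: str
    v: FluxVector | None
    objective: int
    indicators: dict[str, str]
    binary_values: dict[str, dict[str, int]] = field(default_factory=dict)
    diagnostic: str | None = None

    @property
    def model(self) -> MetabolicModel:
        return self.problem.model

    def consistency_count(self, tol: float = 1e-6) -> int:
        """Recount consistent reactions directly from the flux vector."""
        if self.v is None:
            return 0
        eps = self.problem.epsilon_active
        epz = self.problem.epsilon_zero
        count = sum(1 for rid in self.problem.RH
                    if abs(self.v[rid]) >= eps - tol)
        count += sum(1 for rid in self.problem.RL
                     if abs(self.v[rid]) <= epz + tol)
        return count

    def activity_polytope(self) -> Polytope:
        """Freeze the optimal binaries into hard linear constraints.

        Activated RH reactions keep |v| ≥ ε_active (as a tightened
        bound), silenced RL reactions keep |v| ≤ ε_zero; unsatisfied
        indicators impose nothing.  The optimum ``v`` is a member.
        """
        if self.status != OPTIMAL:
            raise ValueError("activity polytope requires an optimal solution")
        model = self.model
        lb = model.v_min.copy()
        ub = model.v_max.copy()
        eps, epz = self.problem.epsilon_active, self.problem.epsilon_zero
        for rid, outcome in self.indicators.items():
            j = model.reaction_index(rid)
            if outcome == ACTIVE_FWD:
                lb[j] = max(lb[j], eps)
            elif outcome == ACTIVE_BWD:
                ub[j] = min(ub[j], -eps)
            elif outcome == INACTIVE:
                lb[j] = max(lb[j], -epz)
                ub[j] = min(ub[j], epz)
        return Polytope(lb=lb, ub=ub, A_eq=model.S.copy(),
                        b_eq=np.zeros(model.n_metabolites),
                        reaction_ids=tuple(model.reaction_ids))

    def to_frame(self) -> pd.DataFrame:
        """Per-reaction table: flux, expression state, activity outcome."""
        model = self.model
        flux = self.v.values if self.v is not None else np.full(model.n_reactions, np.nan)
        return pd.DataFrame({
            "reaction_id": model.reaction_ids,
            "flux": flux,
            "state": [self.problem.assignment.states.get(r, 0)
                      for r in model.reaction_ids],
            "indicator": [self.indicators.get(r, "") for r in model.reaction_ids],
        }).set_index("reaction_id")

    def summary(self) -> str:
        lines = [
            "iMAT results",
            "=" * 40,
            f"status:                {self.status}",
            f"reactions:             {self.model.n_reactions}",
            f"RH (expect active):    {len(self.problem.RH)}",
            f"RL (expect silent):    {len(self.problem.RL)}",
            f"consistent reactions:  {self.objective}",
            f"epsilon_active:        {self.problem.epsilon_active}",
            f"epsilon_zero:          {self.problem.epsilon_zero}",
        ]
        if self.v is not None:
            ok = check_steady_state(self.model, self.v)
            lines.append(f"steady state (1e-6):   {'yes' if ok else 'NO'}")
        if self.diagnostic:
            lines.append(f"diagnostic:            {self.diagnostic}")
        return "\n".join(lines)
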