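"""Thin wrappers around scipy's HiGHS LP/MILP interfaces.

All linear and mixed-integer programs in the package funnel through
these two calls so that solver options, status mapping and determinism
live in one place.  HiGHS is deterministic for a fixed problem, which
the pipeline's reproducibility contract relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

__all__ = ["OptResult", "solve_lp", "solve_milp"]

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
TIME_LIMIT = "time_limit"
UNBOUNDED = "unbounded"


@dataclass(frozen=True)
class OptResult:
    status: str
    x: np.ndarray | None
    fun: float | None


def _constraints(A_eq, b_eq, A_ub, b_ub):
    cons = []
    if A_eq is not None and A_eq.shape[0]:
        b_eq = np.asarray(b_eq, dtype=float)
        cons.append(LinearConstraint(sparse.csr_matrix(A_eq), b_eq, b_eq))
    if A_ub is not None and A_ub.shape[0]:
        b_ub = np.asarray(b_ub, dtype=float)
        cons.append(LinearConstraint(sparse.csr_matrix(A_ub), -np.inf, b_ub))
    return cons


def solve_lp(c, lb, ub, A_eq=None, b_eq=None, A_ub=None, b_ub=None) -> OptResult:
    """Minimize c·x subject to bounds and linear constraints."""
    res = linprog(
        np.asarray(c, dtype=float),
        A_ub=sparse.csr_matrix(A_ub) if A_ub is not None and A_ub.shape[0] else None,
        b_ub=np.asarray(b_ub, dtype=float) if b_ub is not None and len(b_ub) else None,
        A_eq=sparse.csr_matrix(A_eq) if A_eq is not None and A_eq.shape[0] else None,
        b_eq=np.asarray(b_eq, dtype=float) if b_eq is not None and len(b_eq) else None,
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    status = {0: OPTIMAL, 1: TIME_LIMIT, 2: INFEASIBLE, 3: UNBOUNDED}.get(res.status, INFEASIBLE)
    return OptResult(status, res.x if res.x is not None else None,
                     float(res.fun) if res.fun is not None else None)


def solve_milp(c, integrality, lb, ub, A_eq=None, b_eq=None, A_ub=None, b_ub=None,
               time_limit: float | None = None) -> OptResult:
    """Minimize c·x with integrality flags (1 = integer variable)."""
    options = {}
    if time_limit is not None:
        options["time_limit"] = float(time_limit)
    res = milp(
        np.asarray(c, dtype=float),
        integrality=np.asarray(integrality),
        bounds=Bounds(np.asarray(lb, dtype=float), np.asarray(ub, dtype=float)),
        constraints=_constraints(A_eq, b_eq, A_ub, b_ub),
        options=options,
    )
    status = {0: OPTIMAL, 1: TIME_LIMIT, 2: INFEASIBLE, 3: UNBOUNDED,
              4: INFEASIBLE}.get(res.status, INFEASIBLE)
    # scipy returns status 1 for both iteration and time limits
    return OptResult(status, res.x if res.x is not None else None,
                     float(res.fun) if res.fun is not None else None)
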