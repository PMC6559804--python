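"""Independent oracles shared by unit and acceptance tests.

Everything here deliberately avoids the package's own solution paths:
dead-end pruning by exhaustive set re-scanning, iMAT optima by
enumerating activity patterns and testing LP feasibility of each, and
hypergeometric tails by enumerating draws.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
from scipy.optimize import linprog

from fluxshift.core import MetabolicModel


def dead_ends_by_rescan(model: MetabolicModel) -> set[str]:
    """Dead-end reactions via naive repeated re-scanning over id sets."""
    stoich: dict[str, set[str]] = {m: set() for m in model.metabolite_ids}
    for j, rid in enumerate(model.reaction_ids):
        for i, mid in enumerate(model.metabolite_ids):
            if model.S[i, j] != 0:
                stoich[mid].add(rid)
    removed: set[str] = set()
    while True:
        flagged = [m for m, rxns in stoich.items()
                   if 0 < len(rxns - removed) < 2]
        newly = set()
        for m in flagged:
            newly |= stoich[m] - removed
        if not newly:
            return removed
        removed |= newly


def imat_optimum_by_enumeration(model: MetabolicModel, RH: list[str],
                                RL: list[str], eps_active: float = 1.0,
                                eps_zero: float = 1e-4) -> int:
    """Maximum satisfiable expression-consistency count, by brute force.

    Every activity pattern (each RH reaction forward-active,
    backward-active or unconstrained; each RL reaction silenced or
    unconstrained) becomes a set of hard bounds whose LP feasibility is
    tested; the best feasible satisfied-count is returned.  Patterns
    are visited in decreasing count so the search can stop early.
    """
    options = []
    for rid in RH:
        j = model.reaction_index(rid)
        opts = [("skip", j)]
        if model.v_max[j] >= eps_active:
            opts.append(("fwd", j))
        if model.v_min[j] <= -eps_active:
            opts.append(("bwd", j))
        options.append(opts)
    for rid in RL:
        j = model.reaction_index(rid)
        options.append([("skip", j), ("zero", j)])

    def feasible(pattern) -> bool:
        lb = model.v_min.copy()
        ub = model.v_max.copy()
        for kind, j in pattern:
            if kind == "fwd":
                lb[j] = max(lb[j], eps_active)
            elif kind == "bwd":
                ub[j] = min(ub[j], -eps_active)
            elif kind == "zero":
                lb[j] = max(lb[j], -eps_zero)
                ub[j] = min(ub[j], eps_zero)
        if np.any(lb > ub):
            return False
        res = linprog(np.zeros(model.n_reactions), A_eq=model.S,
                      b_eq=np.zeros(model.n_metabolites),
                      bounds=np.column_stack([lb, ub]), method="highs")
        return res.status == 0

    patterns = sorted(
        itertools.product(*options),
        key=lambda p: -sum(1 for kind, _ in p if kind != "skip"))
    for pattern in patterns:
        if feasible(pattern):
            return sum(1 for kind, _ in pattern if kind != "skip")
    return 0  # v = 0 is always feasible when 0 is within bounds


def random_imat_instance(rng: np.random.Generator, max_reactions: int = 20,
                         max_flagged: int = 8):
    """A random bounded toy network plus disjoint RH/RL sets."""
    from fluxshift.gpr import parse_gpr

    m = int(rng.integers(3, 7))
    n = int(rng.integers(6, max_reactions + 1))
    while True:
        S = np.zeros((m, n))
        for j in range(n):
            k = int(rng.integers(1, 3))
            mets = rng.choice(m, size=k, replace=False)
            S[mets, j] = rng.choice([-1.0, 1.0], size=k)
        if np.all(np.any(S != 0, axis=1)):
            break
    reversible = rng.random(n) < 0.4
    v_min = np.where(reversible, -10.0, 0.0)
    v_max = np.full(n, 10.0)
    rids = [f"R{j}" for j in range(n)]
    model = MetabolicModel(
        metabolite_ids=[f"M{i}" for i in range(m)], reaction_ids=rids,
        S=S, v_min=v_min, v_max=v_max,
        gpr={r: parse_gpr(f"g_{r}") for r in rids},
    )
    n_flag = int(rng.integers(2, max_flagged + 1))
    flagged = list(rng.choice(rids, size=min(n_flag, n), replace=False))
    split = int(rng.integers(0, len(flagged) + 1))
    return model, flagged[:split], flagged[split:]


def hypergeom_tail_by_enumeration(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by counting draws: sum over j >= k of C(K,j)C(N-K,n-j)/C(N,n)."""
    total = comb(N, n)
    count = sum(comb(K, j) * comb(N - K, n - j)
                for j in range(k, min(n, K) + 1))
    return count / total
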