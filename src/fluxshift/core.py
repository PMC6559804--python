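"""Stoichiometric metabolic network model and structural filters.

The central object is :class:`MetabolicModel`: a stoichiometric matrix S
(metabolites × reactions), flux bounds, GPR rules, and exchange flags.
Steady-state mass balance S·v = 0 together with v_min ≤ v ≤ v_max defines
the feasible flux space; every downstream computation (iMAT, sampling,
the knockout screen) operates inside it.

Also here: the topological dead-end filter and the knockout candidate
set (GPR-bearing, non-dead-end reactions), which define which reactions
a transformation screen may perturb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gpr import GPR

__all__ = [
    "ModelValidationError",
    "DimensionError",
    "MetabolicModel",
    "FluxVector",
    "find_dead_end_reactions",
    "candidate_reactions",
    "check_steady_state",
]

TOL_STEADY = 1e-6
TOL_BOUND = 1e-9


class ModelValidationError(ValueError):
    """A model violates a structural invariant."""


class DimensionError(ValueError):
    """A vector's length does not match the model."""


@dataclass
class MetabolicModel:
    """A constraint-based metabolic network.

    Parameters
    ----------
    metabolite_ids, reaction_ids
        Unique string identifiers; their order fixes the row/column order
        of ``S`` and of every flux vector.
    S
        Stoichiometric matrix, metabolites × reactions.  ``S[i, j]`` is
        the coefficient of metabolite i in reaction j (negative =
        consumed, positive = produced).
    v_min, v_max
        Flux bounds per reaction (arbitrary flux units; a reversible
        reaction has ``v_min < 0``).
    gpr
        Reaction id → parsed GPR rule.  Reactions without a rule are
        simply absent from the mapping.
    genes
        All gene symbols of the model.  Defaults to the union of GPR
        genes.
    exchange
        Boolean array flagging boundary/exchange reactions (metabolite
        uptake or secretion across the system boundary).
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray
    v_min: np.ndarray
    v_max: np.ndarray
    gpr: dict[str, GPR] = field(default_factory=dict)
    genes: frozenset[str] = None  # type: ignore[assignment]
    exchange: np.ndarray = None  # type: ignore[assignment]
    name: str = "model"

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.v_min = np.asarray(self.v_min, dtype=float)
        self.v_max = np.asarray(self.v_max, dtype=float)
        if self.exchange is None:
            self.exchange = np.zeros(self.n_reactions, dtype=bool)
        else:
            self.exchange = np.asarray(self.exchange, dtype=bool)
        if self.genes is None:
            self.genes = frozenset().union(*(g.genes for g in self.gpr.values())) \
                if self.gpr else frozenset()
        else:
            self.genes = frozenset(self.genes)
        self.validate()

    # -- basic geometry -------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def reaction_index(self, rid: str) -> int:
        try:
            return self._rxn_index[rid]
        except AttributeError:
            self._rxn_index = {r: j for j, r in enumerate(self.reaction_ids)}
            return self._rxn_index[rid]

    def validate(self) -> None:
        m, n = self.S.shape
        if m != self.n_metabolites:
            raise ModelValidationError(
                f"S has {m} rows but {self.n_metabolites} metabolite ids")
        if n != self.n_reactions:
            raise ModelValidationError(
                f"S has {n} columns but {self.n_reactions} reaction ids")
        for name, ids in (("metabolite", self.metabolite_ids),
                          ("reaction", self.reaction_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({x for x in ids if ids.count(x) > 1})
                raise ModelValidationError(f"duplicate {name} ids: {dupes}")
        if self.v_min.shape != (n,) or self.v_max.shape != (n,):
            raise ModelValidationError("bound vectors must have length n_reactions")
        if np.any(self.v_min > self.v_max):
            bad = [self.reaction_ids[j] for j in np.nonzero(self.v_min > self.v_max)[0]]
            raise ModelValidationError(f"v_min > v_max for reactions {bad}")
        if self.exchange.shape != (n,):
            raise ModelValidationError("exchange flags must have length n_reactions")
        unknown_rxn = set(self.gpr) - set(self.reaction_ids)
        if unknown_rxn:
            raise ModelValidationError(f"GPR rules for unknown reactions {sorted(unknown_rxn)}")
        undeclared = sorted(
            frozenset().union(*(g.genes for g in self.gpr.values()), frozenset())
            - self.genes)
        if undeclared:
            raise ModelValidationError(
                f"GPR rules reference undeclared genes: {undeclared}")

    def has_gpr(self, rid: str) -> bool:
        return rid in self.gpr

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
            S=self.S.copy(),
            v_min=self.v_min.copy(),
            v_max=self.v_max.copy(),
            gpr=dict(self.gpr),
            genes=self.genes,
            exchange=self.exchange.copy(),
            name=self.name,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetabolicModel):
            return NotImplemented
        return (self.metabolite_ids == other.metabolite_ids
                and self.reaction_ids == other.reaction_ids
                and np.array_equal(self.S, other.S)
                and np.array_equal(self.v_min, other.v_min)
                and np.array_equal(self.v_max, other.v_max)
                and self.gpr == other.gpr
                and self.genes == other.genes
                and np.array_equal(self.exchange, other.exchange))


@dataclass(frozen=True)
class FluxVector:
    """A flux assignment, indexed identically to ``model.reaction_ids``."""

    values: np.ndarray
    reaction_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "reaction_ids", tuple(self.reaction_ids))
        if self.values.shape != (len(self.reaction_ids),):
            raise DimensionError(
                f"flux vector length {self.values.shape} does not match "
                f"{len(self.reaction_ids)} reaction ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("flux vector has non-finite entries")

    @classmethod
    def from_array(cls, values: np.ndarray, model: MetabolicModel) -> "FluxVector":
        return cls(np.asarray(values, dtype=float), tuple(model.reaction_ids))

    def __getitem__(self, rid: str) -> float:
        return float(self.values[self.reaction_ids.index(rid)])

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.reaction_ids), name="flux")


def check_steady_state(model: MetabolicModel, v: FluxVector | np.ndarray,
                       tol: float = TOL_STEADY,
                       tol_bound: float = TOL_BOUND) -> bool:
    """True iff ``v`` is mass-balanced (‖S·v‖_∞ ≤ tol) and within bounds.

    Mass balance says every metabolite is produced exactly as fast as it
    is consumed — the steady-state assumption of constraint-based
    modeling.
    """
    vals = v.values if isinstance(v, FluxVector) else np.asarray(v, dtype=float)
    if vals.shape != (model.n_reactions,):
        raise DimensionError(
            f"flux vector length {vals.shape[0] if vals.ndim else 0} "
            f"!= n_reactions {model.n_reactions}")
    if np.max(np.abs(model.S @ vals), initial=0.0) > tol:
        return False
    return bool(np.all(vals >= model.v_min - tol_bound)
                and np.all(vals <= model.v_max + tol_bound))


def find_dead_end_reactions(model: MetabolicModel) -> set[str]:
    """Reactions removed by iterative dead-end metabolite pruning.

    A metabolite touched (nonzero stoichiometry) by fewer than two
    remaining reactions cannot be both produced and consumed at steady
    state; every reaction touching it is removed, and pruning repeats
    until a fixed point.  The result is order-independent: a reaction is
    removed in some order iff it is removed in every order.
    """
    touch = model.S != 0  # m × n incidence
    alive = np.ones(model.n_reactions, dtype=bool)
    changed = True
    while changed:
        changed = False
        counts = touch[:, alive].sum(axis=1)
        # metabolites touched by exactly one remaining reaction
        for i in np.nonzero(counts == 1)[0]:
            rxns = np.nonzero(touch[i] & alive)[0]
            if rxns.size:
                alive[rxns] = False
                changed = True
    return {model.reaction_ids[j] for j in np.nonzero(~alive)[0]}


def candidate_reactions(model: MetabolicModel) -> list[str]:
    """Knockout-screen candidates: GPR-bearing, non-dead-end reactions.

    Dead-end reactions cannot carry steady-state flux, and reactions not
    mapped to genes (exchanges, artificial reactions) cannot be targeted
    through a gene product; both are excluded.  Order follows
    ``reaction_ids``.
    """
    dead = find_dead_end_reactions(model)
    return [r for r in model.reaction_ids
            if r not in dead and model.has_gpr(r) and
            not model.exchange[model.reaction_index(r)]]
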