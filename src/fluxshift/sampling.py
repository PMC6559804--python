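"""Artificially-centered hit-and-run (ACHR) sampling of a flux polytope.

A condition's "metabolic state" is summarised as the coordinate-wise
mean of a few thousand flux vectors sampled from the feasible space that
iMAT leaves after fixing reaction activities (default 2000 samples).
ACHR is a hit-and-run Markov chain whose proposal directions point from
a randomly chosen previous point toward/away from the running sample
center, which adapts the step geometry to elongated flux polytopes.

Equality constraints (mass balance) are honoured by projecting every
direction onto the null space of ``A_eq``, computed once per polytope,
so chains never leave the steady-state subspace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space

from ._optimize import OPTIMAL, solve_lp

__all__ = [
    "Polytope",
    "FluxSampleSet",
    "warmup_points",
    "achr_sample",
    "mean_metabolic_state",
    "effective_sample_size",
]

FEAS_TOL = 1e-6
WARMUP_MIN = 100
THINNING_DEFAULT = 10
N_SAMPLES_DEFAULT = 2000


class EmptyPolytopeError(RuntimeError):
    """No feasible point exists."""


@dataclass(frozen=True)
class Polytope:
    """A bounded convex polytope {v : A_eq·v = b_eq, A_ub·v ≤ b_ub, lb ≤ v ≤ ub}."""

    lb: np.ndarray
    ub: np.ndarray
    A_eq: np.ndarray | None = None
    b_eq: np.ndarray | None = None
    A_ub: np.ndarray | None = None
    b_ub: np.ndarray | None = None
    reaction_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "lb", np.asarray(self.lb, dtype=float))
        object.__setattr__(self, "ub", np.asarray(self.ub, dtype=float))
        if self.A_eq is not None:
            object.__setattr__(self, "A_eq", np.asarray(self.A_eq, dtype=float))
            object.__setattr__(self, "b_eq", np.asarray(self.b_eq, dtype=float))
        if self.A_ub is not None:
            object.__setattr__(self, "A_ub", np.asarray(self.A_ub, dtype=float))
            object.__setattr__(self, "b_ub", np.asarray(self.b_ub, dtype=float))
        if np.any(self.lb > self.ub):
            raise ValueError("lb > ub in polytope bounds")
        if not (np.all(np.isfinite(self.lb)) and np.all(np.isfinite(self.ub))):
            raise ValueError("polytope must be bounded in every coordinate")

    @property
    def dim(self) -> int:
        return len(self.lb)

    def contains(self, v: np.ndarray, tol: float = FEAS_TOL) -> bool:
        v = np.asarray(v, dtype=float)
        if np.any(v < self.lb - tol) or np.any(v > self.ub + tol):
            return False
        if self.A_eq is not None and self.A_eq.shape[0]:
            if np.max(np.abs(self.A_eq @ v - self.b_eq), initial=0.0) > tol:
                return False
        if self.A_ub is not None and self.A_ub.shape[0]:
            if np.max(self.A_ub @ v - self.b_ub, initial=-np.inf) > tol:
                return False
        return True

    def _solve(self, c: np.ndarray):
        return solve_lp(c, self.lb, self.ub, self.A_eq, self.b_eq,
                        self.A_ub, self.b_ub)

    def feasible_point(self) -> np.ndarray:
        res = self._solve(np.zeros(self.dim))
        if res.status != OPTIMAL:
            raise EmptyPolytopeError("polytope is empty (feasibility LP failed)")
        return res.x


@dataclass(frozen=True)
class FluxSampleSet:
    """K sampled flux vectors plus the chain's provenance metadata."""

    samples: np.ndarray  # K × n
    seed: int | None
    thinning: int
    n_warmup: int
    reaction_ids: tuple[str, ...] | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def mean(self) -> np.ndarray:
        if self.samples.shape[0] == 0:
            raise ValueError("empty sample set")
        return self.samples.mean(axis=0)


def warmup_points(polytope: Polytope, count: int | None = None) -> np.ndarray:
    """Feasible starting points from optimizing ±unit-coordinate objectives.

    The first 2n objectives are ±e_i in order (on a box these hit every
    axis-extreme vertex); beyond 2n the pattern repeats.  One LP per
    point.
    """
    n = polytope.dim
    if count is None:
        count = max(2 * n, WARMUP_MIN)
    points = np.empty((count, n))
    for k in range(count):
        i, sign = (k // 2) % n, 1.0 if k % 2 == 0 else -1.0
        c = np.zeros(n)
        c[i] = sign  # minimize ±e_i → hits both extremes as k cycles
        res = polytope._solve(c)
        if res.status != OPTIMAL:
            raise EmptyPolytopeError(f"warmup LP #{k} failed: {res.status}")
        points[k] = res.x
    return points


def _nullspace_projector(polytope: Polytope) -> np.ndarray | None:
    if polytope.A_eq is None or not polytope.A_eq.shape[0]:
        return None
    N = null_space(polytope.A_eq)
    return N  # columns: orthonormal basis of the steady-state subspace


def achr_sample(
    polytope: Polytope,
    n_samples: int = N_SAMPLES_DEFAULT,
    seed: int | None = None,
    thinning: int = THINNING_DEFAULT,
    warmup: np.ndarray | None = None,
) -> FluxSampleSet:
    """Sample the polytope with artificially-centered hit-and-run.

    Each step: pick a random stored point, take the direction from the
    running center to it, project onto the equality null space, find the
    feasible chord through the current point, and jump to a uniform
    point on it.  Every ``thinning``-th point is emitted.  Identical
    seeds give bit-identical output.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    if warmup is None:
        warmup = warmup_points(polytope)
    n = polytope.dim
    N = _nullspace_projector(polytope)

    n_store = warmup.shape[0] + n_samples * thinning
    points = np.empty((n_store, n))
    points[:warmup.shape[0]] = warmup
    t = warmup.shape[0]
    center = warmup.mean(axis=0)
    x = warmup[rng.integers(t)].copy()

    out = np.empty((n_samples, n))
    emitted = 0
    step = 0
    failures = 0
    while emitted < n_samples:
        ref = points[rng.integers(t)]
        d = ref - center
        if N is not None:
            d = N @ (N.T @ d)
        norm = np.linalg.norm(d)
        if norm < 1e-12:
            failures += 1
            if failures > 100:
                raise RuntimeError("ACHR: 100 consecutive degenerate directions")
            continue
        d /= norm
        lam_lo, lam_hi = _chord(polytope, x, d)
        if lam_hi - lam_lo < 1e-12:
            failures += 1
            if failures > 100:
                raise RuntimeError("ACHR: 100 consecutive empty chords")
            continue
        failures = 0
        lam = lam_lo + (lam_hi - lam_lo) * rng.random()
        x = x + lam * d
        if N is None:
            # guard against slow numerical drift off the box
            np.clip(x, polytope.lb, polytope.ub, out=x)
        points[t] = x
        center = (t * center + x) / (t + 1)
        t += 1
        step += 1
        if step % thinning == 0:
            out[emitted] = x
            emitted += 1

    return FluxSampleSet(
        samples=out, seed=seed, thinning=thinning, n_warmup=warmup.shape[0],
        reaction_ids=polytope.reaction_ids,
        metadata={"n_steps": step, "prng": "numpy.random.default_rng(PCG64)"},
    )


def _chord(polytope: Polytope, x: np.ndarray, d: np.ndarray) -> tuple[float, float]:
    """Feasible λ-interval of {x + λ·d} inside the polytope."""
    lam_lo, lam_hi = -np.inf, np.inf
    active = np.abs(d) > 1e-12
    if np.any(active):
        da = d[active]
        lo = (polytope.lb[active] - x[active]) / da
        hi = (polytope.ub[active] - x[active]) / da
        lam_lo = float(np.maximum.reduce(np.where(da > 0, lo, hi)))
        lam_hi = float(np.minimum.reduce(np.where(da > 0, hi, lo)))
    if polytope.A_ub is not None and polytope.A_ub.shape[0]:
        ad = polytope.A_ub @ d
        slack = polytope.b_ub - polytope.A_ub @ x
        pos = ad > 1e-12
        neg = ad < -1e-12
        if np.any(pos):
            lam_hi = min(lam_hi, np.min(slack[pos] / ad[pos]))
        if np.any(neg):
            lam_lo = max(lam_lo, np.max(slack[neg] / ad[neg]))
    return float(lam_lo), float(lam_hi)


def mean_metabolic_state(samples: FluxSampleSet):
    """Coordinate-wise mean flux — the sampled condition's metabolic state.

    Returns a :class:`fluxshift.core.FluxVector` when the sample set
    carries reaction ids, else a plain array.
    """
    mean = samples.mean()
    if samples.reaction_ids is not None:
        from .core import FluxVector
        return FluxVector(mean, samples.reaction_ids)
    return mean


def effective_sample_size(x: np.ndarray) -> float:
    """ESS of a 1-D chain via the initial-positive-sequence estimator."""
    x = np.asarray(x, dtype=float)
    k = len(x)
    if k < 3:
        return float(k)
    xc = x - x.mean()
    var = np.dot(xc, xc) / k
    if var == 0:
        return float(k)
    acf = np.correlate(xc, xc, mode="full")[k - 1:] / (k * var)
    rho_sum = 0.0
    for lag in range(1, k):
        if acf[lag] <= 0:
            break
        rho_sum += acf[lag]
    return float(k / (1.0 + 2.0 * rho_sum))
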