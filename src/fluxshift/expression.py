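"""From a genes × samples expression matrix to per-reaction states.

The chain is: map gene symbols onto the model, rank-discretize each
sample into lowly (−1) / moderately (0) / highly (+1) expressed tails,
take a consensus across samples, and propagate gene states to reactions
through the GPR rules (AND = min, OR = max over the ordered states).
The resulting reaction states −1/0/+1 are the input of the iMAT
optimization: RH (state +1) reactions should carry flux, RL (state −1)
reactions should not.

Expression matrices are plain :class:`pandas.DataFrame` objects, genes
as the index, one column per sample.  The TSV layout has a leading
``gene`` column and a header row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil, floor
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import MetabolicModel

__all__ = [
    "MappingReport",
    "ReactionStateAssignment",
    "read_expression",
    "write_expression",
    "map_expression_to_model",
    "discretize_by_rank",
    "discretize_matrix",
    "consensus_state",
    "reaction_states_from_gpr",
]

Q_LOW_DEFAULT = 0.25
Q_HIGH_DEFAULT = 0.25
AGREEMENT_DEFAULT = 2.0 / 3.0


@dataclass(frozen=True)
class MappingReport:
    """Bookkeeping from gene-symbol mapping."""

    unmapped: frozenset[str]      # expression genes absent from the model
    uncovered: frozenset[str]     # model genes with no expression row
    n_collapsed: int = 0          # duplicate rows averaged away


@dataclass
class ReactionStateAssignment:
    """Per-reaction expression state in {−1, 0, +1}.

    ``RH``/``RL`` are the highly/lowly expressed reaction sets handed to
    iMAT; reactions without a GPR are state 0 and in neither.
    """

    states: dict[str, int]
    RH: frozenset[str] = field(init=False)
    RL: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        self.RH = frozenset(r for r, s in self.states.items() if s == 1)
        self.RL = frozenset(r for r, s in self.states.items() if s == -1)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes × samples TSV (first column ``gene``, header row)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "gene":
        raise ValueError(f"{path}: first column must be named 'gene', got {df.columns[0]!r}")
    df = df.set_index("gene")
    if df.shape[1] < 1:
        raise ValueError(f"{path}: expression matrix needs at least one sample column")
    vals = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError(f"{path}: non-finite expression values")
    return df.astype(float)


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene", float_format="%.6g")


def map_expression_to_model(
    expr: pd.DataFrame, model: MetabolicModel
) -> tuple[pd.DataFrame, MappingReport]:
    """Restrict an expression matrix to the model's genes.

    Rows sharing a gene symbol are collapsed to their per-sample mean.
    Raises ``ValueError`` when no expression gene maps to the model.
    """
    n_dup = int(expr.index.duplicated().sum())
    if n_dup:
        expr = expr.groupby(level=0, sort=False).mean()
    genes = frozenset(expr.index)
    keep = [g for g in expr.index if g in model.genes]
    if not keep:
        raise ValueError("no model genes found in expression data")
    report = MappingReport(
        unmapped=frozenset(genes - model.genes),
        uncovered=frozenset(model.genes - genes),
        n_collapsed=n_dup,
    )
    return expr.loc[keep], report


def discretize_by_rank(
    values: pd.Series | Sequence[float],
    q_low: float = Q_LOW_DEFAULT,
    q_high: float = Q_HIGH_DEFAULT,
) -> pd.Series:
    """Rank-discretize one sample into {−1, 0, +1}.

    Exactly ``⌊q_high·n⌋`` genes with the largest values get +1 and
    ``⌊q_low·n⌋`` with the smallest get −1 (ties broken by input order,
    stable).  Rank-based, so any strictly monotone transform of the
    values yields the same states.
    """
    if q_low < 0 or q_high < 0:
        raise ValueError("quantile fractions must be non-negative")
    if q_low + q_high >= 1:
        raise ValueError("q_low + q_high must be < 1")
    s = pd.Series(values, dtype=float) if not isinstance(values, pd.Series) else values.astype(float)
    n = len(s)
    if n < 4:
        raise ValueError(f"need at least 4 genes to discretize, got {n}")
    vals = s.to_numpy()
    if np.all(vals == vals[0]):
        raise ValueError("degenerate expression vector: all values equal")
    n_high = floor(q_high * n)
    n_low = floor(q_low * n)
    order = np.argsort(vals, kind="stable")  # ascending; ties keep input order
    states = np.zeros(n, dtype=np.int8)
    if n_low:
        states[order[:n_low]] = -1
    if n_high:
        states[order[n - n_high:]] = 1
    return pd.Series(states, index=s.index, name="state")


def discretize_matrix(
    expr: pd.DataFrame,
    q_low: float = Q_LOW_DEFAULT,
    q_high: float = Q_HIGH_DEFAULT,
) -> pd.DataFrame:
    """Per-sample discretization of a genes × samples matrix."""
    cols = {c: discretize_by_rank(expr[c], q_low, q_high) for c in expr.columns}
    return pd.DataFrame(cols, index=expr.index, dtype=np.int8)


def consensus_state(
    per_sample_states: pd.DataFrame | Sequence[pd.Series],
    agreement_fraction: float = AGREEMENT_DEFAULT,
) -> pd.Series:
    """Consensus gene state across samples.

    A gene is +1 (−1) iff at least ``⌈agreement_fraction·n_samples⌉``
    samples label it +1 (−1); otherwise 0.  With an agreement fraction
    above 1/2 the two labels can never both qualify.  Invariant under
    sample permutation.
    """
    if not isinstance(per_sample_states, pd.DataFrame):
        seq = list(per_sample_states)
        if not seq:
            raise ValueError("need at least one sample")
        idx = seq[0].index
        for s in seq[1:]:
            if not s.index.equals(idx):
                raise ValueError("per-sample state vectors cover different gene sets")
        per_sample_states = pd.concat(seq, axis=1)
    if per_sample_states.shape[1] < 1:
        raise ValueError("need at least one sample")
    n_samples = per_sample_states.shape[1]
    need = ceil(agreement_fraction * n_samples)
    arr = per_sample_states.to_numpy()
    n_up = (arr == 1).sum(axis=1)
    n_down = (arr == -1).sum(axis=1)
    out = np.zeros(len(per_sample_states), dtype=np.int8)
    out[n_up >= need] = 1
    out[n_down >= need] = -1
    if agreement_fraction > 0.5:
        assert not np.any((n_up >= need) & (n_down >= need))
    return pd.Series(out, index=per_sample_states.index, name="state")


def reaction_states_from_gpr(
    gene_states: Mapping[str, int] | pd.Series,
    model: MetabolicModel,
) -> ReactionStateAssignment:
    """Lift gene states to reaction states through the GPR rules.

    AND takes the minimum of its children, OR the maximum, over the
    ordering −1 < 0 < +1; genes without data count as 0 (moderate).
    Reactions without a GPR are 0 and excluded from RH/RL.
    """
    if isinstance(gene_states, pd.Series):
        gene_states = {g: int(v) for g, v in gene_states.items()}
    bad = {g: v for g, v in gene_states.items() if v not in (-1, 0, 1)}
    if bad:
        raise ValueError(f"gene states outside {{-1,0,1}}: {bad}")
    states = {}
    for rid in model.reaction_ids:
        rule = model.gpr.get(rid)
        states[rid] = rule.evaluate_states(gene_states) if rule is not None else 0
    assignment = ReactionStateAssignment(states)
    # RH/RL may only contain GPR-bearing reactions by construction
    return assignment


def write_states(states: Mapping[str, int] | pd.Series, path: str | Path) -> None:
    """Write a (gene or reaction) state vector as a two-column TSV."""
    s = pd.Series(states, name="state", dtype=int)
    s.to_csv(path, sep="\t", index_label="id")
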