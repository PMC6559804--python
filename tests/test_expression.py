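"""Discretization, consensus, gene→reaction state propagation."""

from math import ceil, floor

import numpy as np
import pandas as pd
import pytest

from conftest import build_model
from fluxshift.expression import (consensus_state, discretize_by_rank,
                                  discretize_matrix, map_expression_to_model,
                                  reaction_states_from_gpr, read_expression,
                                  write_expression)


def _expr(genes, values, samples=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"S{i + 1}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                        columns=samples)


# ---------------------------------------------------------------------------
# TSV I/O and mapping
# ---------------------------------------------------------------------------

def test_expression_tsv_round_trip(tmp_path):
    df = _expr(["G1", "G2", "G3", "G4"], np.arange(8.0).reshape(4, 2))
    path = tmp_path / "e.tsv"
    write_expression(df, path)
    back = read_expression(path)
    pd.testing.assert_frame_equal(back, df)


def test_mapping_reports_unmapped_and_uncovered(three_step_model):
    expr = _expr(["G1", "GX"], [[1.0, 2.0], [3.0, 4.0]])
    mapped, report = map_expression_to_model(expr, three_step_model)
    assert list(mapped.index) == ["G1"]
    assert report.unmapped == {"GX"}
    assert report.uncovered == {"G2"}


def test_duplicate_gene_rows_collapse_to_mean(three_step_model):
    expr = _expr(["G1", "G1"], [[1.0, 3.0], [3.0, 5.0]])
    mapped, report = map_expression_to_model(expr, three_step_model)
    assert report.n_collapsed == 1
    assert mapped.loc["G1"].tolist() == [2.0, 4.0]


def test_disjoint_gene_sets_error(three_step_model):
    with pytest.raises(ValueError, match="no model genes"):
        map_expression_to_model(_expr(["X1", "X2"], [[1.0], [2.0]]),
                                three_step_model)


# ---------------------------------------------------------------------------
# rank discretization
# ---------------------------------------------------------------------------

def test_four_values_default_quantiles():
    states = discretize_by_rank(pd.Series([10.0, 20.0, 30.0, 40.0]))
    assert states.tolist() == [-1, 0, 0, 1]


def test_exact_tail_counts_on_1000_distinct_values():
    rng = np.random.default_rng(0)
    vals = pd.Series(rng.permutation(1000).astype(float))
    states = discretize_by_rank(vals)
    assert (states == 1).sum() == 250
    assert (states == -1).sum() == 250


def test_rank_invariance_under_monotone_transform():
    rng = np.random.default_rng(5)
    vals = pd.Series(rng.uniform(1.0, 50.0, 200))
    assert discretize_by_rank(vals).equals(discretize_by_rank(np.log(vals)))


@pytest.mark.parametrize("n", [7, 23, 100, 999])
def test_tail_counts_are_exact_floors(n):
    vals = pd.Series(np.arange(n, dtype=float))
    states = discretize_by_rank(vals, q_low=0.25, q_high=0.25)
    assert (states == -1).sum() == floor(0.25 * n)
    assert (states == 1).sum() == floor(0.25 * n)


def test_degenerate_and_tiny_inputs_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        discretize_by_rank(pd.Series([2.0, 2.0, 2.0, 2.0]))
    with pytest.raises(ValueError, match="at least 4"):
        discretize_by_rank(pd.Series([1.0, 2.0, 3.0]))
    with pytest.raises(ValueError):
        discretize_by_rank(pd.Series(np.arange(10.0)), q_low=0.5, q_high=0.5)


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("states, expected", [
    ((1, 1, 0), 1),      # 2 of 3 meets the 2/3 threshold
    ((1, -1, 0), 0),     # no label reaches 2
    ((-1, -1, -1), -1),
])
def test_consensus_three_samples(states, expected):
    df = pd.DataFrame({f"S{i}": [s] for i, s in enumerate(states)},
                      index=["G1"], dtype=np.int8)
    assert consensus_state(df).loc["G1"] == expected


def test_consensus_two_samples_needs_both():
    # ceil(2/3 * 2) = 2 > 1: a single +1 is not enough
    df = pd.DataFrame({"S1": [1], "S2": [0]}, index=["G1"], dtype=np.int8)
    assert consensus_state(df).loc["G1"] == 0


def test_consensus_matches_ceiling_oracle_and_permutation_invariance():
    rng = np.random.default_rng(17)
    for _ in range(20):
        n_genes, n_samples = int(rng.integers(2, 10)), int(rng.integers(1, 8))
        arr = rng.choice([-1, 0, 1], size=(n_genes, n_samples))
        df = pd.DataFrame(arr, index=[f"G{i}" for i in range(n_genes)],
                          columns=[f"S{j}" for j in range(n_samples)])
        out = consensus_state(df)
        need = ceil(2 / 3 * n_samples)
        for i in range(n_genes):
            row = arr[i]
            expected = (1 if (row == 1).sum() >= need
                        else -1 if (row == -1).sum() >= need else 0)
            assert out.iloc[i] == expected
        perm = rng.permutation(n_samples)
        assert consensus_state(df.iloc[:, perm]).equals(out)


# ---------------------------------------------------------------------------
# GPR propagation
# ---------------------------------------------------------------------------

def test_reaction_states_and_or_and_missing_gpr():
    model = build_model(
        ["A", "B"],
        [("Rand", {"A": 1}, 0, 1, "G1 and G2", False),
         ("Ror", {"A": -1, "B": 1}, 0, 1, "G1 or G2", False),
         ("Rnone", {"B": -1}, 0, 1, None, False)],
    )
    assign = reaction_states_from_gpr({"G1": 1, "G2": -1}, model)
    assert assign.states == {"Rand": -1, "Ror": 1, "Rnone": 0}
    assert assign.RH == {"Ror"} and assign.RL == {"Rand"}


def test_matrix_discretization_then_consensus_pipeline():
    rng = np.random.default_rng(23)
    df = _expr([f"G{i}" for i in range(40)], rng.normal(size=(40, 6)))
    per_sample = discretize_matrix(df)
    assert set(np.unique(per_sample.to_numpy())) <= {-1, 0, 1}
    cons = consensus_state(per_sample)
    assert cons.index.equals(df.index)
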