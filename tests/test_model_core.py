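"""Model I/O, structural validation, dead-end pruning, candidate filter."""

import numpy as np
import pytest

from _oracles import dead_ends_by_rescan
from conftest import build_model
from fluxshift.core import (DimensionError, FluxVector, MetabolicModel,
                            ModelValidationError, candidate_reactions,
                            check_steady_state, find_dead_end_reactions)
from fluxshift.io import FormatError, read_model, write_model


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _random_model(rng):
    m = int(rng.integers(2, 6))
    n = int(rng.integers(2, 8))
    while True:
        S = rng.choice([-2.0, -1.0, 0.0, 1.0, 2.0], size=(m, n),
                       p=[0.1, 0.25, 0.3, 0.25, 0.1])
        if np.all(np.any(S != 0, axis=1)) and np.all(np.any(S != 0, axis=0)):
            break
    lb = np.where(rng.random(n) < 0.5, -rng.integers(1, 100, n), 0.0).astype(float)
    ub = rng.integers(1, 100, n).astype(float)
    gpr = {f"R{j}": f"G{j} or G{j + 1}" for j in range(n) if rng.random() < 0.7}
    from fluxshift.gpr import parse_gpr
    return MetabolicModel(
        metabolite_ids=[f"M{i}" for i in range(m)],
        reaction_ids=[f"R{j}" for j in range(n)],
        S=S, v_min=lb, v_max=ub,
        gpr={k: parse_gpr(v) for k, v in gpr.items()},
        exchange=rng.random(n) < 0.2,
    )


def test_json_round_trip_randomized(tmp_path):
    rng = np.random.default_rng(3)
    for i in range(10):
        model = _random_model(rng)
        path = tmp_path / f"m{i}.json"
        write_model(model, path)
        assert read_model(path) == model


def test_json_reader_counts_and_reversible_bounds(tmp_path, three_step_model):
    path = tmp_path / "m.json"
    write_model(three_step_model, path)
    back = read_model(path)
    assert back.n_metabolites == 2 and back.n_reactions == 3
    rev = three_step_model.copy()
    rev.v_min[1] = -5.0
    write_model(rev, path)
    assert read_model(path).v_min[1] == -5.0


def test_sbml_round_trip(tmp_path, three_step_model):
    path = tmp_path / "m.xml"
    write_model(three_step_model, path, format="sbml")
    back = read_model(path, format="sbml")
    assert back.reaction_ids == three_step_model.reaction_ids
    assert np.array_equal(back.S, three_step_model.S)
    assert np.array_equal(back.v_min, three_step_model.v_min)
    assert back.gpr == three_step_model.gpr


def test_unknown_format_and_parse_errors(tmp_path, three_step_model):
    with pytest.raises(FormatError):
        write_model(three_step_model, tmp_path / "x", format="csv")
    bad = tmp_path / "bad.json"
    bad.write_text("{not json")
    with pytest.raises(FormatError):
        read_model(bad)


def test_undeclared_gpr_gene_is_a_validation_error(tmp_path):
    doc = """{
      "metabolites": [{"id": "A"}],
      "genes": ["G1"],
      "reactions": [
        {"id": "R1", "stoichiometry": {"A": 1}, "lb": 0, "ub": 1,
         "gpr": "GX", "exchange": false},
        {"id": "R2", "stoichiometry": {"A": -1}, "lb": 0, "ub": 1,
         "gpr": null, "exchange": true}
      ]
    }"""
    path = tmp_path / "m.json"
    path.write_text(doc)
    with pytest.raises(ModelValidationError, match="GX"):
        read_model(path)


def test_duplicate_ids_rejected():
    with pytest.raises(ModelValidationError, match="duplicate"):
        build_model(["A"], [("R1", {"A": 1}, 0, 1, None, False),
                            ("R1", {"A": -1}, 0, 1, None, False)])


def test_bound_order_enforced():
    with pytest.raises(ModelValidationError, match="v_min > v_max"):
        build_model(["A"], [("R1", {"A": 1}, 2.0, 1.0, None, False)])


# ---------------------------------------------------------------------------
# dead ends and candidates
# ---------------------------------------------------------------------------

def test_dead_end_cascade_removes_upstream_exchange():
    # Ein: ∅→A, R1: A→B; B has no consumer: B kills R1, then A kills Ein
    model = build_model(
        ["A", "B"],
        [("Ein", {"A": 1}, 0, 10, None, True),
         ("R1", {"A": -1, "B": 1}, 0, 10, "G1", False)],
    )
    assert find_dead_end_reactions(model) == {"Ein", "R1"}


def test_complete_chain_has_no_dead_ends(three_step_model):
    assert find_dead_end_reactions(three_step_model) == set()


def test_isolated_reversible_reaction_is_dead():
    model = build_model(["A", "B"],
                        [("R1", {"A": -1, "B": 1}, -10, 10, "G1", False)])
    assert find_dead_end_reactions(model) == {"R1"}


def test_dead_ends_match_rescan_oracle_and_are_idempotent():
    rng = np.random.default_rng(11)
    for _ in range(20):
        model = _random_model(rng)
        dead = find_dead_end_reactions(model)
        assert dead == dead_ends_by_rescan(model)
        # pruning the pruned model removes nothing further
        keep = [j for j, r in enumerate(model.reaction_ids) if r not in dead]
        if not keep:
            continue
        pruned = MetabolicModel(
            metabolite_ids=model.metabolite_ids,
            reaction_ids=[model.reaction_ids[j] for j in keep],
            S=model.S[:, keep], v_min=model.v_min[keep],
            v_max=model.v_max[keep],
            gpr={r: g for r, g in model.gpr.items()
                 if r not in dead},
            exchange=model.exchange[keep],
        )
        assert find_dead_end_reactions(pruned) == set()


def test_candidates_exclude_dead_ends_gprless_and_exchanges(three_step_model):
    assert candidate_reactions(three_step_model) == ["R1"]
    model = build_model(
        ["A", "B", "C"],
        [("Ein", {"A": 1}, 0, 10, None, True),
         ("R1", {"A": -1, "B": 1}, 0, 10, "G1", False),
         ("R2", {"A": -1, "B": 1}, 0, 10, None, False),   # no GPR
         ("Rdead", {"A": -1, "C": 1}, 0, 10, "G2", False),  # C never consumed
         ("Eout", {"B": -1}, 0, 10, None, True)],
    )
    dead = find_dead_end_reactions(model)
    assert "Rdead" in dead
    cands = candidate_reactions(model)
    assert set(cands).isdisjoint(dead)
    assert cands == ["R1"]


# ---------------------------------------------------------------------------
# steady state
# ---------------------------------------------------------------------------

def test_zero_flux_is_steady(three_step_model):
    v = FluxVector.from_array(np.zeros(3), three_step_model)
    assert check_steady_state(three_step_model, v)


def test_accumulating_flux_is_not_steady(chain_model):
    v = FluxVector.from_array(np.array([1.0, 2.0]), chain_model)
    assert not check_steady_state(chain_model, v)


def test_lp_solution_is_steady(three_step_model):
    from scipy.optimize import linprog
    res = linprog(-np.ones(3), A_eq=three_step_model.S, b_eq=np.zeros(2),
                  bounds=np.column_stack([three_step_model.v_min,
                                          three_step_model.v_max]),
                  method="highs")
    assert check_steady_state(three_step_model, res.x)


def test_dimension_mismatch_raises(three_step_model):
    with pytest.raises(DimensionError):
        check_steady_state(three_step_model, np.zeros(5))
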