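"""MTA knockout screen: change sets, scoring, ranking, selection, overlap."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import build_model
from fluxshift.core import FluxVector
from fluxshift.mta import (ChangeSets, MTAResults, MTAScore, MTAScreen,
                           derive_change_sets, overlap_across_datasets,
                           reaction_gene_map)


def _expr(genes, values, prefix="S"):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                        columns=[f"{prefix}{i + 1}" for i in range(values.shape[1])])


def _flux(model, mapping):
    v = np.zeros(model.n_reactions)
    for rid, val in mapping.items():
        v[model.reaction_index(rid)] = val
    return FluxVector.from_array(v, model)


@pytest.fixture
def branch_model():
    """Uptake → A → B, then two competing drains B→C→∅ and B→D→∅."""
    return build_model(
        ["A", "B", "C", "D"],
        [("Ein", {"A": 1}, 0, 10, None, True),
         ("Rup", {"A": -1, "B": 1}, 0, 20, "GS", False),
         ("Rc", {"B": -1, "C": 1}, 0, 20, "GC", False),
         ("Ec", {"C": -1}, 0, 20, None, True),
         ("Rf", {"B": -1, "D": 1}, 0, 20, "GF", False),
         ("Ed", {"D": -1}, 0, 20, None, True)],
    )


# ---------------------------------------------------------------------------
# change sets
# ---------------------------------------------------------------------------

def test_change_sets_from_large_shift(branch_model):
    rng = np.random.default_rng(8)
    base = {g: rng.normal(5.0, 0.2, 5) for g in ("GS", "GC", "GF")}
    src = _expr(["GS", "GC", "GF"], [base["GS"], base["GC"], base["GF"]])
    # GF shifted up by >> 3 pooled SDs in the target condition
    tgt = _expr(["GS", "GC", "GF"],
                [base["GS"], base["GC"], base["GF"] + 3.0], prefix="T")
    cs = derive_change_sets(src, tgt, branch_model)
    assert "Rf" in cs.R_F
    assert cs.R_B == frozenset()
    assert {"Rup", "Rc"} <= cs.R_S


def test_identical_conditions_give_all_steady(branch_model):
    rng = np.random.default_rng(9)
    vals = rng.normal(5.0, 1.0, (3, 5))
    src = _expr(["GS", "GC", "GF"], vals)
    tgt = _expr(["GS", "GC", "GF"], vals, prefix="T")
    cs = derive_change_sets(src, tgt, branch_model)
    assert cs.R_F == cs.R_B == frozenset()
    assert cs.R_S == {"Rup", "Rc", "Rf"}


def test_conflicting_or_rule_is_excluded_and_reported():
    model = build_model(
        ["A"],
        [("Rin", {"A": 1}, 0, 10, "GU or GD", False),
         ("Rout", {"A": -1}, 0, 10, "GS", False)],
    )
    rng = np.random.default_rng(10)
    src = _expr(["GU", "GD", "GS"], rng.normal(5.0, 0.1, (3, 5)))
    tgt = src.copy()
    tgt.loc["GU"] += 3.0   # up
    tgt.loc["GD"] -= 3.0   # down: conflict inside one rule
    tgt.columns = [f"T{i}" for i in range(5)]
    cs = derive_change_sets(src, tgt, model)
    assert cs.conflicts == {"Rin"}
    assert "Rin" not in cs.R_F | cs.R_B | cs.R_S


def test_too_few_samples_rejected(branch_model):
    src = _expr(["GS"], [[1.0, 2.0]])
    with pytest.raises(ValueError, match="samples"):
        derive_change_sets(src, src, branch_model)


def test_change_sets_must_be_disjoint():
    with pytest.raises(ValueError, match="overlap"):
        ChangeSets(frozenset({"R1"}), frozenset({"R1"}), frozenset())


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def test_knockout_of_competitor_reroutes_into_desired_drain(branch_model):
    """Forcing the competing drain to zero frees flux through the
    reaction that should increase; the score beats the null's."""
    cs = ChangeSets(R_F=frozenset({"Rf"}), R_B=frozenset(),
                    R_S=frozenset({"Rup"}))
    v_source = _flux(branch_model, {"Ein": 10, "Rup": 10, "Rc": 10, "Ec": 10})
    screen = MTAScreen(branch_model, v_source, cs, candidates=["Rc", "Rf"])
    null = screen.score_null()
    ko = screen.score_knockout("Rc")
    assert ko.achieved_F == {"Rf"}
    assert ko.ts > null.ts
    # rerouting preserved the steady reaction
    assert ko.steady_deviation < 1e-6


def test_knockout_starving_the_steady_set_scores_below_null(branch_model):
    """Knocking out the reaction feeding both the steady set and a
    should-increase reaction moves everything the wrong way."""
    cs = ChangeSets(R_F=frozenset({"Rf", "Rc"}), R_B=frozenset(),
                    R_S=frozenset({"Rup"}))
    v_source = _flux(branch_model, {"Ein": 10, "Rup": 10, "Rc": 10, "Ec": 10})
    screen = MTAScreen(branch_model, v_source, cs,
                       candidates=["Rup", "Rc", "Rf"])
    ko = screen.score_knockout("Rup")
    assert ko.steady_deviation > 0
    assert ko.ts < screen.score_null().ts


def test_disconnected_candidate_equals_null():
    """A knockout whose constraint is already satisfied by the null
    optimum changes nothing: its score equals the null score."""
    model = build_model(
        ["A", "X", "Y"],
        [("Ein", {"A": 1}, 0, 10, None, True),
         ("Rout", {"A": -1}, 0, 10, "G1", False),
         ("Riso", {"X": -1, "Y": 1}, -10, 10, "G2", False)],
    )
    cs = ChangeSets(R_F=frozenset({"Rout"}), R_B=frozenset(), R_S=frozenset())
    v_source = _flux(model, {"Ein": 2, "Rout": 2})
    screen = MTAScreen(model, v_source, cs, candidates=["Riso"])
    null = screen.score_null()
    ko = screen.score_knockout("Riso")
    assert ko.ts == pytest.approx(null.ts, abs=1e-9)
    assert ko.steady_deviation == pytest.approx(null.steady_deviation, abs=1e-9)


def test_null_with_empty_change_sets_scores_zero(branch_model):
    cs = ChangeSets(frozenset(), frozenset(), frozenset())
    v_source = _flux(branch_model, {"Ein": 10, "Rup": 10, "Rc": 10, "Ec": 10})
    null = MTAScreen(branch_model, v_source, cs, candidates=["Rc"]).score_null()
    assert null.ts == 0.0
    assert null.steady_deviation == 0.0


def test_epsilon_change_rule(branch_model):
    v_source = _flux(branch_model, {"Rup": 8.0, "Rc": 0.2})
    screen = MTAScreen(branch_model, v_source,
                       ChangeSets(frozenset(), frozenset(), frozenset(), ),
                       candidates=["Rc"])
    assert screen.epsilon_change("Rup") == pytest.approx(0.8)   # 0.1 * 8
    assert screen.epsilon_change("Rc") == pytest.approx(0.1)    # floor at 1.0


def test_infeasible_knockout_gets_sentinel_and_lexicographic_ties():
    """A forced-flux chain: knocking out either internal step is
    infeasible; both get ts = −inf and sort lexicographically."""
    model = build_model(
        ["A", "B", "C"],
        [("Ein", {"A": 1}, 5, 10, None, True),    # obligatory uptake
         ("Ry", {"A": -1, "B": 1}, 0, 10, "G1", False),
         ("Rx", {"B": -1, "C": 1}, 0, 10, "G2", False),
         ("Eout", {"C": -1}, 0, 10, None, True)],
    )
    cs = ChangeSets(frozenset(), frozenset(), frozenset({"Ry", "Rx"}))
    v_source = _flux(model, {"Ein": 5, "Ry": 5, "Rx": 5, "Eout": 5})
    results = MTAScreen(model, v_source, cs, candidates=["Ry", "Rx"]).fit()
    assert all(s.ts == -math.inf for s in results.scores)
    assert [s.candidate for s in results.scores] == ["Rx", "Ry"]
    assert results.percentile == {"Rx": 50.0, "Ry": 100.0}


def test_scale_invariance_of_ranking(branch_model):
    """Scaling bounds, source state and movement thresholds by a common
    factor leaves the transformation scores unchanged."""
    cs = ChangeSets(R_F=frozenset({"Rf"}), R_B=frozenset({"Rc"}),
                    R_S=frozenset({"Rup"}))
    v1 = _flux(branch_model, {"Ein": 10, "Rup": 10, "Rc": 10, "Ec": 10})
    r1 = MTAScreen(branch_model, v1, cs, candidates=["Rc", "Rf"]).fit()

    scaled = branch_model.copy()
    scaled.v_min = scaled.v_min * 10
    scaled.v_max = scaled.v_max * 10
    v2 = FluxVector.from_array(v1.values * 10, scaled)
    r2 = MTAScreen(scaled, v2, cs, candidates=["Rc", "Rf"],
                   epsilon_change_floor=10.0, delta=1.0).fit()
    assert [s.candidate for s in r1.scores] == [s.candidate for s in r2.scores]
    for a, b in zip(r1.scores, r2.scores):
        assert a.ts == pytest.approx(b.ts, rel=1e-6)


def test_gene_knockout_mode(branch_model):
    """Losing the sole gene of a rule silences its reaction (same score
    as the reaction knockout); losing one isozyme of an OR rule
    disables nothing and scores at the null."""
    model = build_model(
        ["A", "B", "C", "D"],
        [("Ein", {"A": 1}, 0, 10, None, True),
         ("Rup", {"A": -1, "B": 1}, 0, 20, "GS", False),
         ("Rc", {"B": -1, "C": 1}, 0, 20, "GC1 or GC2", False),
         ("Ec", {"C": -1}, 0, 20, None, True),
         ("Rf", {"B": -1, "D": 1}, 0, 20, "GF", False),
         ("Ed", {"D": -1}, 0, 20, None, True)],
    )
    cs = ChangeSets(R_F=frozenset({"Rf"}), R_B=frozenset(),
                    R_S=frozenset({"Rup"}))
    v_source = _flux(model, {"Ein": 10, "Rup": 10, "Rc": 10, "Ec": 10})
    screen = MTAScreen(model, v_source, cs, candidates=["Rc", "Rf"])
    assert screen.reactions_disabled_by_gene("GF") == ["Rf"]
    assert screen.reactions_disabled_by_gene("GC1") == []   # isozyme rescues
    gene_ko = screen.score_gene_knockout("GF")
    assert gene_ko.candidate == "gene:GF"
    assert gene_ko.ts == pytest.approx(screen.score_knockout("Rf").ts, abs=1e-9)
    iso = screen.score_gene_knockout("GC1")
    assert iso.ts == pytest.approx(screen.score_null().ts, abs=1e-9)
    with pytest.raises(KeyError):
        screen.score_gene_knockout("NOPE")


# ---------------------------------------------------------------------------
# ranking / selection arithmetic
# ---------------------------------------------------------------------------

def _fake_results(ts_values, null_ts=0.0):
    scores = [MTAScore(f"R{i:05d}", ts, frozenset(), frozenset(),
                       0.0, 0.0, 0.0, "optimal")
              for i, ts in enumerate(ts_values)]
    scores.sort(key=lambda s: (-s.ts, s.candidate))
    null = MTAScore("null", null_ts, frozenset(), frozenset(),
                    0.0, 0.0, 0.0, "optimal")
    return MTAResults(None, scores, null)


def test_top_decile_of_1504_is_exactly_150():
    rng = np.random.default_rng(1)
    res = _fake_results(rng.normal(size=1504))
    sel = res.select(0.10)
    assert len(sel.criterion2_pass) == 150


def test_select_floor_and_empty_cases():
    res = _fake_results(np.linspace(1, 10, 10))
    assert len(res.select(0.10).criterion2_pass) == 1
    low = _fake_results(np.full(8, -1.0), null_ts=5.0)
    assert low.select(0.10).passing == []


def test_percentile_of_single_candidate_is_100():
    res = _fake_results([3.0])
    assert res.percentile[res.scores[0].candidate] == 100.0


def test_selection_is_intersection_in_rank_order():
    res = _fake_results([5.0, 4.0, 3.0, -1.0, -2.0, -3.0, -4.0, -5.0, -6.0,
                         -7.0], null_ts=3.5)
    sel = res.select(0.30)
    assert sel.criterion2_pass == {"R00000", "R00001", "R00002"}
    assert sel.criterion1_pass == {"R00000", "R00001"}
    assert sel.passing == ["R00000", "R00001"]


# ---------------------------------------------------------------------------
# overlap
# ---------------------------------------------------------------------------

def test_overlap_venn_counts():
    gene_map = {"Ra": {"a"}, "Rb": {"b"}, "Rc": {"c"}, "Rd": {"d"}}
    table = overlap_across_datasets(
        {"d1": ["Ra", "Rb", "Rc"], "d2": ["Rb", "Rc", "Rd"], "d3": ["Rc"]},
        gene_map)
    assert table["full_intersection"] == {"c"}
    assert table["full_intersection_count"] == 1
    assert table["exclusive_counts"][("d1",)] == 1          # a
    assert table["exclusive_counts"][("d1", "d2")] == 1     # b


def test_overlap_identical_sets(branch_model):
    gene_map = reaction_gene_map(branch_model)
    sel = ["Rup", "Rc"]
    table = overlap_across_datasets({"d1": sel, "d2": sel}, gene_map)
    assert table["full_intersection"] == {"GS", "GC"}
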