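import numpy as np
import pytest

from fluxshift.core import MetabolicModel
from fluxshift.gpr import parse_gpr


def build_model(mets, reactions, genes=None):
    """Compact model builder for tests.

    ``reactions``: list of (id, {met: coef}, lb, ub, gpr_str_or_None,
    exchange_bool).
    """
    met_index = {m: i for i, m in enumerate(mets)}
    S = np.zeros((len(mets), len(reactions)))
    rids, lb, ub, exch, gpr = [], [], [], [], {}
    for j, (rid, stoich, lo, hi, rule, is_ex) in enumerate(reactions):
        rids.append(rid)
        lb.append(lo)
        ub.append(hi)
        exch.append(is_ex)
        for m, coef in stoich.items():
            S[met_index[m], j] = coef
        if rule:
            gpr[rid] = parse_gpr(rule)
    return MetabolicModel(
        metabolite_ids=list(mets), reaction_ids=rids, S=S,
        v_min=np.array(lb, dtype=float), v_max=np.array(ub, dtype=float),
        gpr=gpr, genes=frozenset(genes) if genes is not None else None,
        exchange=np.array(exch, dtype=bool),
    )


@pytest.fixture
def chain_model():
    """∅ → A → ∅: uptake Ein, secretion Eout, bounds [0, 10]."""
    return build_model(
        ["A"],
        [("Ein", {"A": 1.0}, 0.0, 10.0, None, True),
         ("Eout", {"A": -1.0}, 0.0, 10.0, "G1", False)],
    )


@pytest.fixture
def three_step_model():
    """∅ → A → B → ∅ with GPRs on the internal conversion."""
    return build_model(
        ["A", "B"],
        [("Ein", {"A": 1.0}, 0.0, 10.0, None, True),
         ("R1", {"A": -1.0, "B": 1.0}, 0.0, 10.0, "G1 and G2", False),
         ("Eout", {"B": -1.0}, 0.0, 10.0, None, True)],
    )
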