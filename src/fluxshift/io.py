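"""Reading and writing metabolic models.

Two dialects:

* ``json_tabular`` — the package's native format: one JSON object with a
  ``metabolites`` array, an optional ``genes`` array, and a ``reactions``
  array (id, stoichiometry map, lb, ub, gpr string or null, exchange
  flag).  Lossless round-trip.
* ``sbml`` — SBML Level 3 (core + fbc bounds and gene products), read
  and written through cobrapy.

Expression matrices and per-gene/per-reaction state vectors travel as
TSV (see :mod:`fluxshift.expression`).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .core import MetabolicModel, ModelValidationError
from .gpr import parse_gpr

__all__ = ["FormatError", "read_model", "write_model"]

FORMATS = ("json_tabular", "sbml")


class FormatError(ValueError):
    """The file does not parse in the named dialect."""


def read_model(path: str | Path, format: str = "json_tabular") -> MetabolicModel:
    """Read a metabolic model from ``path`` in the given dialect."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "json_tabular":
        return _read_json(path)
    if format == "sbml":
        return _read_sbml(path)
    raise FormatError(f"unknown model format {format!r}; expected one of {FORMATS}")


def write_model(model: MetabolicModel, path: str | Path,
                format: str = "json_tabular") -> None:
    """Write ``model`` so that :func:`read_model` round-trips it."""
    path = Path(path)
    if format == "json_tabular":
        _write_json(model, path)
    elif format == "sbml":
        _write_sbml(model, path)
    else:
        raise FormatError(f"unknown model format {format!r}; expected one of {FORMATS}")


# ---------------------------------------------------------------------------
# native JSON dialect
# ---------------------------------------------------------------------------

def _read_json(path: Path) -> MetabolicModel:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
    for key in ("metabolites", "reactions"):
        if key not in doc:
            raise FormatError(f"{path}: missing required array {key!r}")

    met_ids = [m["id"] if isinstance(m, dict) else str(m) for m in doc["metabolites"]]
    met_index = {mid: i for i, mid in enumerate(met_ids)}
    if len(met_index) != len(met_ids):
        raise ModelValidationError(f"{path}: duplicate metabolite ids")

    rxn_ids, gpr, exchange, lb, ub = [], {}, [], [], []
    S = np.zeros((len(met_ids), len(doc["reactions"])))
    for j, rec in enumerate(doc["reactions"]):
        try:
            rid = rec["id"]
            stoich = rec["stoichiometry"]
            lb.append(float(rec["lb"]))
            ub.append(float(rec["ub"]))
        except (KeyError, TypeError) as exc:
            raise FormatError(f"{path}: reaction #{j} missing field {exc}") from exc
        rxn_ids.append(rid)
        for mid, coef in stoich.items():
            if mid not in met_index:
                raise FormatError(
                    f"{path}: reaction {rid!r} references unknown metabolite {mid!r}")
            S[met_index[mid], j] = float(coef)
        rule = rec.get("gpr")
        if rule:
            gpr[rid] = parse_gpr(rule)
        exchange.append(bool(rec.get("exchange", False)))

    genes = doc.get("genes")
    declared = frozenset(genes) if genes is not None else None
    if declared is not None:
        used = frozenset().union(*(g.genes for g in gpr.values()), frozenset())
        missing = sorted(used - declared)
        if missing:
            raise ModelValidationError(
                f"{path}: GPR rules reference undeclared genes: {missing}")
    return MetabolicModel(
        metabolite_ids=met_ids, reaction_ids=rxn_ids, S=S,
        v_min=np.array(lb), v_max=np.array(ub), gpr=gpr,
        genes=declared, exchange=np.array(exchange, dtype=bool),
        name=doc.get("name", path.stem),
    )


def _write_json(model: MetabolicModel, path: Path) -> None:
    reactions = []
    for j, rid in enumerate(model.reaction_ids):
        nz = np.nonzero(model.S[:, j])[0]
        reactions.append({
            "id": rid,
            "stoichiometry": {model.metabolite_ids[i]: model.S[i, j] for i in nz},
            "lb": model.v_min[j],
            "ub": model.v_max[j],
            "gpr": str(model.gpr[rid]) if rid in model.gpr else None,
            "exchange": bool(model.exchange[j]),
        })
    doc = {
        "name": model.name,
        "metabolites": [{"id": m} for m in model.metabolite_ids],
        "genes": sorted(model.genes),
        "reactions": reactions,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# SBML via cobrapy
# ---------------------------------------------------------------------------

def _read_sbml(path: Path) -> MetabolicModel:
    import cobra.io

    try:
        cm = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra raises several parser exception types
        raise FormatError(f"{path}: SBML parse failure: {exc}") from exc
    met_ids = [m.id for m in cm.metabolites]
    met_index = {mid: i for i, mid in enumerate(met_ids)}
    n = len(cm.reactions)
    S = np.zeros((len(met_ids), n))
    rxn_ids, gpr, exchange, lb, ub = [], {}, [], [], []
    for j, rxn in enumerate(cm.reactions):
        rxn_ids.append(rxn.id)
        for met, coef in rxn.metabolites.items():
            S[met_index[met.id], j] = coef
        lb.append(rxn.lower_bound)
        ub.append(rxn.upper_bound)
        rule = rxn.gene_reaction_rule
        if rule:
            gpr[rxn.id] = parse_gpr(rule)
        exchange.append(bool(rxn.boundary))
    return MetabolicModel(
        metabolite_ids=met_ids, reaction_ids=rxn_ids, S=S,
        v_min=np.array(lb), v_max=np.array(ub), gpr=gpr,
        genes=frozenset(g.id for g in cm.genes) or None,
        exchange=np.array(exchange, dtype=bool), name=cm.id or path.stem,
    )


def _write_sbml(model: MetabolicModel, path: Path) -> None:
    import cobra
    import cobra.io

    cm = cobra.Model(model.name)
    mets = {mid: cobra.Metabolite(mid, compartment="c")
            for mid in model.metabolite_ids}
    for j, rid in enumerate(model.reaction_ids):
        rxn = cobra.Reaction(rid)
        # plain Python floats: libsbml rejects numpy scalars
        rxn.lower_bound = float(model.v_min[j])
        rxn.upper_bound = float(model.v_max[j])
        cm.add_reactions([rxn])
        nz = np.nonzero(model.S[:, j])[0]
        rxn.add_metabolites({mets[model.metabolite_ids[i]]: float(model.S[i, j])
                             for i in nz})
        if rid in model.gpr:
            rxn.gene_reaction_rule = str(model.gpr[rid])
    cobra.io.write_sbml_model(cm, str(path))
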