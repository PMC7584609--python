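"""Readers and writers for metabolic models.

Supported formats: BiGG-style JSON (read + write) and SBML Level 3 with the
fbc package (read, via libsbml). The packaged ``INDIGOIDINE_RXN`` encodes
the cytosolic biosynthesis of the blue pigment indigoidine from two
molecules of L-glutamine (ATP-, CoA-, FMN- and O2-dependent, as catalyzed
by the NRPS BpsA), in BiGG metabolite ids.
"""

from __future__ import annotations

import json
from pathlib import Path
from .model_core import (
    DEFAULT_BOUND,
    GPRExpression,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    classify_reactions,
    parse_gpr,
)

__all__ = [
    "read_model",
    "read_bigg_json",
    "read_sbml",
    "write_bigg_json",
    "write_census_tsv",
    "INDIGOIDINE_RXN",
    "INDIGOIDINE_METABOLITES",
    "add_indigoidine_pathway",
]


class ModelParseError(ValueError):
    """File did not parse under the named standard; names the offending element."""


# ---------------------------------------------------------------------------
# BiGG-style JSON
# ---------------------------------------------------------------------------


def read_bigg_json(path: str | Path) -> MetabolicModel:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise ModelParseError(f"{path}: not valid JSON ({e})") from None
    for key in ("metabolites", "reactions"):
        if key not in doc:
            raise ModelParseError(f"{path}: missing required key {key!r}")

    mets = []
    for m in doc["metabolites"]:
        if "id" not in m:
            raise ModelParseError(f"{path}: metabolite without id")
        mets.append(
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment") or _infer_compartment(m["id"]),
                formula=m.get("formula"),
                charge=m.get("charge"),
                is_boundary=bool(m.get("is_boundary", False)),
            )
        )
    met_ids = {m.id for m in mets}

    rxns = []
    objective = None
    for r in doc["reactions"]:
        rid = r.get("id")
        if rid is None:
            raise ModelParseError(f"{path}: reaction without id")
        stoich = {str(k): float(v) for k, v in r.get("metabolites", {}).items()}
        unknown = sorted(set(stoich) - met_ids)
        if unknown:
            raise ModelParseError(
                f"{path}: reaction {rid} cites unknown metabolite(s) {', '.join(unknown)}"
            )
        try:
            rxn = Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=float(r.get("lower_bound", -DEFAULT_BOUND)),
                upper_bound=float(r.get("upper_bound", DEFAULT_BOUND)),
                gpr=parse_gpr(r.get("gene_reaction_rule", "")),
                name=r.get("name", ""),
                subsystem=r.get("subsystem"),
                is_spontaneous=bool(r.get("is_spontaneous", False))
                or "spontaneous" in str(r.get("gene_reaction_rule", "")).lower(),
            )
        except ModelValidationError as e:
            raise ModelParseError(f"{path}: reaction {rid}: {e}") from None
        rxns.append(rxn)
        if r.get("objective_coefficient"):
            objective = rid

    genes = [g["id"] for g in doc.get("genes", [])]
    model = MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        genes=genes,
        objective_reaction=objective,
        name=doc.get("id", doc.get("name", "")),
        version=str(doc.get("version", "")),
    )
    return model


def _infer_compartment(met_id: str) -> str:
    if "_" in met_id:
        suffix = met_id.rsplit("_", 1)[1]
        if 1 <= len(suffix) <= 2 and suffix.isalnum():
            return suffix
    return "c"


def write_bigg_json(model: MetabolicModel, path: str | Path) -> None:
    doc = {
        "id": model.name or "model",
        "version": model.version,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                **({"formula": m.formula} if m.formula else {}),
                **({"charge": m.charge} if m.charge is not None else {}),
                **({"is_boundary": True} if m.is_boundary else {}),
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": dict(sorted(r.stoichiometry.items())),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": r.gpr.to_string(),
                **({"subsystem": r.subsystem} if r.subsystem else {}),
                **({"is_spontaneous": True} if r.is_spontaneous else {}),
                **(
                    {"objective_coefficient": 1.0}
                    if r.id == model.objective_reaction
                    else {}
                ),
            }
            for r in model.reactions
        ],
        "genes": [{"id": g} for g in model.genes],
        "compartments": {c: c for c in sorted({m.compartment for m in model.metabolites})},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=False)
        fh.write("\n")


# ---------------------------------------------------------------------------
# SBML L3 + fbc (read-only)
# ---------------------------------------------------------------------------

SBO_SPONTANEOUS = "SBO:0000672"


def read_sbml(path: str | Path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelParseError(f"{path}: SBML error: {err.getMessage().strip()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelParseError(f"{path}: no <model> element")
    fbc = sbml_model.getPlugin("fbc")

    def strip(sid: str) -> str:
        # SBML ids are prefixed M_/R_/G_ relative to BiGG ids
        for pre in ("M_", "R_", "G_"):
            if sid.startswith(pre):
                return sid[len(pre):]
        return sid

    mets = []
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        spf = sp.getPlugin("fbc")
        mets.append(
            Metabolite(
                id=strip(sp.getId()),
                name=sp.getName() or "",
                compartment=sp.getCompartment() or "c",
                formula=(spf.getChemicalFormula() if spf and spf.isSetChemicalFormula() else None),
                charge=(spf.getCharge() if spf and spf.isSetCharge() else None),
                is_boundary=sp.getBoundaryCondition(),
            )
        )

    def param_value(pid: str, default: float) -> float:
        p = sbml_model.getParameter(pid) if pid else None
        return p.getValue() if p is not None else default

    objective_rxn = None
    if fbc is not None and fbc.getActiveObjective() is not None:
        obj = fbc.getActiveObjective()
        for i in range(obj.getNumFluxObjectives()):
            fo = obj.getFluxObjective(i)
            if fo.getCoefficient():
                objective_rxn = strip(fo.getReaction())

    rxns = []
    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        rid = strip(rx.getId())
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            sr = rx.getReactant(j)
            mid = strip(sr.getSpecies())
            stoich[mid] = stoich.get(mid, 0.0) - sr.getStoichiometry()
        for j in range(rx.getNumProducts()):
            sr = rx.getProduct(j)
            mid = strip(sr.getSpecies())
            stoich[mid] = stoich.get(mid, 0.0) + sr.getStoichiometry()
        stoich = {k: v for k, v in stoich.items() if v != 0}
        rxf = rx.getPlugin("fbc")
        if rxf is not None and rxf.isSetLowerFluxBound():
            lb = param_value(rxf.getLowerFluxBound(), -DEFAULT_BOUND)
            ub = param_value(rxf.getUpperFluxBound(), DEFAULT_BOUND)
        else:
            lb = -DEFAULT_BOUND if rx.getReversible() else 0.0
            ub = DEFAULT_BOUND
        gpr = GPRExpression(None)
        if rxf is not None and rxf.getGeneProductAssociation() is not None:
            gpr = _gpa_to_gpr(rxf.getGeneProductAssociation().getAssociation(), strip)
        spont = SBO_SPONTANEOUS in (rx.getSBOTermID() or "")
        try:
            rxns.append(
                Reaction(
                    id=rid, stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
                    gpr=gpr, name=rx.getName() or "", is_spontaneous=spont,
                )
            )
        except ModelValidationError as e:
            raise ModelParseError(f"{path}: reaction {rid}: {e}") from None

    genes = []
    if fbc is not None:
        for i in range(fbc.getNumGeneProducts()):
            genes.append(strip(fbc.getGeneProduct(i).getId()))

    return MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        genes=genes,
        objective_reaction=objective_rxn,
        name=sbml_model.getId() or "",
    )


def _gpa_to_gpr(assoc, strip) -> GPRExpression:
    import libsbml

    def walk(node):
        if node is None:
            return None
        if isinstance(node, libsbml.GeneProductRef):
            return ("gene", strip(node.getGeneProduct()))
        kind = "and" if isinstance(node, libsbml.FbcAnd) else "or"
        children = [walk(node.getAssociation(i)) for i in range(node.getNumAssociations())]
        children = [c for c in children if c is not None]
        if not children:
            return None
        if len(children) == 1:
            return children[0]
        return (kind, children)

    return GPRExpression(walk(assoc))


# ---------------------------------------------------------------------------
# Dispatch + reports
# ---------------------------------------------------------------------------


def read_model(path: str | Path, format: str = "auto") -> MetabolicModel:
    """Read a model from BiGG JSON or SBML(fbc); ``format='auto'`` sniffs by suffix."""
    path = Path(path)
    if format == "auto":
        if path.suffix.lower() == ".json":
            format = "bigg-json"
        elif path.suffix.lower() in (".xml", ".sbml"):
            format = "sbml"
        else:
            raise ValueError(f"cannot infer model format from suffix of {path.name}")
    if format == "bigg-json":
        return read_bigg_json(path)
    if format == "sbml":
        return read_sbml(path)
    raise ValueError(f"unknown model format {format!r} (expected sbml, bigg-json, auto)")


def write_census_tsv(model: MetabolicModel, path: str | Path, classification=None) -> None:
    cls = classification or classify_reactions(model)
    with open(path, "w") as fh:
        fh.write("reaction_id\tcategory\tgpr\tlower_bound\tupper_bound\n")
        for r in model.reactions:
            fh.write(
                f"{r.id}\t{cls[r.id]}\t{r.gpr.to_string()}\t{r.lower_bound}\t{r.upper_bound}\n"
            )


# ---------------------------------------------------------------------------
# Packaged indigoidine pathway (BiGG ids, cytosolic)
# ---------------------------------------------------------------------------

INDIGOIDINE_METABOLITES = (
    Metabolite(id="ind_c", name="Indigoidine", compartment="c", formula="C10H8N4O4"),
)

#: 2 L-glutamine + 2 ATP + 2 CoA + 2 FMN + 2.5 O2 ->
#:   2 adenosine-3',5'-bisphosphate + 2 FMNH2 + 2 diphosphate + 2 AMP
#:   + 2 pantetheine + H2O + 2 phosphate + 1 indigoidine
INDIGOIDINE_RXN = Reaction(
    id="IND_SYN",
    name="Indigoidine synthase (BpsA)",
    stoichiometry={
        "gln__L_c": -2.0,
        "atp_c": -2.0,
        "coa_c": -2.0,
        "fmn_c": -2.0,
        "o2_c": -2.5,
        "pap_c": 2.0,
        "fmnh2_c": 2.0,
        "ppi_c": 2.0,
        "amp_c": 2.0,
        "pan4p_c": 2.0,
        "h2o_c": 1.0,
        "pi_c": 2.0,
        "ind_c": 1.0,
    },
    lower_bound=0.0,
    upper_bound=DEFAULT_BOUND,
)


def add_indigoidine_pathway(model: MetabolicModel) -> tuple[MetabolicModel, str]:
    """Add the indigoidine synthesis reaction plus its exchange.

    Returns ``(extended model, exchange reaction id)``. The pantetheine
    product is mapped to the pantetheine species present in the model
    (``ptth_c`` when available, else pantetheine 4'-phosphate ``pan4p_c``).
    """
    from .model_core import add_reaction

    rxn = INDIGOIDINE_RXN.copy()
    if "ptth_c" in {m.id for m in model.metabolites}:
        rxn.stoichiometry["ptth_c"] = rxn.stoichiometry.pop("pan4p_c")
    out = add_reaction(model, rxn, new_metabolites=INDIGOIDINE_METABOLITES)
    exchange = Reaction(
        id="EX_ind_c",
        name="Indigoidine exchange",
        stoichiometry={"ind_c": -1.0},
        lower_bound=0.0,
        upper_bound=DEFAULT_BOUND,
    )
    out = add_reaction(out, exchange)
    return out, exchange.id
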