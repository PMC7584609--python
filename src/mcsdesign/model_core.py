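"""Core data structures for constraint-based metabolic models.

A :class:`MetabolicModel` is a stoichiometric reconstruction: metabolites,
reactions with flux bounds (mmol/gDW/h), boolean gene-protein-reaction (GPR)
rules, and a biomass objective. The module also provides GPR parsing and
evaluation and a total classification of reactions into structural
categories (exchange, transport, biomass, ATP maintenance, demand/sink,
spontaneous, no-GPR, gene-associated).

Sign convention (BiGG): exchange reactions are written ``met <-> (nothing)``;
negative flux is uptake, positive flux is secretion.
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

DEFAULT_BOUND = 1000.0

__all__ = [
    "Metabolite",
    "Reaction",
    "GPRExpression",
    "MetabolicModel",
    "GPRParseError",
    "ModelValidationError",
    "parse_gpr",
    "add_reaction",
    "classify_reactions",
    "CATEGORY_PRECEDENCE",
]


class ModelValidationError(ValueError):
    """A model or reaction violates a structural invariant."""


class GPRParseError(ValueError):
    """Malformed GPR string; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None
    charge: int | None = None
    is_boundary: bool = False

    def __post_init__(self):
        if not self.id:
            raise ModelValidationError("metabolite id must be non-empty")
        if not self.compartment:
            raise ModelValidationError(f"metabolite {self.id}: compartment must be non-empty")


# ---------------------------------------------------------------------------
# GPR boolean expressions
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(\(|\)|[A-Za-z0-9_.\-]+)")


class GPRExpression:
    """Boolean AND/OR tree over gene identifiers.

    The empty expression (``GPRExpression(None)``) marks "no gene
    association": it always evaluates active and contributes no genes.
    Internal nodes are tuples ``("and"|"or", children)``; leaves are
    ``("gene", gene_id)``.
    """

    def __init__(self, root=None):
        self.root = root

    @property
    def is_empty(self) -> bool:
        return self.root is None

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()

        def walk(node):
            if node[0] == "gene":
                out.add(node[1])
            else:
                for c in node[1]:
                    walk(c)

        if self.root is not None:
            walk(self.root)
        return frozenset(out)

    def evaluate(self, knocked_out: Iterable[str] = ()) -> bool:
        """True iff the reaction remains catalyzable with ``knocked_out`` genes removed."""
        ko = set(knocked_out)
        if self.root is None:
            return True

        def ev(node) -> bool:
            kind = node[0]
            if kind == "gene":
                return node[1] not in ko
            vals = (ev(c) for c in node[1])
            return all(vals) if kind == "and" else any(vals)

        return ev(self.root)

    def to_string(self) -> str:
        if self.root is None:
            return ""

        def fmt(node, parent=None) -> str:
            kind = node[0]
            if kind == "gene":
                return node[1]
            joiner = f" {kind} "
            inner = joiner.join(fmt(c, kind) for c in node[1])
            if parent is not None and parent != kind:
                return f"({inner})"
            return inner

        return fmt(self.root)

    def __repr__(self):
        return f"GPRExpression({self.to_string()!r})"

    def __eq__(self, other):
        return isinstance(other, GPRExpression) and self.root == other.root


def parse_gpr(text: str | None) -> GPRExpression:
    """Parse a GPR string like ``"(g1 and g2) or g3"`` into a boolean tree.

    Keywords ``and``/``or`` are case-insensitive; gene tokens may contain
    dots, underscores and hyphens (PP_#### style ids). An empty or
    whitespace-only string yields the empty-marker expression.
    """
    if text is None or not text.strip():
        return GPRExpression(None)

    tokens: list[tuple[str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip():
                raise GPRParseError(f"unexpected character {text[pos]!r}", pos)
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()

    idx = 0

    def peek():
        return tokens[idx][0] if idx < len(tokens) else None

    def expect_operand():
        nonlocal idx
        tok = peek()
        if tok is None:
            raise GPRParseError("dangling operator or empty group", tokens[-1][1] if tokens else 0)
        tpos = tokens[idx][1]
        if tok == "(":
            idx += 1
            node = parse_or()
            if peek() != ")":
                raise GPRParseError("unbalanced parentheses", tpos)
            idx += 1
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRParseError(f"expected gene or '(', got {tok!r}", tpos)
        idx += 1
        return ("gene", tok)

    def parse_and():
        nonlocal idx
        node = expect_operand()
        children = [node]
        while peek() is not None and peek().lower() == "and":
            idx += 1
            children.append(expect_operand())
        if len(children) == 1:
            return node
        flat = []
        for c in children:
            flat.extend(c[1] if c[0] == "and" else [c])
        return ("and", flat)

    def parse_or():
        nonlocal idx
        node = parse_and()
        children = [node]
        while peek() is not None and peek().lower() == "or":
            idx += 1
            children.append(parse_and())
        if len(children) == 1:
            return node
        flat = []
        for c in children:
            flat.extend(c[1] if c[0] == "or" else [c])
        return ("or", flat)

    root = parse_or()
    if idx < len(tokens):
        raise GPRParseError(f"unexpected token {tokens[idx][0]!r}", tokens[idx][1])
    return GPRExpression(root)


# ---------------------------------------------------------------------------
# Reactions and models
# ---------------------------------------------------------------------------


@dataclass
class Reaction:
    """A stoichiometric reaction with flux bounds in mmol/gDW/h.

    ``stoichiometry`` maps metabolite id -> signed coefficient (negative =
    consumed). ``gpr`` is the parsed boolean gene association.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: GPRExpression = field(default_factory=GPRExpression)
    name: str = ""
    subsystem: str | None = None
    is_spontaneous: bool = False

    def __post_init__(self):
        if isinstance(self.gpr, str):
            self.gpr = parse_gpr(self.gpr)
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id}: stoichiometry is empty")
        for met, coeff in self.stoichiometry.items():
            if not np.isfinite(coeff) or coeff == 0:
                raise ModelValidationError(
                    f"reaction {self.id}: coefficient for {met} must be finite and nonzero"
                )
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id}: lower_bound {self.lower_bound} > upper_bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def copy(self) -> "Reaction":
        r = replace(self, stoichiometry=dict(self.stoichiometry))
        return r


@dataclass
class MetabolicModel:
    """A genome-scale (or toy) metabolic model.

    The implied stoichiometric matrix S has one row per non-boundary
    metabolite and one column per reaction; steady state is S v = 0.
    """

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    genes: list[str] = field(default_factory=list)
    objective_reaction: str | None = None
    name: str = ""
    version: str = ""

    def __post_init__(self):
        self.validate()

    # -- lookups ----------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, mid: str) -> Metabolite:
        return self._met_index[mid]

    def reaction(self, rid: str) -> Reaction:
        return self._rxn_index[rid]

    def has_reaction(self, rid: str) -> bool:
        return rid in self._rxn_index

    def validate(self) -> None:
        self._met_index = {m.id: m for m in self.metabolites}
        if len(self._met_index) != len(self.metabolites):
            raise ModelValidationError("duplicate metabolite ids")
        self._rxn_index = {r.id: r for r in self.reactions}
        if len(self._rxn_index) != len(self.reactions):
            raise ModelValidationError("duplicate reaction ids")
        for r in self.reactions:
            for mid in r.stoichiometry:
                if mid not in self._met_index:
                    raise ModelValidationError(
                        f"reaction {r.id} references unknown metabolite {mid}"
                    )
        if self.objective_reaction is not None and self.objective_reaction not in self._rxn_index:
            raise ModelValidationError(
                f"objective reaction {self.objective_reaction} not in model"
            )
        if not self.genes:
            inferred: set[str] = set()
            for r in self.reactions:
                inferred |= r.gpr.genes
            self.genes = sorted(inferred)

    # -- matrix view ------------------------------------------------------
    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        """Dense S over non-boundary metabolites; returns (S, met_ids, rxn_ids)."""
        mets = [m.id for m in self.metabolites if not m.is_boundary]
        midx = {mid: i for i, mid in enumerate(mets)}
        S = np.zeros((len(mets), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for mid, coeff in r.stoichiometry.items():
                i = midx.get(mid)
                if i is not None:
                    S[i, j] = coeff
        return S, mets, self.reaction_ids

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=[r.copy() for r in self.reactions],
            genes=list(self.genes),
            objective_reaction=self.objective_reaction,
            name=self.name,
            version=self.version,
        )


def add_reaction(
    model: MetabolicModel,
    rxn: Reaction,
    new_metabolites: Iterable[Metabolite] = (),
) -> MetabolicModel:
    """Return a copy of ``model`` with ``rxn`` (and any new metabolites) added.

    Raises on duplicate reaction id, duplicate new metabolite, or a
    stoichiometry coefficient referencing a metabolite that is neither in
    the model nor in ``new_metabolites``.
    """
    if model.has_reaction(rxn.id):
        raise ModelValidationError(f"reaction {rxn.id} already present in model")
    out = model.copy()
    known = set(out.metabolite_ids)
    for m in new_metabolites:
        if m.id in known:
            raise ModelValidationError(f"metabolite {m.id} already present in model")
        out.metabolites.append(m)
        known.add(m.id)
    missing = [mid for mid in rxn.stoichiometry if mid not in known]
    if missing:
        raise ModelValidationError(
            f"reaction {rxn.id} references absent metabolite(s): {', '.join(missing)}"
        )
    out.reactions.append(rxn.copy())
    out.genes = sorted(set(out.genes) | rxn.gpr.genes)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Reaction classification
# ---------------------------------------------------------------------------

CATEGORY_PRECEDENCE = (
    "exchange",
    "transport",
    "biomass",
    "atpm",
    "demand_or_sink",
    "spontaneous",
    "no_gpr",
    "gene_associated",
)

_COMPARTMENT_SUFFIX = re.compile(r"_([a-z][a-z0-9]?)$")


def _base_met_id(mid: str) -> str:
    return _COMPARTMENT_SUFFIX.sub("", mid)


def classify_reactions(
    model: MetabolicModel,
    biomass_ids: Iterable[str] | None = None,
    atpm_ids: Iterable[str] = ("ATPM",),
    extracellular_compartments: Iterable[str] = ("e",),
) -> dict[str, str]:
    """Assign each reaction its highest-precedence structural category.

    Rules: *exchange* = single metabolite crossing the system boundary
    (extracellular species or explicit boundary metabolite); *transport* =
    the same base metabolite appears in >=2 compartments; *biomass*/*atpm*
    by configured ids (objective reaction defaults to biomass);
    *demand_or_sink* = irreversible single-metabolite drain or source in a
    non-boundary compartment; then the spontaneous flag, then empty GPR,
    else *gene_associated*. Classification is total.
    """
    biomass = set(biomass_ids) if biomass_ids is not None else set()
    if model.objective_reaction:
        biomass.add(model.objective_reaction)
    atpm = set(atpm_ids)
    extra = set(extracellular_compartments)

    out: dict[str, str] = {}
    for r in model.reactions:
        mets = [model.metabolite(mid) for mid in r.stoichiometry]
        cat = None
        if len(mets) == 1:
            m = mets[0]
            if m.is_boundary or m.compartment in extra or r.id.upper().startswith("EX_"):
                cat = "exchange"
        if cat is None:
            comps_by_base: dict[str, set[str]] = {}
            for m in mets:
                comps_by_base.setdefault(_base_met_id(m.id), set()).add(m.compartment)
            if any(len(cs) >= 2 for cs in comps_by_base.values()):
                cat = "transport"
        if cat is None and r.id in biomass:
            cat = "biomass"
        if cat is None and r.id in atpm:
            cat = "atpm"
        if cat is None and len(mets) == 1 and not r.reversible:
            cat = "demand_or_sink"
        if cat is None and r.is_spontaneous:
            cat = "spontaneous"
        if cat is None and r.gpr.is_empty:
            cat = "no_gpr"
        out[r.id] = cat or "gene_associated"
    return out


def census(model: MetabolicModel, classification: Mapping[str, str] | None = None) -> dict:
    """Summary counts used in model triage reports.

    Reports both the direct gene-associated count and the complement of the
    no-gene-association count; published reconstructions sometimes disagree
    between the two because of annotation gaps, so neither is forced.
    """
    cls = classification or classify_reactions(model)
    no_gene = [r.id for r in model.reactions if r.gpr.is_empty]
    structural = {"exchange", "transport", "biomass", "atpm", "demand_or_sink"}
    no_gene_structural = [rid for rid in no_gene if cls[rid] in structural]
    return {
        "n_reactions": len(model.reactions),
        "n_metabolites": len(model.metabolites),
        "n_genes": len(model.genes),
        "n_without_gpr": len(no_gene),
        "n_without_gpr_structural": len(no_gene_structural),
        "n_gene_associated_direct": sum(1 for r in model.reactions if not r.gpr.is_empty),
        "n_gene_associated_complement": len(model.reactions) - len(no_gene),
        "by_category": {c: sum(1 for v in cls.values() if v == c) for c in CATEGORY_PRECEDENCE},
    }
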