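"""Translate reaction cut sets into implementable gene intervention sets.

A reaction cut set is only actionable once its reactions are mapped
through their GPR rules to genes, and the genes screened against what is
known outside the model: transposon-fitness (RB-TnSeq-style) essentiality
calls, multi-functional proteins whose inactivation would perturb more
than the targeted reaction, and reactions with no gene association at
all. The conservative mapping rule is used: for a reaction catalyzed by
several gene products (isozymes or complex subunits) *all* genes are
targeted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .constraint_engine import (
    FLUX_ZERO_TOL,
    GrowthCondition,
    apply_gene_knockouts,
    fba,
)
from .coupling_mcs import CutSet
from .model_core import MetabolicModel, ModelValidationError

__all__ = [
    "EssentialityTable",
    "GeneInterventionSet",
    "map_cutset_to_genes",
    "filter_by_essentiality",
    "exclude_multifunctional",
    "rank_candidate_cmcs",
    "check_alternate_carbon",
]

CALLS = ("essential", "dispensable", "unknown")
EXCLUSION_REASONS = ("essential_omics", "multifunctional", "no_gpr_reaction")


@dataclass(frozen=True)
class EssentialityTable:
    """Gene -> {essential, dispensable, unknown} calls from fitness data."""

    calls: Mapping[str, str]
    source: str = "RB-TnSeq"

    def __post_init__(self):
        bad = {g: c for g, c in self.calls.items() if c not in CALLS}
        if bad:
            raise ModelValidationError(f"invalid essentiality calls: {bad}")

    def call(self, gene: str) -> str:
        return self.calls.get(gene, "unknown")

    @classmethod
    def from_tsv(cls, path: str | Path, source: str = "RB-TnSeq") -> "EssentialityTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"gene_id", "call"}
        if not required <= set(df.columns):
            raise ModelValidationError(
                f"{path}: essentiality TSV needs columns {sorted(required)}"
            )
        return cls(calls=dict(zip(df["gene_id"], df["call"])), source=source)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.calls.items()), columns=["gene_id", "call"]
        ).to_csv(path, sep="\t", index=False)


@dataclass
class GeneInterventionSet:
    """Gene-level realisation of a reaction cut set, with exclusion provenance."""

    target_genes: frozenset[str]
    source_cutset: frozenset[str]
    provenance: dict[str, list[str]] = field(default_factory=dict)  # gene -> reactions
    excluded_genes: dict[str, str] = field(default_factory=dict)  # gene -> reason
    no_gpr_reactions: frozenset[str] = frozenset()
    feasible: bool = True
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        overlap = self.target_genes & set(self.excluded_genes)
        if overlap:
            raise ModelValidationError(
                f"genes both targeted and excluded: {sorted(overlap)}"
            )

    def _uncovered_reactions(self) -> set[str]:
        covered = set()
        for g in self.target_genes:
            covered.update(self.provenance.get(g, []))
        return set(self.source_cutset) - covered - set(self.no_gpr_reactions)

    def recompute_feasibility(self) -> "GeneInterventionSet":
        """A set is feasible when every gene-associated reaction of the
        source cut retains at least one targetable gene and no reaction
        lacks a GPR."""
        uncovered = self._uncovered_reactions()
        feasible = not uncovered and not self.no_gpr_reactions
        return replace(self, feasible=feasible)

    def to_json(self) -> str:
        return json.dumps(
            {
                "target_genes": sorted(self.target_genes),
                "source_cutset": sorted(self.source_cutset),
                "excluded_genes": dict(sorted(self.excluded_genes.items())),
                "no_gpr_reactions": sorted(self.no_gpr_reactions),
                "feasible": self.feasible,
                "warnings": self.warnings,
            },
            indent=1,
        )


def map_cutset_to_genes(model: MetabolicModel, cut: Iterable[str]) -> GeneInterventionSet:
    """Conservative GPR translation: every gene in a cut reaction's rule is
    targeted, for both AND (complex) and OR (isozyme) structures.

    Reactions without a gene association are flagged and contribute no
    genes; the resulting set is marked infeasible because such a reaction
    cannot be removed genetically.
    """
    cut = frozenset(cut)
    missing = sorted(r for r in cut if not model.has_reaction(r))
    if missing:
        raise ModelValidationError(f"cut reactions not in model: {', '.join(missing)}")
    provenance: dict[str, list[str]] = {}
    no_gpr = set()
    for rid in sorted(cut):
        gpr = model.reaction(rid).gpr
        if gpr.is_empty:
            no_gpr.add(rid)
            continue
        for g in sorted(gpr.genes):
            provenance.setdefault(g, []).append(rid)
    gis = GeneInterventionSet(
        target_genes=frozenset(provenance),
        source_cutset=cut,
        provenance=provenance,
        no_gpr_reactions=frozenset(no_gpr),
    )
    return gis.recompute_feasibility()


def filter_by_essentiality(
    gis: GeneInterventionSet, table: EssentialityTable
) -> GeneInterventionSet:
    """Move omics-essential genes to the exclusion list.

    Genes with an ``unknown`` call are kept as dispensable, with a logged
    warning. Omics calls override model-predicted essentiality.
    """
    excluded = dict(gis.excluded_genes)
    keep = set()
    warn = list(gis.warnings)
    for g in sorted(gis.target_genes):
        call = table.call(g)
        if call == "essential":
            excluded[g] = "essential_omics"
        else:
            if call == "unknown":
                warn.append(f"gene {g}: no essentiality call; treated as dispensable")
            keep.add(g)
    out = replace(
        gis, target_genes=frozenset(keep), excluded_genes=excluded, warnings=warn
    )
    return out.recompute_feasibility()


def exclude_multifunctional(
    gis: GeneInterventionSet, multifunctional_genes: Iterable[str]
) -> GeneInterventionSet:
    """Exclude genes encoding multi-functional proteins (idempotent).

    An already-excluded gene keeps its first (primary) reason code.
    """
    multi = set(multifunctional_genes)
    excluded = dict(gis.excluded_genes)
    keep = set()
    for g in gis.target_genes:
        if g in multi:
            excluded[g] = "multifunctional"
        else:
            keep.add(g)
    out = replace(gis, target_genes=frozenset(keep), excluded_genes=excluded)
    return out.recompute_feasibility()


@dataclass(frozen=True)
class TriagePolicy:
    multifunctional_genes: frozenset[str] = frozenset()
    max_targets: int | None = None
    allow_partial: bool = False


def triage_cutset(
    model: MetabolicModel,
    cut: Iterable[str],
    table: EssentialityTable,
    policy: TriagePolicy = TriagePolicy(),
) -> GeneInterventionSet:
    """Full triage of one cut set: GPR mapping, then both exclusion filters."""
    gis = map_cutset_to_genes(model, cut)
    gis = filter_by_essentiality(gis, table)
    gis = exclude_multifunctional(gis, policy.multifunctional_genes)
    if policy.allow_partial and not gis.feasible and gis.target_genes:
        gis = replace(
            gis,
            feasible=True,
            warnings=gis.warnings
            + ["partial implementation waiver: proceeding without full reaction coverage"],
        )
    return gis


def rank_candidate_cmcs(
    candidates: Sequence[CutSet],
    model: MetabolicModel,
    table: EssentialityTable,
    policy: TriagePolicy = TriagePolicy(),
) -> pd.DataFrame:
    """Feasibility-annotated, deterministically ordered triage report.

    Ordering: feasible candidates first, then by target-gene count, then
    lexicographically by reaction ids — stable under input permutation.
    """
    rows = []
    for cs in candidates:
        gis = triage_cutset(model, cs.reactions, table, policy)
        reasons = []
        if gis.no_gpr_reactions:
            reasons.append("no_gpr_reaction")
        if any(r == "essential_omics" for r in gis.excluded_genes.values()):
            if gis._uncovered_reactions():
                reasons.append("essential_gene_required")
        if any(r == "multifunctional" for r in gis.excluded_genes.values()):
            if gis._uncovered_reactions():
                reasons.append("multifunctional_conflict")
        feasible = gis.feasible
        if policy.max_targets is not None and len(gis.target_genes) > policy.max_targets:
            feasible = False
            reasons.append("size_above_policy_limit")
        rows.append(
            {
                "cutset": ";".join(sorted(cs.reactions)),
                "n_reactions": cs.size,
                "n_target_genes": len(gis.target_genes),
                "target_genes": ";".join(sorted(gis.target_genes)),
                "excluded_genes": ";".join(
                    f"{g}:{r}" for g, r in sorted(gis.excluded_genes.items())
                ),
                "feasible": feasible,
                "infeasibility_reasons": ";".join(sorted(set(reasons))),
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(
            by=["feasible", "n_target_genes", "cutset"],
            ascending=[False, True, True],
            kind="mergesort",
        ).reset_index(drop=True)
    return df


def check_alternate_carbon(
    model: MetabolicModel,
    gene_set: Iterable[str],
    carbon_exchanges: Sequence[str],
    product_exchange: str,
    condition: GrowthCondition,
) -> pd.DataFrame:
    """Growth and product capability of the knockout strain per carbon source.

    For each candidate substrate the other listed carbon exchanges are
    closed to uptake, the gene knockouts applied, and FBA run twice
    (biomass, then product). A design coupled on one substrate typically
    loses product capability — and often growth — on bypass substrates.
    """
    for rid in carbon_exchanges:
        if not model.has_reaction(rid):
            raise ModelValidationError(f"carbon exchange {rid} not in model")
    ko_model = apply_gene_knockouts(model, gene_set)
    rows = []
    for carbon in carbon_exchanges:
        others = tuple(c for c in carbon_exchanges if c != carbon)
        cond = replace(
            condition,
            substrate_exchange=carbon,
            closed_exchanges=tuple(condition.closed_exchanges) + others,
        )
        growth_sol = fba(ko_model, cond)
        growth = growth_sol.objective_value if growth_sol.optimal else 0.0
        prod_sol = fba(ko_model, cond, objective=product_exchange)
        prod = prod_sol.objective_value if prod_sol.optimal else 0.0
        rows.append(
            {
                "carbon_exchange": carbon,
                "growth_flux": growth,
                "max_product_flux": prod,
                "product_capable": prod > FLUX_ZERO_TOL,
            }
        )
    return pd.DataFrame(rows).set_index("carbon_exchange")
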