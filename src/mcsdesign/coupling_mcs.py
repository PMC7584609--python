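"""Strong growth coupling and constrained minimal cut set (cMCS) enumeration.

A reaction cut set strongly couples product formation to substrate
metabolism when, after removing the cut reactions, every admissible
steady-state flux distribution (fixed substrate uptake, maintenance ATP
enforced, byproduct secretion restricted to the allowed overflow
metabolites) secretes the product at or above a demanded fraction of the
maximum theoretical yield — even at zero growth — while at least one
distribution still reaches a demanded fraction of the maximum biomass
yield.

Enumeration is an explicit cardinality-ascending search over the knockable
reaction set with superset pruning, verified per candidate by two LPs:
worst-case (minimum guaranteed) product yield, and feasibility of the
desired high-growth/high-yield region. On desk-scale networks this is
exhaustive and therefore returns exactly the minimal cut sets.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable

from .constraint_engine import (
    FLUX_ZERO_TOL,
    GrowthCondition,
    InfeasibleProblemError,
    LinearProblem,
    condition_overrides,
)
from .model_core import MetabolicModel, ModelValidationError, classify_reactions

__all__ = [
    "CouplingSpec",
    "CutSet",
    "default_knockable",
    "min_guaranteed_yield",
    "is_strongly_coupled",
    "enumerate_cmcs",
    "verify_cutset_fva",
]

YIELD_EPS = 1e-6

#: Demanded product-yield grid used in the published design sweeps.
DEFAULT_YIELD_GRID = (0.10, 0.50, 0.70, 0.80, 0.85)


@dataclass(frozen=True)
class CouplingSpec:
    """What 'coupled' means: demanded yields, knockable set, search size.

    ``demanded_yield_fraction`` is a fraction of the product's maximum
    theoretical yield; ``demanded_biomass_fraction`` a fraction of the
    wild-type maximum biomass yield. Exchanges and spontaneous reactions
    are never knockable.
    """

    condition: GrowthCondition
    product_exchange: str
    demanded_yield_fraction: float = 0.80
    demanded_biomass_fraction: float = 0.10
    knockable: tuple[str, ...] = ()
    max_cut_size: int = 5
    enforce_byproduct_policy: bool = True

    def __post_init__(self):
        for name in ("demanded_yield_fraction", "demanded_biomass_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ModelValidationError(f"{name} must lie in (0, 1]")
        if self.max_cut_size < 1:
            raise ModelValidationError("max_cut_size must be >= 1")


@dataclass
class CutSet:
    """A verified reaction cut set with its coupling diagnostics."""

    reactions: frozenset[str]
    guaranteed_min_yield: float
    max_biomass_after: float
    minimal: bool = True
    verified: bool = True
    diagnostics: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.reactions)

    def sort_key(self):
        return (self.size, tuple(sorted(self.reactions)))


def default_knockable(
    model: MetabolicModel,
    spec_condition: GrowthCondition | None = None,
    forbidden: Iterable[str] = (),
) -> tuple[str, ...]:
    """Gene-associated, non-exchange, non-spontaneous, non-ATPM, non-biomass
    reactions — the published exclusion policy."""
    cls = classify_reactions(model)
    banned = set(forbidden)
    if spec_condition is not None and spec_condition.atpm_reaction:
        banned.add(spec_condition.atpm_reaction)
    if model.objective_reaction:
        banned.add(model.objective_reaction)
    out = []
    for r in model.reactions:
        if r.id in banned or r.is_spontaneous:
            continue
        if cls[r.id] in ("exchange", "biomass", "atpm"):
            continue
        if r.gpr.is_empty:
            continue
        out.append(r.id)
    return tuple(sorted(out))


# ---------------------------------------------------------------------------
# Coupling predicates
# ---------------------------------------------------------------------------


def _cut_overrides(cut: Iterable[str]) -> dict[str, tuple[float, float]]:
    return {rid: (0.0, 0.0) for rid in cut}


class _CouplingChecker:
    """Shared LP state for repeated coupling checks on one model/spec."""

    def __init__(self, model: MetabolicModel, spec: CouplingSpec):
        self.model = model
        self.spec = spec
        self.lp = LinearProblem(model)
        self.base_ov = condition_overrides(
            model,
            spec.condition,
            enforce_byproduct_policy=spec.enforce_byproduct_policy,
            byproduct_exempt=(spec.product_exchange,),
        )
        self.uptake = spec.condition.uptake_rate
        biomass = model.objective_reaction
        if biomass is None:
            raise ModelValidationError("model has no biomass objective")
        self.biomass = biomass
        mty_sol = self.lp.solve(spec.product_exchange, "max", self.base_ov, want_fluxes=False)
        if not mty_sol.optimal or mty_sol.objective_value <= FLUX_ZERO_TOL:
            raise InfeasibleProblemError(
                "maximum theoretical yield is zero; nothing to couple"
            )
        self.mty = mty_sol.objective_value / self.uptake
        mu_sol = self.lp.solve(biomass, "max", self.base_ov, want_fluxes=False)
        self.mu_max = mu_sol.objective_value if mu_sol.optimal else 0.0

    def min_yield(self, cut: Iterable[str]) -> float | None:
        """Worst-case product yield over all admissible states, or None if
        the cut model is infeasible under the condition."""
        ov = dict(self.base_ov)
        ov.update(_cut_overrides(cut))
        sol = self.lp.solve(self.spec.product_exchange, "min", ov, want_fluxes=False)
        if not sol.optimal:
            return None
        return sol.objective_value / self.uptake

    def desired_region_feasible(self, cut: Iterable[str]) -> tuple[bool, float]:
        """Can the cut strain still grow at the demanded biomass while
        meeting the demanded yield? Returns (flag, max biomass after cut)."""
        spec = self.spec
        ov = dict(self.base_ov)
        ov.update(_cut_overrides(cut))
        demanded_flux = spec.demanded_yield_fraction * self.mty * self.uptake
        jp = self.lp.rxn_index[spec.product_exchange]
        lo, hi = ov.get(spec.product_exchange, (self.lp.lb[jp], self.lp.ub[jp]))
        ov[spec.product_exchange] = (max(lo, demanded_flux - YIELD_EPS), hi)
        sol = self.lp.solve(self.biomass, "max", ov, want_fluxes=False)
        if not sol.optimal:
            return False, 0.0
        mu = sol.objective_value
        return mu + FLUX_ZERO_TOL >= spec.demanded_biomass_fraction * self.mu_max, mu

    def check(self, cut: Iterable[str]) -> tuple[bool, dict]:
        spec = self.spec
        wc = self.min_yield(cut)
        diagnostics = {
            "mty": self.mty,
            "demanded_yield": spec.demanded_yield_fraction * self.mty,
            "min_guaranteed_yield": wc,
            "mu_max_wildtype": self.mu_max,
        }
        if wc is None:
            diagnostics["reason"] = "infeasible_after_cut"
            return False, diagnostics
        ok_yield = wc >= spec.demanded_yield_fraction * self.mty - YIELD_EPS
        ok_desired, mu_after = self.desired_region_feasible(cut)
        diagnostics["max_biomass_after"] = mu_after
        diagnostics["demanded_biomass"] = spec.demanded_biomass_fraction * self.mu_max
        if not ok_yield:
            diagnostics["reason"] = "worst_case_yield_below_demand"
        elif not ok_desired:
            diagnostics["reason"] = "desired_region_empty"
        return ok_yield and ok_desired, diagnostics


def min_guaranteed_yield(
    model: MetabolicModel,
    condition: GrowthCondition,
    product_exchange: str,
    cut: Iterable[str] = (),
    enforce_byproduct_policy: bool = True,
) -> float:
    """Minimum product yield (mol/mol) over all admissible flux states.

    Biomass is free (including zero); uptake is fixed; ATPM enforced.
    Raises :class:`InfeasibleProblemError` when the condition itself is
    infeasible — distinct from a feasible worst case of zero yield.
    """
    lp = LinearProblem(model)
    ov = condition_overrides(
        model, condition, enforce_byproduct_policy, byproduct_exempt=(product_exchange,)
    )
    ov.update(_cut_overrides(cut))
    sol = lp.solve(product_exchange, "min", ov, want_fluxes=False)
    if not sol.optimal:
        raise InfeasibleProblemError(
            f"condition infeasible (status {sol.status})", status=sol.status
        )
    return sol.objective_value / condition.uptake_rate


def is_strongly_coupled(
    model: MetabolicModel,
    spec: CouplingSpec,
    cut: Iterable[str],
) -> tuple[bool, dict]:
    """Test one cut set against the coupling demands; returns (flag, diagnostics)."""
    checker = _CouplingChecker(model, spec)
    return checker.check(frozenset(cut))


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------


def enumerate_cmcs(
    model: MetabolicModel,
    spec: CouplingSpec,
    budget: int | None = 200_000,
) -> list[CutSet]:
    """All minimal cut sets enforcing strong coupling, up to ``max_cut_size``.

    Cardinality-ascending subset search with superset pruning; complete
    (hence exactly minimal) within the size limit and subset budget. When
    the budget is exhausted a partial result is returned with a warning
    recording the explored frontier.
    """
    checker = _CouplingChecker(model, spec)
    knockable = tuple(spec.knockable) or default_knockable(model, spec.condition)
    unknown = sorted(set(knockable) - set(model.reaction_ids))
    if unknown:
        raise ModelValidationError(f"knockable reactions not in model: {', '.join(unknown)}")
    knockable = tuple(sorted(knockable))

    accepted: list[CutSet] = []
    accepted_sets: list[frozenset[str]] = []
    explored = 0
    truncated_at = None
    for size in range(1, min(spec.max_cut_size, len(knockable)) + 1):
        for combo in itertools.combinations(knockable, size):
            cut = frozenset(combo)
            if any(prev <= cut for prev in accepted_sets):
                continue
            if budget is not None and explored >= budget:
                truncated_at = (size, combo)
                break
            explored += 1
            ok, diag = checker.check(cut)
            if ok:
                accepted_sets.append(cut)
                accepted.append(
                    CutSet(
                        reactions=cut,
                        guaranteed_min_yield=diag["min_guaranteed_yield"],
                        max_biomass_after=diag["max_biomass_after"],
                        minimal=True,
                        verified=True,
                        diagnostics=diag,
                    )
                )
        if truncated_at:
            break
    if truncated_at:
        warnings.warn(
            f"cMCS search budget ({budget} subsets) exhausted at size "
            f"{truncated_at[0]} near {truncated_at[1]}; result is partial",
            stacklevel=2,
        )
    accepted.sort(key=CutSet.sort_key)
    return accepted


def verify_cutset_fva(
    model: MetabolicModel,
    spec: CouplingSpec,
    cut: Iterable[str],
) -> tuple[float, float, bool]:
    """(min, max) product flux at the demanded biomass after applying ``cut``.

    Production-obligatory growth is confirmed when both values are
    positive. Infeasibility after the cut is a verification failure
    (returns ``(nan, nan, False)``), not an exception.
    """
    checker = _CouplingChecker(model, spec)
    ov = dict(checker.base_ov)
    ov.update(_cut_overrides(cut))
    jb = checker.lp.rxn_index[checker.biomass]
    floor = spec.demanded_biomass_fraction * checker.mu_max
    lo, hi = ov.get(checker.biomass, (checker.lp.lb[jb], checker.lp.ub[jb]))
    ov[checker.biomass] = (max(lo, floor), hi)
    mn = checker.lp.solve(spec.product_exchange, "min", ov, want_fluxes=False)
    mx = checker.lp.solve(spec.product_exchange, "max", ov, want_fluxes=False)
    if not (mn.optimal and mx.optimal):
        return float("nan"), float("nan"), False
    vmin, vmax = mn.objective_value, mx.objective_value
    return vmin, vmax, bool(vmin > FLUX_ZERO_TOL and vmax > FLUX_ZERO_TOL)
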