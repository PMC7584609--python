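"""Linear-programming layer: FBA, FVA, yields, deletions, envelopes.

All optimisations are plain LPs over the steady-state flux cone
``{v : S v = 0, lb <= v <= ub}`` solved with HiGHS (via
``scipy.optimize.linprog``). Growth conditions fix the substrate uptake
rate, enforce the non-growth-associated ATP maintenance (ATPM) demand, and
optionally clamp secretion of non-allowed byproducts to zero.

Units: fluxes in mmol/gDW/h; yields in mol product per mol substrate
unless explicitly converted to g/g.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from .model_core import MetabolicModel, ModelValidationError, classify_reactions

__all__ = [
    "GrowthCondition",
    "FluxSolution",
    "ProductionEnvelope",
    "InfeasibleProblemError",
    "fba",
    "fva",
    "max_theoretical_yield",
    "mass_yield",
    "apply_gene_knockouts",
    "single_gene_deletion",
    "production_envelope",
    "MW",
]

FEASIBILITY_TOL = 1e-9
FLUX_ZERO_TOL = 1e-9

#: Molecular weights (g/mol) of the species used in yield reports.
MW = {
    "glucose": 180.16,
    "galactose": 180.16,
    "glutamine": 146.15,
    "indigoidine": 248.20,
    "alpha_ketoglutarate": 146.10,
}

#: Overflow metabolites whose secretion stays open under the byproduct
#: policy (BiGG exchange ids): gluconate, 2-ketogluconate, 3-oxoadipate,
#: catechol, lactate, methanol, CO2, acetate — plus water and protons,
#: which every aerobic balance requires.
DEFAULT_ALLOWED_BYPRODUCTS = (
    "EX_glcn_e",
    "EX_2dhglcn_e",
    "EX_3oxoadp_e",
    "EX_catechol_e",
    "EX_lac__D_e",
    "EX_lac__L_e",
    "EX_meoh_e",
    "EX_co2_e",
    "EX_ac_e",
    "EX_h2o_e",
    "EX_h_e",
)


class InfeasibleProblemError(RuntimeError):
    """Base LP is infeasible; carries the solver status."""

    def __init__(self, message: str, status: str = "infeasible"):
        super().__init__(message)
        self.status = status


@dataclass(frozen=True)
class GrowthCondition:
    """Environmental constraints for a simulation.

    ``uptake_rate`` fixes the substrate exchange flux at ``-uptake_rate``
    (BiGG sign convention: uptake is negative). ``atpm_value`` is the
    lower bound on the ATP maintenance reaction.
    """

    substrate_exchange: str
    uptake_rate: float = 6.3
    atpm_reaction: str | None = None
    atpm_value: float = 0.97
    aerobic: bool = True
    oxygen_exchange: str | None = None
    allowed_byproducts: tuple[str, ...] = DEFAULT_ALLOWED_BYPRODUCTS
    closed_exchanges: tuple[str, ...] = ()

    def __post_init__(self):
        if self.uptake_rate <= 0:
            raise ModelValidationError("uptake_rate must be > 0")
        if self.atpm_value < 0:
            raise ModelValidationError("atpm_value must be >= 0")


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded
    objective_value: float | None
    fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class ProductionEnvelope:
    """Attainable min/max product yield over a grid of biomass fractions."""

    biomass_fractions: np.ndarray
    min_yield: np.ndarray
    max_yield: np.ndarray
    mty: float
    max_biomass: float
    product_exchange: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "biomass_fraction": self.biomass_fractions,
                "min_yield": self.min_yield,
                "max_yield": self.max_yield,
            }
        )


# ---------------------------------------------------------------------------
# LP assembly
# ---------------------------------------------------------------------------


class LinearProblem:
    """Cached steady-state LP for one model; bounds are overridable per solve."""

    def __init__(self, model: MetabolicModel):
        self.model = model
        S, mets, rxns = model.stoichiometric_matrix()
        self.S = sparse.csr_matrix(S)
        self.rxn_index = {rid: j for j, rid in enumerate(rxns)}
        self.rxn_ids = rxns
        self.lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
        self.ub = np.array([r.upper_bound for r in model.reactions], dtype=float)

    def bounds_for(self, overrides: Mapping[str, tuple[float, float]] | None = None):
        lb, ub = self.lb.copy(), self.ub.copy()
        if overrides:
            for rid, (lo, hi) in overrides.items():
                j = self.rxn_index.get(rid)
                if j is None:
                    raise ModelValidationError(f"unknown reaction in constraint: {rid}")
                lb[j], ub[j] = lo, hi
        return lb, ub

    def solve(
        self,
        objective: str,
        sense: str = "max",
        overrides: Mapping[str, tuple[float, float]] | None = None,
        want_fluxes: bool = True,
    ) -> FluxSolution:
        j_obj = self.rxn_index.get(objective)
        if j_obj is None:
            raise ModelValidationError(f"objective reaction {objective} not in model")
        lb, ub = self.bounds_for(overrides)
        if np.any(lb > ub + 1e-12):
            return FluxSolution(status="infeasible", objective_value=None)
        c = np.zeros(len(self.rxn_ids))
        c[j_obj] = -1.0 if sense == "max" else 1.0
        res = linprog(
            c,
            A_eq=self.S,
            b_eq=np.zeros(self.S.shape[0]),
            bounds=np.column_stack([lb, ub]),
            method="highs",
        )
        if res.status == 2:
            return FluxSolution(status="infeasible", objective_value=None)
        if res.status == 3:
            return FluxSolution(status="unbounded", objective_value=None)
        if not res.success:  # pragma: no cover - solver hiccup
            return FluxSolution(status="infeasible", objective_value=None)
        value = float(res.x[j_obj]) + 0.0  # normalise IEEE -0.0
        fluxes = dict(zip(self.rxn_ids, res.x)) if want_fluxes else {}
        return FluxSolution(status="optimal", objective_value=value, fluxes=fluxes)


def condition_overrides(
    model: MetabolicModel,
    condition: GrowthCondition,
    enforce_byproduct_policy: bool = False,
    byproduct_exempt: Iterable[str] = (),
) -> dict[str, tuple[float, float]]:
    """Translate a :class:`GrowthCondition` into per-reaction bound overrides."""
    ov: dict[str, tuple[float, float]] = {}
    if not model.has_reaction(condition.substrate_exchange):
        raise ModelValidationError(
            f"substrate exchange {condition.substrate_exchange} not in model"
        )
    u = condition.uptake_rate
    ov[condition.substrate_exchange] = (-u, -u)
    if condition.atpm_reaction is not None:
        r = model.reaction(condition.atpm_reaction)
        ov[condition.atpm_reaction] = (condition.atpm_value, r.upper_bound)
    if not condition.aerobic and condition.oxygen_exchange is not None:
        r = model.reaction(condition.oxygen_exchange)
        ov[condition.oxygen_exchange] = (0.0, r.upper_bound)
    for rid in condition.closed_exchanges:
        if rid != condition.substrate_exchange:
            ov[rid] = (0.0, 0.0)
    if enforce_byproduct_policy:
        allowed = set(condition.allowed_byproducts) | set(byproduct_exempt)
        allowed.add(condition.substrate_exchange)
        cls = classify_reactions(model)
        for rid, cat in cls.items():
            if cat == "exchange" and rid not in allowed and rid not in ov:
                r = model.reaction(rid)
                ov[rid] = (r.lower_bound, min(r.upper_bound, 0.0))
    return ov


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def fba(
    model: MetabolicModel,
    condition: GrowthCondition,
    objective: str | None = None,
    sense: str = "max",
    extra_constraints: Mapping[str, tuple[float, float]] | None = None,
    enforce_byproduct_policy: bool = False,
    byproduct_exempt: Iterable[str] = (),
    _lp: LinearProblem | None = None,
) -> FluxSolution:
    """Flux balance analysis: optimise one reaction flux over the flux cone.

    Infeasibility and unboundedness are reported in ``FluxSolution.status``,
    not raised.
    """
    objective = objective or model.objective_reaction
    if objective is None:
        raise ModelValidationError("no objective reaction given and model has none")
    lp = _lp or LinearProblem(model)
    ov = condition_overrides(
        model, condition, enforce_byproduct_policy, byproduct_exempt
    )
    if extra_constraints:
        ov.update(extra_constraints)
    return lp.solve(objective, sense=sense, overrides=ov)


def fva(
    model: MetabolicModel,
    condition: GrowthCondition,
    reactions: Sequence[str] | None = None,
    objective_fraction: float = 1.0,
    objective: str | None = None,
    extra_constraints: Mapping[str, tuple[float, float]] | None = None,
    enforce_byproduct_policy: bool = False,
    byproduct_exempt: Iterable[str] = (),
) -> dict[str, tuple[float, float]]:
    """Flux variability analysis under ``objective >= fraction * optimum``."""
    if not 0 <= objective_fraction <= 1:
        raise ModelValidationError("objective_fraction must lie in [0, 1]")
    objective = objective or model.objective_reaction
    lp = LinearProblem(model)
    base = fba(
        model, condition, objective, "max", extra_constraints,
        enforce_byproduct_policy, byproduct_exempt, _lp=lp,
    )
    if not base.optimal:
        raise InfeasibleProblemError(
            f"FVA base problem is {base.status}", status=base.status
        )
    ov = condition_overrides(model, condition, enforce_byproduct_policy, byproduct_exempt)
    if extra_constraints:
        ov.update(extra_constraints)
    j = lp.rxn_index[objective]
    floor = objective_fraction * base.objective_value
    lo_obj = ov.get(objective, (lp.lb[j], lp.ub[j]))
    ov[objective] = (max(lo_obj[0], floor), lo_obj[1])

    reactions = list(reactions) if reactions is not None else list(lp.rxn_ids)
    out: dict[str, tuple[float, float]] = {}
    for rid in reactions:
        lo = lp.solve(rid, "min", ov, want_fluxes=False)
        hi = lp.solve(rid, "max", ov, want_fluxes=False)
        out[rid] = (
            lo.objective_value if lo.optimal else np.nan,
            hi.objective_value if hi.optimal else np.nan,
        )
    return out


def max_theoretical_yield(
    model: MetabolicModel,
    condition: GrowthCondition,
    product_exchange: str,
    atpm_active: bool = True,
    enforce_byproduct_policy: bool = False,
) -> float:
    """Maximum theoretical yield (mol product / mol substrate) at fixed uptake.

    ``atpm_active=False`` drops the maintenance demand; the yield is then
    invariant to the uptake magnitude (homogeneity of the flux cone).
    """
    cond = condition if atpm_active else replace(condition, atpm_value=0.0)
    sol = fba(
        model, cond, product_exchange, "max",
        enforce_byproduct_policy=enforce_byproduct_policy,
        byproduct_exempt=(product_exchange,),
    )
    if not sol.optimal or sol.objective_value <= FLUX_ZERO_TOL:
        warnings.warn(
            f"no feasible production of {product_exchange}; reporting yield 0",
            stacklevel=2,
        )
        return 0.0
    return sol.objective_value / condition.uptake_rate


def mass_yield(molar_yield: float, mw_product: float, mw_substrate: float) -> float:
    """Convert mol/mol to g product per g substrate."""
    if mw_product <= 0 or mw_substrate <= 0:
        raise ModelValidationError("molecular weights must be positive")
    return molar_yield * mw_product / mw_substrate


def apply_gene_knockouts(model: MetabolicModel, genes: Iterable[str]) -> MetabolicModel:
    """Zero the bounds of every reaction whose GPR evaluates inactive.

    Reactions with no gene association are untouched.
    """
    genes = set(genes)
    unknown = sorted(genes - set(model.genes))
    if unknown:
        raise ModelValidationError(f"unknown gene id(s): {', '.join(unknown)}")
    out = model.copy()
    for r in out.reactions:
        if not r.gpr.is_empty and not r.gpr.evaluate(genes):
            r.lower_bound = 0.0
            r.upper_bound = 0.0
    return out


def single_gene_deletion(
    model: MetabolicModel,
    condition: GrowthCondition,
    threshold: float = 1e-3,
) -> pd.DataFrame:
    """One-FBA-per-gene deletion screen against the growth objective.

    Returns a frame indexed by gene with columns ``growth`` and
    ``essential`` (growth below ``threshold`` x wild-type optimum).
    """
    wt = fba(model, condition)
    wt_growth = wt.objective_value if wt.optimal else 0.0
    rows = []
    for gene in model.genes:
        ko_bounds: dict[str, tuple[float, float]] = {}
        for r in model.reactions:
            if not r.gpr.is_empty and gene in r.gpr.genes and not r.gpr.evaluate({gene}):
                ko_bounds[r.id] = (0.0, 0.0)
        sol = fba(model, condition, extra_constraints=ko_bounds)
        growth = sol.objective_value if sol.optimal else 0.0
        rows.append((gene, growth, growth < threshold * max(wt_growth, FLUX_ZERO_TOL)))
    return pd.DataFrame(rows, columns=["gene", "growth", "essential"]).set_index("gene")


def production_envelope(
    model: MetabolicModel,
    condition: GrowthCondition,
    product_exchange: str,
    n_points: int = 20,
    enforce_byproduct_policy: bool = False,
) -> ProductionEnvelope:
    """Min/max product yield at biomass fixed to each fraction of its optimum.

    Grid point f=0 covers the non-growing states. Infeasible grid points
    are recorded as NaN, not raised.
    """
    if n_points < 2:
        raise ModelValidationError("n_points must be >= 2")
    lp = LinearProblem(model)
    biomass = model.objective_reaction
    if biomass is None:
        raise ModelValidationError("model has no objective (biomass) reaction")
    ov = condition_overrides(
        model, condition, enforce_byproduct_policy, byproduct_exempt=(product_exchange,)
    )
    growth = lp.solve(biomass, "max", ov, want_fluxes=False)
    if not growth.optimal:
        raise InfeasibleProblemError(
            f"growth problem is {growth.status}", status=growth.status
        )
    mu_max = growth.objective_value
    mty = max_theoretical_yield(
        model, condition, product_exchange,
        enforce_byproduct_policy=enforce_byproduct_policy,
    )
    fracs = np.linspace(0.0, 1.0, n_points)
    lo = np.full(n_points, np.nan)
    hi = np.full(n_points, np.nan)
    for i, f in enumerate(fracs):
        ovf = dict(ov)
        ovf[biomass] = (f * mu_max, f * mu_max)
        mn = lp.solve(product_exchange, "min", ovf, want_fluxes=False)
        mx = lp.solve(product_exchange, "max", ovf, want_fluxes=False)
        if mn.optimal:
            lo[i] = mn.objective_value / condition.uptake_rate
        if mx.optimal:
            hi[i] = mx.objective_value / condition.uptake_rate
    return ProductionEnvelope(
        biomass_fractions=fracs,
        min_yield=lo,
        max_yield=hi,
        mty=mty,
        max_biomass=mu_max,
        product_exchange=product_exchange,
    )
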