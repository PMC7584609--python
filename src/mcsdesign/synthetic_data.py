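"""Desk-scale generators for every input the design pipeline consumes.

Three families:

* **Toy coupled networks** with cofactor-forced coupling whose minimal cut
  sets are known by construction: the substrate is oxidised to a growth
  precursor plus NADH, and NADH can be reoxidised either by the
  product-forming reaction or by one or more futile respiration sinks.
  Cutting all sinks forces every admissible flux state to secrete product
  — the strong-coupling motif at its smallest.
* **Random branched pathway networks** (backbone chain plus parallel
  productive / non-productive edges), growth-feasible by construction, as
  non-trivial instances for the cut-set enumerator.
* **Fermentation time courses** with Luedeking-Piret product kinetics
  (``dP/dt = alpha*dX/dt + beta*X``), so growth-associated and
  stationary-phase production regimes can be generated at will; plus
  RB-TnSeq-like gene essentiality tables.

All randomness flows through one explicitly passed seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constraint_engine import GrowthCondition, fba
from .ferm_analytics import (
    DCW_PER_OD600,
    STANDARD_CURVE_INTERCEPT,
    STANDARD_CURVE_SLOPE,
    FermentationTimeCourse,
)
from .model_core import MetabolicModel, Metabolite, Reaction
from .target_triage import EssentialityTable

__all__ = [
    "ToyCouplingParams",
    "FermSimParams",
    "make_toy_coupled_model",
    "make_random_network",
    "make_essentiality_table",
    "simulate_fermentation",
    "toy_condition",
]

DEFAULT_UPTAKE = 6.3  # mmol/gDW/h, the reference glucose uptake rate
DEFAULT_ATPM = 0.97  # mmol ATP/gDW/h non-growth maintenance


@dataclass(frozen=True)
class ToyCouplingParams:
    """Configuration of the toy strong-coupling network.

    ``n_extra_nadh_sinks`` adds futile NADH sinks beyond the first, so the
    unique minimal cut set has size ``1 + n_extra_nadh_sinks``.
    """

    n_extra_nadh_sinks: int = 0
    include_atpm: bool = False
    include_bypass_carbon: bool = False
    uptake: float = DEFAULT_UPTAKE
    seed: int = 0

    def __post_init__(self):
        if self.n_extra_nadh_sinks < 0:
            raise ValueError("n_extra_nadh_sinks must be >= 0")
        if self.uptake <= 0:
            raise ValueError("uptake must be > 0")


def make_toy_coupled_model(p: ToyCouplingParams) -> tuple[MetabolicModel, dict]:
    """Build the toy network and its ground-truth record.

    Network (BiGG sign convention, substrate uptake negative)::

        EX_S:   glc_e <->            (uptake, bounds [-uptake, 0])
        OXI:    glc_e + nad_c -> 2 acc_c + nadh_c
        PRD:    acc_c + nadh_c -> prd_e + nad_c [+ atp_c]
        GRW:    acc_c ->             (biomass objective)
        RSP_i:  nadh_c -> nad_c [+ atp_c]   (i = 1 .. 1+k, futile sinks)
        EX_P:   prd_e ->

    Ground truth (derived from the NADH/carbon balance and re-verified by
    LP in the tests): MTY of P is 1.0 mol/mol, and for any demanded yield
    fraction above the trivial 0 with demanded biomass at 10% of maximum,
    the unique minimal cut set is *all* RSP sinks.
    """
    k = p.n_extra_nadh_sinks
    mets = [
        Metabolite("glc_e", "substrate", "e"),
        Metabolite("s2_e", "bypass substrate", "e"),
        Metabolite("acc_c", "growth precursor", "c"),
        Metabolite("nad_c", "NAD+", "c"),
        Metabolite("nadh_c", "NADH", "c"),
        Metabolite("prd_e", "product", "e"),
        Metabolite("atp_c", "ATP", "c"),
    ]
    if not p.include_bypass_carbon:
        mets = [m for m in mets if m.id != "s2_e"]
    if not p.include_atpm:
        mets = [m for m in mets if m.id != "atp_c"]

    atp_out = {"atp_c": 1.0} if p.include_atpm else {}
    rxns = [
        Reaction("EX_S", {"glc_e": -1.0}, lower_bound=-p.uptake, upper_bound=0.0),
        Reaction(
            "OXI",
            {"glc_e": -1.0, "nad_c": -1.0, "acc_c": 2.0, "nadh_c": 1.0},
            lower_bound=0.0,
            gpr="g_oxi",
        ),
        Reaction(
            "PRD",
            {"acc_c": -1.0, "nadh_c": -1.0, "prd_e": 1.0, "nad_c": 1.0, **atp_out},
            lower_bound=0.0,
            gpr="g_prd",
        ),
        Reaction("GRW", {"acc_c": -1.0}, lower_bound=0.0),
        Reaction("EX_P", {"prd_e": -1.0}, lower_bound=0.0),
    ]
    sinks = []
    for i in range(1, k + 2):
        rid = f"RSP_{i}"
        rxns.append(
            Reaction(
                rid,
                {"nadh_c": -1.0, "nad_c": 1.0, **atp_out},
                lower_bound=0.0,
                gpr=f"g_rsp_{i}",
            )
        )
        sinks.append(rid)
    if p.include_atpm:
        rxns.append(Reaction("ATPM", {"atp_c": -1.0}, lower_bound=0.0))
    if p.include_bypass_carbon:
        rxns.append(
            Reaction("EX_S2", {"s2_e": -1.0}, lower_bound=0.0, upper_bound=0.0)
        )
        rxns.append(
            Reaction(
                "BYP", {"s2_e": -1.0, "acc_c": 1.0}, lower_bound=0.0, gpr="g_byp"
            )
        )

    model = MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        objective_reaction="GRW",
        name=f"toy_coupled_k{k}",
    )
    ground_truth = {
        "mty_mol_per_mol": 1.0,
        "cmcs": [sorted(sinks)],
        "cmcs_size": 1 + k,
        "product_exchange": "EX_P",
        "substrate_exchange": "EX_S",
        "gene_map": {rid: f"g_rsp_{i}" for i, rid in enumerate(sinks, start=1)},
    }
    return model, ground_truth


def toy_condition(p: ToyCouplingParams) -> GrowthCondition:
    """The growth condition matching a toy model's construction."""
    return GrowthCondition(
        substrate_exchange="EX_S",
        uptake_rate=p.uptake,
        atpm_reaction="ATPM" if p.include_atpm else None,
        atpm_value=DEFAULT_ATPM if p.include_atpm else 0.0,
    )


# ---------------------------------------------------------------------------
# Random branched networks
# ---------------------------------------------------------------------------


def make_random_network(
    n_mets: int,
    n_rxns: int,
    seed: int | np.random.Generator = 0,
    p_productive: float = 0.5,
) -> MetabolicModel:
    """Random growth-feasible branched pathway with a product exchange.

    A linear backbone ``s_e -> m1 -> ... -> m_last -> biomass`` guarantees
    growth; the remaining reaction budget adds parallel edges at random
    backbone positions, each either productive (also secreting the product
    P) or futile. Every internal reaction carries its own single gene.
    Deterministic for a fixed seed; the generated model always satisfies
    the model invariants and grows under its default condition (asserted
    at generation time).
    """
    if n_mets < 3:
        raise ValueError("n_mets must be >= 3")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_internal = n_mets - 2  # minus substrate and product species
    mets = [Metabolite("s_e", "substrate", "e")]
    mets += [Metabolite(f"m{i}_c", f"intermediate {i}", "c") for i in range(1, n_internal + 1)]
    mets += [Metabolite("p_e", "product", "e")]
    chain = ["s_e"] + [f"m{i}_c" for i in range(1, n_internal + 1)]

    rxns = [
        Reaction("EX_S", {"s_e": -1.0}, lower_bound=-10.0, upper_bound=0.0),
        Reaction("EX_P", {"p_e": -1.0}, lower_bound=0.0),
        Reaction("GRW", {chain[-1]: -1.0}, lower_bound=0.0),
    ]
    gene_counter = 0

    def next_gene():
        nonlocal gene_counter
        gene_counter += 1
        return f"g{gene_counter:03d}"

    for j in range(len(chain) - 1):
        rxns.append(
            Reaction(
                f"R{j + 1}",
                {chain[j]: -1.0, chain[j + 1]: 1.0},
                lower_bound=0.0,
                gpr=next_gene(),
            )
        )
    n_backbone = len(chain) - 1
    budget = max(0, n_rxns - len(rxns))
    if n_rxns < n_mets:
        raise ValueError("n_rxns must be >= n_mets")
    for _ in range(budget):
        j = int(rng.integers(0, n_backbone))
        productive = rng.random() < p_productive
        stoich = {chain[j]: -1.0, chain[j + 1]: 1.0}
        if productive:
            stoich["p_e"] = 1.0
            rid_base = f"ALT{j + 1}"
        else:
            rid_base = f"PAR{j + 1}"
        rid = rid_base
        i = 1
        existing = {r.id for r in rxns}
        while rid in existing:
            i += 1
            rid = f"{rid_base}_{i}"
        rxns.append(Reaction(rid, stoich, lower_bound=0.0, gpr=next_gene()))

    model = MetabolicModel(
        metabolites=mets, reactions=rxns, objective_reaction="GRW", name="random_net"
    )
    cond = GrowthCondition(substrate_exchange="EX_S", uptake_rate=10.0, atpm_value=0.0)
    sol = fba(model, cond)
    if not sol.optimal or sol.objective_value <= 1e-9:
        raise RuntimeError("generated network is not growth-feasible")  # pragma: no cover
    return model


def make_essentiality_table(
    genes,
    essential_ids,
    seed: int | None = None,
    unknown_fraction: float = 0.0,
    source: str = "synthetic-RB-TnSeq",
) -> EssentialityTable:
    """Deterministic essentiality table: named genes essential, rest
    dispensable; optionally a seeded fraction of the dispensable genes is
    downgraded to ``unknown`` to emulate low-coverage fitness data."""
    genes = list(genes)
    essential = set(essential_ids)
    stray = essential - set(genes)
    if stray:
        raise ValueError(f"essential ids not in gene list: {sorted(stray)}")
    calls = {g: ("essential" if g in essential else "dispensable") for g in genes}
    if unknown_fraction > 0:
        rng = np.random.default_rng(seed)
        dispensable = sorted(g for g in genes if g not in essential)
        n_unknown = int(round(unknown_fraction * len(dispensable)))
        for g in rng.choice(dispensable, size=n_unknown, replace=False):
            calls[str(g)] = "unknown"
    return EssentialityTable(calls=calls, source=source)


# ---------------------------------------------------------------------------
# Fermentation simulator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FermSimParams:
    """Luedeking-Piret batch/fed-batch simulation parameters.

    ``alpha`` (g product/gDCW) scales growth-associated production,
    ``beta`` (g product/gDCW/h) non-growth-associated production, the two
    regimes the engineered vs control strains exhibit. Defaults emulate a
    minimal-medium cultivation on a 10 g/L sugar charge.
    """

    mu_max: float = 0.35  # 1/h
    yield_xs: float = 0.40  # gDCW / g substrate
    alpha: float = 0.5  # g product / gDCW
    beta: float = 0.0  # g product / gDCW / h
    initial_substrate: float = 10.0  # g/L
    initial_biomass: float = 0.038  # gDCW/L (OD600 0.1)
    feed_schedule: tuple[tuple[float, float], ...] = ()  # (time_h, substrate_g/L)
    noise_sd: float = 0.05  # relative (multiplicative Gaussian)
    t_end: float = 36.0  # h
    sample_interval: float = 1.0  # h
    seed: int = 0

    def __post_init__(self):
        for name in ("mu_max", "yield_xs", "initial_substrate", "initial_biomass"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("alpha", "beta", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def simulate_fermentation(p: FermSimParams) -> FermentationTimeCourse:
    """Simulate a cultivation and return noisy sampled observations.

    Biomass grows exponentially at ``mu_max`` until the substrate charge
    (initial plus feeds) is exhausted, debiting substrate at
    ``1/yield_xs`` g per gDCW formed; product follows
    ``dP/dt = alpha*dX/dt + beta*X``. Non-growth-associated production
    continues after carbon depletion (drawing on reserves, as observed for
    stationary-phase producers), so the substrate ledger tracks biomass
    only. Observables (OD600, OD612, substrate, product) carry
    multiplicative Gaussian noise; the true trajectories are attached as
    ``tc.truth`` for oracle use.
    """
    rng = np.random.default_rng(p.seed)
    dt = 0.05
    n_steps = int(round(p.t_end / dt))
    times = [0.0]
    X, S, P = [p.initial_biomass], [p.initial_substrate], [0.0]
    feeds = sorted(p.feed_schedule)
    fi = 0
    x, s, prod = p.initial_biomass, p.initial_substrate, 0.0
    for step in range(1, n_steps + 1):
        t = step * dt
        while fi < len(feeds) and feeds[fi][0] <= t:
            s += feeds[fi][1]
            fi += 1
        dx = p.mu_max * x * dt
        dx = min(dx, p.yield_xs * s)  # growth stops at substrate exhaustion
        s -= dx / p.yield_xs
        prod += p.alpha * dx + p.beta * x * dt
        x += dx
        times.append(t)
        X.append(x)
        S.append(s)
        P.append(prod)
    times, X, S, P = map(np.asarray, (times, X, S, P))

    stride = max(1, int(round(p.sample_interval / dt)))
    idx = np.arange(0, len(times), stride)
    t_s, x_s, s_s, p_s = times[idx], X[idx], S[idx], P[idx]

    def noisy(arr):
        return np.clip(arr * (1.0 + p.noise_sd * rng.standard_normal(arr.shape)), 0.0, None)

    od600 = noisy(x_s / DCW_PER_OD600)
    od612 = noisy((p_s - STANDARD_CURVE_INTERCEPT) / STANDARD_CURVE_SLOPE)
    tc = FermentationTimeCourse(
        time=t_s,
        substrate=noisy(s_s),
        product=noisy(p_s),
        od600=od600,
        od612=od612,
        feed_events=[(t, g) for t, g in feeds],
        label=f"sim_a{p.alpha}_b{p.beta}_seed{p.seed}",
    )
    tc.truth = {"time": t_s, "biomass": x_s, "substrate": s_s, "product": p_s}
    return tc
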