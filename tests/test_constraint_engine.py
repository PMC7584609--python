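"""LP layer: FBA/FVA correctness against an independent solver, yields, deletions."""

from dataclasses import replace

import numpy as np
import pytest

from mcsdesign.constraint_engine import (
    MW,
    GrowthCondition,
    InfeasibleProblemError,
    apply_gene_knockouts,
    fba,
    fva,
    mass_yield,
    max_theoretical_yield,
    production_envelope,
    single_gene_deletion,
)
from mcsdesign.model_core import ModelValidationError
from mcsdesign.model_io import write_bigg_json
from mcsdesign.synthetic_data import ToyCouplingParams, make_toy_coupled_model, toy_condition


def _cobra_fba(model, cond, objective, sense="maximize", knockouts=()):
    """Independent oracle: solve the same FBA with cobrapy/GLPK."""
    import cobra

    import tempfile, os

    with tempfile.TemporaryDirectory() as d:
        path = os.path.join(d, "m.json")
        write_bigg_json(model, path)
        cb = cobra.io.load_json_model(path)
    cb.reactions.get_by_id(cond.substrate_exchange).bounds = (
        -cond.uptake_rate,
        -cond.uptake_rate,
    )
    if cond.atpm_reaction:
        rx = cb.reactions.get_by_id(cond.atpm_reaction)
        rx.lower_bound = cond.atpm_value
    for gid in knockouts:
        cb.genes.get_by_id(gid).knock_out()
    cb.objective = cb.reactions.get_by_id(objective)
    cb.objective_direction = sense
    sol = cb.optimize()
    return sol


def test_fba_toy_growth_matches_hand_lp(toy, toy_cond):
    """Carbon balance: 2 precursors per substrate, one may feed the product,
    so max growth routes everything to biomass: mu = 2 * uptake."""
    model, _, cond = toy
    sol = fba(model, cond)
    assert sol.optimal
    assert sol.objective_value == pytest.approx(2 * cond.uptake_rate, rel=1e-9)
    # steady state residual
    S, mets, rxns = model.stoichiometric_matrix()
    v = np.array([sol.fluxes[r] for r in rxns])
    assert np.abs(S @ v).max() < 1e-6 * max(1.0, np.abs(v).max())


def test_fba_agrees_with_cobra_oracle(toy, toy_cond):
    model, _, cond = toy
    ours = fba(model, cond)
    theirs = _cobra_fba(model, cond, "GRW")
    assert ours.objective_value == pytest.approx(theirs.objective_value, rel=1e-6)
    ours_p = fba(model, cond, objective="EX_P")
    theirs_p = _cobra_fba(model, cond, "EX_P")
    assert ours_p.objective_value == pytest.approx(theirs_p.objective_value, rel=1e-6)


def test_fba_infeasible_when_atpm_exceeds_supply():
    params = ToyCouplingParams(include_atpm=True)
    model, _ = make_toy_coupled_model(params)
    cond = replace(toy_condition(params), atpm_value=1e6)
    sol = fba(model, cond)
    assert sol.status == "infeasible" and sol.objective_value is None


def test_fva_brackets_fba_and_blocked_reactions(toy, toy_cond):
    model, _, cond = toy
    sol = fba(model, cond)
    ranges = fva(model, cond, objective_fraction=0.9)
    for rid, (lo, hi) in ranges.items():
        assert lo <= hi + 1e-9
    # at fraction 1.0 the FBA solution must lie inside every interval
    ranges_full = fva(model, cond, objective_fraction=1.0)
    for rid, (lo, hi) in ranges_full.items():
        assert lo - 1e-6 <= sol.fluxes[rid] <= hi + 1e-6
    blocked = model.copy()
    blocked.reaction("RSP_1").lower_bound = 0.0
    blocked.reaction("RSP_1").upper_bound = 0.0
    lo, hi = fva(blocked, cond, reactions=["RSP_1"], objective_fraction=0.0)["RSP_1"]
    assert lo == pytest.approx(0.0, abs=1e-9) and hi == pytest.approx(0.0, abs=1e-9)


def test_fva_positive_product_range_after_sink_removal(toy, toy_cond):
    """The strong-coupling signature: with the futile NADH sink removed,
    even the minimum product flux is positive at zero demanded growth."""
    model, _, cond = toy
    cut = model.copy()
    cut.reaction("RSP_1").lower_bound = 0.0
    cut.reaction("RSP_1").upper_bound = 0.0
    lo, hi = fva(cut, cond, reactions=["EX_P"], objective_fraction=0.0)["EX_P"]
    assert lo > 0 and hi > 0
    assert lo == pytest.approx(cond.uptake_rate, rel=1e-6)


def test_fva_raises_on_infeasible_base():
    params = ToyCouplingParams(include_atpm=True)
    model, _ = make_toy_coupled_model(params)
    cond = replace(toy_condition(params), atpm_value=1e6)
    with pytest.raises(InfeasibleProblemError) as exc:
        fva(model, cond)
    assert exc.value.status == "infeasible"


def test_mty_toy_is_one_and_uptake_invariant(toy):
    model, truth, cond = toy
    assert max_theoretical_yield(model, cond, "EX_P") == pytest.approx(
        truth["mty_mol_per_mol"], rel=1e-9
    )
    # homogeneity of the flux cone: doubling uptake leaves the yield alone
    p2 = ToyCouplingParams(uptake=2 * cond.uptake_rate)
    model2, _ = make_toy_coupled_model(p2)
    y2 = max_theoretical_yield(model2, toy_condition(p2), "EX_P", atpm_active=False)
    assert y2 == pytest.approx(truth["mty_mol_per_mol"], rel=1e-9)


def test_mty_zero_production_warns():
    params = ToyCouplingParams()
    model, _ = make_toy_coupled_model(params)
    model.reaction("PRD").upper_bound = 0.0
    with pytest.warns(UserWarning, match="no feasible production"):
        y = max_theoretical_yield(model, toy_condition(params), "EX_P")
    assert y == 0.0


@pytest.mark.parametrize(
    "molar,mw_product,mw_substrate,expected",
    [
        (1.141, MW["glutamine"], MW["glucose"], 0.93),
        (0.537, MW["indigoidine"], MW["glucose"], 0.74),
        (0.556, MW["indigoidine"], MW["galactose"], 0.77),
        (1.320, MW["alpha_ketoglutarate"], MW["glucose"], 1.07),
        (1.181, MW["glutamine"], MW["galactose"], 0.96),
        (1.366, MW["alpha_ketoglutarate"], MW["galactose"], 1.11),
    ],
)
def test_mass_yield_reference_values(molar, mw_product, mw_substrate, expected):
    assert round(mass_yield(molar, mw_product, mw_substrate), 2) == expected


def test_mass_yield_identity_and_validation():
    assert mass_yield(0.42, 100.0, 100.0) == pytest.approx(0.42)
    with pytest.raises(ModelValidationError):
        mass_yield(1.0, -5.0, 180.16)


def test_gene_knockouts_follow_gpr_logic(toy):
    model, _, _ = toy
    ko = apply_gene_knockouts(model, {"g_rsp_1"})
    assert ko.reaction("RSP_1").upper_bound == 0.0
    assert ko.reaction("PRD").upper_bound > 0  # untouched
    assert ko.reaction("GRW").upper_bound > 0  # empty GPR untouched
    with pytest.raises(ModelValidationError, match="ghost"):
        apply_gene_knockouts(model, {"ghost"})


def test_single_gene_deletion_flags_the_oxidation_gene(toy, toy_cond):
    model, _, cond = toy
    table = single_gene_deletion(model, cond)
    assert bool(table.loc["g_oxi", "essential"])  # sole entry into metabolism
    assert not bool(table.loc["g_rsp_1", "essential"])  # PRD reoxidises NADH too
    theirs = _cobra_fba(model, cond, "GRW", knockouts=["g_rsp_1"])
    assert table.loc["g_rsp_1", "growth"] == pytest.approx(
        theirs.objective_value, rel=1e-6
    )


def test_production_envelope_shape_and_coupling_signature(toy, toy_cond):
    model, _, cond = toy
    env = production_envelope(model, cond, "EX_P", n_points=5)
    feas = ~np.isnan(env.max_yield)
    assert np.all(env.min_yield[feas] <= env.max_yield[feas] + 1e-9)
    assert np.nanmax(env.max_yield) <= env.mty + 1e-6
    # wild type at max growth produces nothing
    assert env.max_yield[-1] == pytest.approx(0.0, abs=1e-9)
    # after the cut, min = max = demanded yield wherever feasible
    cut = model.copy()
    cut.reaction("RSP_1").lower_bound = 0.0
    cut.reaction("RSP_1").upper_bound = 0.0
    env_cut = production_envelope(cut, cond, "EX_P", n_points=5)
    feas = ~np.isnan(env_cut.max_yield)
    assert feas.any()
    assert np.allclose(env_cut.min_yield[feas], 1.0, atol=1e-9)
    assert np.allclose(env_cut.max_yield[feas], 1.0, atol=1e-9)
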