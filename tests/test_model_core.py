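"""Model container, GPR boolean logic, IO round trips, reaction classification."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcsdesign.constraint_engine import fba
from mcsdesign.model_core import (
    GPRParseError,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    add_reaction,
    census,
    classify_reactions,
    parse_gpr,
)
from mcsdesign.model_io import (
    INDIGOIDINE_RXN,
    ModelParseError,
    read_bigg_json,
    read_model,
    write_bigg_json,
)


# ---------------------------------------------------------------------------
# GPR parsing and evaluation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "text,knocked,active",
    [
        ("(g1 and g2) or g3", {"g1"}, True),
        ("(g1 and g2) or g3", {"g1", "g3"}, False),
        ("g1 or g2", {"g1"}, True),
        ("g1 and g2", {"g1"}, False),
        ("PP_1444", {"PP_1444"}, False),
        ("PP_1444 AND PP_0001", set(), True),  # keywords case-insensitive
        ("", {"anything"}, True),  # empty marker: no gene association
    ],
)
def test_gpr_evaluation(text, knocked, active):
    assert parse_gpr(text).evaluate(knocked) is active


def test_empty_gpr_is_marker():
    gpr = parse_gpr("   ")
    assert gpr.is_empty and gpr.genes == frozenset() and gpr.to_string() == ""


@pytest.mark.parametrize("bad", ["g1 and", "(g1 or g2", "g1 g2", "and g1", "g1 or or g2"])
def test_gpr_parse_errors_carry_position(bad):
    with pytest.raises(GPRParseError) as exc:
        parse_gpr(bad)
    assert exc.value.position >= 0


_gpr_exprs = st.recursive(
    st.sampled_from(["g0", "g1", "g2", "g3", "g4", "g5"]),
    lambda kids: st.tuples(
        st.sampled_from([" and ", " or "]), st.lists(kids, min_size=2, max_size=3)
    ).map(lambda t: "(" + t[0].join(t[1]) + ")"),
    max_leaves=8,
)


@settings(max_examples=80, deadline=None)
@given(expr=_gpr_exprs)
def test_gpr_truth_table_matches_python_eval(expr):
    """Brute-force oracle: parsed GPR equals Python's own and/or semantics
    over all 2^k gene states (k <= 6)."""
    parsed = parse_gpr(expr)
    genes = sorted(parsed.genes)
    for state in itertools.product([False, True], repeat=len(genes)):
        env = dict(zip(genes, state))
        knocked = {g for g, alive in env.items() if not alive}
        expected = eval(expr, {"__builtins__": {}}, env)  # independent oracle
        assert parsed.evaluate(knocked) is bool(expected)


@settings(max_examples=40, deadline=None)
@given(expr=_gpr_exprs)
def test_gpr_round_trip_preserves_truth_table(expr):
    first = parse_gpr(expr)
    second = parse_gpr(first.to_string())
    genes = sorted(first.genes | second.genes)
    for state in itertools.product([False, True], repeat=len(genes)):
        knocked = {g for g, alive in zip(genes, state) if not alive}
        assert first.evaluate(knocked) == second.evaluate(knocked)


# ---------------------------------------------------------------------------
# Model construction and IO
# ---------------------------------------------------------------------------


def test_reaction_invariants_enforced():
    with pytest.raises(ModelValidationError):
        Reaction("R1", {})
    with pytest.raises(ModelValidationError):
        Reaction("R1", {"a_c": 0.0})
    with pytest.raises(ModelValidationError):
        Reaction("R1", {"a_c": 1.0}, lower_bound=5, upper_bound=-5)


def test_model_rejects_unknown_metabolite_reference():
    with pytest.raises(ModelValidationError, match="unknown metabolite"):
        MetabolicModel(
            metabolites=[Metabolite("a_c")],
            reactions=[Reaction("R1", {"a_c": -1.0, "ghost_c": 1.0})],
        )


def test_bigg_json_round_trip(toy_model, tmp_path):
    path = tmp_path / "toy.json"
    write_bigg_json(toy_model, path)
    back = read_bigg_json(path)
    assert back.reaction_ids == toy_model.reaction_ids
    assert back.metabolite_ids == toy_model.metabolite_ids
    assert back.objective_reaction == toy_model.objective_reaction
    for rid in toy_model.reaction_ids:
        a, b = toy_model.reaction(rid), back.reaction(rid)
        assert a.stoichiometry == b.stoichiometry
        assert (a.lower_bound, a.upper_bound) == (b.lower_bound, b.upper_bound)
        # GPR equality as boolean functions
        genes = sorted(a.gpr.genes | b.gpr.genes)
        for state in itertools.product([False, True], repeat=len(genes)):
            ko = {g for g, alive in zip(genes, state) if not alive}
            assert a.gpr.evaluate(ko) == b.gpr.evaluate(ko)


def test_read_model_error_contracts(tmp_path):
    bad = tmp_path / "bad.json"
    bad.write_text(
        '{"metabolites": [{"id": "a_c", "compartment": "c"}],'
        ' "reactions": [{"id": "R1", "metabolites": {"ghost_c": 1.0}}]}'
    )
    with pytest.raises(ModelParseError, match="ghost_c"):
        read_bigg_json(bad)
    with pytest.raises(ValueError, match="format"):
        read_model(bad, format="hdf5")


def test_sbml_round_trip_via_cobra(toy_model, tmp_path):
    """Write with cobra (independent SBML writer), read back with our
    libsbml-based reader; stoichiometry, bounds and GPRs must survive."""
    cobra = pytest.importorskip("cobra")
    from mcsdesign.model_io import read_sbml

    json_path = tmp_path / "toy.json"
    write_bigg_json(toy_model, json_path)
    cb = cobra.io.load_json_model(str(json_path))
    sbml_path = tmp_path / "toy.xml"
    cobra.io.write_sbml_model(cb, str(sbml_path))
    back = read_sbml(sbml_path)
    assert sorted(back.reaction_ids) == sorted(toy_model.reaction_ids)
    for rid in toy_model.reaction_ids:
        a, b = toy_model.reaction(rid), back.reaction(rid)
        assert a.stoichiometry == b.stoichiometry
        assert a.gpr.genes == b.gpr.genes


# ---------------------------------------------------------------------------
# add_reaction
# ---------------------------------------------------------------------------


def test_add_reaction_conflict_and_validation(toy_model):
    with pytest.raises(ModelValidationError, match="already present"):
        add_reaction(toy_model, toy_model.reaction("PRD").copy())
    orphan = Reaction("NEW", {"unseen_c": -1.0})
    with pytest.raises(ModelValidationError, match="absent metabolite"):
        add_reaction(toy_model, orphan)


def test_add_zero_flux_reaction_leaves_fba_objective_unchanged(toy, toy_cond):
    model, _, cond = toy
    before = fba(model, cond).objective_value
    rxn = Reaction("DEAD_END", {"acc_c": -1.0, "waste_c": 1.0}, lower_bound=0.0, upper_bound=0.0)
    extended = add_reaction(model, rxn, new_metabolites=[Metabolite("waste_c")])
    after = fba(extended, cond).objective_value
    assert after == pytest.approx(before, abs=1e-9)


def test_packaged_indigoidine_reaction_stoichiometry():
    s = INDIGOIDINE_RXN.stoichiometry
    assert s["gln__L_c"] == -2.0 and s["atp_c"] == -2.0 and s["coa_c"] == -2.0
    assert s["fmn_c"] == -2.0 and s["o2_c"] == -2.5
    assert s["ind_c"] == 1.0 and s["h2o_c"] == 1.0
    for mid in ("pap_c", "fmnh2_c", "ppi_c", "amp_c", "pan4p_c", "pi_c"):
        assert s[mid] == 2.0
    # elementally: 2 glutamine in, 1 indigoidine out
    assert INDIGOIDINE_RXN.lower_bound == 0.0


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def test_classification_rules_and_totality(toy):
    model, _, _ = toy
    cls = classify_reactions(model)
    assert set(cls) == set(model.reaction_ids)  # total
    assert cls["EX_S"] == "exchange" and cls["EX_P"] == "exchange"
    assert cls["GRW"] == "biomass"
    assert cls["OXI"] == "gene_associated"
    assert cls["RSP_1"] == "gene_associated"


def test_classification_transport_atpm_spontaneous_no_gpr():
    model = MetabolicModel(
        metabolites=[
            Metabolite("glc_e", compartment="e"),
            Metabolite("glc_c", compartment="c"),
            Metabolite("atp_c", compartment="c"),
        ],
        reactions=[
            Reaction("GLCt", {"glc_e": -1.0, "glc_c": 1.0}),
            Reaction("ATPM", {"atp_c": -1.0}, lower_bound=0.0),
            Reaction("SPONT", {"glc_c": -1.0, "atp_c": 1.0}, lower_bound=0.0, is_spontaneous=True),
            Reaction("ORPHAN", {"glc_c": -1.0, "atp_c": 2.0}, lower_bound=0.0),
            Reaction("DM_atp", {"atp_c": -1.0}, lower_bound=0.0),
        ],
        genes=[],
    )
    cls = classify_reactions(model, atpm_ids=("ATPM",))
    assert cls["GLCt"] == "transport"
    assert cls["ATPM"] == "atpm"
    assert cls["SPONT"] == "spontaneous"
    assert cls["ORPHAN"] == "no_gpr"
    assert cls["DM_atp"] == "demand_or_sink"


def test_census_counts_are_consistent(toy_model):
    c = census(toy_model)
    assert c["n_gene_associated_direct"] + c["n_without_gpr"] == c["n_reactions"]
    assert sum(c["by_category"].values()) == c["n_reactions"]
    assert c["n_without_gpr_structural"] <= c["n_without_gpr"]
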