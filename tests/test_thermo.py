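"""Stoichiometry, balance checking and standard reaction energies."""

from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

import deepseep as ds
from deepseep.thermo import parse_formula

from conftest import PRINTED_TABLE2


# -- species and reaction construction ---------------------------------------

def test_parse_formula_hill_style():
    assert parse_formula("C16H34") == {"C": 16, "H": 34}
    assert parse_formula("CHO3") == {"C": 1, "H": 1, "O": 3}
    with pytest.raises(ValueError):
        parse_formula("16CH")


def test_species_requires_nonempty_formula():
    with pytest.raises(ValueError):
        ds.SpeciesEntry(name="x", formula={})


def test_missing_formation_value_raises_named_error(db):
    db2 = db.without_constant("acetate", "dGf0")
    rxn = ds.Reaction.from_string("toy", "acetate:-1;HCO3-:1")
    with pytest.raises(ds.MissingConstantError, match="acetate"):
        ds.standard_reaction_energy(rxn, db2)


def test_proton_convention_is_zero(db):
    proton = db.get("H+")
    assert proton.dGf0 == 0.0 and proton.dHf0 == 0.0


def test_reaction_rejects_zero_and_one_sided_coefficients():
    with pytest.raises(ValueError):
        ds.Reaction(id="z", label="", coefficients={"A": Fraction(0), "B": Fraction(1)})
    with pytest.raises(ValueError):
        ds.Reaction(id="p", label="", coefficients={"A": Fraction(1), "B": Fraction(2)})


def test_fractional_coefficients_exact():
    rxn = ds.Reaction.from_string("r", "benzoate:-1;acetate:3.75;H+:2.25;HCO3-:-0.5")
    assert rxn.coefficients["acetate"] == Fraction(15, 4)
    assert rxn.coefficients["HCO3-"] == Fraction(-1, 2)


# -- balance checking ---------------------------------------------------------

def test_complete_hexadecane_oxidation_is_balanced(db, reactions):
    report = ds.check_balance(reactions["r3"], db)
    assert report.balanced
    assert all(r == 0 for r in report.element_residuals.values())
    assert report.charge_residual == 0


def test_printed_benzoate_acetogenic_reaction_is_element_unbalanced(db, reactions):
    # the printed stoichiometry omits 4 waters on the reactant side: the
    # products carry 8 excess H and 4 excess O, while charge still balances
    report = ds.check_balance(reactions["r5"], db)
    assert not report.balanced
    assert report.element_residuals["H"] == 8
    assert report.element_residuals["O"] == 4
    assert report.charge_residual == 0


def test_identity_reaction_balances_and_unknown_species_raises(db):
    rxn = ds.Reaction(id="swap", label="", coefficients={"H2": Fraction(-1), "H2(aq)": Fraction(1)})
    report = ds.check_balance(rxn, db)
    assert report.element_residuals["H"] == 0 and report.balanced
    with pytest.raises(ds.UnknownSpeciesError, match="kryptonite"):
        ds.check_balance(ds.Reaction.from_string("k", "kryptonite:-1;H2O:1"), db)


# -- standard energies --------------------------------------------------------

@pytest.mark.parametrize("rid", ["r2", "r3", "r5", "r6"])
def test_table_reproduction_of_standard_gibbs_energies(db, reactions, rid):
    dG0, _ = ds.standard_reaction_energy(reactions[rid], db)
    assert dG0 == pytest.approx(PRINTED_TABLE2[rid][0], abs=1.0)


def test_hydrogenogenic_hexadecane_needs_aqueous_hydrogen_convention(db, reactions):
    dG0, dH0 = ds.standard_reaction_energy(reactions["r1"], db)
    assert dG0 == pytest.approx(1089.1, abs=1.0)
    assert dH0 == pytest.approx(1069.8, abs=1.0)
    # swapping in gas-phase H2 shifts dG0 by -17.6 kJ per mole of H2
    gas_coeffs = dict(reactions["r1"].coefficients)
    gas_coeffs["H2"] = gas_coeffs.pop("H2(aq)")
    dG0_gas, _ = ds.standard_reaction_energy(gas_coeffs, db)
    assert dG0_gas == pytest.approx(dG0 - 17.6 * 17, abs=1e-9)


def test_empty_net_reaction_has_zero_energy(db, reactions):
    combo = ds.linear_combination([reactions["r5"], reactions["r5"]], [1, -1])
    assert combo == {}
    assert ds.standard_reaction_energy(combo, db) == (0.0, 0.0)


def test_unbalanced_reaction_computes_with_warning(db, reactions, caplog):
    import logging

    with caplog.at_level(logging.WARNING, logger="deepseep.thermo"):
        ds.standard_reaction_energy(reactions["r5"], db)
    assert any("unbalanced" in rec.message for rec in caplog.records)


def test_energy_oracle_brute_force(db, reactions):
    for rxn in reactions.values():
        expect_g = sum(float(nu) * db.get(n).dGf0 for n, nu in rxn.coefficients.items())
        expect_h = sum(float(nu) * db.get(n).dHf0 for n, nu in rxn.coefficients.items())
        dG0, dH0 = ds.standard_reaction_energy(rxn, db)
        assert dG0 == pytest.approx(expect_g, abs=1e-9)
        assert dH0 == pytest.approx(expect_h, abs=1e-9)


# -- back-derivation of formation constants -----------------------------------

def test_derive_hexadecane_gibbs_energy_predicts_complete_oxidation(db, reactions):
    blind = db.without_constant("hexadecane(aq)", "dGf0")
    derived = ds.derive_formation_energy(reactions["r2"], 176.3, blind, "hexadecane(aq)")
    assert derived == pytest.approx(49.5, abs=0.1)
    restored = blind.with_entry(
        ds.SpeciesEntry("hexadecane(aq)", {"C": 16, "H": 34}, 0, ds.Phase.AQUEOUS, derived, -455.8525)
    )
    dG0_r2, _ = ds.standard_reaction_energy(reactions["r2"], restored)
    assert dG0_r2 == pytest.approx(176.3, abs=1e-9)
    dG0_r3, _ = ds.standard_reaction_energy(reactions["r3"], restored)
    assert dG0_r3 == pytest.approx(-407.3, abs=1.0)


def test_derive_benzoate_enthalpy_predicts_acetogenic_reaction(db, reactions):
    blind = db.without_constant("benzoate", "dHf0")
    derived = ds.derive_formation_energy(reactions["r6"], 29.4, blind, "benzoate", which="dHf0")
    assert derived == pytest.approx(-386.0, abs=1.0)
    restored = blind.with_entry(
        ds.SpeciesEntry("benzoate", {"C": 7, "H": 5, "O": 2}, -1, ds.Phase.AQUEOUS, -245.6, derived)
    )
    _, dH0_r5 = ds.standard_reaction_energy(reactions["r5"], restored)
    assert dH0_r5 == pytest.approx(-1091.3, abs=2.0)


def test_derive_single_species_and_error_paths(db, reactions):
    blind = db.without_constant("benzoate", "dGf0")
    # single-species pseudo-reaction: the derived value is the printed value
    assert ds.derive_formation_energy({"benzoate": 1}, -245.6, blind, "benzoate") == pytest.approx(-245.6)
    with pytest.raises(ValueError):  # zero unknowns
        ds.derive_formation_energy(reactions["r5"], -846.3, db, "benzoate")
    with pytest.raises(ValueError):  # two unknowns
        double_blind = blind.without_constant("acetate", "dGf0")
        ds.derive_formation_energy(reactions["r5"], -846.3, double_blind, "benzoate")


# -- algebraic property suite -------------------------------------------------

_POOL = ["H2O", "H+", "HCO3-", "acetate", "SO4-2", "HS-", "H2", "benzoate"]


@st.composite
def small_reactions(draw):
    names = draw(st.lists(st.sampled_from(_POOL), min_size=2, max_size=5, unique=True))
    coeffs = {}
    for i, n in enumerate(names):
        num = draw(st.integers(min_value=1, max_value=12))
        den = draw(st.sampled_from([1, 2, 4]))
        sign = -1 if i == 0 else (1 if i == 1 else draw(st.sampled_from([-1, 1])))
        coeffs[n] = Fraction(sign * num, den)
    return ds.Reaction(id="h", label="", coefficients=coeffs)


@given(small_reactions())
def test_reversal_antisymmetry(db, rxn):
    dG0, dH0 = ds.standard_reaction_energy(rxn, db)
    dG0_rev, dH0_rev = ds.standard_reaction_energy(rxn.reversed(), db)
    assert dG0_rev == pytest.approx(-dG0, abs=1e-9)
    assert dH0_rev == pytest.approx(-dH0, abs=1e-9)


@given(small_reactions(), st.integers(min_value=-6, max_value=6).filter(bool))
def test_scaling(db, rxn, k):
    dG0, _ = ds.standard_reaction_energy(rxn, db)
    dG0_k, _ = ds.standard_reaction_energy(rxn.scaled(k), db)
    assert dG0_k == pytest.approx(k * dG0, abs=1e-9)


@given(
    st.lists(small_reactions(), min_size=1, max_size=4),
    st.lists(st.integers(min_value=-3, max_value=3), min_size=4, max_size=4),
)
def test_hess_law_linearity(db, rxns, weights):
    weights = weights[: len(rxns)]
    combo = ds.linear_combination(rxns, weights)
    dG0_combo, dH0_combo = ds.standard_reaction_energy(combo, db)
    expect_g = sum(w * ds.standard_reaction_energy(r, db)[0] for r, w in zip(rxns, weights))
    expect_h = sum(w * ds.standard_reaction_energy(r, db)[1] for r, w in zip(rxns, weights))
    assert dG0_combo == pytest.approx(expect_g, abs=1e-9)
    assert dH0_combo == pytest.approx(expect_h, abs=1e-9)
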