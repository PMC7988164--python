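"""Mass calculus: printed-value checks, additivity, digestion oracle."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glaquant import chem
from glaquant.chem import (
    DEAMIDATION,
    GAMMA_CARBOXY,
    METHYL,
    OXIDATION,
    PHOSPHO,
    PROPIONAMIDE,
    SULFATION,
    GlycanComposition,
    Peptidoform,
)
from glaquant.constants import PROTON, RESIDUE_MASS

from .conftest import GLA_DOMAIN

AA = "".join(sorted(RESIDUE_MASS))
peptides = st.text(alphabet=AA, min_size=1, max_size=30)


# -- neutral mass and precursor m/z ----------------------------------------

def test_neutral_mass_unmodified():
    assert chem.neutral_mass(Peptidoform("VATVSLPR")) == pytest.approx(841.5021, abs=2e-4)


def test_neutral_mass_with_methyl():
    p = Peptidoform("TTEFWK", ((None, METHYL),))
    assert chem.neutral_mass(p) == pytest.approx(824.4068, abs=2e-4)


def test_unknown_residue_is_named_in_error():
    with pytest.raises(ValueError, match="B"):
        Peptidoform("PEPTIBE")


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        Peptidoform("")


@pytest.mark.parametrize(
    "sequence, mods, z, expected, tol",
    [
        # sulfated, alkylated GluC peptide spanning the end of the GLA domain
        ("FWKQYVDGDQCE", ((11, PROPIONAMIDE), (5, SULFATION)), 2, 834.8189, 0.002),
        # doubly O-glycosylated EGF-like-2 peptide with deamidated Asn
        (
            "QFCKNSADNKVVCSCTE",
            (
                (3, PROPIONAMIDE),
                (13, PROPIONAMIDE),
                (15, PROPIONAMIDE),
                (5, DEAMIDATION),
                (9, DEAMIDATION),
                (6, GlycanComposition.parse("Hex1Xyl2")),
                (16, GlycanComposition.parse("Fuc1HexNAc1Hex1NeuAc1")),
            ),
            3,
            1107.1067,
            0.009,
        ),
        # trypsin autolysis reference peptide
        ("VATVSLPR", (), 2, 421.7584, 0.002),
    ],
)
def test_precursor_mz_reproduces_reference_values(sequence, mods, z, expected, tol):
    assert chem.precursor_mz(Peptidoform(sequence, mods), z) == pytest.approx(
        expected, abs=tol
    )


def test_nonpositive_charge_rejected():
    with pytest.raises(ValueError):
        chem.precursor_mz(Peptidoform("PEPTIDE"), 0)


@settings(derandomize=True, max_examples=30)
@given(peptides)
def test_singly_protonated_precursor_is_neutral_plus_proton(seq):
    p = Peptidoform(seq)
    assert chem.precursor_mz(p, 1) - chem.neutral_mass(p) == pytest.approx(
        PROTON, abs=1e-9
    )


@settings(derandomize=True, max_examples=30)
@given(peptides, st.integers(1, 4))
def test_charge_relation_invariant(seq, z):
    p = Peptidoform(seq)
    neutral = z * chem.precursor_mz(p, z) - z * PROTON
    assert neutral == pytest.approx(chem.neutral_mass(p), abs=1e-6)


def test_modification_additivity():
    p = Peptidoform("TTEFWK")
    for mod in (METHYL, PHOSPHO, DEAMIDATION):
        q = p.with_mods((None, mod))
        assert chem.neutral_mass(q) - chem.neutral_mass(p) == pytest.approx(
            mod.delta_mass, abs=1e-6
        )


def test_mod_target_validation():
    with pytest.raises(ValueError):
        Peptidoform("VATVSLPR", ((1, SULFATION),))  # V is not a Tyr
    with pytest.raises(ValueError):
        Peptidoform("VATVSLPR", ((1, GlycanComposition.parse("Hex1")),))  # not S/T/N


# -- glycan compositions ----------------------------------------------------

@pytest.mark.parametrize(
    "comp, mass, nominal",
    [
        ("HexNAc1Hex1NeuAc1", 656.2276, 656),
        ("HexNAc1Hex1NeuAc2", 947.3230, 947),
        ("", 0.0, 0),
    ],
)
def test_glycan_mass(comp, mass, nominal):
    g = GlycanComposition.parse(comp)
    assert chem.glycan_mass(g) == pytest.approx(mass, abs=1e-3)
    assert g.nominal == nominal


def test_neugc_for_neuac_swap_adds_one_oxygen():
    a = GlycanComposition.parse("HexNAc1Hex1NeuAc2")
    b = GlycanComposition.parse("HexNAc1Hex1NeuAc1NeuGc1")
    assert b.mass - a.mass == pytest.approx(15.99490, abs=1e-4)


def test_negative_glycan_count_rejected():
    with pytest.raises(ValueError):
        GlycanComposition.from_dict({"Hex": -1})


# -- fragment, Y, and immonium ions ----------------------------------------

def test_full_length_y_ion_equals_protonated_precursor():
    p = Peptidoform("CSFEEAR", ((4, GAMMA_CARBOXY),))
    ions = dict(chem.fragment_ions(p, "y", 1))
    assert ions["y7"] == pytest.approx(chem.neutral_mass(p) + PROTON, abs=1e-9)


def test_b_and_a_ion_arithmetic():
    ions = dict(chem.fragment_ions(Peptidoform("GAR"), "ba", 1))
    assert ions["b1"] == pytest.approx(RESIDUE_MASS["G"] + PROTON, abs=1e-4)
    assert ions["a1"] == pytest.approx(30.0338, abs=1e-3)  # b1 - CO


def test_unsupported_series_rejected():
    with pytest.raises(ValueError):
        chem.fragment_ions(Peptidoform("PEPTIDE"), "c", 1)


def test_so3_neutral_loss_ladder_matches_unmodified():
    bare = Peptidoform("FWKQYVDGDQCE", ((11, PROPIONAMIDE),))
    sulfo = bare.with_mods((5, SULFATION))
    loss = dict(chem.fragment_ions(sulfo, "by", 1, neutral_loss="SO3"))
    ref = dict(chem.fragment_ions(bare, "by", 1))
    # fragments spanning Y5 shed the SO3 and coincide with the bare ladder
    for label in ("b5", "b8", "y8", "y11"):
        assert loss[label] == pytest.approx(ref[label], abs=1e-6)
    # fragments not containing Y5 are identical anyway
    assert loss["b4"] == pytest.approx(ref["b4"], abs=1e-9)
    assert loss["y7"] == pytest.approx(ref["y7"], abs=1e-9)


def test_glycopeptide_y_series_reproduces_reference_values():
    p = Peptidoform(
        "TTEFWK",
        ((None, METHYL), (1, GlycanComposition.parse("HexNAc1Hex1NeuAc1"))),
    )
    ions = dict(chem.glycopeptide_y_ions(p))
    assert ions["Y0"] == pytest.approx(825.4141, abs=0.002)
    assert ions["Y1"] == pytest.approx(1028.4935, abs=0.002)  # + HexNAc
    assert ions["Y2"] == pytest.approx(1190.5463, abs=0.002)  # + Hex


def test_y_ions_empty_without_glycan():
    assert chem.glycopeptide_y_ions(Peptidoform("TTEFWK")) == []


def test_immonium_ions():
    assert chem.immonium_mz("Y", [PHOSPHO]) == pytest.approx(216.042, abs=0.002)
    assert chem.immonium_mz("Y") == pytest.approx(136.0757, abs=0.001)
    delta = chem.immonium_mz("Y", [PHOSPHO]) - chem.immonium_mz("Y")
    assert delta == pytest.approx(PHOSPHO.delta_mass, abs=1e-9)


# -- digestion ---------------------------------------------------------------

def test_tryptic_gla_domain_peptides():
    peps = {p.sequence for p in chem.digest(GLA_DOMAIN, "trypsin", 0)}
    assert {"LEEFVQGNLER", "CSFEEAR", "EVFENTER", "TTEFWK"} <= peps
    missed = {p.sequence for p in chem.digest(GLA_DOMAIN, "trypsin", 1)}
    assert "CSFEEAREVFENTER" in missed


def test_digest_coordinates_are_protein_positions():
    peps = {p.sequence: p for p in chem.digest(GLA_DOMAIN, "trypsin", 0, protein_id="FIX")}
    ttefwk = peps["TTEFWK"]
    assert (ttefwk.start, ttefwk.end) == (38, 43)
    assert ttefwk.protein_id == "FIX"


def test_no_cleavage_sites_returns_whole_sequence():
    peps = chem.digest("AAAAAA", "trypsin", 0)
    assert [p.sequence for p in peps] == ["AAAAAA"]


def test_unknown_rule_rejected():
    with pytest.raises(ValueError):
        chem.digest("PEPTIDEK", "pepsin")


def _brute_force_digest(protein, rule, max_missed):
    sites = set(rule.cleavage_sites(protein))
    bounds = sorted({0, len(protein)} | sites)
    out = set()
    for i in bounds:
        for j in bounds:
            if j <= i:
                continue
            if i not in ({0} | sites) or j not in ({len(protein)} | sites):
                continue
            internal = [s for s in sites if i < s < j]
            if len(internal) <= max_missed:
                out.add((i + 1, j, protein[i:j]))
    return out


@settings(derandomize=True, max_examples=60)
@given(
    st.text(alphabet=AA, min_size=1, max_size=60),
    st.sampled_from(["trypsin", "gluc", "aspn", "chymotrypsin"]),
    st.integers(0, 2),
)
def test_digestion_matches_brute_force_enumeration(protein, rule_name, max_missed):
    rule = chem.PROTEASES[rule_name]
    got = {(p.start, p.end, p.sequence) for p in chem.digest(protein, rule, max_missed)}
    assert got == _brute_force_digest(protein, rule, max_missed)


# -- carboxyform and methylform enumeration ---------------------------------

def test_carboxyform_family_is_arithmetic_in_mass():
    p = Peptidoform("LEEFVQGNLER")
    forms = chem.enumerate_carboxyforms(p, [2, 3, 10])
    assert len(forms) == 4
    masses = [chem.neutral_mass(f) for f in forms]
    steps = [b - a for a, b in zip(masses, masses[1:])]
    assert all(s == pytest.approx(43.98983, abs=1e-6) for s in steps)
    assert [f.carboxyl_count() for f in forms] == [0, 1, 2, 3]


def test_single_site_family_has_two_forms():
    forms = chem.enumerate_carboxyforms(Peptidoform("TTEFWK"), [3])
    assert len(forms) == 2


def test_empty_gla_sites_returns_input_alone():
    p = Peptidoform("TTEFWK")
    assert chem.enumerate_carboxyforms(p, []) == [p]


def test_non_glutamate_gla_site_rejected():
    with pytest.raises(ValueError):
        chem.enumerate_carboxyforms(Peptidoform("TTEFWK"), [1])


def test_methylform_inventory_of_carboxylated_ttefwk():
    p = Peptidoform("TTEFWK", ((3, GAMMA_CARBOXY),))
    assert chem.free_carboxyl_inventory(p) == 3  # 2 from Gla + C-terminus
    forms = chem.enumerate_methylforms(p)
    assert [f.methyl_count() for f in forms] == [0, 1, 2, 3]


def test_methylform_no_free_carboxyls():
    p = Peptidoform("VATVSLPK")
    assert chem.enumerate_methylforms(p, c_term_free=False) == [p]


def test_methylform_cap():
    p = Peptidoform("LEEFVQGNLER")
    full = p.with_mods(*((s, GAMMA_CARBOXY) for s in (2, 3, 10)))
    assert chem.free_carboxyl_inventory(full) == 7  # 3 Gla x2 + C-terminus
    forms = chem.enumerate_methylforms(full)
    assert max(f.methyl_count() for f in forms) == 6  # capped


# -- modification string round trip ------------------------------------------

@pytest.mark.parametrize(
    "mods",
    [
        (),
        ((5, SULFATION), (11, PROPIONAMIDE)),
        ((None, METHYL), (None, METHYL), (1, GlycanComposition.parse("HexNAc1Hex1NeuAc1"))),
        ((4, OXIDATION),),
    ],
)
def test_mod_string_round_trip(mods):
    text = chem.format_mods(mods)
    assert chem.parse_mods(text) == mods
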