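"""Carboxyform profiles and PTM relative-abundance series."""

import numpy as np
import pandas as pd
import pytest

from glaquant import stoich, synth


def family_df(intensities, prefix="fam|k"):
    return pd.DataFrame(
        {
            "peptide_class": [f"{prefix}{k}" for k in range(len(intensities))],
            "intensity": intensities,
        }
    )


def k_map(n, prefix="fam|k"):
    return {f"{prefix}{k}": k for k in range(n)}


def test_profile_single_occupied_form():
    prof = stoich.carboxyform_profile(family_df([0, 0, 0, 100]), k_map(4))
    assert prof.percentage[3] == pytest.approx(100.0)
    assert sum(prof.percentage.values()) == pytest.approx(100.0)
    assert prof.defined and prof.mean_k == pytest.approx(3.0)


def test_profile_uniform_intensities():
    prof = stoich.carboxyform_profile(family_df([25, 25, 25, 25]), k_map(4))
    assert prof.percentage == {k: pytest.approx(25.0) for k in range(4)}
    assert sum(prof.percentage.values()) == pytest.approx(100.0, abs=1e-9)


def test_profile_scale_invariance():
    a = stoich.carboxyform_profile(family_df([1, 2, 3, 4]), k_map(4))
    b = stoich.carboxyform_profile(family_df([10, 20, 30, 40]), k_map(4))
    assert a.percentage == pytest.approx(b.percentage)


def test_zero_total_family_is_undefined_not_zero():
    prof = stoich.carboxyform_profile(family_df([0, 0]), k_map(2))
    assert not prof.defined
    assert prof.percentage == {}
    assert np.isnan(prof.mean_k)


def test_unannotated_class_rejected():
    with pytest.raises(KeyError):
        stoich.carboxyform_profile(family_df([1, 2]), {"fam|k0": 0})


def test_marginalization_consistency():
    """Summing methyl sub-variants before or after computing percentages
    gives the same profile."""
    sub = pd.DataFrame(
        {
            "peptide_class": ["f|k0m0", "f|k0m1", "f|k1m0", "f|k1m2"],
            "intensity": [10.0, 30.0, 25.0, 35.0],
        }
    )
    kmap = {"f|k0m0": 0, "f|k0m1": 0, "f|k1m0": 1, "f|k1m2": 1}
    fine = stoich.carboxyform_profile(sub, kmap)
    coarse = stoich.carboxyform_profile(family_df([40.0, 60.0], prefix="f|k"), k_map(2, "f|k"))
    assert fine.percentage == pytest.approx(coarse.percentage)


def test_noiseless_recovery_matches_simulator_truth(scenario, library):
    from glaquant import quant

    states = synth.simulate_timecourse(scenario)
    state = next(s for s in states if s.condition == "B" and s.day == 13)
    noise = synth.NoiseModel(sigma=0.0, censor_limit=0.0)
    table = synth.render_dia(state, library, noise, seed=4)
    peps, _, _ = quant.quantify(table, library, profile=quant.GLA_METHYL_PROFILE)
    prof = stoich.carboxyform_profiles(peps, synth.class_table(scenario))
    truth = synth.family_truth(scenario, "B", 13)
    for fam in ("LEEFVQGNLER", "CSFEEAR", "EVFENTER", "TTEFWK"):
        sub = prof[prof["family"] == fam].set_index("k")["percentage"]
        for k, expected in enumerate(truth[fam]):
            assert sub[k] == pytest.approx(100 * expected, abs=1e-6)


def test_purified_profile_mean_k_not_below_supernatant(scenario, library):
    from glaquant import quant

    states = synth.simulate_timecourse(scenario)
    final = next(s for s in states if s.condition == "A" and s.day == 13)
    pur = synth.simulate_purification(final, scenario)
    noise = synth.NoiseModel(sigma=0.0, censor_limit=0.0)
    ann = synth.class_table(scenario)
    means = {}
    for state in (final, pur):
        table = synth.render_dia(state, library, noise, seed=4)
        peps, _, _ = quant.quantify(table, library, profile=quant.GLA_METHYL_PROFILE)
        prof = stoich.carboxyform_profiles(peps, ann)
        means[state.day] = {
            fam: (sub["k"] * sub["percentage"]).sum() / 100.0
            for fam, sub in prof.groupby("family")
        }
    for fam in ("LEEFVQGNLER", "CSFEEAR", "EVFENTER", "TTEFWK"):
        assert means["purified"][fam] >= means[13][fam] - 1e-9


# -- PTM relative abundance --------------------------------------------------

def variants_df():
    return pd.DataFrame(
        {
            "sample": ["s1", "s1", "s2"],
            "peptide_class": ["v1", "v2", "v1"],
            "intensity": [50.0, 25.0, 80.0],
        }
    )


def proteins_df(p1_s1=50.0, p1_s2=40.0):
    return pd.DataFrame(
        {
            "sample": ["s1", "s2"],
            "protein": ["rFIX", "rFIX"],
            "intensity": [p1_s1, p1_s2],
        }
    )


def test_variant_equal_to_product_gives_ratio_one():
    out = stoich.ptm_relative_abundance(variants_df(), proteins_df())
    row = out[(out["sample"] == "s1") & (out["peptide_class"] == "v1")]
    assert row["rel_abundance"].iloc[0] == pytest.approx(1.0)


def test_relative_abundance_invariant_to_common_scaling():
    base = stoich.ptm_relative_abundance(variants_df(), proteins_df())
    doubled = stoich.ptm_relative_abundance(
        variants_df().assign(intensity=lambda d: d["intensity"] * 2),
        proteins_df(100.0, 80.0),
    )
    assert np.allclose(base["rel_abundance"], doubled["rel_abundance"])


def test_samples_without_product_are_omitted():
    prots = proteins_df().iloc[:1]
    out = stoich.ptm_relative_abundance(variants_df(), prots)
    assert set(out["sample"]) == {"s1"}
    assert out.attrs["omitted_samples"] == ["s2"]


def test_occupancy_ramp_is_monotone_in_rendered_series(scenario, library):
    """The glycosylated linker-site variants gain relative abundance as the
    process progresses (site occupancy rises)."""
    from glaquant import quant

    states = [s for s in synth.simulate_timecourse(scenario)
              if s.condition == "B" and s.day in (1, 7, 13)]
    noise = synth.NoiseModel(sigma=0.0, censor_limit=0.0)
    tables = [synth.render_dia(s, library, noise, seed=8) for s in states]
    table = pd.concat(tables, ignore_index=True)
    peps, prots, _ = quant.quantify(table, library, profile=quant.PTM_PROFILE)
    glyc = peps[peps["peptide_class"].isin(["S141|+656", "S141|+947"])]
    series = stoich.ptm_relative_abundance(glyc, prots)
    per_day = series.groupby("sample")["rel_abundance"].sum().sort_index()
    vals = per_day.to_numpy()
    assert np.all(np.diff(vals) > 0)


# -- time-course matrix ------------------------------------------------------

def test_timecourse_matrix_shape_and_missing_marks():
    series = pd.DataFrame(
        {
            "peptide_class": ["v1", "v1", "v2"],
            "sample": ["d1", "d2", "d1"],
            "rel_abundance": [0.1, 0.2, 0.5],
        }
    )
    mat = stoich.timecourse_matrix(series)
    assert mat.shape == (2, 2)
    assert np.isnan(mat.loc["v2", "d2"])  # absent, not zero


def test_timecourse_matrix_rejects_duplicates():
    series = pd.DataFrame(
        {
            "peptide_class": ["v1", "v1"],
            "sample": ["d1", "d1"],
            "rel_abundance": [0.1, 0.2],
        }
    )
    with pytest.raises(ValueError):
        stoich.timecourse_matrix(series)


def test_single_cell_matrix():
    series = pd.DataFrame(
        {"peptide_class": ["v1"], "sample": ["d1"], "rel_abundance": [0.3]}
    )
    mat = stoich.timecourse_matrix(series)
    assert mat.shape == (1, 1)
    assert mat.loc["v1", "d1"] == pytest.approx(0.3)
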