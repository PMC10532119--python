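"""Nested species/strain ANOVA and compact letter displays."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from codyn.monoculture import NestedGrowthAnova, compact_letter_display, nested_anova


def simulate_design(rng, species_means, strain_sd, resid_sd, n_strains=3, n_reps=3):
    values, species, strain = [], [], []
    for sp, mu in species_means.items():
        for k in range(n_strains):
            mu_strain = mu + rng.normal(0.0, strain_sd)
            for _ in range(n_reps):
                values.append(mu_strain + rng.normal(0.0, resid_sd))
                species.append(sp)
                strain.append(f"{sp}-{k}")
    return np.array(values), np.array(species), np.array(strain)


def test_single_strain_design_equals_oneway_anova():
    """With one strain per species the species F is the classical one-way F."""
    rng = np.random.default_rng(0)
    groups = [rng.normal(m, 1.0, size=4) for m in (0.0, 0.5, 1.0, 2.0, 0.2)]
    values = np.concatenate(groups)
    species = np.repeat([f"sp{i}" for i in range(5)], 4)
    res = nested_anova(values, species, species)  # strain == species label
    F, p = stats.f_oneway(*groups)
    assert res.species_F == pytest.approx(F, abs=1e-10)
    assert res.species_p == pytest.approx(p, abs=1e-10)


def test_matches_statsmodels_sums_of_squares():
    """EMS decomposition agrees with OLS type-I ANOVA on a balanced design."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    rng = np.random.default_rng(1)
    values, species, strain = simulate_design(
        rng, {"A": 0.0, "B": 1.0, "C": 2.0}, strain_sd=0.5, resid_sd=0.3)
    res = nested_anova(values, species, strain)
    # statsmodels needs the nested factor coded within species
    code = np.array([s.split("-")[-1] for s in strain])
    df = pd.DataFrame({"y": values, "species": species, "code": code})
    ols = smf.ols("y ~ C(species) + C(species):C(code)", data=df).fit()
    tab = sm.stats.anova_lm(ols, typ=1)
    ms_sp = tab.loc["C(species)", "sum_sq"] / tab.loc["C(species)", "df"]
    ms_st = tab.loc["C(species):C(code)", "sum_sq"] / tab.loc["C(species):C(code)", "df"]
    ms_res = tab.loc["Residual", "sum_sq"] / tab.loc["Residual", "df"]
    assert res.species_F == pytest.approx(ms_sp / ms_st, rel=1e-10)
    assert res.strain_F == pytest.approx(ms_st / ms_res, rel=1e-10)


def test_invariant_to_strain_relabelling_within_species():
    rng = np.random.default_rng(2)
    values, species, strain = simulate_design(rng, {"A": 0, "B": 1}, 0.4, 0.3)
    res1 = nested_anova(values, species, strain)
    relabel = {s: f"x{abs(hash(s)) % 97}" for s in set(strain)}
    res2 = nested_anova(values, species, np.array([relabel[s] for s in strain]))
    assert res1.species_F == pytest.approx(res2.species_F, rel=1e-12)
    assert res1.strain_F == pytest.approx(res2.strain_F, rel=1e-12)


def test_strain_null_rejection_rate_at_alpha():
    """Identical strain means within species: the strain test is exact."""
    rng = np.random.default_rng(3)
    rejections = 0
    n_runs = 200
    for _ in range(n_runs):
        values, species, strain = simulate_design(
            rng, {"A": 0.0, "B": 1.0}, strain_sd=0.0, resid_sd=1.0)
        res = nested_anova(values, species, strain)
        rejections += res.strain_p < 0.05
    rate = rejections / n_runs
    se = np.sqrt(0.05 * 0.95 / n_runs)
    assert abs(rate - 0.05) < 3 * se + 1e-9


def test_species_power_with_large_effect():
    """Two species 10 residual SDs apart are detected at p < 0.01."""
    rng = np.random.default_rng(4)
    values, species, strain = simulate_design(
        rng, {"A": 0.0, "B": 10.0}, strain_sd=0.0, resid_sd=1.0)
    res = nested_anova(values, species, strain)
    assert res.species_p < 0.01


class TestLetterGroups:
    def test_identical_species_share_one_letter(self):
        rng = np.random.default_rng(5)
        values, species, strain = simulate_design(
            rng, {"A": 0.0, "B": 0.0, "C": 0.0}, strain_sd=0.1, resid_sd=0.5)
        letters = nested_anova(values, species, strain).letter_groups()
        assert set(letters.values()) == {"a"}

    def test_three_separated_species_get_three_letters(self):
        rng = np.random.default_rng(6)
        values, species, strain = simulate_design(
            rng, {"A": 0.0, "B": 50.0, "C": 100.0}, strain_sd=0.2, resid_sd=0.3)
        letters = nested_anova(values, species, strain).letter_groups()
        assert len(set(letters.values())) == 3

    def test_two_block_structure_like_monoculture_auc(self):
        """Strong vs weak growers (means/SDs at observed magnitudes) split."""
        rng = np.random.default_rng(7)
        means = {"Lt": 26.8, "Sc": 28.2, "Td": 26.1, "Hu": 18.7, "Sb": 15.5}
        sds = {"Lt": 0.7, "Sc": 1.3, "Td": 1.5, "Hu": 0.5, "Sb": 0.6}
        values, species, strain = [], [], []
        for sp, mu in means.items():
            for k in range(3):
                mu_strain = mu + rng.normal(0.0, sds[sp])
                for _ in range(3):
                    values.append(mu_strain + rng.normal(0.0, 0.4))
                    species.append(sp)
                    strain.append(f"{sp}-{k}")
        res = nested_anova(np.array(values), np.array(species), np.array(strain))
        assert res.species_p < 0.01
        letters = res.letter_groups()
        top = {letters[sp] for sp in ("Lt", "Sc", "Td")}
        assert len(top) == 1  # strong growers are one statistical group
        top_letter = top.pop()
        assert top_letter not in letters["Hu"] and top_letter not in letters["Sb"]

    def test_cld_separation_constraint(self):
        letters = compact_letter_display(
            ["a1", "a2", "b1"], [("a1", "b1"), ("a2", "b1")],
            means={"a1": 2.0, "a2": 1.9, "b1": 0.0})
        assert letters["a1"] == letters["a2"]
        assert set(letters["a1"]) & set(letters["b1"]) == set()


def test_summary_smoke():
    rng = np.random.default_rng(8)
    values, species, strain = simulate_design(rng, {"A": 0, "B": 5}, 0.3, 0.3)
    text = nested_anova(values, species, strain).summary()
    assert "species" in text and "F" in text
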