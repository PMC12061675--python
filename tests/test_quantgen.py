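"""Variance components, heritability, correlations and species ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stemgrowth.exceptions import NonEstimableError
from stemgrowth.quantgen import (
    VarianceComponents,
    broad_sense_heritability,
    compact_letter_display,
    estimate_dry_weight,
    pearson_correlation_matrix,
    species_anova_tukey,
)
from stemgrowth.simulate import simulate_balanced_trait


def mom_balanced(df: pd.DataFrame) -> tuple[float, float, float]:
    """Method-of-moments (expected mean squares) oracle for balanced data."""
    wide = df.pivot(index="genotype", columns="block", values="value").to_numpy()
    g, b = wide.shape
    gm, bm, mu = wide.mean(1), wide.mean(0), wide.mean()
    msg = b * np.sum((gm - mu) ** 2) / (g - 1)
    msb = g * np.sum((bm - mu) ** 2) / (b - 1)
    mse = np.sum((wide - gm[:, None] - bm[None, :] + mu) ** 2) / ((g - 1) * (b - 1))
    return (msg - mse) / b, (msb - mse) / g, mse


class TestDryWeight:
    def test_basic_arithmetic(self):
        mc, dw = estimate_dry_weight(1000, 200, 100)
        assert mc == 0.5 and dw == 500.0

    def test_bone_dry_subsample(self):
        mc, dw = estimate_dry_weight(1234.0, 150.0, 150.0)
        assert mc == 0.0 and dw == 1234.0

    def test_hand_computed_check(self):
        mc, dw = estimate_dry_weight(2500, 198.4, 87.3)
        assert mc == pytest.approx((198.4 - 87.3) / 198.4, rel=1e-12)
        assert dw == pytest.approx(2500 * 87.3 / 198.4, rel=1e-12)

    def test_inconsistent_or_invalid_weights(self):
        with pytest.raises(ValueError):
            estimate_dry_weight(1000, 100, 150)
        with pytest.raises(ValueError):
            estimate_dry_weight(1000, 0, 0)


class TestVarianceComponents:
    def test_reml_equals_moments_oracle_on_balanced_data(self):
        df = simulate_balanced_trait(80, 3, 1.0, 0.25, 1.0, seed=5)
        res = VarianceComponents(df["value"], df["genotype"], df["block"]).fit()
        vg, vb, ve = mom_balanced(df)
        assert res.v_g == pytest.approx(vg, abs=1e-5)
        assert res.v_block == pytest.approx(vb, abs=1e-5)
        assert res.v_e == pytest.approx(ve, abs=1e-5)

    def test_reml_close_to_truth_on_simulated_design(self):
        df = simulate_balanced_trait(200, 3, 1.0, 0.25, 1.0, seed=1)
        res = VarianceComponents(df["value"], df["genotype"], df["block"]).fit()
        assert res.v_g == pytest.approx(1.0, rel=0.15)
        assert res.v_e == pytest.approx(1.0, rel=0.15)

    def test_noiseless_limit_h2_near_one(self):
        df = simulate_balanced_trait(60, 3, 4.0, 0.0, 1e-8, seed=2)
        res = VarianceComponents(df["value"], df["genotype"], df["block"]).fit()
        assert res.h2 > 0.999

    def test_no_genotype_effect_h2_near_zero(self):
        df = simulate_balanced_trait(120, 3, 0.0, 0.1, 1.0, seed=3)
        res = VarianceComponents(df["value"], df["genotype"], df["block"]).fit()
        assert res.h2 < 0.1

    def test_statsmodels_crossed_vc_cross_check(self):
        # independent route: MixedLM variance components (loose optimizer tol)
        import statsmodels.formula.api as smf

        df = simulate_balanced_trait(60, 3, 1.0, 0.25, 1.0, seed=7)
        res = VarianceComponents(df["value"], df["genotype"], df["block"]).fit()
        m = smf.mixedlm("value ~ 1", df, groups=np.ones(len(df)),
                        vc_formula={"geno": "0 + C(genotype)", "blk": "0 + C(block)"})
        fit = m.fit(reml=True)
        sm_vg = float(fit.vcomp[list(m.exog_vc.names).index("geno")])
        assert res.v_g == pytest.approx(sm_vg, rel=0.05, abs=0.02)
        assert res.v_e == pytest.approx(float(fit.scale), rel=0.05)

    def test_h2_invariant_to_affine_rescaling(self):
        df = simulate_balanced_trait(80, 3, 1.0, 0.25, 1.0, seed=9)
        r1 = VarianceComponents(df["value"], df["genotype"], df["block"]).fit()
        r2 = VarianceComponents(3.5 * df["value"] - 7.0, df["genotype"], df["block"]).fit()
        assert r1.h2 == pytest.approx(r2.h2, abs=1e-5)

    def test_no_replication_is_non_estimable(self):
        with pytest.raises(NonEstimableError):
            VarianceComponents([1.0, 2.0, 3.0], ["g1", "g2", "g3"], [1, 1, 1])


class TestHeritabilityFormula:
    @pytest.mark.parametrize("vg,ve,expected", [(2, 2, 0.5), (1, 0, 1.0), (1, 3, 0.25)])
    def test_printed_formula(self, vg, ve, expected):
        assert broad_sense_heritability(vg, ve) == expected

    def test_undefined_when_both_zero(self):
        with pytest.raises(ValueError):
            broad_sense_heritability(0.0, 0.0)


class TestCorrelations:
    def test_exact_linear_relationships(self):
        df = pd.DataFrame({"x": np.arange(10.0)})
        df["up"] = 2 * df["x"] + 1
        df["down"] = -df["x"]
        out = pearson_correlation_matrix(df, ["x", "up", "down"]).set_index(
            ["trait_i", "trait_j"])
        assert out.loc[("x", "up"), "r"] == pytest.approx(1.0)
        assert out.loc[("x", "down"), "r"] == pytest.approx(-1.0)
        assert out.loc[("x", "x"), "r"] == 1.0

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(21)
        z = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=50)
        df = pd.DataFrame(z, columns=["u", "v"])
        out = pearson_correlation_matrix(df, ["u", "v"]).set_index(["trait_i", "trait_j"])
        u, v = z[:, 0], z[:, 1]
        r = np.sum((u - u.mean()) * (v - v.mean())) / np.sqrt(
            np.sum((u - u.mean()) ** 2) * np.sum((v - v.mean()) ** 2))
        t = r * np.sqrt(48 / (1 - r**2))
        p = 2 * stats.t.sf(abs(t), 48)
        assert out.loc[("u", "v"), "r"] == pytest.approx(r, rel=1e-12)
        assert out.loc[("u", "v"), "p"] == pytest.approx(p, rel=1e-9)
        assert out.loc[("u", "v"), "n"] == 50

    def test_zero_variance_reported_as_missing(self):
        df = pd.DataFrame({"x": np.arange(10.0), "const": np.ones(10)})
        out = pearson_correlation_matrix(df, ["x", "const"]).set_index(
            ["trait_i", "trait_j"])
        cell = out.loc[("x", "const")]
        assert np.isnan(cell["r"]) and cell["note"] == "zero variance"


class TestSpeciesAnova:
    def test_identical_groups_share_a_letter(self):
        df = pd.DataFrame({
            "species_group": np.repeat(["A", "B", "C"], 5),
            "y": np.tile([1.0, 2.0, 3.0, 4.0, 5.0], 3),
        })
        res = species_anova_tukey(df, "y")
        assert float(res["anova"].loc["C(species, Sum)", "PR(>F)"]) > 0.99
        assert len(set(res["letters"].values())) == 1

    def test_separated_groups_get_distinct_letters_and_f_matches_oracle(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({
            "species_group": np.repeat(["lo", "hi"], 30),
            "y": np.concatenate([rng.normal(0, 1, 30), rng.normal(5, 1, 30)]),
        })
        res = species_anova_tukey(df, "y")
        # one-way ANOVA oracle on balanced data
        f_oracle, _ = stats.f_oneway(df["y"][:30], df["y"][30:])
        assert float(res["anova"].loc["C(species, Sum)", "F"]) == pytest.approx(
            f_oracle, rel=1e-9)
        assert res["letters"]["lo"] != res["letters"]["hi"]

    def test_type3_ss_equals_model_comparison_on_unbalanced_data(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({
            "species_group": np.repeat(["a", "b", "c"], [3, 5, 8]),
            "y": rng.normal(0, 1, 16) + np.repeat([0.0, 1.0, 2.0], [3, 5, 8]),
        })
        res = species_anova_tukey(df, "y")
        means = df.groupby("species_group")["y"].transform("mean")
        rss_full = float(np.sum((df["y"] - means) ** 2))
        rss_reduced = float(np.sum((df["y"] - df["y"].mean()) ** 2))
        ss_oracle = rss_reduced - rss_full
        assert float(res["anova"].loc["C(species, Sum)", "sum_sq"]) == pytest.approx(
            ss_oracle, rel=1e-9)

    def test_singleton_species_dropped_with_warning(self):
        df = pd.DataFrame({
            "species_group": ["a"] * 5 + ["b"] * 5 + ["solo"],
            "y": list(range(5)) + list(range(5, 10)) + [99.0],
        })
        res = species_anova_tukey(df, "y")
        assert res["dropped"] == ["solo"]
        assert "solo" not in res["letters"]


class TestCompactLetters:
    def test_chain_structure(self):
        # A differs from C; B bridges both
        letters = compact_letter_display(
            ["A", "B", "C"], {("A", "C")},
            order_stat={"A": 3.0, "B": 2.0, "C": 1.0})
        assert letters["A"] == "a"
        assert letters["C"] == "b"
        assert set(letters["B"]) == {"a", "b"}

    def test_all_different(self):
        letters = compact_letter_display(
            ["x", "y", "z"], {("x", "y"), ("y", "z"), ("x", "z")},
            order_stat={"x": 1.0, "y": 2.0, "z": 3.0})
        assert len({letters["x"], letters["y"], letters["z"]}) == 3
        assert letters["z"] == "a"  # highest mean takes the first letter
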