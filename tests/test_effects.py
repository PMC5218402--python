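import numpy as np
import pandas as pd
import pytest

from epiqtl.effects import (GENOTYPES, LinearCombo, conditional_effects,
                            effect_se, epistasis_plot_data, genotypic_values,
                            holm_adjust, independent_effects_model,
                            pair_term_names, variance_explained)
from epiqtl.modelbuild import (GeneticModelSpec, PairTerm, fit_full_model)

PAIR = PairTerm(("1", 30.0), ("2", 70.0))
COEF_KEYS = [("a", PAIR.locus1), ("d", PAIR.locus1),
             ("a", PAIR.locus2), ("d", PAIR.locus2),
             ("i_aa", PAIR.loci), ("i_ad", PAIR.loci),
             ("i_da", PAIR.loci), ("i_dd", PAIR.loci)]
_A = {"EE": -1.0, "EW": 0.0, "WW": 1.0}
_D = {"EE": 0.0, "EW": 1.0, "WW": 0.0}


class FakeFit:
    """Coefficient container standing in for a fitted model (synthetic)."""

    def __init__(self, values, cov=None):
        self.names = COEF_KEYS
        self.coef = np.asarray(values, float)
        self.cov = cov if cov is not None else np.zeros((8, 8))
        self.spec = GeneticModelSpec("t", pairs=[PAIR])


def _gv_value(df, g1, g2):
    return float(df.loc[(df.g1 == g1) & (df.g2 == g2), "value"].iloc[0])


class TestGenotypicValues:
    def test_all_zero_coefficients(self):
        df = genotypic_values(FakeFit(np.zeros(8)), PAIR)
        assert np.allclose(df["value"], 0.0)
        assert len(df) == 9

    def test_pure_additive_locus_one(self):
        fit = FakeFit([1, 0, 0, 0, 0, 0, 0, 0])
        df = genotypic_values(fit, PAIR)
        for g2 in GENOTYPES:
            assert _gv_value(df, "WW", g2) == 1.0
            assert _gv_value(df, "EW", g2) == 0.0
            assert _gv_value(df, "EE", g2) == -1.0

    def test_additive_by_additive_corners(self):
        fit = FakeFit([1, 0, 1, 0, 1, 0, 0, 0])    # a1 = a2 = i_aa = 1
        df = genotypic_values(fit, PAIR)
        assert _gv_value(df, "WW", "WW") == 3.0
        assert _gv_value(df, "EE", "EE") == -1.0

    def test_triple_has_27_rows(self):
        pair2 = PairTerm(("1", 30.0), ("3", 10.0))
        names = COEF_KEYS + [("a", pair2.locus2), ("d", pair2.locus2),
                             ("i_aa", pair2.loci), ("i_ad", pair2.loci),
                             ("i_da", pair2.loci), ("i_dd", pair2.loci)]
        fit = FakeFit(np.zeros(8))
        fit.names = names
        fit.coef = np.zeros(len(names))
        fit.cov = np.zeros((len(names), len(names)))
        df = genotypic_values(fit, PAIR, pair2)
        assert len(df) == 27


class TestConditionalEffects:
    def test_closed_forms(self):
        # a1' = 0.1, i_aa = 0.2
        fit = FakeFit([0.1, 0, 0, 0, 0.2, 0, 0, 0])
        df = conditional_effects(fit, PAIR)
        get = lambda locus, bg, kind: float(
            df[(df.locus == locus) & (df.background == bg)
               & (df.kind == kind)]["estimate"].iloc[0])
        assert get(PAIR.locus1, "WW", "additive") == pytest.approx(0.3)
        assert get(PAIR.locus1, "EE", "additive") == pytest.approx(-0.1)
        assert get(PAIR.locus1, "EW", "additive") == pytest.approx(0.1)
        # d2' = 0.2, i_dd = 0.3 -> d2(EW) = 0.5
        fit2 = FakeFit([0, 0, 0, 0.2, 0, 0, 0, 0.3])
        df2 = conditional_effects(fit2, PAIR)
        assert float(df2[(df2.locus == PAIR.locus2) & (df2.background == "EW")
                         & (df2.kind == "dominance")]["estimate"].iloc[0]) \
            == pytest.approx(0.5)

    def test_coefficient_route_equals_genotypic_value_route(self):
        """For 1000 random coefficient vectors the closed forms agree
        exactly with recomputation from the genotypic-value table."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            fit = FakeFit(rng.normal(size=8))
            gvt = genotypic_values(fit, PAIR)
            eff = conditional_effects(fit, PAIR)
            for g in GENOTYPES:
                a1 = (_gv_value(gvt, "WW", g) - _gv_value(gvt, "EE", g)) / 2
                d1 = _gv_value(gvt, "EW", g) - (_gv_value(gvt, "WW", g)
                                                + _gv_value(gvt, "EE", g)) / 2
                a2 = (_gv_value(gvt, g, "WW") - _gv_value(gvt, g, "EE")) / 2
                d2 = _gv_value(gvt, g, "EW") - (_gv_value(gvt, g, "WW")
                                                + _gv_value(gvt, g, "EE")) / 2
                sel = lambda locus, kind: float(
                    eff[(eff.locus == locus) & (eff.background == g)
                        & (eff.kind == kind)]["estimate"].iloc[0])
                assert sel(PAIR.locus1, "additive") == pytest.approx(a1, abs=1e-12)
                assert sel(PAIR.locus1, "dominance") == pytest.approx(d1, abs=1e-12)
                assert sel(PAIR.locus2, "additive") == pytest.approx(a2, abs=1e-12)
                assert sel(PAIR.locus2, "dominance") == pytest.approx(d2, abs=1e-12)

    def test_linkage_equilibrium_average_recovers_marginal(self):
        """(1/4, 1/2, 1/4)-weighted conditional effects equal the
        single-locus-model coefficients. Under linkage equilibrium the
        marginal additive coefficient of locus 1 is a1' + i_ad/2 (the
        partner's expected dominance score is 1/2 and expected additive
        score 0), and analogously for the other three."""
        rng = np.random.default_rng(1)
        w = {"EE": 0.25, "EW": 0.5, "WW": 0.25}
        for _ in range(50):
            c = rng.normal(size=8)
            fit = FakeFit(c)
            eff = conditional_effects(fit, PAIR)
            marginal = {
                (PAIR.locus1, "additive"): c[0] + 0.5 * c[5],
                (PAIR.locus1, "dominance"): c[1] + 0.5 * c[7],
                (PAIR.locus2, "additive"): c[2] + 0.5 * c[6],
                (PAIR.locus2, "dominance"): c[3] + 0.5 * c[7],
            }
            for (locus, kind), expected in marginal.items():
                sub = eff[(eff.locus == locus) & (eff.kind == kind)]
                avg = sum(w[row.background] * row.estimate
                          for row in sub.itertuples())
                assert avg == pytest.approx(expected, abs=1e-12)

    def test_triple_shared_locus_conditions_on_both_partners(self):
        pair2 = PairTerm(("1", 30.0), ("3", 10.0))
        names = COEF_KEYS + [("a", pair2.locus2), ("d", pair2.locus2),
                             ("i_aa", pair2.loci), ("i_ad", pair2.loci),
                             ("i_da", pair2.loci), ("i_dd", pair2.loci)]
        rng = np.random.default_rng(2)
        fit = FakeFit(np.zeros(8))
        fit.names = names
        fit.coef = rng.normal(size=len(names))
        fit.cov = np.zeros((len(names), len(names)))
        eff = conditional_effects(fit, PAIR, pair2)
        gvt = genotypic_values(fit, PAIR, pair2)
        shared = eff[eff.locus == PAIR.locus1]
        assert len(shared) == 18                 # 9 backgrounds x (a, d)
        for (g2, g3) in [("EE", "WW"), ("EW", "EW")]:
            pick = lambda g1: float(gvt[(gvt.g1 == g1) & (gvt.g2 == g2)
                                        & (gvt.g3 == g3)]["value"].iloc[0])
            a = (pick("WW") - pick("EE")) / 2
            got = float(shared[(shared.background == (g2, g3))
                               & (shared.kind == "additive")]["estimate"].iloc[0])
            assert got == pytest.approx(a, abs=1e-12)


class TestEffectSE:
    def test_single_coefficient_se(self):
        cov = np.diag([0.01] * 8)
        fit = FakeFit(np.zeros(8), cov)
        se = effect_se(LinearCombo({("a", PAIR.locus1): 1.0}), fit)
        assert se == pytest.approx(0.1)

    def test_sum_of_independent_variances(self):
        cov = np.diag([0.01] * 8)
        fit = FakeFit(np.zeros(8), cov)
        se = effect_se(LinearCombo({("a", PAIR.locus1): 1.0,
                                    ("i_aa", PAIR.loci): 1.0}), fit)
        assert se == pytest.approx(0.1414, abs=1e-3)

    def test_matches_parametric_bootstrap(self, qtl_study):
        """Analytic SEs track refit-to-refit variability of the conditional
        effect across fresh noise draws (within ~10-15%)."""
        table = qtl_study["table"].copy()
        grid = qtl_study["grid"]
        truth = qtl_study["truth"]["G_a"]
        spec = GeneticModelSpec("G_a", pairs=[PairTerm(("1", 30.0),
                                                       ("2", 70.0))])
        fit0 = fit_full_model("G_a", table, ["C(sex)", "C(batch)"], grid, spec)
        combo = LinearCombo({("a", ("1", 30.0)): 1.0,
                             ("i_aa", (("1", 30.0), ("2", 70.0))): 1.0})
        se_analytic = effect_se(combo, fit0)
        rng = np.random.default_rng(3)
        signal = table["G_a"].to_numpy() - truth["residual"]
        draws = []
        for _ in range(60):
            table["G_sim"] = signal + rng.normal(0, 1.0, len(table))
            f = fit_full_model("G_sim", table, ["C(sex)", "C(batch)"], grid,
                               spec)
            draws.append(combo.vector(f) @ f.coef)
        se_boot = np.std(draws, ddof=1)
        assert se_analytic == pytest.approx(se_boot, rel=0.25)


class TestHolm:
    def test_step_down_definition(self):
        p = np.array([0.001, 0.02, 0.04] + [0.5] * 9)
        flags = holm_adjust(p, alpha=0.05)
        assert flags[0]                           # 0.001 <= 0.05/12
        assert not flags[1]                       # 0.02 > 0.05/11 stops chain
        assert not flags[2:].any()

    def test_all_ones_nothing_significant(self):
        assert not holm_adjust(np.ones(12)).any()

    def test_matches_statsmodels_reference(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(4)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(2, 15))
            ours = holm_adjust(p, alpha=0.05)
            ref = multipletests(p, alpha=0.05, method="holm")[0]
            np.testing.assert_array_equal(ours, ref)


class TestVarianceExplained:
    def test_null_term_explains_nothing(self, qtl_study):
        table = qtl_study["table"]
        grid = qtl_study["grid"]
        spec = GeneticModelSpec("G_b", independent=[("1", 30.0), ("2", 50.0)])
        fit = fit_full_model("G_b", table, ["C(sex)", "C(batch)"], grid, spec)
        base = fit_full_model("G_b", table, ["C(sex)", "C(batch)"], grid,
                              GeneticModelSpec("G_b"))
        pct = variance_explained(fit, [("a", ("2", 50.0)), ("d", ("2", 50.0))],
                                 base.pss)
        true_pct = variance_explained(
            fit, [("a", ("1", 30.0)), ("d", ("1", 30.0))], base.pss)
        assert abs(pct) < 3.0                   # a 2-df chance contribution
        assert pct < true_pct / 2

    def test_known_fraction_recovered(self, qtl_study):
        """The simulated additive locus explains a known share of the
        adjusted variance; PSS-based accounting recovers it."""
        table = qtl_study["table"]
        grid = qtl_study["grid"]
        spec = GeneticModelSpec("G_b", independent=[("1", 30.0)])
        fit = fit_full_model("G_b", table, ["C(sex)", "C(batch)"], grid, spec)
        base = fit_full_model("G_b", table, ["C(sex)", "C(batch)"], grid,
                              GeneticModelSpec("G_b"))
        pct = variance_explained(fit, [("a", ("1", 30.0)), ("d", ("1", 30.0))],
                                 base.pss)
        # var(aA) = a^2 * var(A) = 0.16 * 0.5 over ~1.18 adjusted variance
        expected = 100 * (0.16 * 0.5) / (0.16 * 0.5 + 1.0 + 0.1)
        assert pct == pytest.approx(expected, rel=0.5)

    def test_unknown_terms_rejected(self, qtl_study):
        table = qtl_study["table"]
        grid = qtl_study["grid"]
        fit = fit_full_model("G_b", table, ["C(sex)", "C(batch)"], grid,
                             GeneticModelSpec("G_b"))
        with pytest.raises(KeyError):
            variance_explained(fit, [("a", ("9", 9.0))], 100.0)


class TestIndependentEffectsModel:
    def test_additive_architecture_agrees_with_full_model(self, qtl_study):
        from epiqtl.scan import PutativeQTL
        table = qtl_study["table"]
        grid = qtl_study["grid"]
        q = PutativeQTL("1", 30.0, (20.0, 40.0), 15.0)
        fit, report = independent_effects_model(
            "G_b", table, ["C(sex)", "C(batch)"], grid, [q], base_sigma2=1.0)
        assert report.loc[0, "significant"]
        assert report.loc[0, "a"] == pytest.approx(0.4, abs=0.15)
        assert report.loc[0, "a_std"] == report.loc[0, "a"]

    def test_empty_qtl_set_reduces_to_base(self, qtl_study):
        table = qtl_study["table"]
        grid = qtl_study["grid"]
        fit, report = independent_effects_model(
            "G_b", table, ["C(sex)", "C(batch)"], grid, [])
        assert report.empty
        assert len(fit.names) == 4               # intercept + sex + 2 batch


class TestPlotData:
    def test_parallel_lines_iff_no_interaction(self):
        fit = FakeFit([0.3, 0.1, -0.2, 0.4, 0, 0, 0, 0])
        df = epistasis_plot_data(genotypic_values(fit, PAIR), base_sigma2=1.0)
        lines = {g2: df[df.g2 == g2]["value"].to_numpy() for g2 in GENOTYPES}
        gaps = lines["WW"] - lines["EE"]
        assert np.allclose(gaps, gaps[0])
        # pure i_aa > 0 crosses symmetrically about EW
        fit2 = FakeFit([0, 0, 0, 0, 0.5, 0, 0, 0])
        df2 = epistasis_plot_data(genotypic_values(fit2, PAIR), base_sigma2=1.0)
        l = {g2: df2[df2.g2 == g2]["value"].to_numpy() for g2 in GENOTYPES}
        assert np.allclose(l["WW"], -l["EE"])
        assert np.allclose(l["EW"], 0.0)

    def test_row_counts(self):
        fit = FakeFit(np.arange(8) / 10)
        assert len(epistasis_plot_data(genotypic_values(fit, PAIR), 1.0)) == 9

    def test_standardization_scale_invariance(self):
        """Scaling phenotype (hence coefficients and residual SD) by c > 0
        leaves standardized values unchanged."""
        coef = np.array([0.3, 0.1, -0.2, 0.4, 0.25, 0, 0, -0.1])
        d1 = epistasis_plot_data(genotypic_values(FakeFit(coef), PAIR), 2.0)
        d2 = epistasis_plot_data(genotypic_values(FakeFit(3 * coef), PAIR),
                                 2.0 * 9)
        np.testing.assert_allclose(d1["standardized"], d2["standardized"],
                                   atol=1e-12)
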