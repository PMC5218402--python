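import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epiqtl.lmm import fit_random_intercept
from epiqtl.phenotypes import (DEFAULT_TRAITS, TraitDefinition, apply_filters,
                               backward_select, coarsen_move_age,
                               derive_traits, effective_mother,
                               fit_base_model, fit_fixed_only)
from epiqtl.phenotypes import test_fixed_effect as fixed_effect_p
from epiqtl.phenotypes import test_mother as mother_lrt_p

TDEF = {t.name: t for t in DEFAULT_TRAITS}


def _records(n=6, **cols):
    base = {
        "individual": [f"i{k}" for k in range(n)],
        "sex": ["M", "F"] * (n // 2),
        "batch": [3] * n,
        "mother": ["d1"] * (n // 2) + ["d2"] * (n - n // 2),
        "weight_0": [1.2] * n,
        "weight_21": [5.3] * n,
        "weight_46": [11.0] * n,
        "weight_120": [32.0] * n,
        "weight_210": [80.0] * n,
        "weight_240": [95.0] * n,
        "age_120": [121] * n,
        "age_210": [210] * n,
        "age_240": [239] * n,
    }
    base.update(cols)
    return pd.DataFrame(base)


class TestDeriveTraits:
    def test_growth_is_weight_difference(self):
        tr = derive_traits(_records())
        assert tr.loc[0, "G_0_21"] == pytest.approx(4.1)
        assert tr.loc[0, "BW"] == pytest.approx(1.2)

    def test_missing_endpoint_excluded(self):
        rec = _records()
        rec.loc[0, "weight_21"] = np.nan
        tr = derive_traits(rec)
        assert np.isnan(tr.loc[0, "G_0_21"])

    def test_weight_decline_flagged_unless_final_starved(self):
        rec = _records(starved=[False] * 6)
        rec.loc[0, "weight_120"] = 5.0          # mid-experiment decline
        rec.loc[1, "weight_240"] = 70.0         # final decline, not starved
        rec.loc[2, "weight_240"] = 70.0         # final decline, starved
        rec.loc[2, "starved"] = True
        tr = derive_traits(rec)
        assert tr.loc[0, "declined"]
        assert tr.loc[1, "declined"]
        assert not tr.loc[2, "declined"]


class TestApplyFilters:
    def test_measurement_window_enforced(self):
        rec = _records()
        rec.loc[0, "age_120"] = 131             # outside 119-130
        keep = apply_filters(rec, TDEF["G_46_120"])
        assert not keep.iloc[0] and keep.iloc[1]

    def test_early_batch_females_excluded_after_46(self):
        rec = _records(batch=[2] * 6)
        keep = apply_filters(rec, TDEF["G_46_210"])
        assert all(keep[rec["sex"] == "M"])
        assert not any(keep[rec["sex"] == "F"])
        # but not for early growth
        keep_early = apply_filters(rec, TDEF["G_0_21"])
        assert keep_early.all()

    def test_interval_window_enforced(self):
        rec = _records()
        rec.loc[0, "age_120"] = 119
        rec.loc[0, "age_210"] = 211             # interval 92 > 90
        keep = apply_filters(rec, TDEF["G_120_210"])
        assert not keep.iloc[0]

    def test_clean_cohort_fully_retained(self):
        rec = _records()
        tr = derive_traits(rec)
        for tdef in DEFAULT_TRAITS:
            assert apply_filters(rec, tdef, tr).all()


def _simulated_mixed(n=1500, n_mothers=57, beta=(1.0, 0.5), tau2=0.2,
                     sigma2=1.0, seed=0):
    rng = np.random.default_rng(seed)
    mothers = rng.integers(n_mothers, size=n)
    x = rng.normal(size=n)
    mat = rng.normal(0, np.sqrt(tau2), n_mothers)
    y = beta[0] + beta[1] * x + mat[mothers] + rng.normal(0, np.sqrt(sigma2), n)
    return pd.DataFrame({"y": y, "x": x,
                         "mother": [f"m{k}" for k in mothers]})


class TestMixedModel:
    def test_recovers_known_variance_components(self):
        df = _simulated_mixed(seed=1)
        fit = fit_base_model(df, "y", ["x"])
        assert fit.beta[1] == pytest.approx(0.5, abs=3 * 0.03)
        assert fit.sigma2 == pytest.approx(1.0, rel=0.15)
        assert fit.mother_var == pytest.approx(0.2, rel=0.5)

    def test_matches_statsmodels_mixedlm(self):
        """Cross-check of the closed-form REML solver against the standard
        iterative implementation on a well-conditioned problem."""
        import statsmodels.api as sm

        df = _simulated_mixed(n=600, n_mothers=30, seed=2)
        X = np.column_stack([np.ones(len(df)), df["x"]])
        ours = fit_random_intercept(df["y"].to_numpy(), X, df["mother"])
        ref = sm.MixedLM(df["y"].to_numpy(), X, groups=df["mother"]).fit(reml=True)
        np.testing.assert_allclose(ours.beta, np.asarray(ref.fe_params),
                                   atol=1e-5)
        assert ours.sigma2 == pytest.approx(float(ref.scale), rel=1e-4)
        assert ours.tau2 == pytest.approx(float(np.asarray(ref.cov_re)[0, 0]),
                                          rel=1e-3, abs=1e-6)

    def test_zero_variance_boundary(self):
        df = _simulated_mixed(tau2=0.0, n=800, seed=3)
        fit = fit_base_model(df, "y", ["x"])
        assert fit.mother_var == pytest.approx(0.0, abs=0.02)

    def test_intercept_only_residuals(self):
        df = _simulated_mixed(tau2=0.0, n=400, seed=4)
        fit = fit_base_model(df, "y", [])
        # y~ = y - (GLS mean) - mother BLUPs; the GLS mean approaches the
        # sample mean as the mother variance vanishes
        np.testing.assert_allclose(
            fit.adjusted, df["y"] - fit.beta[0]
            - np.array([fit.blups[m] for m in df["mother"]]), atol=1e-10)
        assert fit.beta[0] == pytest.approx(df["y"].mean(), abs=0.05)
        assert abs(fit.adjusted.mean()) < 0.01

    def test_singular_design_raises(self):
        df = _simulated_mixed(n=200, seed=5)
        df["x2"] = 2 * df["x"]
        with pytest.raises(ValueError, match="aliased|singular"):
            fit_base_model(df, "y", ["x", "x2"])


class TestFixedEffectTest:
    def test_chi2_approximation_examples(self):
        """p = P(chi2_d >= d*F): F=2, d=3 -> sf(6, 3) = 0.1116."""
        df = _simulated_mixed(n=300, seed=6)
        df["g"] = pd.Categorical(np.tile(["a", "b", "c", "d"], 75))
        fit = fit_base_model(df, "y", ["x", "C(g)"])
        # recompute from the fit's own Wald statistic
        p = fixed_effect_p(fit, "C(g)")
        assert 0.0 <= p <= 1.0
        assert stats.chi2.sf(3 * 2.0, 3) == pytest.approx(0.1116, abs=1e-4)
        # d = 1 equals a two-sided normal test of sqrt(d*F)
        p1 = fixed_effect_p(fit, "x")
        idx = fit.design_info.term_name_slices["x"]
        z = fit.beta[idx][0] / np.sqrt(fit.cov_beta[idx, idx][0, 0])
        assert p1 == pytest.approx(2 * stats.norm.sf(abs(z)), rel=1e-10)

    def test_unknown_term_raises(self):
        df = _simulated_mixed(n=100, seed=7)
        fit = fit_base_model(df, "y", ["x"])
        with pytest.raises(KeyError):
            fixed_effect_p(fit, "nope")


class TestMotherLRT:
    def test_zero_statistic_boundary(self):
        df = _simulated_mixed(tau2=0.0, n=300, seed=8)
        fit = fit_base_model(df, "y", ["x"])
        ll0, _, _ = fit_fixed_only(df, "y", ["x"])
        p = mother_lrt_p(fit, ll0)
        assert p > 0.3                           # no evidence for mother
        p_mix = mother_lrt_p(fit, ll0, null="mixture")
        assert p_mix <= p

    def test_null_calibration(self):
        """Under no maternal effect the chi2_1 LRT rejects at most ~5%."""
        rej = 0
        R = 120
        for s in range(R):
            df = _simulated_mixed(tau2=0.0, n=300, n_mothers=30, seed=100 + s)
            fit = fit_base_model(df, "y", ["x"])
            ll0, _, _ = fit_fixed_only(df, "y", ["x"])
            if mother_lrt_p(fit, ll0) < 0.05:
                rej += 1
        assert rej / R <= 0.08                  # conservative by construction

    def test_power_with_real_maternal_variance(self):
        hits = 0
        R = 20
        for s in range(R):
            df = _simulated_mixed(tau2=0.3, n=1500, n_mothers=57, seed=200 + s)
            fit = fit_base_model(df, "y", ["x"])
            ll0, _, _ = fit_fixed_only(df, "y", ["x"])
            if mother_lrt_p(fit, ll0) < 0.05:
                hits += 1
        assert hits / R > 0.9


class TestBackwardSelect:
    def test_strong_effect_retained_nulls_dropped(self):
        rng = np.random.default_rng(9)
        n = 800
        df = pd.DataFrame({
            "x_true": rng.normal(size=n),
            "x_null1": rng.normal(size=n),
            "x_null2": rng.normal(size=n),
            "mother": [f"m{k}" for k in rng.integers(30, size=n)],
        })
        df["y"] = 0.5 * df["x_true"] + rng.normal(size=n)
        fit = backward_select(df, "y", ["x_true", "x_null1", "x_null2"])
        assert "x_true" in fit.selected_terms

    def test_all_null_candidates_mostly_dropped(self):
        rng = np.random.default_rng(10)
        n = 500
        df = pd.DataFrame({f"x{k}": rng.normal(size=n) for k in range(4)})
        df["mother"] = [f"m{k}" for k in rng.integers(25, size=n)]
        df["y"] = rng.normal(size=n)
        kept = 0
        for s in range(10):
            df["y"] = np.random.default_rng(300 + s).normal(size=n)
            fit = backward_select(df, "y", [f"x{k}" for k in range(4)])
            kept += len(fit.selected_terms)
        assert kept / (10 * 4) < 0.2            # each term ~5% retention


class TestCoarsenMoveAge:
    def test_step_effect_boundary_recovered(self):
        rng = np.random.default_rng(11)
        n = 900
        move = np.full(n, np.nan)
        moved = rng.random(n) < 0.6
        move[moved] = rng.integers(80, 132, size=moved.sum())
        y = np.where(np.isnan(move), 0.0, np.where(move < 105, 0.0, 1.0))
        y = y + rng.normal(0, 0.3, n)
        groups = coarsen_move_age(pd.Series(move), y)
        lab = groups[moved]
        # the recovered boundary splits moved animals into two levels near 105
        split_ages = sorted({int(s.split("_")[1]) for s in lab.unique()})
        assert any(abs(b - 105) <= 6 for b in split_ages)

    def test_no_effect_collapses_levels(self):
        rng = np.random.default_rng(12)
        n = 600
        move = np.full(n, np.nan)
        moved = rng.random(n) < 0.5
        move[moved] = rng.integers(80, 132, size=moved.sum())
        y = rng.normal(size=n)
        groups = coarsen_move_age(pd.Series(move), y)
        n_bins_initial = int(np.ceil((132 - 80) / 6))
        assert groups[moved].nunique() < n_bins_initial
        # a looser merge tolerance collapses harder
        loose = coarsen_move_age(pd.Series(move), y, merge_tol_se=3.0)
        assert loose[moved].nunique() <= groups[moved].nunique()

    def test_all_unmoved_single_level(self):
        groups = coarsen_move_age(pd.Series([np.nan] * 5), np.zeros(5))
        assert set(groups) == {"not_moved"}


class TestAdjustedTraitProperties:
    def test_nonoverlapping_null_traits_uncorrelated(self):
        """With no shared genetics, adjusted traits are uncorrelated within
        3/sqrt(n)."""
        rng = np.random.default_rng(13)
        n = 1000
        mothers = [f"m{k}" for k in rng.integers(40, size=n)]
        mat = {m: rng.normal(0, 0.3) for m in set(mothers)}
        df = pd.DataFrame({"mother": mothers,
                           "x": rng.normal(size=n)})
        for t in ("t1", "t2"):
            df[t] = (0.4 * df["x"] + np.array([mat[m] for m in mothers])
                     + rng.normal(size=n))
            mat = {m: rng.normal(0, 0.3) for m in set(mothers)}  # new effects
        f1 = fit_base_model(df, "t1", ["x"])
        f2 = fit_base_model(df, "t2", ["x"])
        r = np.corrcoef(f1.adjusted, f2.adjusted)[0, 1]
        assert abs(r) < 3 / np.sqrt(n)

    def test_residual_variance_drops_with_true_covariate(self):
        rng = np.random.default_rng(14)
        n = 600
        df = pd.DataFrame({"x": rng.normal(size=n),
                           "mother": [f"m{k}" for k in rng.integers(30, size=n)]})
        df["y"] = 0.5 * df["x"] + rng.normal(size=n)
        with_x = fit_base_model(df, "y", ["x"])
        without = fit_base_model(df, "y", [])
        assert with_x.sigma2 < without.sigma2


class TestEffectiveMother:
    def test_growth_uses_rearing_mother_bw_uses_birth_mother(self):
        rec = _records(foster_mother=[np.nan, "d9", np.nan, "d9", np.nan,
                                      np.nan])
        growth = effective_mother(rec, TDEF["G_0_21"])
        assert growth.iloc[1] == "d9" and growth.iloc[0] == "d1"
        bw = effective_mother(rec, TDEF["BW"])
        assert list(bw) == list(rec["mother"])
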