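"""Growth-trait derivation, inclusion filters and base-model adjustment.

Raw phenotypes are birth weight and interval weight gains. Before scanning,
each trait is adjusted for management and litter covariates with a linear
mixed model: fixed explanatory variables plus a random intercept per mother,
fit by REML. Candidate variables are pruned by backward selection (drop the
least significant at p >= 0.05, refit, repeat). Fixed effects are tested by
a Wald statistic with the estimated residual variance in the denominator; p
is taken from the chi-square approximation to d*F with d the term's degrees
of freedom, appropriate when the denominator degrees of freedom are large.
The maternal effect is tested by a REML likelihood-ratio test between models
with and without the random intercept. The adjusted phenotype y~ used by all
scans is the conditional residual: observed minus fixed effects minus the
predicted (BLUP) mother effect. The base model's residual variance is the
standardization denominator for all reported effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats

__all__ = [
    "TraitDefinition", "DEFAULT_TRAITS", "BaseModelFit",
    "derive_traits", "apply_filters", "effective_mother", "fit_base_model", "test_fixed_effect",
    "test_mother", "backward_select", "coarsen_move_age", "reml_loglik",
]

MEASUREMENT_AGES = (0, 21, 46, 120, 210, 240)


@dataclass(frozen=True)
class TraitDefinition:
    """A growth trait and its inclusion windows.

    ``first_window``/``second_window`` bound the actual measurement ages at
    the interval endpoints; ``interval_window`` bounds the elapsed days.
    ``None`` means unconstrained.
    """
    name: str
    start_age: int | None
    end_age: int
    first_window: tuple | None = None
    second_window: tuple | None = None
    interval_window: tuple | None = None
    candidates: tuple = ()


DEFAULT_TRAITS = (
    TraitDefinition("BW", None, 0,
                    candidates=("C(sex)", "C(batch)", "C(parity)",
                                "litter_size", "litter_live")),
    TraitDefinition("G_0_21", 0, 21,
                    candidates=("C(sex)", "C(batch)", "C(parity)",
                                "start_weight", "group_size")),
    TraitDefinition("G_21_46", 21, 46,
                    candidates=("C(sex)", "C(batch)", "C(parity)",
                                "start_weight", "group_size")),
    TraitDefinition("G_46_120", 46, 120, second_window=(119, 130),
                    candidates=("C(sex)", "C(batch)", "C(parity)",
                                "start_weight", "measure_age")),
    TraitDefinition("G_120_210", 120, 210, first_window=(119, 130),
                    second_window=(209, 213), interval_window=(80, 90),
                    candidates=("C(sex)", "C(batch)", "C(parity)",
                                "start_weight", "interval", "C(castration)")),
    TraitDefinition("G_46_210", 46, 210, second_window=(205, 213),
                    candidates=("C(sex)", "C(batch)", "C(parity)",
                                "start_weight", "C(moved)", "C(castration)")),
    TraitDefinition("G_210_240", 210, 240, first_window=(207, 211),
                    second_window=(237, 242), interval_window=(27, 34),
                    candidates=("C(sex)", "C(batch)", "C(parity)",
                                "measure_age", "interval", "C(moved)",
                                "C(castration)", "C(starved)")),
)


def _weight_col(age: int) -> str:
    return f"weight_{age}"


def _age_col(age: int) -> str:
    return f"age_{age}"


def derive_traits(records: pd.DataFrame,
                  definitions=DEFAULT_TRAITS) -> pd.DataFrame:
    """Trait values per individual: BW is the birth weight, a growth trait is
    the weight difference between its endpoint measurements. Individuals
    missing an endpoint are left NaN for that trait. A ``declined`` column
    flags animals whose weight fell between successive measurements (the
    final post-starvation weight excepted)."""
    out = pd.DataFrame({"individual": records["individual"]})
    for tdef in definitions:
        if tdef.start_age is None:
            out[tdef.name] = records[_weight_col(0)]
        else:
            w0 = records[_weight_col(tdef.start_age)]
            w1 = records[_weight_col(tdef.end_age)]
            out[tdef.name] = w1 - w0
    starved = records.get("starved", pd.Series(False, index=records.index))
    declined = np.zeros(len(records), dtype=bool)
    present = [a for a in MEASUREMENT_AGES if _weight_col(a) in records.columns]
    W = records[[_weight_col(a) for a in present]].to_numpy(float)
    for i in range(len(records)):
        w = W[i]
        ok = ~np.isnan(w)
        vals = w[ok]
        if len(vals) < 2:
            continue
        drops = np.flatnonzero(np.diff(vals) < 0)
        for k in drops:
            final = k == len(vals) - 2
            if final and bool(starved.iloc[i]):
                continue                     # starved before last weighing
            declined[i] = True
    out["declined"] = declined
    return out


def apply_filters(records: pd.DataFrame, trait: TraitDefinition,
                  traits: pd.DataFrame | None = None) -> pd.Series:
    """Boolean inclusion mask for one trait.

    Applies the measurement-age and interval windows, removes weight
    decliners and pre-endpoint deaths, and (for growth after day 46)
    excludes females of batches 1-2, which were managed differently.
    """
    keep = pd.Series(True, index=records.index)
    if traits is not None and "declined" in traits.columns:
        keep &= ~traits["declined"].to_numpy()
    if "died" in records.columns:
        keep &= ~records["died"].fillna(False).astype(bool)

    if trait.start_age is not None:
        for age in (trait.start_age, trait.end_age):
            keep &= records[_weight_col(age)].notna()
        a0 = records.get(_age_col(trait.start_age))
        a1 = records.get(_age_col(trait.end_age))
        if trait.first_window is not None and a0 is not None:
            lo, hi = trait.first_window
            keep &= (a0 >= lo) & (a0 <= hi)
        if trait.second_window is not None and a1 is not None:
            lo, hi = trait.second_window
            keep &= (a1 >= lo) & (a1 <= hi)
        if trait.interval_window is not None and a0 is not None and a1 is not None:
            lo, hi = trait.interval_window
            iv = a1 - a0
            keep &= (iv >= lo) & (iv <= hi)
        if trait.end_age > 46 and {"sex", "batch"} <= set(records.columns):
            early_female = (records["sex"] == "F") & records["batch"].isin([1, 2])
            keep &= ~early_female
    else:
        keep &= records[_weight_col(0)].notna()
    return keep


def effective_mother(records: pd.DataFrame, trait: TraitDefinition) -> pd.Series:
    """The maternal grouping for a trait: the birth mother for birth weight,
    the rearing (foster) mother, where one exists, for growth after birth."""
    mother = records["mother"].copy()
    if trait.start_age is None or "foster_mother" not in records.columns:
        return mother
    foster = records["foster_mother"]
    return mother.where(foster.isna(), foster)


# ---------------------------------------------------------------------------
# mixed model


def reml_loglik(y: np.ndarray, X: np.ndarray, groups: np.ndarray,
                tau2: float, sigma2: float) -> float:
    """Restricted log-likelihood of a Gaussian random-intercept model.

    V is block diagonal with blocks sigma2*I + tau2*J per group, so every
    determinant and quadratic form is available in closed form. Evaluating
    both the with- and without-mother models through this one function keeps
    their likelihoods on the same constant convention for the LRT.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    codes, _ = pd.factorize(np.asarray(groups))
    logdetV = 0.0
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    ytVy = 0.0
    for g in np.unique(codes):
        idx = codes == g
        ng = int(idx.sum())
        Xg, yg = X[idx], y[idx]
        denom = sigma2 + ng * tau2
        logdetV += (ng - 1) * np.log(sigma2) + np.log(denom)
        # V_g^{-1} = (I - (tau2/denom) J) / sigma2
        sx = Xg.sum(axis=0)
        sy = yg.sum()
        XtVX += (Xg.T @ Xg - (tau2 / denom) * np.outer(sx, sx)) / sigma2
        XtVy += (Xg.T @ yg - (tau2 / denom) * sx * sy) / sigma2
        ytVy += (yg @ yg - (tau2 / denom) * sy ** 2) / sigma2
    beta = np.linalg.solve(XtVX, XtVy)
    quad = ytVy - XtVy @ beta
    sign, logdetX = np.linalg.slogdet(XtVX)
    return float(-0.5 * (logdetV + logdetX + quad + (n - p) * np.log(2 * np.pi)))


@dataclass
class BaseModelFit:
    trait: str
    formula: str
    X: np.ndarray
    design_info: object
    groups: np.ndarray
    beta: np.ndarray
    cov_beta: np.ndarray
    mother_var: float
    sigma2: float
    loglik: float                    # restricted log-likelihood
    adjusted: np.ndarray             # conditional residuals y~
    blups: dict
    y: np.ndarray
    index: pd.Index

    @property
    def residual_variance(self) -> float:
        return self.sigma2


def _fit_random_intercept(y, X, groups):
    """REML random-intercept fit; returns (beta, cov_beta, tau2, sigma2,
    blups_by_group)."""
    from .lmm import fit_random_intercept

    res = fit_random_intercept(y, X, groups)
    return res.beta, res.cov_beta, res.tau2, res.sigma2, res.blups


def fit_base_model(data: pd.DataFrame, y, formula_terms, groups="mother",
                   trait: str = "trait") -> BaseModelFit:
    """REML fit of the explanatory variables with mother as a random effect.

    ``formula_terms`` is a sequence of patsy terms (e.g. ``["C(sex)",
    "start_weight"]``); the intercept is implicit. The adjusted phenotype is
    y - X beta - BLUP(mother)."""
    yv = np.asarray(data[y] if isinstance(y, str) else y, float)
    rhs = " + ".join(formula_terms) if formula_terms else "1"
    dm = patsy.dmatrix(rhs, data, return_type="dataframe")
    X = dm.to_numpy(float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"singular fixed-effect design for terms {list(formula_terms)}; "
            "drop aliased terms"
        )
    grp = np.asarray(data[groups] if isinstance(groups, str) else groups)
    if len(set(grp)) < 2:
        raise ValueError("need at least two mothers for the random effect")
    beta, cov, tau2, sigma2, blups = _fit_random_intercept(yv, X, grp)
    ll = reml_loglik(yv, X, grp, max(tau2, 0.0), sigma2)
    blup_vec = np.array([blups.get(g, 0.0) for g in grp])
    adjusted = yv - X @ beta - blup_vec
    return BaseModelFit(
        trait=trait, formula=rhs, X=X, design_info=dm.design_info, groups=grp,
        beta=beta, cov_beta=cov, mother_var=tau2, sigma2=sigma2, loglik=ll,
        adjusted=adjusted, blups=blups, y=yv,
        index=data.index if hasattr(data, "index") else pd.RangeIndex(len(yv)),
    )


def test_fixed_effect(fit: BaseModelFit, term: str) -> float:
    """p-value for one fixed term: Wald F with the residual variance as
    denominator, referred to chi-square via d*F ~ chi2_d."""
    sl = fit.design_info.term_name_slices.get(term)
    if sl is None:
        raise KeyError(f"term {term!r} not in model ({list(fit.design_info.term_names)})")
    idx = np.arange(fit.X.shape[1])[sl]
    d = len(idx)
    if d == 0:
        raise ValueError(f"term {term!r} has zero degrees of freedom")
    b = fit.beta[idx]
    V = fit.cov_beta[np.ix_(idx, idx)]
    F = float(b @ np.linalg.solve(V, b)) / d
    return float(stats.chi2.sf(d * F, d))


def fit_fixed_only(data: pd.DataFrame, y, formula_terms) -> tuple:
    """OLS fit without the mother term; returns (rss-based sigma2 REML,
    restricted loglik on the shared convention, residuals)."""
    yv = np.asarray(data[y] if isinstance(y, str) else y, float)
    rhs = " + ".join(formula_terms) if formula_terms else "1"
    dm = patsy.dmatrix(rhs, data, return_type="dataframe")
    X = dm.to_numpy(float)
    beta, _, rank, _ = np.linalg.lstsq(X, yv, rcond=None)
    resid = yv - X @ beta
    sigma2 = float(resid @ resid) / (len(yv) - rank)
    dummy_groups = np.arange(len(yv))        # tau2 = 0 makes grouping inert
    ll = reml_loglik(yv, X, dummy_groups, 0.0, sigma2)
    return ll, sigma2, resid


def test_mother(fit_with: BaseModelFit, loglik_without: float,
                null: str = "chi2_1") -> float:
    """REML likelihood-ratio test for the maternal variance component.

    ``null`` selects the reference distribution: "chi2_1" (conservative
    default) or "mixture" for the 50:50 chi2_0/chi2_1 boundary mixture.
    """
    lr = 2.0 * (fit_with.loglik - loglik_without)
    lr = max(lr, 0.0)
    p = float(stats.chi2.sf(lr, 1))
    if null == "mixture":
        p = 0.5 * p if lr > 0 else 1.0
    return p


def backward_select(data: pd.DataFrame, y, candidates, groups="mother",
                    alpha: float = 0.05, trait: str = "trait",
                    test_mother_effect: bool = True) -> BaseModelFit:
    """The base-model selection loop: fit all candidates, repeatedly remove
    the fixed term with the highest p >= alpha (ties resolved by dropping the
    later term in declaration order), refit and retest until every remaining
    term is significant. The maternal random effect is kept when its REML LRT
    is significant; otherwise the final fit simply carries a ~zero variance
    component."""
    terms = list(candidates)
    while True:
        fit = fit_base_model(data, y, terms, groups=groups, trait=trait)
        if not terms:
            break
        pvals = [test_fixed_effect(fit, t) for t in terms]
        worst = max(range(len(terms)), key=lambda k: (pvals[k], k))
        if pvals[worst] < alpha:
            break
        terms.pop(worst)
    if test_mother_effect:
        ll0, _, _ = fit_fixed_only(data, y, terms)
        fit.mother_p = test_mother(fit, ll0)
    fit.selected_terms = terms
    return fit


def coarsen_move_age(move_age: pd.Series, y_adjusted: np.ndarray,
                     bin_days: int = 6, merge_tol_se: float = 1.0) -> pd.Series:
    """Collapse a move-age covariate into a few levels.

    Starts from ``bin_days``-wide bins ("not moved" its own level), merges
    adjacent bins whose effect estimates differ by less than ``merge_tol_se``
    pooled standard errors, then shifts each remaining boundary across a
    +/- ``bin_days`` window to maximize the explained sum of squares.
    Returns a string-labelled factor aligned to the input.
    """
    ages = pd.to_numeric(move_age, errors="coerce")
    moved = ages.notna()
    y = np.asarray(y_adjusted, float)
    if moved.sum() == 0:
        return pd.Series("not_moved", index=move_age.index)

    lo = int(np.floor(ages[moved].min()))
    edges = list(np.arange(lo, ages[moved].max() + bin_days, bin_days))
    if len(edges) < 2:
        edges = [lo, lo + bin_days]

    def _levels(edges_):
        lev = np.full(len(ages), -1)      # -1 = not moved
        a = ages.to_numpy(float)
        for k in range(len(edges_) - 1):
            sel = moved.to_numpy() & (a >= edges_[k]) & (a < edges_[k + 1])
            lev[sel] = k
        sel = moved.to_numpy() & (a >= edges_[-1])
        lev[sel] = len(edges_) - 2
        return lev

    def _ess(edges_):
        lev = _levels(edges_)
        tot = ((y - y.mean()) ** 2).sum()
        rss = sum(((y[lev == g] - y[lev == g].mean()) ** 2).sum()
                  for g in np.unique(lev) if (lev == g).sum() > 0)
        return tot - rss

    # merge similar adjacent bins
    while len(edges) > 2:
        lev = _levels(edges)
        stats_ = {}
        for g in range(len(edges) - 1):
            sel = lev == g
            ng = sel.sum()
            if ng:
                stats_[g] = (y[sel].mean(), y[sel].var(ddof=1) / ng if ng > 1 else np.inf)
        mergeable = None
        best_gap = np.inf
        keys = sorted(stats_)
        for a_, b_ in zip(keys, keys[1:]):
            m1, v1 = stats_[a_]
            m2, v2 = stats_[b_]
            se = np.sqrt(v1 + v2)
            gap = abs(m1 - m2) / se if se > 0 else 0.0
            if gap < merge_tol_se and gap < best_gap:
                best_gap = gap
                mergeable = b_
        if mergeable is None:
            break
        edges.pop(mergeable)

    # boundary refinement
    for k in range(1, len(edges) - 1):
        candidates = [edges[k] + s for s in range(-bin_days, bin_days + 1)]
        candidates = [c for c in candidates if edges[k - 1] < c < edges[k + 1]]
        edges[k] = max(candidates, key=lambda c: _ess(edges[:k] + [c] + edges[k + 1:]))

    lev = _levels(edges)
    labels = np.where(lev == -1, "not_moved",
                      np.array([f"moved_{int(edges[g]) if g >= 0 else 0}"
                                for g in np.maximum(lev, 0)]))
    return pd.Series(labels, index=move_age.index)
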