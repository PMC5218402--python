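"""Background-conditional decomposition of epistatic effects.

For an epistatic pair the fitted coefficients do not read directly as
additive and dominance effects: in the F-inf parameterization the
interaction terms shift a locus's effect depending on the partner genotype.
The decomposition works from genotypic values. With A(EE), A(EW), A(WW) =
-1, 0, 1 and D = 0, 1, 0 the genotypic value of combination (g1, g2) is

    G(g1, g2) = a1' A(g1) + d1' D(g1) + a2' A(g2) + d2' D(g2)
                + i_aa A(g1) A(g2) + i_ad A(g1) D(g2)
                + i_da D(g1) A(g2) + i_dd D(g1) D(g2)

relative to the mean of the all-homozygote classes. The additive effect of
locus 1 conditional on partner genotype X is (G(WW,X) - G(EE,X))/2 and the
dominance effect G(EW,X) - (G(WW,X) + G(EE,X))/2, exactly as in the
single-locus model; expanding gives the closed forms

    a1(X) = a1' + A(X) i_aa + D(X) i_ad
    d1(X) = d1' + A(X) i_da + D(X) i_dd        (and symmetrically for locus 2).

Under linkage equilibrium the (1/4, 1/2, 1/4)-weighted average of the
conditional effects recovers the single-locus coefficients. Every effect is
a linear combination c of model coefficients, so its standard error is
sqrt(c' V c) with V the fitted coefficient covariance; t tests are
Holm-corrected within a pair's family of 12 effects (24, at level 0.1, for
a locus shared between two pairs). Reported effects are standardized by the
square root of the base model's residual variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .modelbuild import (FittedGeneticModel, GeneticModelSpec, PairTerm,
                         fit_mixed_design)

__all__ = [
    "GENOTYPES", "genotypic_values", "conditional_effects", "effect_se",
    "holm_adjust", "variance_explained", "independent_effects_model",
    "epistasis_plot_data",
]

GENOTYPES = ("EE", "EW", "WW")
_A = {"EE": -1.0, "EW": 0.0, "WW": 1.0}
_D = {"EE": 0.0, "EW": 1.0, "WW": 0.0}


class LinearCombo(dict):
    """Sparse linear combination over model coefficient names."""

    def vector(self, fit: FittedGeneticModel) -> np.ndarray:
        c = np.zeros(len(fit.names))
        lookup = {nm: i for i, nm in enumerate(fit.names)}
        for nm, w in self.items():
            if nm in lookup:            # aliased coefficients were dropped
                c[lookup[nm]] += w
        return c

    def value(self, fit: FittedGeneticModel) -> float:
        return float(self.vector(fit) @ fit.coef)


def _pair_combo(pair: PairTerm, g1: str, g2: str) -> LinearCombo:
    l1, l2 = pair.locus1, pair.locus2
    key = pair.loci
    return LinearCombo({
        ("a", l1): _A[g1], ("d", l1): _D[g1],
        ("a", l2): _A[g2], ("d", l2): _D[g2],
        ("i_aa", key): _A[g1] * _A[g2], ("i_ad", key): _A[g1] * _D[g2],
        ("i_da", key): _D[g1] * _A[g2], ("i_dd", key): _D[g1] * _D[g2],
    })


def _triple_combo(pair12: PairTerm, pair13: PairTerm,
                  g1: str, g2: str, g3: str) -> LinearCombo:
    """Genotypic value for a locus interacting with two partners; pair12 and
    pair13 share their first locus."""
    combo = _pair_combo(pair12, g1, g2)
    extra = _pair_combo(pair13, g1, g3)
    for nm, w in extra.items():
        if nm[0] in ("a", "d") and nm[1] == pair13.locus1:
            continue                      # shared locus main effect once
        combo[nm] = combo.get(nm, 0.0) + w
    return combo


def genotypic_values(fit: FittedGeneticModel, pair: PairTerm,
                     pair2: PairTerm | None = None,
                     standardize_var: float | None = None) -> pd.DataFrame:
    """Genotypic values (relative to the all-homozygote mean) for the 9
    genotype combinations of a pair, or the 27 of a shared-locus triple
    (``pair2`` sharing its first locus with ``pair``)."""
    rows = []
    if pair2 is None:
        for g1 in GENOTYPES:
            for g2 in GENOTYPES:
                combo = _pair_combo(pair, g1, g2)
                rows.append({"g1": g1, "g2": g2, "combo": combo})
    else:
        if pair.locus1 != pair2.locus1:
            raise ValueError("triple requires the shared locus first in both pairs")
        for g1 in GENOTYPES:
            for g2 in GENOTYPES:
                for g3 in GENOTYPES:
                    combo = _triple_combo(pair, pair2, g1, g2, g3)
                    rows.append({"g1": g1, "g2": g2, "g3": g3, "combo": combo})
    for r in rows:
        c = r.pop("combo")
        r["value"] = c.value(fit)
        r["se"] = effect_se(c, fit)
        if standardize_var is not None:
            r["standardized"] = r["value"] / np.sqrt(standardize_var)
    return pd.DataFrame(rows)


def conditional_effects(fit: FittedGeneticModel, pair: PairTerm,
                        pair2: PairTerm | None = None,
                        standardize_var: float | None = None) -> pd.DataFrame:
    """The 12 background-conditional effects of a pair (closed forms above),
    or the extended set when the first locus of ``pair`` also interacts with
    ``pair2``'s partner: the shared locus's effects are then indexed by the
    genotype pair at both partners (18 effects) while the partners' own
    effects still condition only on the shared locus (12 more)."""
    rows = []

    def locus_effects(locus, partner_key, which, cond_label, Ax, Dx):
        # which: 1 if locus is first in its pair else 2
        if which == 1:
            a = LinearCombo({("a", locus): 1.0, ("i_aa", partner_key): Ax,
                             ("i_ad", partner_key): Dx})
            d = LinearCombo({("d", locus): 1.0, ("i_da", partner_key): Ax,
                             ("i_dd", partner_key): Dx})
        else:
            a = LinearCombo({("a", locus): 1.0, ("i_aa", partner_key): Ax,
                             ("i_da", partner_key): Dx})
            d = LinearCombo({("d", locus): 1.0, ("i_ad", partner_key): Ax,
                             ("i_dd", partner_key): Dx})
        for kind, combo in (("additive", a), ("dominance", d)):
            rows.append({"locus": locus, "background": cond_label,
                         "kind": kind, "combo": combo})

    if pair2 is None:
        for g in GENOTYPES:
            locus_effects(pair.locus1, pair.loci, 1, g, _A[g], _D[g])
        for g in GENOTYPES:
            locus_effects(pair.locus2, pair.loci, 2, g, _A[g], _D[g])
    else:
        if pair.locus1 != pair2.locus1:
            raise ValueError("triple requires the shared locus first in both pairs")
        shared = pair.locus1
        for g2 in GENOTYPES:
            for g3 in GENOTYPES:
                a = LinearCombo({("a", shared): 1.0,
                                 ("i_aa", pair.loci): _A[g2],
                                 ("i_ad", pair.loci): _D[g2],
                                 ("i_aa", pair2.loci): _A[g3],
                                 ("i_ad", pair2.loci): _D[g3]})
                d = LinearCombo({("d", shared): 1.0,
                                 ("i_da", pair.loci): _A[g2],
                                 ("i_dd", pair.loci): _D[g2],
                                 ("i_da", pair2.loci): _A[g3],
                                 ("i_dd", pair2.loci): _D[g3]})
                for kind, combo in (("additive", a), ("dominance", d)):
                    rows.append({"locus": shared, "background": (g2, g3),
                                 "kind": kind, "combo": combo})
        for g in GENOTYPES:
            locus_effects(pair.locus2, pair.loci, 2, g, _A[g], _D[g])
        for g in GENOTYPES:
            locus_effects(pair2.locus2, pair2.loci, 2, g, _A[g], _D[g])

    for r in rows:
        combo = r.pop("combo")
        r["estimate"] = combo.value(fit)
        r["se"] = effect_se(combo, fit)
        z = r["estimate"] / r["se"] if r["se"] > 0 else 0.0
        r["p"] = float(2 * stats.norm.sf(abs(z)))
        if standardize_var is not None:
            r["standardized"] = r["estimate"] / np.sqrt(standardize_var)
    df = pd.DataFrame(rows)
    alpha = 0.05 if pair2 is None else 0.1
    df["significant"] = holm_adjust(df["p"].to_numpy(), alpha=alpha)
    df["nominal"] = df["p"].to_numpy() < 0.025
    return df


def effect_se(combo, fit: FittedGeneticModel) -> float:
    """Standard error of a linear combination of coefficients from the
    fitted covariance: sqrt(c' V c)."""
    c = combo.vector(fit) if isinstance(combo, LinearCombo) else np.asarray(combo, float)
    var = float(c @ fit.cov @ c)
    if var < -1e-8:
        raise ValueError("coefficient covariance not PSD along the contrast")
    return float(np.sqrt(max(var, 0.0)))


def holm_adjust(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Holm step-down significance flags at family level ``alpha``.

    The smallest p is compared with alpha/m, the next with alpha/(m-1), and
    so on; the procedure stops at the first failure.
    """
    p = np.asarray(pvalues, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    flags = np.zeros(m, dtype=bool)
    for rank, i in enumerate(order):
        if p[i] <= alpha / (m - rank):
            flags[i] = True
        else:
            break
    return flags


def variance_explained(fit: FittedGeneticModel, drop_names, base_pss: float,
                       ) -> float:
    """Percent of base-model residual variation explained by a term set:
    100 * (PSS without the terms - PSS with them) / PSS of the base model."""
    drop = set(drop_names)
    present = [nm for nm in fit.names if nm in drop]
    if not present:
        if drop & set(getattr(fit, "dropped", [])):
            return 0.0                  # terms were aliased out of the design
        raise KeyError("none of the requested terms are in the model")
    keep = [i for i, nm in enumerate(fit.names) if nm not in drop]
    reduced = fit_mixed_design(fit.y, fit.X[:, keep], fit.groups,
                               [fit.names[i] for i in keep])
    pct = 100.0 * (reduced.pss - fit.pss) / base_pss
    # the REML variance estimates are re-profiled in the reduced model, so
    # PSS is not exactly monotone; tolerate sub-half-percent noise only
    if pct < -0.5:
        raise ValueError("reduced model has materially lower PSS than the "
                         "full model; refit failed")
    return float(pct)


def pair_term_names(pair: PairTerm, include_loci: bool = True) -> list:
    names = [(k, pair.loci) for k in ("i_aa", "i_ad", "i_da", "i_dd")]
    if include_loci:
        for key in pair.loci:
            names.extend([("a", key), ("d", key)])
    return names


def independent_effects_model(y, data, covariate_terms, grid, qtls,
                              groups: str = "mother",
                              base_sigma2: float | None = None,
                              alpha_joint: float = 0.05,
                              alpha_t: float = 0.025):
    """The no-interaction comparator: covariates + mother + per-locus (a, d)
    for the single-locus-scan QTL set, fit by REML. Returns (fit, table of
    per-locus tests with standardized coefficients)."""
    from .modelbuild import fit_full_model

    spec = GeneticModelSpec(trait="independent")
    spec.independent = [(q.chromosome, float(q.position)) for q in qtls]
    fit = fit_full_model(y, data, covariate_terms, grid, spec, groups)
    rows = []
    for key in spec.independent:
        p_joint = fit.wald_p([("a", key), ("d", key)])
        p_a, p_d = fit.t_p(("a", key)), fit.t_p(("d", key))
        sig = p_joint < alpha_joint or p_a < alpha_t or p_d < alpha_t
        a_hat = fit.coef[fit.idx(("a", key))[0]]
        d_hat = fit.coef[fit.idx(("d", key))[0]]
        row = {"locus": key, "a": a_hat, "d": d_hat, "p_joint": p_joint,
               "p_a": p_a, "p_d": p_d, "significant": sig}
        if base_sigma2 is not None:
            row["a_std"] = a_hat / np.sqrt(base_sigma2)
            row["d_std"] = d_hat / np.sqrt(base_sigma2)
        rows.append(row)
    return fit, pd.DataFrame(rows)


def epistasis_plot_data(gvt: pd.DataFrame, base_sigma2: float) -> pd.DataFrame:
    """Long-format plot table of standardized genotypic values: x-axis
    genotype at the first locus ordered EE, EW, WW, one line per genotype at
    the second locus (per conditioning genotype at a third locus for
    triples). Parallel lines mean no interaction."""
    df = gvt.copy()
    df["standardized"] = df["value"] / np.sqrt(base_sigma2)
    order = {g: i for i, g in enumerate(GENOTYPES)}
    sort_cols = [c for c in ("g3", "g2", "g1") if c in df.columns]
    df = df.sort_values(sort_cols, key=lambda s: s.map(order)).reset_index(drop=True)
    cols = [c for c in ("g1", "g2", "g3") if c in df.columns]
    return df[cols + ["value", "standardized"]]
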