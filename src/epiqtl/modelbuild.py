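"""Assembly and simplification of the full genetic model.

The putative QTL from the single-locus scan and the putative epistatic
pairs from the two-locus scan are combined into one mixed model of the raw
phenotype:

    y = mu + X beta + Z gamma
        + sum_r (a_r A_r + d_r D_r)
        + sum_s (a'_{s1} A_{s1} + d'_{s1} D_{s1} + a'_{s2} A_{s2}
                 + d'_{s2} D_{s2} + i_aa I_AA + i_ad I_AD
                 + i_da I_DA + i_dd I_DD) + e

with gamma the random maternal intercepts. A pair locus within 20 cM of a
putative QTL (or inside its span) is treated as the same locus and enters
only through the pair, at the two-locus-analysis position. Simplification
removes non-significant pairs one at a time (highest joint interaction p
first), demoting matched loci back to independent QTL with their position
re-chosen by REML log-likelihood, until every remaining pair is significant;
pair loci within 20 cM of each other in different pairs are then merged.
Detected pairs are finally probed at the other ages (pointwise tests), and
left-over independent loci kept only if jointly or marginally significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import patsy
from scipy import stats

from .grids import ADGrid
from .phenotypes import reml_loglik
from .scan import PutativeQTL

__all__ = [
    "LocusKey", "PairTerm", "GeneticModelSpec", "FittedGeneticModel",
    "match_loci", "assemble_model", "fit_full_model", "simplify",
    "crossage_pointwise", "test_independent_loci", "unify_across_ages",
]

LocusKey = tuple        # (chromosome, position)
INTERACTION_KINDS = ("i_aa", "i_ad", "i_da", "i_dd")


@dataclass(frozen=True)
class PairTerm:
    locus1: LocusKey
    locus2: LocusKey
    pointwise: bool = False
    order: int = 0          # addition order; later pairs lose ties

    @property
    def loci(self):
        return (self.locus1, self.locus2)


@dataclass
class GeneticModelSpec:
    trait: str = "trait"
    independent: list = field(default_factory=list)     # LocusKey
    pairs: list = field(default_factory=list)           # PairTerm
    matches: dict = field(default_factory=dict)         # LocusKey -> PutativeQTL

    def loci(self) -> list:
        seen = {}
        for key in self.independent:
            seen.setdefault(key, None)
        for pair in self.pairs:
            for key in pair.loci:
                seen.setdefault(key, None)
        return list(seen)

    def copy(self) -> "GeneticModelSpec":
        return GeneticModelSpec(self.trait, list(self.independent),
                                list(self.pairs), dict(self.matches))


@dataclass
class FittedGeneticModel:
    spec: GeneticModelSpec
    names: list                     # coefficient identifiers
    coef: np.ndarray
    cov: np.ndarray                 # fixed-coefficient covariance
    sigma2: float
    mother_var: float
    loglik: float
    pss: float
    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray | None = None
    dropped: list = field(default_factory=list)

    def idx(self, *names) -> np.ndarray:
        lookup = {nm: i for i, nm in enumerate(self.names)}
        return np.array([lookup[nm] for nm in names])

    def wald_p(self, names) -> float:
        """chi2 approximation of d*F for a coefficient subset; aliased
        (dropped) coefficients contribute nothing."""
        names = [nm for nm in names if nm in set(self.names)]
        if not names:
            return 1.0
        idx = self.idx(*names)
        b = self.coef[idx]
        V = self.cov[np.ix_(idx, idx)]
        try:
            stat = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError:
            Vp = np.linalg.pinv(V, hermitian=True)
            stat = float(b @ Vp @ b)
        return float(stats.chi2.sf(stat, len(idx)))

    def t_p(self, name) -> float:
        if name not in set(self.names):
            return 1.0
        i = self.idx(name)[0]
        se = np.sqrt(max(self.cov[i, i], 0.0))
        if se == 0:
            return 1.0
        z = self.coef[i] / se
        return float(2 * stats.norm.sf(abs(z)))

    def interaction_p(self, pair: PairTerm) -> dict:
        names = [(k, pair.loci) for k in INTERACTION_KINDS]
        p_joint = self.wald_p(names)
        p_coef = {k: self.t_p((k, pair.loci)) for k in INTERACTION_KINDS}
        return {"p_joint": p_joint, "p_coef": p_coef}

    def pair_significant(self, pair: PairTerm, alpha_joint=0.05,
                         alpha_coef=0.0125) -> bool:
        t = self.interaction_p(pair)
        return t["p_joint"] < alpha_joint or min(t["p_coef"].values()) < alpha_coef


def match_loci(pair_locus: LocusKey, qtls, max_dist: float = 20.0):
    """The putative QTL a pair locus should be identified with, if any:
    same chromosome and within ``max_dist`` cM of the peak or inside the
    span. The nearest peak wins when several match."""
    chrom, pos = pair_locus
    best, best_d = None, np.inf
    for q in qtls:
        if q.chromosome != chrom:
            continue
        d = abs(q.position - pos)
        if d <= max_dist + 1e-9 or q.contains(pos):
            if d < best_d:
                best, best_d = q, d
    return best


def assemble_model(trait: str, qtls, candidate_pairs,
                   max_dist: float = 20.0) -> GeneticModelSpec:
    """Initial full-model spec: pair loci absorb matching putative QTL (the
    two-locus-analysis position is used); unmatched putative QTL enter as
    independent loci; similar positions among different pairs stay separate
    loci until the post-simplification merge."""
    spec = GeneticModelSpec(trait=trait)
    matched_qtls = set()
    for k, cand in enumerate(candidate_pairs):
        l1 = (cand["chrom1"], float(cand["pos1"]))
        l2 = (cand["chrom2"], float(cand["pos2"]))
        spec.pairs.append(PairTerm(l1, l2, order=k))
        for key in (l1, l2):
            q = match_loci(key, qtls, max_dist)
            if q is not None:
                spec.matches[key] = q
                matched_qtls.add(id(q))
    for q in qtls:
        if id(q) not in matched_qtls:
            spec.independent.append((q.chromosome, float(q.position)))
    return spec


def _locus_columns(grid: ADGrid, key: LocusKey):
    j = grid.nearest_index(key[0], key[1])
    return grid.A[:, j], grid.D[:, j]


def fit_full_model(y, data: pd.DataFrame, covariate_terms, grid: ADGrid,
                   spec: GeneticModelSpec, groups: str = "mother",
                   ) -> FittedGeneticModel:
    """REML fit of the full mixed model for a given locus/pair structure."""
    yv = np.asarray(data[y] if isinstance(y, str) else y, float)
    rhs = " + ".join(covariate_terms) if covariate_terms else "1"
    dm = patsy.dmatrix(rhs, data, return_type="dataframe")
    cols = [dm.to_numpy(float)]
    names = [("cov", c) for c in dm.columns]
    locus_ad = {}
    for key in spec.loci():
        A, D = _locus_columns(grid, key)
        locus_ad[key] = (A, D)
        cols.append(np.column_stack([A, D]))
        names.extend([("a", key), ("d", key)])
    for pair in spec.pairs:
        A1, D1 = locus_ad[pair.locus1]
        A2, D2 = locus_ad[pair.locus2]
        cols.append(np.column_stack([A1 * A2, A1 * D2, D1 * A2, D1 * D2]))
        names.extend([(k, pair.loci) for k in INTERACTION_KINDS])
    X = np.hstack(cols)
    X, names, dropped = _drop_aliased(X, names)
    grp = np.asarray(data[groups])
    fit = fit_mixed_design(yv, X, grp, names)
    fit.spec = spec
    fit.dropped = dropped
    return fit


def _drop_aliased(X: np.ndarray, names: list):
    """Remove exactly collinear columns (first occurrence kept). Happens when
    pairs share loci whose scores satisfy algebraic identities (with 0/1
    genotype scores A^2 = 1 - D), or when merged loci coincide."""
    n, p = X.shape
    if np.linalg.matrix_rank(X) == p:
        return X, names, []
    keep, dropped = [], []
    R = np.empty((n, 0))
    for j in range(p):
        trial = np.column_stack([R, X[:, j]])
        if np.linalg.matrix_rank(trial) > R.shape[1]:
            R = trial
            keep.append(j)
        else:
            dropped.append(names[j])
    return X[:, keep], [names[j] for j in keep], dropped


def fit_mixed_design(y: np.ndarray, X: np.ndarray, groups: np.ndarray,
                     names: list) -> FittedGeneticModel:
    """REML random-intercept fit of an explicit design matrix.

    PSS is the penalised residual sum of squares at the REML solution:
    ||y - X b - Z g||^2 + (sigma2/tau2) ||g||^2 with g the BLUPs.
    """
    from .lmm import fit_random_intercept

    res = fit_random_intercept(np.asarray(y, float), X, groups)
    return FittedGeneticModel(spec=None, names=list(names), coef=res.beta,
                              cov=res.cov_beta, sigma2=res.sigma2,
                              mother_var=res.tau2, loglik=res.loglik,
                              pss=res.pss, X=X, y=np.asarray(y, float),
                              groups=np.asarray(groups))


def _best_position(y, data, covariate_terms, grid, spec, locus_key,
                   candidates, groups="mother"):
    """Replace ``locus_key`` by each candidate position in turn and keep the
    one with the highest REML log-likelihood (first candidate wins ties —
    pass the two-locus-analysis position first)."""
    best_key, best_ll = None, -np.inf
    for cand in candidates:
        trial = spec.copy()
        trial.independent = [cand if k == locus_key else k
                             for k in trial.independent]
        trial.pairs = [replace(p,
                               locus1=cand if p.locus1 == locus_key else p.locus1,
                               locus2=cand if p.locus2 == locus_key else p.locus2)
                       for p in trial.pairs]
        try:
            fit = fit_full_model(y, data, covariate_terms, grid, trial, groups)
        except ValueError:
            continue
        if fit.loglik > best_ll + 1e-9:
            best_key, best_ll = cand, fit.loglik
    return best_key if best_key is not None else locus_key


def simplify(y, data, covariate_terms, grid, spec: GeneticModelSpec,
             groups: str = "mother", alpha_joint: float = 0.05,
             alpha_coef: float = 0.0125, merge_dist: float = 20.0,
             max_iter: int = 50) -> tuple:
    """Sequential removal of non-significant pairs, with locus demotion,
    position reassessment and the final 20 cM pair-locus merge. Returns
    (final spec, final fit)."""
    spec = spec.copy()
    for _ in range(max_iter):
        fit = fit_full_model(y, data, covariate_terms, grid, spec, groups)
        failing = []
        for pair in spec.pairs:
            t = fit.interaction_p(pair)
            ok = (t["p_joint"] < alpha_joint
                  or min(t["p_coef"].values()) < alpha_coef)
            if not ok:
                failing.append((t["p_joint"], pair.order, pair))
        if not failing:
            break
        _, _, worst = max(failing, key=lambda r: (r[0], r[1]))
        spec.pairs = [p for p in spec.pairs if p is not worst]
        for key in worst.loci:
            still_in_pair = any(
                k[0] == key[0] and abs(k[1] - key[1]) <= merge_dist
                for p in spec.pairs for k in p.loci
            )
            matched = spec.matches.get(key)
            if matched is not None and not still_in_pair:
                spec.independent.append(key)
                if abs(matched.position - key[1]) > 1e-9:
                    cands = [key, (matched.chromosome, float(matched.position))]
                    best = _best_position(y, data, covariate_terms, grid,
                                          spec, key, cands, groups)
                    spec.independent = [best if k == key else k
                                        for k in spec.independent]
    else:
        raise RuntimeError(f"simplification did not converge in {max_iter} steps")

    # merge pair loci within merge_dist of each other across different pairs
    changed = True
    while changed:
        changed = False
        keyed = [(k, pi) for pi, p in enumerate(spec.pairs) for k in p.loci]
        for i in range(len(keyed)):
            for j in range(i + 1, len(keyed)):
                (k1, p1), (k2, p2) = keyed[i], keyed[j]
                if p1 == p2 or k1 == k2 or k1[0] != k2[0]:
                    continue
                if abs(k1[1] - k2[1]) <= merge_dist:
                    best = _merge_positions(y, data, covariate_terms, grid,
                                            spec, k1, k2, groups)
                    spec.pairs = [replace(
                        p,
                        locus1=best if p.locus1 in (k1, k2) else p.locus1,
                        locus2=best if p.locus2 in (k1, k2) else p.locus2,
                    ) for p in spec.pairs]
                    changed = True
                    break
            if changed:
                break
    # merging can leave two pairs on identical loci; keep the earlier one
    seen = set()
    unique = []
    for p in spec.pairs:
        key = frozenset(((p.locus1), (p.locus2)))
        if key not in seen:
            seen.add(key)
            unique.append(p)
    spec.pairs = unique
    fit = fit_full_model(y, data, covariate_terms, grid, spec, groups)
    return spec, fit


def _merge_positions(y, data, covariate_terms, grid, spec, k1, k2, groups):
    """Log-likelihood comparison of the two candidate positions for a merged
    locus."""
    best, best_ll = k1, -np.inf
    for cand in (k1, k2):
        trial = spec.copy()
        trial.pairs = [replace(
            p,
            locus1=cand if p.locus1 in (k1, k2) else p.locus1,
            locus2=cand if p.locus2 in (k1, k2) else p.locus2,
        ) for p in trial.pairs]
        try:
            fit = fit_full_model(y, data, covariate_terms, grid, trial, groups)
        except ValueError:
            continue
        if fit.loglik > best_ll + 1e-9:
            best, best_ll = cand, fit.loglik
    return best


def crossage_pointwise(results: dict, alpha_joint: float = 0.05,
                       alpha_coef: float = 0.0125,
                       match_dist: float = 20.0) -> dict:
    """Probe each detected epistatic pair in every other trait's model.

    ``results`` maps trait -> dict with keys y, data, covariate_terms, grid,
    spec (final GeneticModelSpec), qtls. Each foreign pair is added alone to
    the trait's model (matching putative QTL removed); pairs significant
    alone are then, if more than one, also evaluated jointly, and those
    passing are retained flagged ``pointwise``. Returns trait -> (spec, fit).
    """
    all_pairs = []
    for trait, r in results.items():
        for pair in r["spec"].pairs:
            key = (pair.locus1, pair.locus2)
            if key not in [(p.locus1, p.locus2) for _, p in all_pairs]:
                all_pairs.append((trait, pair))

    out = {}
    for trait, r in results.items():
        spec = r["spec"].copy()
        own = {(p.locus1, p.locus2) for p in spec.pairs}
        foreign = [p for src, p in all_pairs if src != trait
                   and (p.locus1, p.locus2) not in own]
        singly = []
        next_order = max([p.order for p in spec.pairs], default=-1) + 1
        for pair in foreign:
            trial = _with_pair(spec, pair, r["qtls"], match_dist, next_order)
            try:
                fit = fit_full_model(r["y"], r["data"], r["covariate_terms"],
                                     r["grid"], trial)
            except ValueError:
                continue
            added = trial.pairs[-1]
            if fit.pair_significant(added, alpha_joint, alpha_coef):
                singly.append(pair)
        keep = singly
        if len(singly) > 1:
            trial = spec.copy()
            for pair in singly:
                trial = _with_pair(trial, pair, r["qtls"], match_dist, next_order)
                next_order += 1
            fit = fit_full_model(r["y"], r["data"], r["covariate_terms"],
                                 r["grid"], trial)
            keep = [p for p, tp in zip(singly, trial.pairs[-len(singly):])
                    if fit.pair_significant(tp, alpha_joint, alpha_coef)]
        final = spec
        for pair in keep:
            final = _with_pair(final, pair, r["qtls"], match_dist, next_order,
                               pointwise=True)
            next_order += 1
        fit = fit_full_model(r["y"], r["data"], r["covariate_terms"],
                             r["grid"], final)
        out[trait] = (final, fit)
    return out


def _with_pair(spec: GeneticModelSpec, pair: PairTerm, qtls, match_dist,
               order, pointwise: bool = True) -> GeneticModelSpec:
    trial = spec.copy()
    new = PairTerm(pair.locus1, pair.locus2, pointwise=pointwise, order=order)
    trial.pairs.append(new)
    for key in new.loci:
        trial.independent = [
            k for k in trial.independent
            if not (k[0] == key[0] and abs(k[1] - key[1]) <= match_dist)
        ]
        q = match_loci(key, qtls, match_dist)
        if q is not None:
            trial.matches.setdefault(key, q)
    return trial


def test_independent_loci(fit: FittedGeneticModel, alpha_joint: float = 0.05,
                          alpha_t: float = 0.025) -> list:
    """Independent QTL surviving the joint-F-or-marginal-t criterion."""
    kept = []
    for key in fit.spec.independent:
        p_joint = fit.wald_p([("a", key), ("d", key)])
        p_a = fit.t_p(("a", key))
        p_d = fit.t_p(("d", key))
        if p_joint < alpha_joint or p_a < alpha_t or p_d < alpha_t:
            kept.append({"locus": key, "p_joint": p_joint,
                         "p_a": p_a, "p_d": p_d})
    return kept


def unify_across_ages(locus_records, max_dist: float = 30.0) -> pd.DataFrame:
    """Group loci from all traits into cross-age QTL by single-linkage
    chaining at ``max_dist`` cM per chromosome.

    ``locus_records`` is an iterable of dicts with keys trait, chromosome,
    position, epistatic (bool) and optionally pointwise (bool). Returns a
    table with one row per (QTL, trait) occurrence; QTL are labelled
    Q<chromosome>.<k> in map order.
    """
    records = sorted(locus_records,
                     key=lambda r: (str(r["chromosome"]), r["position"]))
    rows = []
    by_chrom = {}
    for r in records:
        by_chrom.setdefault(r["chromosome"], []).append(r)
    for chrom, recs in by_chrom.items():
        groups = []
        for r in recs:                      # recs sorted by position
            if groups and r["position"] - groups[-1][-1]["position"] <= max_dist:
                groups[-1].append(r)
            else:
                groups.append([r])
        multiple = len(groups) > 1
        for k, grp in enumerate(groups, start=1):
            name = f"Q{chrom}.{k}" if multiple else f"Q{chrom}"
            for r in grp:
                rows.append({
                    "QTL": name, "chromosome": chrom,
                    "position": r["position"], "trait": r["trait"],
                    "epistatic": bool(r.get("epistatic", False)),
                    "pointwise": bool(r.get("pointwise", False)),
                })
    return pd.DataFrame(rows, columns=["QTL", "chromosome", "position",
                                       "trait", "epistatic", "pointwise"])
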