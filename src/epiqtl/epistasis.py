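"""Exhaustive two-locus epistasis scan with permutation SSE thresholds.

For every eligible pair of grid positions the nine-parameter model

    y~ = mu + a1' A1 + d1' D1 + a2' A2 + d2' D2
         + i_aa A1 A2 + i_ad A1 D2 + i_da D1 A2 + i_dd D1 D2 + e

is fit by OLS and judged on its residual sum of squares (SSE): a lower SSE
is a better joint fit. Two permutation thresholds govern which pairs are
kept. SSE_genome is the alpha quantile of the per-permutation minimum SSE
over all pairs when the phenotype is permuted against the whole grid.
SSE_specific, computed per putative QTL from the single-locus analysis,
keeps that locus's A/D columns fixed and permutes the partner position's
rows (interaction columns rebuilt from the permuted partner), so it
discounts the SSE reduction the known locus causes on its own. Pairs with a
position inside a QTL span are tested against that locus's SSE_specific
(the lowest when both positions fall in spans); everything else against
SSE_genome. Retained pairs form clusters on the pair lattice; one candidate
per cluster (the pair with its SSE furthest below the governing threshold)
goes forward to an interaction test, after an edge-effect check along QTL
span boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .grids import ADGrid
from .scan import PutativeQTL

__all__ = [
    "TwoLocusFit", "PairScan", "two_locus_fit", "pair_indices",
    "pair_sse_scan", "genomewide_sse_threshold", "locus_specific_sse_threshold",
    "apply_thresholds", "select_cluster_peaks", "interaction_test",
]

COEF_NAMES = ("mu", "a1", "d1", "a2", "d2", "i_aa", "i_ad", "i_da", "i_dd")
INTERACTION_IDX = np.array([5, 6, 7, 8])


@dataclass
class TwoLocusFit:
    """OLS fit of the 9-parameter two-locus model at one position pair."""
    chrom1: object
    pos1: float
    chrom2: object
    pos2: float
    coef: np.ndarray                 # ordered as COEF_NAMES
    cov: np.ndarray                  # coefficient covariance (sigma^2 (X'X)^-1)
    sse: float
    df_resid: int

    @property
    def coefficients(self) -> dict:
        return dict(zip(COEF_NAMES, self.coef))


def _pair_design(A1, D1, A2, D2) -> np.ndarray:
    n = len(A1)
    return np.column_stack([
        np.ones(n), A1, D1, A2, D2,
        A1 * A2, A1 * D2, D1 * A2, D1 * D2,
    ])


def two_locus_fit(y, A1, D1, A2, D2, meta=(None, np.nan, None, np.nan)) -> TwoLocusFit:
    y = np.asarray(y, float)
    X = _pair_design(np.asarray(A1, float), np.asarray(D1, float),
                     np.asarray(A2, float), np.asarray(D2, float))
    n, p = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sse = float(resid @ resid)
    df_resid = n - rank
    sigma2 = sse / df_resid if df_resid > 0 else np.nan
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    return TwoLocusFit(meta[0], meta[1], meta[2], meta[3],
                       coef=beta, cov=cov, sse=sse, df_resid=df_resid)


def pair_indices(grid: ADGrid, min_same_chrom_sep: float = 20.0) -> np.ndarray:
    """Eligible (i, j) grid-index pairs, i < j: every between-chromosome pair
    plus same-chromosome pairs at least ``min_same_chrom_sep`` cM apart."""
    P = grid.n_positions
    ii, jj = np.triu_indices(P, k=1)
    same = grid.chromosomes[ii] == grid.chromosomes[jj]
    far = np.abs(grid.positions[ii] - grid.positions[jj]) >= min_same_chrom_sep - 1e-9
    keep = ~same | far
    return np.column_stack([ii[keep], jj[keep]])


def _sse_matrix(Y: np.ndarray, grid: ADGrid, pairs: np.ndarray) -> np.ndarray:
    """SSE of the two-locus model for every pair (rows) x phenotype column.

    Uses per-pair 9x9 grams: SSE = y'y - s' G^+ s with s = X'y.
    """
    n, B = Y.shape
    X = np.empty((len(pairs), n, 9))
    A, D = grid.A, grid.D
    i, j = pairs[:, 0], pairs[:, 1]
    X[:, :, 0] = 1.0
    X[:, :, 1] = A[:, i].T
    X[:, :, 2] = D[:, i].T
    X[:, :, 3] = A[:, j].T
    X[:, :, 4] = D[:, j].T
    X[:, :, 5] = X[:, :, 1] * X[:, :, 3]
    X[:, :, 6] = X[:, :, 1] * X[:, :, 4]
    X[:, :, 7] = X[:, :, 2] * X[:, :, 3]
    X[:, :, 8] = X[:, :, 2] * X[:, :, 4]
    G = np.einsum("pni,pnj->pij", X, X)
    Ginv = np.linalg.pinv(G, hermitian=True)
    S = np.einsum("pni,nb->pib", X, Y)
    ess = np.einsum("pib,pij,pjb->pb", S, Ginv, S)
    yty = np.einsum("nb,nb->b", Y, Y)
    return np.maximum(yty[None, :] - ess, 0.0)


@dataclass
class PairScan:
    """Two-locus SSE surface over the eligible pair lattice."""
    trait: str
    grid: ADGrid
    pairs: np.ndarray                # (n_pairs, 2) grid indices
    sse: np.ndarray                  # (n_pairs,)
    sse_genome: float | None = None
    sse_specific: dict = field(default_factory=dict)   # PutativeQTL idx -> thr
    governing: np.ndarray | None = None
    retained: np.ndarray | None = None
    heat: np.ndarray | None = None


def pair_sse_scan(y: np.ndarray, grid: ADGrid, trait: str = "trait",
                  min_same_chrom_sep: float = 20.0) -> PairScan:
    y = np.asarray(y, float)
    pairs = pair_indices(grid, min_same_chrom_sep)
    sse = _sse_matrix(y[:, None], grid, pairs)[:, 0]
    return PairScan(trait=trait, grid=grid, pairs=pairs, sse=sse)


def genomewide_sse_threshold(y: np.ndarray, grid: ADGrid, n_perm: int = 1000,
                             alpha: float = 0.05, rng=None,
                             coarse_step: float = 5.0,
                             min_same_chrom_sep: float = 20.0) -> float:
    """alpha quantile of per-permutation minimum SSE over eligible pairs.

    The per-permutation minimisation is an exhaustive search on a grid
    coarsened to ``coarse_step`` cM (set to the scan resolution for the exact
    full-grid search)."""
    rng = np.random.default_rng(rng)
    y = np.asarray(y, float)
    n = len(y)
    cgrid = _coarsen(grid, coarse_step)
    pairs = pair_indices(cgrid, min_same_chrom_sep)
    perms = np.column_stack([y[rng.permutation(n)] for _ in range(n_perm)])
    sse = _sse_matrix(perms, cgrid, pairs)
    minima = sse.min(axis=0)
    return float(np.quantile(minima, alpha))


def _coarsen(grid: ADGrid, step: float) -> ADGrid:
    keep = []
    for chrom in dict.fromkeys(grid.chromosomes):
        on = np.flatnonzero(grid.chromosomes == chrom)
        pos = grid.positions[on]
        targets = np.arange(pos.min(), pos.max() + step / 2, step)
        for t in targets:
            keep.append(on[np.argmin(np.abs(pos - t))])
    keep = np.unique(keep)
    return ADGrid(grid.individuals, grid.chromosomes[keep], grid.positions[keep],
                  grid.A[:, keep], grid.D[:, keep])


def locus_specific_sse_threshold(y: np.ndarray, qtl: PutativeQTL, grid: ADGrid,
                                 n_perm: int = 1000, alpha: float = 0.05,
                                 rng=None, coarse_step: float = 5.0,
                                 min_same_chrom_sep: float = 20.0) -> float:
    """Permutation SSE threshold conditional on a known locus.

    The locus's A/D columns stay tied to the phenotype; the partner
    position's A and D rows are jointly permuted and the four interaction
    columns rebuilt from the permuted partner. The per-permutation statistic
    is the minimum SSE over all eligible partner positions."""
    rng = np.random.default_rng(rng)
    y = np.asarray(y, float)
    n = len(y)
    cgrid = _coarsen(grid, coarse_step)
    jq = cgrid.nearest_index(qtl.chromosome, qtl.position)
    Aq, Dq = cgrid.A[:, jq], cgrid.D[:, jq]
    partner = np.array([
        j for j in range(cgrid.n_positions)
        if j != jq and (cgrid.chromosomes[j] != qtl.chromosome
                        or abs(cgrid.positions[j] - qtl.position)
                        >= min_same_chrom_sep - 1e-9)
    ])
    P = len(partner)
    yty = float(y @ y)
    X = np.empty((P, n, 9))
    X[:, :, 0] = 1.0
    X[:, :, 1] = Aq
    X[:, :, 2] = Dq
    minima = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        Ap = cgrid.A[perm][:, partner].T            # (P, n)
        Dp = cgrid.D[perm][:, partner].T
        X[:, :, 3] = Ap
        X[:, :, 4] = Dp
        X[:, :, 5] = Aq[None, :] * Ap
        X[:, :, 6] = Aq[None, :] * Dp
        X[:, :, 7] = Dq[None, :] * Ap
        X[:, :, 8] = Dq[None, :] * Dp
        G = np.einsum("pni,pnj->pij", X, X)
        Ginv = np.linalg.pinv(G, hermitian=True)
        s = np.einsum("pni,n->pi", X, y)
        ess = np.einsum("pi,pij,pj->p", s, Ginv, s)
        minima[b] = yty - ess.max()
    return float(np.quantile(minima, alpha))


def apply_thresholds(scan: PairScan, qtls: list, sse_genome: float,
                     sse_specific: dict) -> PairScan:
    """Assign each pair its governing threshold and the heat value.

    A pair with a position inside a putative QTL's span is governed by that
    locus's SSE_specific; with both positions inside spans, by the lowest
    SSE_specific of the loci involved. A locus whose SSE_specific exceeds
    SSE_genome contributes no span restriction (the genomewide threshold is
    already the stricter bound there). All other pairs are governed by
    SSE_genome. heat = governing threshold - SSE; retained where heat > 0.
    """
    grid = scan.grid
    gov = np.full(len(scan.pairs), sse_genome)
    in_span = np.zeros((len(qtls), grid.n_positions), dtype=bool)
    for k, q in enumerate(qtls):
        in_span[k] = ((grid.chromosomes == q.chromosome)
                      & (grid.positions >= q.span[0] - 1e-9)
                      & (grid.positions <= q.span[1] + 1e-9))
    for idx in range(len(scan.pairs)):
        i, j = scan.pairs[idx]
        specs = [sse_specific[k] for k in range(len(qtls))
                 if (in_span[k, i] or in_span[k, j]) and sse_specific[k] < sse_genome]
        if specs:
            gov[idx] = min(specs)
    scan.sse_genome = sse_genome
    scan.sse_specific = dict(sse_specific)
    scan.governing = gov
    scan.heat = gov - scan.sse
    scan.retained = scan.heat > 0
    return scan


def _pair_matrix(scan: PairScan, values: np.ndarray, fill=np.nan) -> np.ndarray:
    P = scan.grid.n_positions
    M = np.full((P, P), fill, dtype=float)
    i, j = scan.pairs[:, 0], scan.pairs[:, 1]
    M[i, j] = values
    M[j, i] = values
    return M


def select_cluster_peaks(scan: PairScan) -> list:
    """One candidate pair per connected cluster of retained pairs.

    Clusters are 8-connected components on the pair lattice. The candidate
    is the pair with the highest heat (lowest SSE beneath its governing
    threshold). Edge-effect rule: a cluster formed along a QTL-span boundary
    (it touches lattice cells governed by a different threshold) is discarded
    when an adjacent cell across the boundary holds a lower absolute SSE than
    anything in the cluster.
    """
    if scan.retained is None:
        raise ValueError("thresholds not applied")
    retained = _pair_matrix(scan, scan.retained.astype(float), fill=0.0) > 0
    heat = _pair_matrix(scan, scan.heat)
    sse = _pair_matrix(scan, scan.sse)
    gov = _pair_matrix(scan, scan.governing)
    labels, n_lab = ndimage.label(retained, structure=np.ones((3, 3), dtype=int))
    grid = scan.grid
    out = []
    shifts = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
              if (di, dj) != (0, 0)]
    P = grid.n_positions
    for lab in range(1, n_lab + 1):
        cells = np.argwhere(labels == lab)
        # keep only the upper triangle representative of the symmetric lattice
        cells = cells[cells[:, 0] < cells[:, 1]]
        if len(cells) == 0:
            continue
        h = heat[cells[:, 0], cells[:, 1]]
        best = cells[np.argmax(h)]
        cluster_min_sse = sse[cells[:, 0], cells[:, 1]].min()
        discard = False
        for ci, cj in cells:
            for di, dj in shifts:
                ni, nj = ci + di, cj + dj
                if not (0 <= ni < P and 0 <= nj < P):
                    continue
                if labels[ni, nj] == lab or np.isnan(gov[ni, nj]):
                    continue
                if gov[ni, nj] != gov[ci, cj] and sse[ni, nj] < cluster_min_sse:
                    discard = True
                    break
            if discard:
                break
        if discard:
            continue
        i, j = int(best[0]), int(best[1])
        out.append({
            "cluster": lab,
            "i": i, "j": j,
            "chrom1": grid.chromosomes[i], "pos1": float(grid.positions[i]),
            "chrom2": grid.chromosomes[j], "pos2": float(grid.positions[j]),
            "sse": float(sse[i, j]), "heat": float(heat[i, j]),
            "governing": float(gov[i, j]),
        })
    return out


def interaction_test(fit: TwoLocusFit, alpha_joint: float = 0.05,
                     alpha_coef: float = 0.0125) -> dict:
    """Joint 4-df F test of the interaction coefficients plus per-coefficient
    t tests; the pair passes at p < alpha_joint jointly or p < alpha_coef for
    any single interaction coefficient."""
    idx = INTERACTION_IDX
    b = fit.coef[idx]
    scale = max(1.0, float(np.abs(fit.coef).max()) ** 2)
    if fit.df_resid > 0 and fit.sse / fit.df_resid < 1e-20 * scale:
        # exact (noiseless) fit: a coefficient is either exactly present or 0
        present = bool((np.abs(b) > 1e-8 * np.sqrt(scale)).any())
        p = 0.0 if present else 1.0
        return {"F": np.inf if present else 0.0, "p_joint": p,
                "p_coef": {nm: p for nm in np.array(COEF_NAMES)[idx]},
                "pass": present}
    V = fit.cov[np.ix_(idx, idx)]
    Vinv = np.linalg.pinv(V, hermitian=True)
    df1 = int(np.linalg.matrix_rank(V))
    Fstat = float(b @ Vinv @ b) / max(df1, 1)
    p_joint = float(stats.f.sf(Fstat, max(df1, 1), fit.df_resid)) if df1 else 1.0
    se = np.sqrt(np.maximum(np.diag(V), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, b / se, 0.0)
    p_coef = 2 * stats.t.sf(np.abs(t), fit.df_resid)
    p_coef = np.where(se > 0, p_coef, 1.0)
    passed = (p_joint < alpha_joint) or bool((p_coef < alpha_coef).any())
    return {
        "F": Fstat, "p_joint": p_joint,
        "p_coef": dict(zip(np.array(COEF_NAMES)[idx], p_coef)),
        "pass": passed,
    }


def pair_table(scan: PairScan) -> pd.DataFrame:
    grid = scan.grid
    i, j = scan.pairs[:, 0], scan.pairs[:, 1]
    return pd.DataFrame({
        "trait": scan.trait,
        "chrom1": grid.chromosomes[i], "pos1": grid.positions[i],
        "chrom2": grid.chromosomes[j], "pos2": grid.positions[j],
        "SSE": scan.sse,
        "governing_threshold": scan.governing if scan.governing is not None else np.nan,
        "heat": scan.heat if scan.heat is not None else np.nan,
        "retained": scan.retained if scan.retained is not None else False,
    })
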