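"""Single-locus Haley-Knott genome scan with permutation thresholds.

At each grid position the adjusted phenotype is regressed on the additive
and dominance scores,

    y~ = mu + a A + d D + e,

optionally conditioning on the A/D scores of already-detected loci. The test
statistic is the joint F ratio for (a, d). Genomewide significance is set
empirically: the phenotype vector is permuted against the whole genotype
grid, the maximum F over all positions recorded per permutation, and the
threshold taken as the upper alpha quantile of those maxima. Putative QTL
are chromosome-wise peaks above the threshold; the surrounding
supra-threshold stretch (small gaps merged) is the QTL span. A forward
search conditions on all detected loci and rescans until no new peak
appears.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import ADGrid

__all__ = [
    "SingleLocusFit", "PutativeQTL", "ScanProfile",
    "hk_fit", "scan_profile", "permutation_threshold",
    "call_putative_qtl", "forward_search",
]

_RANK_TOL = 1e-10


@dataclass
class SingleLocusFit:
    chromosome: object
    position: float
    mu: float
    a: float
    d: float
    F_ratio: float
    sse: float
    df_test: int = 2


@dataclass
class PutativeQTL:
    chromosome: object
    position: float
    span: tuple
    peak_F: float

    def contains(self, position: float) -> bool:
        return self.span[0] - 1e-9 <= position <= self.span[1] + 1e-9


@dataclass
class ScanProfile:
    trait: str
    grid: ADGrid
    F: np.ndarray
    fits: list
    threshold: float | None = None
    n_perm: int = 0
    conditioning: list = field(default_factory=list)


def _residualize(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Project columns of M off the column space of C."""
    coef, *_ = np.linalg.lstsq(C, M, rcond=None)
    return M - C @ coef


def _condition_matrix(grid: ADGrid, conditioning, n: int) -> np.ndarray:
    cols = [np.ones(n)]
    for q in conditioning:
        j = grid.index_of(q.chromosome, q.position)
        cols.append(grid.A[:, j])
        cols.append(grid.D[:, j])
    return np.column_stack(cols)


def hk_fit(y: np.ndarray, A: np.ndarray, D: np.ndarray,
           conditioning_cols: np.ndarray | None = None) -> SingleLocusFit:
    """OLS fit of one position; F is the 2-df joint test of (a, d) given any
    conditioning columns (which must include the intercept)."""
    y = np.asarray(y, float)
    n = len(y)
    C = conditioning_cols if conditioning_cols is not None else np.ones((n, 1))
    X = np.column_stack([C, A, D])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sse = float(resid @ resid)
    r0 = _residualize(y[:, None], C)[:, 0]
    sse0 = float(r0 @ r0)
    df_test = rank - np.linalg.matrix_rank(C)
    df_resid = n - rank
    if df_test <= 0 or df_resid <= 0 or sse <= 0:
        F = 0.0
        df_test = max(df_test, 0)
    else:
        F = ((sse0 - sse) / df_test) / (sse / df_resid)
    return SingleLocusFit(chromosome=None, position=np.nan, mu=beta[0],
                          a=float(beta[-2]), d=float(beta[-1]),
                          F_ratio=float(max(F, 0.0)), sse=sse, df_test=int(df_test))


def _f_profile_matrix(Y: np.ndarray, grid: ADGrid, C: np.ndarray) -> np.ndarray:
    """F ratios for every position (rows) x every phenotype column of Y.

    Y has shape (n, B). Vectorized via residualization: with y and the A/D
    columns projected off the conditioning space, the 2-df F ratio follows
    from the cross-products alone.
    """
    n, B = Y.shape
    P = grid.n_positions
    q = C.shape[1]
    Yr = _residualize(Y, C)
    Ar = _residualize(grid.A, C)
    Dr = _residualize(grid.D, C)
    sse0 = np.einsum("nb,nb->b", Yr, Yr)

    # per-position 2x2 grams and cross-products
    gAA = np.einsum("np,np->p", Ar, Ar)
    gAD = np.einsum("np,np->p", Ar, Dr)
    gDD = np.einsum("np,np->p", Dr, Dr)
    sA = Ar.T @ Yr                       # (P, B)
    sD = Dr.T @ Yr
    det = gAA * gDD - gAD ** 2
    scaleref = np.maximum(gAA, gDD)
    ok = det > _RANK_TOL * np.maximum(scaleref, 1.0) ** 2
    ess = np.zeros((P, B))
    dft = np.full(P, 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        # explained SS for the 2-column case: s' G^{-1} s
        num = (gDD[:, None] * sA ** 2 - 2 * gAD[:, None] * sA * sD
               + gAA[:, None] * sD ** 2)
        ess[ok] = num[ok] / det[ok, None]
    rank1 = ~ok & (scaleref > _RANK_TOL)
    if rank1.any():
        # collinear A and D: 1-df test on whichever column has mass
        useA = gAA >= gDD
        g1 = np.where(useA, gAA, gDD)
        s1 = np.where(useA[:, None], sA, sD)
        ess[rank1] = s1[rank1] ** 2 / g1[rank1, None]
        dft[rank1] = 1
    dead = ~ok & ~rank1
    dft[dead] = 0
    sse = sse0[None, :] - ess
    df_resid = n - q - dft
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ess / np.maximum(dft, 1)[:, None]) / (sse / df_resid[:, None])
    F[dft == 0] = 0.0
    return np.maximum(np.nan_to_num(F, nan=0.0), 0.0)


def scan_profile(y: np.ndarray, grid: ADGrid, trait: str = "trait",
                 conditioning: list | None = None) -> ScanProfile:
    """F-ratio profile over every grid position."""
    conditioning = list(conditioning or [])
    y = np.asarray(y, float)
    C = _condition_matrix(grid, conditioning, len(y))
    F = _f_profile_matrix(y[:, None], grid, C)[:, 0]
    fits = []
    for j in range(grid.n_positions):
        fit = hk_fit(y, grid.A[:, j], grid.D[:, j], C)
        fit.chromosome = grid.chromosomes[j]
        fit.position = float(grid.positions[j])
        fits.append(fit)
    return ScanProfile(trait=trait, grid=grid, F=F, fits=fits,
                       conditioning=conditioning)


def permutation_threshold(y: np.ndarray, grid: ADGrid, n_perm: int = 1000,
                          alpha: float = 0.05, rng=None,
                          conditioning: list | None = None) -> float:
    """Genomewide F threshold from permutations of the phenotype against the
    whole grid: the empirical (1 - alpha) quantile of per-permutation maximum
    F ratios."""
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives an unstable "
                      "genomewide threshold", stacklevel=2)
    rng = np.random.default_rng(rng)
    y = np.asarray(y, float)
    n = len(y)
    C = _condition_matrix(grid, list(conditioning or []), n)
    perms = np.column_stack([y[rng.permutation(n)] for _ in range(n_perm)])
    F = _f_profile_matrix(perms, grid, C)
    maxima = F.max(axis=0)
    return float(np.quantile(maxima, 1.0 - alpha))


def call_putative_qtl(profile: ScanProfile, gap_max: float = 10.0) -> list:
    """Chromosome-wise peaks above the threshold with their QTL spans.

    The span is the contiguous supra-threshold stretch containing the peak;
    supra-threshold blocks separated by a sub-threshold gap of at most
    ``gap_max`` cM are merged into one stretch.
    """
    if profile.threshold is None:
        raise ValueError("scan profile has no permutation threshold")
    thr = profile.threshold
    grid = profile.grid
    out = []
    for chrom in dict.fromkeys(grid.chromosomes):
        on = np.flatnonzero(grid.chromosomes == chrom)
        pos = grid.positions[on]
        F = profile.F[on]
        above = F > thr
        if not above.any():
            continue
        # supra-threshold blocks as [start, end] position intervals
        blocks = []
        j = 0
        while j < len(on):
            if above[j]:
                k = j
                while k + 1 < len(on) and above[k + 1]:
                    k += 1
                blocks.append([pos[j], pos[k]])
                j = k + 1
            else:
                j += 1
        merged = [blocks[0]]
        for blk in blocks[1:]:
            if blk[0] - merged[-1][1] <= gap_max:
                merged[-1][1] = blk[1]
            else:
                merged.append(blk)
        peak_j = int(np.argmax(F))
        peak_pos = float(pos[peak_j])
        span = next(b for b in merged if b[0] - 1e-9 <= peak_pos <= b[1] + 1e-9)
        out.append(PutativeQTL(chromosome=chrom, position=peak_pos,
                               span=(float(span[0]), float(span[1])),
                               peak_F=float(F[peak_j])))
    return out


def forward_search(y: np.ndarray, grid: ADGrid, trait: str = "trait",
                   n_perm: int = 1000, alpha: float = 0.05, rng=None,
                   gap_max: float = 10.0, threshold: float | None = None,
                   max_rounds: int = 10) -> tuple:
    """Iterative conditional scan: detect, condition on everything detected,
    rescan with the same genomewide threshold, until no new QTL appears.

    A chromosome already carrying a putative QTL can contribute a further
    locus only at a peak outside every existing span on that chromosome.
    Returns (list of PutativeQTL, final ScanProfile).
    """
    rng = np.random.default_rng(rng)
    if threshold is None:
        threshold = permutation_threshold(y, grid, n_perm=n_perm, alpha=alpha,
                                          rng=rng)
    detected = []
    profile = None
    for _ in range(max_rounds):
        profile = scan_profile(y, grid, trait=trait, conditioning=detected)
        profile.threshold = threshold
        profile.n_perm = n_perm
        calls = call_putative_qtl(profile, gap_max=gap_max)
        new = []
        for q in calls:
            covered = any(
                d.chromosome == q.chromosome and
                (d.contains(q.position) or abs(d.position - q.position) < 1e-9)
                for d in detected
            )
            if not covered:
                new.append(q)
        if not new:
            return detected, profile
        detected.extend(new)
    raise RuntimeError("forward search did not converge within "
                       f"{max_rounds} rounds")


def scan_table(profile: ScanProfile) -> pd.DataFrame:
    """Per-position scan results as a tidy table."""
    rows = []
    for fit, F in zip(profile.fits, profile.F):
        rows.append({
            "trait": profile.trait, "chromosome": fit.chromosome,
            "position": fit.position, "a": fit.a, "d": fit.d, "F": F,
            "supra_threshold": bool(profile.threshold is not None
                                    and F > profile.threshold),
        })
    return pd.DataFrame(rows)
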