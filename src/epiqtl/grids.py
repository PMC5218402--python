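"""Containers for line-origin probabilities and the A/D regression variables.

An F2 from a two-line cross carries, at every genome position, zero, one or
two alleles descended from each founder line (E or W). The regression
variables used for interval mapping are linear in the genotype posteriors:

    A = p(WW) - p(EE)        (additive score, in [-1, 1])
    D = p(EW)                (dominance score, in [0, 1])

where p(X) is the posterior probability of line-origin genotype X and EW
pools both orderings of the heterozygote.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["LineOriginGrid", "ADGrid", "ad_variables"]


@dataclass
class LineOriginGrid:
    """Line-origin posteriors for one chromosome, all individuals.

    ``probs`` has shape (n_individuals, n_positions, 3) ordered
    (p(EE), p(EW), p(WW)); rows sum to 1 at every position.
    """

    chromosome: object
    positions: np.ndarray
    individuals: list
    probs: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        n, p, k = self.probs.shape
        if k != 3 or n != len(self.individuals) or p != len(self.positions):
            raise ValueError("probs shape does not match individuals/positions")
        total = self.probs.sum(axis=2)
        if not np.allclose(total, 1.0, atol=1e-9):
            raise ValueError("line-origin posteriors are not normalized")

    @property
    def A(self) -> np.ndarray:
        return self.probs[:, :, 2] - self.probs[:, :, 0]

    @property
    def D(self) -> np.ndarray:
        return self.probs[:, :, 1]


def ad_variables(grid: LineOriginGrid) -> pd.DataFrame:
    """A and D per individual and position, long format, from the posteriors."""
    recs = []
    for i, ind in enumerate(grid.individuals):
        for j, pos in enumerate(grid.positions):
            recs.append((ind, grid.chromosome, pos, grid.A[i, j], grid.D[i, j]))
    return pd.DataFrame(recs, columns=["individual", "chromosome", "position", "A", "D"])


class ADGrid:
    """Genome-wide A/D variables: matrices of shape (n_individuals, n_positions).

    Positions are identified by (chromosome, position_cM) pairs, concatenated
    chromosome by chromosome in map order. This is the object every scan
    consumes; it can be built from HMM posteriors, from simulated true
    line origins, or read from an A/D table on disk.
    """

    def __init__(self, individuals, chromosomes, positions, A, D):
        self.individuals = list(individuals)
        self.chromosomes = np.asarray(chromosomes)
        self.positions = np.asarray(positions, dtype=float)
        self.A = np.asarray(A, dtype=float)
        self.D = np.asarray(D, dtype=float)
        n, p = self.A.shape
        if self.D.shape != (n, p) or len(self.individuals) != n \
                or len(self.positions) != p or len(self.chromosomes) != p:
            raise ValueError("inconsistent ADGrid dimensions")
        if np.any(self.A < -1 - 1e-9) or np.any(self.A > 1 + 1e-9):
            raise ValueError("A values outside [-1, 1]")
        if np.any(self.D < -1e-9) or np.any(self.D > 1 + 1e-9):
            raise ValueError("D values outside [0, 1]")

    @property
    def n_individuals(self) -> int:
        return self.A.shape[0]

    @property
    def n_positions(self) -> int:
        return self.A.shape[1]

    @classmethod
    def from_line_origin_grids(cls, grids) -> "ADGrid":
        grids = list(grids)
        inds = grids[0].individuals
        for g in grids:
            if g.individuals != inds:
                raise ValueError("chromosome grids cover different individuals")
        chroms = np.concatenate([[g.chromosome] * len(g.positions) for g in grids])
        pos = np.concatenate([g.positions for g in grids])
        A = np.hstack([g.A for g in grids])
        D = np.hstack([g.D for g in grids])
        return cls(inds, chroms, pos, A, D)

    def index_of(self, chromosome, position) -> int:
        hit = np.flatnonzero(
            (self.chromosomes == chromosome)
            & np.isclose(self.positions, position, atol=1e-6)
        )
        if len(hit) == 0:
            raise KeyError(f"no grid position {chromosome}:{position}")
        return int(hit[0])

    def nearest_index(self, chromosome, position) -> int:
        on = np.flatnonzero(self.chromosomes == chromosome)
        if len(on) == 0:
            raise KeyError(f"no such chromosome: {chromosome}")
        return int(on[np.argmin(np.abs(self.positions[on] - position))])

    def subset_individuals(self, individuals) -> "ADGrid":
        lookup = {ind: i for i, ind in enumerate(self.individuals)}
        idx = [lookup[i] for i in individuals]
        return ADGrid(list(individuals), self.chromosomes, self.positions,
                      self.A[idx], self.D[idx])

    def to_frame(self) -> pd.DataFrame:
        """Wide table with columns '<chromosome>.<position>.A' / '.D'."""
        data = {}
        for j in range(self.n_positions):
            stem = f"{self.chromosomes[j]}.{_fmt_pos(self.positions[j])}"
            data[f"{stem}.A"] = self.A[:, j]
            data[f"{stem}.D"] = self.D[:, j]
        df = pd.DataFrame(data)
        df.insert(0, "individual", self.individuals)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ADGrid":
        cols = [c for c in df.columns if c != "individual"]
        seen = {}
        for c in cols:
            parts = c.rsplit(".", 2)
            if len(parts) != 3 or parts[2] not in ("A", "D"):
                raise ValueError(f"cannot parse A/D column name: {c!r}")
            chrom, pos, kind = parts
            seen.setdefault((chrom, float(pos)), {})[kind] = c
        keys = list(seen)
        for key in keys:
            if set(seen[key]) != {"A", "D"}:
                raise ValueError(f"unpaired A/D columns at {key[0]}.{key[1]}")
        # preserve column order of first appearance
        A = np.column_stack([df[seen[k]["A"]].to_numpy(float) for k in keys])
        D = np.column_stack([df[seen[k]["D"]].to_numpy(float) for k in keys])
        chroms = [k[0] for k in keys]
        pos = [k[1] for k in keys]
        inds = list(df["individual"]) if "individual" in df.columns else list(range(len(df)))
        return cls(inds, chroms, pos, A, D)


def _fmt_pos(p: float) -> str:
    return f"{p:g}"
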