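"""Linkage-map arithmetic for an F2 line cross.

Sex-specific linkage maps are stored in centimorgans. Interval mapping under
the Haldane map function assumes no crossover interference, so maps estimated
under Kosambi (which models interference) are converted to Haldane distances
before any probability computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LinkageMap",
    "kosambi_to_haldane",
    "haldane_recombination",
    "haldane_distance",
    "convert_position",
    "read_map",
    "write_map",
]


def kosambi_to_haldane(distance_cM):
    """Convert a Kosambi map distance (cM) to the Haldane scale.

    The Kosambi inverse gives the recombination fraction
    ``r = 0.5 * tanh(2 d / 100)``; the Haldane map function then maps r back
    to a distance ``-50 * ln(1 - 2 r)``. Haldane distances are always at
    least as large as the Kosambi input because interference is dropped.
    """
    d = np.asarray(distance_cM, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distances must be non-negative")
    r = 0.5 * np.tanh(2.0 * d / 100.0)
    out = -50.0 * np.log1p(-2.0 * r)
    return out if out.ndim else float(out)


def haldane_recombination(distance_cM):
    """Recombination fraction for a Haldane map distance in cM.

    ``r = 0.5 * (1 - exp(-2 d / 100))``, in [0, 0.5).
    """
    d = np.asarray(distance_cM, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distances must be non-negative")
    r = 0.5 * -np.expm1(-2.0 * d / 100.0)
    return r if r.ndim else float(r)


def haldane_distance(r):
    """Inverse Haldane map function: recombination fraction -> distance (cM)."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = -50.0 * np.log1p(-2.0 * r)
    return d if d.ndim else float(d)


@dataclass
class LinkageMap:
    """Sex-specific marker map for one or more chromosomes.

    ``markers`` holds one row per marker with columns
    (chromosome, marker, female_cM, male_cM, sexavg_cM). Positions must be
    non-decreasing within a chromosome for every sex. ``map_function`` tags
    the scale the positions are on ("kosambi" or "haldane").
    """

    markers: pd.DataFrame
    map_function: str = "haldane"

    COLUMNS = ("chromosome", "marker", "female_cM", "male_cM", "sexavg_cM")

    def __post_init__(self):
        missing = set(self.COLUMNS) - set(self.markers.columns)
        if missing:
            raise ValueError(f"map table missing columns: {sorted(missing)}")
        if self.markers["marker"].duplicated().any():
            dup = self.markers.loc[self.markers["marker"].duplicated(), "marker"]
            raise ValueError(f"marker on more than one row: {sorted(set(dup))}")
        for chrom, sub in self.markers.groupby("chromosome", sort=False):
            for col in ("female_cM", "male_cM", "sexavg_cM"):
                pos = sub[col].to_numpy(float)
                if np.any(np.diff(pos) < 0):
                    raise ValueError(
                        f"positions in {col} decrease on chromosome {chrom}"
                    )

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.markers["chromosome"]))

    def chromosome(self, chrom) -> pd.DataFrame:
        sub = self.markers[self.markers["chromosome"] == chrom]
        if sub.empty:
            raise KeyError(f"no such chromosome: {chrom}")
        return sub.reset_index(drop=True)

    def to_haldane(self) -> "LinkageMap":
        """Return the map with all per-chromosome distances on the Haldane scale.

        Successive Kosambi inter-marker distances are converted interval by
        interval and re-accumulated from the first marker's position.
        """
        if self.map_function == "haldane":
            return self
        parts = []
        for chrom in self.chromosomes:
            sub = self.chromosome(chrom).copy()
            for col in ("female_cM", "male_cM", "sexavg_cM"):
                pos = sub[col].to_numpy(float)
                gaps = kosambi_to_haldane(np.diff(pos))
                sub[col] = pos[0] + np.concatenate([[0.0], np.cumsum(gaps)])
            parts.append(sub)
        return LinkageMap(pd.concat(parts, ignore_index=True), map_function="haldane")

    def sex_positions(self, chrom, positions, sex: str) -> np.ndarray:
        """Interpolate sex-averaged axis positions onto the female or male map.

        Piecewise linear between markers; beyond the terminal markers the
        slope of the nearest interval is extended (slope 1 for single-marker
        chromosomes).
        """
        sub = self.chromosome(chrom)
        col = {"female": "female_cM", "male": "male_cM"}[sex]
        x = sub["sexavg_cM"].to_numpy(float)
        y = sub[col].to_numpy(float)
        return _piecewise_interp(np.asarray(positions, float), x, y)


def _piecewise_interp(q: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Monotone piecewise-linear interpolation with end-slope extrapolation."""
    # collapse zero-length intervals so slopes are finite
    keep = np.concatenate([[True], np.diff(x) > 1e-12])
    x, y = x[keep], y[keep]
    if len(x) == 1:
        return y[0] + (q - x[0])
    out = np.interp(q, x, y)
    lo = q < x[0]
    hi = q > x[-1]
    if lo.any():
        s = (y[1] - y[0]) / (x[1] - x[0])
        out[lo] = y[0] + s * (q[lo] - x[0])
    if hi.any():
        s = (y[-1] - y[-2]) / (x[-1] - x[-2])
        out[hi] = y[-1] + s * (q[hi] - x[-1])
    return out


def convert_position(pos_cM, chrom, source_map: LinkageMap, target_map: LinkageMap,
                     sex: str = "sexavg") -> float:
    """Carry a position from one map to another by interpolating between the
    nearest flanking markers shared by both maps.

    Raises if the position has no shared marker on one side (no
    extrapolation: the position is reported instead of guessed at).
    """
    col = {"female": "female_cM", "male": "male_cM", "sexavg": "sexavg_cM"}[sex]
    src = source_map.chromosome(chrom)
    tgt = target_map.chromosome(chrom)
    shared = [m for m in src["marker"] if m in set(tgt["marker"])]
    if not shared:
        raise ValueError(f"no shared markers on chromosome {chrom}")
    s = src.set_index("marker").loc[shared, col].to_numpy(float)
    t = tgt.set_index("marker").loc[shared, col].to_numpy(float)
    order = np.argsort(s)
    s, t = s[order], t[order]
    pos = float(pos_cM)
    at = np.isclose(s, pos, atol=1e-9)
    if at.any():
        return float(t[np.argmax(at)])
    if pos < s[0] or pos > s[-1]:
        raise ValueError(
            f"position {pos} cM on chromosome {chrom} lies outside the shared "
            f"markers [{s[0]}, {s[-1]}]; refusing to extrapolate"
        )
    return float(np.interp(pos, s, t))


def read_map(path) -> LinkageMap:
    """Read a tab-delimited map file (chromosome, marker, female_cM, male_cM,
    sexavg_cM) with a header row."""
    df = pd.read_csv(path, sep="\t")
    df["chromosome"] = df["chromosome"].astype(str)
    df["marker"] = df["marker"].astype(str)
    return LinkageMap(df)


def write_map(lmap: LinkageMap, path) -> None:
    lmap.markers.to_csv(path, sep="\t", index=False)
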