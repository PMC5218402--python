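"""Readers and writers for the study's tab-delimited file formats.

All formats are plain TSV with a header row and "NA" for missing values:
marker maps (chromosome, marker, female_cM, male_cM, sexavg_cM), pedigrees
(individual, sire, dam, generation, line), long-format genotypes
(individual, marker, allele1, allele2), phenotype/covariate tables (one row
per individual), and the wide A/D grid whose columns are labelled
``<chromosome>.<position>.A`` / ``<chromosome>.<position>.D``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grids import ADGrid
from .maps import LinkageMap, read_map, write_map  # noqa: F401  (re-export)

__all__ = [
    "read_map", "write_map", "read_pedigree", "read_genotypes",
    "read_phenotype_table", "write_phenotype_table",
    "read_ad_grid", "write_ad_grid",
]


def read_pedigree(path) -> pd.DataFrame:
    ped = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"])
    required = {"individual", "sire", "dam", "generation"}
    missing = required - set(ped.columns)
    if missing:
        raise ValueError(f"pedigree file missing columns: {sorted(missing)}")
    return ped


def read_genotypes(path) -> dict:
    """Long-format genotype file -> {individual: {marker: (a1, a2) | None}}."""
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"])
    out = {}
    for ind, marker, a1, a2 in df.itertuples(index=False):
        geno = None if pd.isna(a1) or pd.isna(a2) else (_allele(a1), _allele(a2))
        out.setdefault(ind, {})[marker] = geno
    return out


def _allele(a: str):
    try:
        return int(a)
    except (TypeError, ValueError):
        return a


def write_genotypes(genotypes: dict, path) -> None:
    rows = []
    for ind, markers in genotypes.items():
        for mk, g in markers.items():
            rows.append((ind, mk, "NA" if g is None else g[0],
                         "NA" if g is None else g[1]))
    pd.DataFrame(rows, columns=["individual", "marker", "allele1", "allele2"]) \
        .to_csv(path, sep="\t", index=False)


def read_phenotype_table(path, required=(), numeric=()) -> pd.DataFrame:
    """Phenotype/explanatory-variable table; "NA" is missing. ``required``
    columns must be present; ``numeric`` columns are coerced with a row-level
    error on failure."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad)[0]) + 2  # header is line 1
            raise ValueError(f"non-numeric value in column {col!r} at line {line}")
        df[col] = coerced
    return df


def write_phenotype_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_ad_grid(path) -> ADGrid:
    """Wide A/D table with '<chromosome>.<position>.A/D' columns; validates
    pairing and value ranges (A in [-1, 1], D in [0, 1])."""
    df = pd.read_csv(path, sep="\t")
    return ADGrid.from_frame(df)


def write_ad_grid(grid: ADGrid, path) -> None:
    grid.to_frame().to_csv(path, sep="\t", index=False)
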