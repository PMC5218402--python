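"""Synthetic F2 line-cross studies with known genetic architecture.

The generator mirrors the design of a two-line pig intercross: a handful of
founder (F0) animals per line, an F1 generation, and a large F2 mapping
population. Founders are homozygous for line-labelled haplotypes; meiosis
places crossovers by a Poisson process on the sex-specific Haldane map (no
interference), so every F2 chromosome is a mosaic of E- and W-origin
segments whose true origin is retained as ground truth. Markers are
multi-allelic microsatellite-style loci whose line allele pools may overlap
(partial informativeness) and genotypes may be missing at random.

Phenotypes follow the additive/dominance/epistasis decomposition in the F-inf
parameterization: at a true genotype the additive score is A in {-1, 0, 1}
(W-allele count minus 1) and the dominance score D in {0, 1}; pair
interactions are products of these scores. A maternal random effect (one
draw per dam), balanced sex/batch covariates and Gaussian residual noise
complete the model, so the generating equation matches the full mixed model
the pipeline fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grids import ADGrid
from .maps import LinkageMap

__all__ = [
    "QTLLocus", "EpistaticPairSpec", "TraitSpec", "SimulationConfig",
    "SyntheticCross", "simulate_cross", "simulate_phenotypes",
    "true_ad_grid", "make_fixtures", "mini_config", "paper_scale_config",
]


@dataclass(frozen=True)
class QTLLocus:
    chromosome: object
    position: float
    a: float = 0.0
    d: float = 0.0


@dataclass(frozen=True)
class EpistaticPairSpec:
    """Interaction coefficients between two loci (indices into a trait's
    locus list)."""
    locus1: int
    locus2: int
    i_aa: float = 0.0
    i_ad: float = 0.0
    i_da: float = 0.0
    i_dd: float = 0.0


@dataclass(frozen=True)
class TraitSpec:
    name: str
    loci: tuple = ()
    pairs: tuple = ()
    maternal_var: float = 0.1
    residual_var: float = 1.0
    mean: float = 0.0
    sex_effect: float = 0.3
    batch_effects: tuple = (0.0, 0.2, -0.2)


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chrom_length_cM: float = 100.0
    markers_per_chromosome: int = 8
    female_expansion: float = 1.15
    male_expansion: float = 0.85
    alleles_per_line: int = 4
    shared_allele_prob: float = 0.3
    missing_rate: float = 0.03
    n_f0_dams: int = 17
    n_f0_sires: int = 2
    n_f1_dams: int = 59
    n_f1_sires: int = 9
    n_f2: int = 400
    traits: tuple = (TraitSpec("G"),)


def mini_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Two 100 cM chromosomes, 8 markers each, 400 F2 — the desk-scale preset."""
    cfg = SimulationConfig(seed=seed, n_chromosomes=2, chrom_length_cM=100.0,
                           markers_per_chromosome=8, n_f2=400,
                           n_f0_dams=4, n_f0_sires=2, n_f1_dams=20, n_f1_sires=5)
    return replace(cfg, **overrides)


def paper_scale_config(seed: int = 0, **overrides) -> SimulationConfig:
    """18 autosomes, ~10 markers each (178 total scale), ~1750 F2."""
    cfg = SimulationConfig(seed=seed, n_chromosomes=18, chrom_length_cM=130.0,
                           markers_per_chromosome=10, n_f2=1750)
    return replace(cfg, **overrides)


# ---------------------------------------------------------------------------
# cross structure


@dataclass
class _Gamete:
    """One transmitted chromosome: line origin as a step function.

    ``breaks`` are crossover positions on the relevant sex-specific map;
    origin at position p is ``start`` flipped once per crossover below p.
    """
    start: int                       # 0 = E, 1 = W
    breaks: np.ndarray

    def origin_at(self, pos_sex: np.ndarray) -> np.ndarray:
        pos_sex = np.atleast_1d(np.asarray(pos_sex, float))
        flips = np.searchsorted(self.breaks, pos_sex)
        return (self.start + flips) % 2


@dataclass
class SyntheticCross:
    config: SimulationConfig
    lmap: LinkageMap
    pedigree: pd.DataFrame
    genotypes: dict                  # individual -> {marker: (a1, a2) | None}
    founder_alleles: dict            # individual -> {marker: allele}
    maternal_gametes: dict           # F2 id -> {chrom: _Gamete} (female map)
    paternal_gametes: dict           # F2 id -> {chrom: _Gamete} (male map)
    f2_ids: list = field(default_factory=list)

    def true_origin(self, chromosome, position_sexavg) -> np.ndarray:
        """(maternal, paternal) origin codes for all F2 at one position;
        shape (n_f2, 2), 0 = E, 1 = W."""
        fpos = self.lmap.sex_positions(chromosome, [position_sexavg], "female")[0]
        mpos = self.lmap.sex_positions(chromosome, [position_sexavg], "male")[0]
        out = np.empty((len(self.f2_ids), 2), dtype=int)
        for i, ind in enumerate(self.f2_ids):
            out[i, 0] = self.maternal_gametes[ind][chromosome].origin_at(fpos)[0]
            out[i, 1] = self.paternal_gametes[ind][chromosome].origin_at(mpos)[0]
        return out

    def true_ad(self, chromosome, position_sexavg):
        """True F-inf scores at a position: A = W-allele count - 1, D =
        heterozygosity indicator."""
        org = self.true_origin(chromosome, position_sexavg)
        w = org.sum(axis=1)
        return (w - 1).astype(float), (w == 1).astype(float)


def _default_map(cfg: SimulationConfig) -> LinkageMap:
    rows = []
    for c in range(1, cfg.n_chromosomes + 1):
        pos = np.linspace(0, cfg.chrom_length_cM, cfg.markers_per_chromosome)
        for k, p in enumerate(pos):
            rows.append({
                "chromosome": str(c),
                "marker": f"M{c}_{k + 1}",
                "female_cM": p * cfg.female_expansion,
                "male_cM": p * cfg.male_expansion,
                "sexavg_cM": p,
            })
    return LinkageMap(pd.DataFrame(rows), map_function="haldane")


def _line_pools(cfg: SimulationConfig, markers, rng) -> dict:
    """Per-marker allele pools for the two lines; a fraction of W alleles is
    shared with E so markers are only partially informative."""
    pools = {}
    for mk in markers:
        e_pool = [100 + i for i in range(cfg.alleles_per_line)]
        w_pool = []
        for i in range(cfg.alleles_per_line):
            if rng.random() < cfg.shared_allele_prob:
                w_pool.append(int(rng.choice(e_pool)))
            else:
                w_pool.append(200 + i)
        pools[mk] = {"E": e_pool, "W": w_pool}
    return pools


def _meiosis(chrom_lengths_sex: dict, rng) -> dict:
    """One gamete per chromosome: Poisson crossovers on the sex map."""
    gametes = {}
    for chrom, length in chrom_lengths_sex.items():
        n_x = rng.poisson(length / 100.0)
        breaks = np.sort(rng.uniform(0.0, length, size=n_x))
        gametes[chrom] = _Gamete(start=int(rng.integers(2)), breaks=breaks)
    return gametes


def simulate_cross(config: SimulationConfig, lmap: LinkageMap | None = None) -> SyntheticCross:
    """Generate pedigree, marker genotypes and fully-known line origins."""
    rng = np.random.default_rng(config.seed)
    if lmap is None:
        lmap = _default_map(config)
    markers = list(lmap.markers["marker"])
    marker_chrom = dict(zip(lmap.markers["marker"], lmap.markers["chromosome"]))
    pools = _line_pools(config, markers, rng)

    ped_rows = []
    founder_alleles = {}
    genotypes = {}

    def _add_founder(ind, line):
        ped_rows.append({"individual": ind, "sire": "NA", "dam": "NA",
                         "generation": "F0", "line": line})
        alleles = {mk: int(rng.choice(pools[mk][line])) for mk in markers}
        founder_alleles[ind] = alleles
        genotypes[ind] = {mk: (alleles[mk], alleles[mk]) for mk in markers}

    e_dams = [f"E{i + 1}" for i in range(config.n_f0_dams)]
    w_sires = [f"W{i + 1}" for i in range(config.n_f0_sires)]
    for ind in e_dams:
        _add_founder(ind, "E")
    for ind in w_sires:
        _add_founder(ind, "W")

    # F1: each from one E dam x one W sire; homologues are pure-line
    f1_parents = {}
    f1_ids = [f"F1_{i + 1}" for i in range(config.n_f1_dams + config.n_f1_sires)]
    f1_dams = f1_ids[: config.n_f1_dams]
    f1_sires = f1_ids[config.n_f1_dams:]
    for ind in f1_ids:
        dam = e_dams[rng.integers(len(e_dams))]
        sire = w_sires[rng.integers(len(w_sires))]
        f1_parents[ind] = (dam, sire)
        ped_rows.append({"individual": ind, "sire": sire, "dam": dam,
                         "generation": "F1", "line": "NA"})
        genotypes[ind] = {
            mk: (founder_alleles[dam][mk], founder_alleles[sire][mk])
            for mk in markers
        }

    chrom_len_f = {}
    chrom_len_m = {}
    for chrom in lmap.chromosomes:
        sub = lmap.chromosome(chrom)
        chrom_len_f[chrom] = float(sub["female_cM"].iloc[-1])
        chrom_len_m[chrom] = float(sub["male_cM"].iloc[-1])

    marker_fpos = {}
    marker_mpos = {}
    for chrom in lmap.chromosomes:
        sub = lmap.chromosome(chrom)
        for mk, fp, mp in zip(sub["marker"], sub["female_cM"], sub["male_cM"]):
            marker_fpos[mk] = fp
            marker_mpos[mk] = mp

    f2_ids = [f"F2_{i + 1}" for i in range(config.n_f2)]
    maternal_gametes = {}
    paternal_gametes = {}
    for ind in f2_ids:
        dam = f1_dams[rng.integers(len(f1_dams))]
        sire = f1_sires[rng.integers(len(f1_sires))]
        ped_rows.append({"individual": ind, "sire": sire, "dam": dam,
                         "generation": "F2", "line": "NA"})
        mg = _meiosis(chrom_len_f, rng)
        pg = _meiosis(chrom_len_m, rng)
        maternal_gametes[ind] = mg
        paternal_gametes[ind] = pg
        geno = {}
        for mk in markers:
            chrom = marker_chrom[mk]
            m_org = mg[chrom].origin_at(marker_fpos[mk])[0]
            p_org = pg[chrom].origin_at(marker_mpos[mk])[0]
            dam_e, dam_w = f1_parents[dam]
            sire_e, sire_w = f1_parents[sire]
            # F1 homologue of the given origin carries that F0 parent's allele
            a1 = founder_alleles[dam_e][mk] if m_org == 0 else founder_alleles[dam_w][mk]
            a2 = founder_alleles[sire_e][mk] if p_org == 0 else founder_alleles[sire_w][mk]
            if rng.random() < config.missing_rate:
                geno[mk] = None
            else:
                geno[mk] = (a1, a2)
        genotypes[ind] = geno

    return SyntheticCross(
        config=config, lmap=lmap, pedigree=pd.DataFrame(ped_rows),
        genotypes=genotypes, founder_alleles=founder_alleles,
        maternal_gametes=maternal_gametes, paternal_gametes=paternal_gametes,
        f2_ids=f2_ids,
    )


def true_ad_grid(cross: SyntheticCross, step: float = 1.0) -> ADGrid:
    """A/D variables from the true line origins at a regular grid (A in
    {-1,0,1}, D in {0,1}: the zero-uncertainty limit of HMM posteriors)."""
    from .hmm import grid_positions

    chroms, positions, A_cols, D_cols = [], [], [], []
    for chrom in cross.lmap.chromosomes:
        sub = cross.lmap.chromosome(chrom)
        pos = grid_positions(float(sub["sexavg_cM"].iloc[-1]), step)
        fpos = cross.lmap.sex_positions(chrom, pos, "female")
        mpos = cross.lmap.sex_positions(chrom, pos, "male")
        n = len(cross.f2_ids)
        org = np.empty((n, len(pos), 2), dtype=int)
        for i, ind in enumerate(cross.f2_ids):
            org[i, :, 0] = cross.maternal_gametes[ind][chrom].origin_at(fpos)
            org[i, :, 1] = cross.paternal_gametes[ind][chrom].origin_at(mpos)
        w = org.sum(axis=2)
        A_cols.append((w - 1).astype(float))
        D_cols.append((w == 1).astype(float))
        chroms.extend([chrom] * len(pos))
        positions.extend(pos)
    return ADGrid(cross.f2_ids, chroms, positions,
                  np.hstack(A_cols), np.hstack(D_cols))


def simulate_phenotypes(cross: SyntheticCross, config: SimulationConfig | None = None,
                        ) -> tuple[pd.DataFrame, dict]:
    """Phenotypes for every trait in the config plus a truth ledger.

    Returns (table, truth). The table has one row per F2 with columns
    individual, sex, batch, mother and one column per trait. ``truth`` maps
    trait name -> dict with the genetic values and variance bookkeeping.
    """
    if config is None:
        config = cross.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7081]))
    n = len(cross.f2_ids)
    ped = cross.pedigree.set_index("individual")
    mothers = [ped.loc[i, "dam"] for i in cross.f2_ids]
    sex = rng.integers(2, size=n)                       # 0 female, 1 male
    n_batches = len(config.traits[0].batch_effects)
    batch = rng.integers(n_batches, size=n)

    table = pd.DataFrame({
        "individual": cross.f2_ids,
        "sex": np.where(sex == 1, "M", "F"),
        "batch": batch + 1,
        "mother": mothers,
    })
    truth = {}
    dams = sorted(set(mothers))
    for spec in config.traits:
        scores = {}
        for k, locus in enumerate(spec.loci):
            scores[k] = cross.true_ad(locus.chromosome, locus.position)
        g = np.zeros(n)
        for k, locus in enumerate(spec.loci):
            A, D = scores[k]
            g += locus.a * A + locus.d * D
        for pair in spec.pairs:
            A1, D1 = scores[pair.locus1]
            A2, D2 = scores[pair.locus2]
            g += (pair.i_aa * A1 * A2 + pair.i_ad * A1 * D2
                  + pair.i_da * D1 * A2 + pair.i_dd * D1 * D2)
        mat_fx = dict(zip(dams, rng.normal(0.0, np.sqrt(spec.maternal_var), len(dams))))
        maternal = np.array([mat_fx[m] for m in mothers])
        resid = rng.normal(0.0, np.sqrt(spec.residual_var), n)
        fixed = (spec.mean + spec.sex_effect * sex
                 + np.asarray(spec.batch_effects)[batch])
        y = fixed + g + maternal + resid
        table[spec.name] = y
        truth[spec.name] = {
            "genetic_value": g, "maternal": maternal, "residual": resid,
            "fixed": fixed, "maternal_effects": mat_fx, "spec": spec,
        }
    return table, truth


def make_fixtures(config: SimulationConfig, outdir) -> dict:
    """Write a complete study bundle (map, pedigree, genotypes, phenotypes,
    true-origin A/D grid, truth sidecar) as tab-delimited text; deterministic
    given the config seed. Returns the paths."""
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cross = simulate_cross(config)
    table, truth = simulate_phenotypes(cross)
    grid = true_ad_grid(cross)

    paths = {
        "map": outdir / "map.tsv",
        "pedigree": outdir / "pedigree.tsv",
        "genotypes": outdir / "genotypes.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
        "ad_grid": outdir / "ad_grid.tsv",
        "truth": outdir / "truth.json",
    }
    cross.lmap.markers.to_csv(paths["map"], sep="\t", index=False)
    cross.pedigree.to_csv(paths["pedigree"], sep="\t", index=False)
    rows = []
    for ind, geno in cross.genotypes.items():
        for mk, g in geno.items():
            rows.append((ind, mk, "NA" if g is None else g[0],
                         "NA" if g is None else g[1]))
    pd.DataFrame(rows, columns=["individual", "marker", "allele1", "allele2"]) \
        .to_csv(paths["genotypes"], sep="\t", index=False)
    table.to_csv(paths["phenotypes"], sep="\t", index=False, na_rep="NA")
    grid.to_frame().to_csv(paths["ad_grid"], sep="\t", index=False)
    sidecar = {
        trait: {
            "loci": [vars(l) for l in t["spec"].loci],
            "pairs": [vars(p) for p in t["spec"].pairs],
            "maternal_var": t["spec"].maternal_var,
            "residual_var": t["spec"].residual_var,
        }
        for trait, t in truth.items()
    }
    with open(paths["truth"], "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return {k: str(v) for k, v in paths.items()}
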