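"""End-to-end orchestration: base models, scans, simplification, effects.

``run_pipeline`` chains the analysis stages for one or more traits on a
shared A/D grid: backward-selected base model with a maternal random effect,
single-locus scan with a permutation threshold and forward search, two-locus
scan with genomewide and locus-specific SSE thresholds, cluster-peak
selection and interaction tests, full-model assembly and simplification,
cross-age pointwise tests, independent-locus tests, cross-age unification,
and the background-conditional effect tables with variance explained.
All randomness flows from ``config.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .effects import (conditional_effects, genotypic_values,
                      independent_effects_model, pair_term_names,
                      variance_explained)
from .epistasis import (apply_thresholds, genomewide_sse_threshold,
                        interaction_test, locus_specific_sse_threshold,
                        pair_sse_scan, select_cluster_peaks, two_locus_fit,
                        _coarsen)
from .grids import ADGrid
from .modelbuild import (assemble_model, crossage_pointwise, fit_full_model,
                         simplify, test_independent_loci, unify_across_ages)
from .phenotypes import backward_select
from .scan import forward_search, permutation_threshold

__all__ = ["TraitResult", "PipelineResult", "run_pipeline"]


@dataclass
class TraitResult:
    trait: str
    base_fit: object
    qtls: list
    threshold: float
    candidate_pairs: list
    spec: object
    fit: object
    independent: list = field(default_factory=list)
    effects: pd.DataFrame | None = None
    variance: dict = field(default_factory=dict)


@dataclass
class PipelineResult:
    traits: dict
    crossage: pd.DataFrame | None = None


def run_pipeline(data: pd.DataFrame, grid: ADGrid, traits: dict,
                 config: RunConfig | None = None,
                 outdir=None) -> PipelineResult:
    """Run the full analysis.

    ``data`` holds one row per individual with an ``individual`` column, a
    ``mother`` column, covariates and one column per trait; ``traits`` maps
    trait name -> candidate covariate terms (patsy syntax). With ``outdir``
    the per-trait scan tables, detected-locus reports, effect tables and the
    cross-age QTL matrix are also written as TSV.
    """
    config = config or RunConfig()
    rng = np.random.default_rng(config.seed)
    results = {}
    for trait, candidates in traits.items():
        results[trait] = _analyse_trait(data, grid, trait, list(candidates),
                                        config, rng)

    # cross-age pointwise tests need every trait's final model
    ca_input = {
        t: {
            "y": r._y_raw, "data": r._data, "covariate_terms": r._terms,
            "grid": r._grid, "spec": r.spec, "qtls": r.qtls,
        }
        for t, r in results.items()
    }
    updated = crossage_pointwise(ca_input,
                                 alpha_joint=config.alpha_interaction_joint,
                                 alpha_coef=config.alpha_interaction_coef,
                                 match_dist=config.locus_match_cM)
    for trait, (spec, fit) in updated.items():
        r = results[trait]
        r.spec, r.fit = spec, fit
        r.independent = test_independent_loci(
            fit, alpha_joint=config.alpha_interaction_joint,
            alpha_t=config.alpha_marginal_t)
        r.spec.independent = [rec["locus"] for rec in r.independent]
        r.fit = fit_full_model(r._y_raw, r._data, r._terms, r._grid, r.spec)
        _report_effects(r, config)

    locus_records = []
    for trait, r in results.items():
        pair_loci = {k for p in r.spec.pairs for k in p.loci}
        pointwise_loci = {k for p in r.spec.pairs if p.pointwise for k in p.loci}
        for key in pair_loci:
            locus_records.append({
                "trait": trait, "chromosome": key[0], "position": key[1],
                "epistatic": True, "pointwise": key in pointwise_loci,
            })
        for key in r.spec.independent:
            locus_records.append({
                "trait": trait, "chromosome": key[0], "position": key[1],
                "epistatic": False, "pointwise": False,
            })
    crossage = unify_across_ages(locus_records,
                                 max_dist=config.crossage_match_cM)
    result = PipelineResult(traits=results, crossage=crossage)
    if outdir is not None:
        _write_reports(result, outdir)
    return result


def _write_reports(result: PipelineResult, outdir) -> None:
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.crossage.to_csv(outdir / "crossage_qtl.tsv", sep="\t", index=False)
    for trait, r in result.traits.items():
        rows = []
        for q in r.qtls:
            rows.append({"trait": trait, "chromosome": q.chromosome,
                         "position": q.position, "span_lo": q.span[0],
                         "span_hi": q.span[1], "peak_F": q.peak_F,
                         "threshold": r.threshold})
        pd.DataFrame(rows).to_csv(outdir / f"{trait}_putative_qtl.tsv",
                                  sep="\t", index=False)
        pairs = pd.DataFrame([
            {"trait": trait, "chrom1": p.locus1[0], "pos1": p.locus1[1],
             "chrom2": p.locus2[0], "pos2": p.locus2[1],
             "pointwise": p.pointwise}
            for p in r.spec.pairs])
        pairs.to_csv(outdir / f"{trait}_epistatic_pairs.tsv", sep="\t",
                     index=False)
        if r.effects is not None:
            r.effects.to_csv(outdir / f"{trait}_effects.tsv", sep="\t",
                             index=False)
        pd.DataFrame([{"term": str(k), "pct_variance": v}
                      for k, v in r.variance.items()]) \
            .to_csv(outdir / f"{trait}_variance.tsv", sep="\t", index=False)


def _analyse_trait(data, grid, trait, candidates, config, rng) -> TraitResult:
    sub = data.dropna(subset=[trait]).reset_index(drop=True)
    tgrid = grid.subset_individuals(list(sub["individual"]))
    base = backward_select(sub, trait, candidates, trait=trait)
    terms = base.selected_terms
    y_adj = base.adjusted

    thr = permutation_threshold(y_adj, tgrid, n_perm=config.n_perm,
                                alpha=config.alpha_genomewide, rng=rng)
    qtls, profile = forward_search(y_adj, tgrid, trait=trait,
                                   threshold=thr, gap_max=config.gap_max_cM)

    cgrid = _coarsen(tgrid, config.pair_scan_step_cM)
    scan = pair_sse_scan(y_adj, cgrid, trait=trait,
                         min_same_chrom_sep=config.pair_min_separation_cM)
    sse_g = genomewide_sse_threshold(
        y_adj, tgrid, n_perm=config.n_perm, alpha=config.alpha_genomewide,
        rng=rng, coarse_step=config.pair_scan_step_cM,
        min_same_chrom_sep=config.pair_min_separation_cM)
    sse_s = {
        k: locus_specific_sse_threshold(
            y_adj, q, tgrid, n_perm=config.n_perm,
            alpha=config.alpha_genomewide, rng=rng,
            coarse_step=config.pair_scan_step_cM,
            min_same_chrom_sep=config.pair_min_separation_cM)
        for k, q in enumerate(qtls)
    }
    scan = apply_thresholds(scan, qtls, sse_g, sse_s)
    peaks = select_cluster_peaks(scan)
    candidate_pairs = []
    for p in peaks:
        i1 = cgrid.index_of(p["chrom1"], p["pos1"])
        i2 = cgrid.index_of(p["chrom2"], p["pos2"])
        fit2 = two_locus_fit(y_adj, cgrid.A[:, i1], cgrid.D[:, i1],
                             cgrid.A[:, i2], cgrid.D[:, i2],
                             meta=(p["chrom1"], p["pos1"], p["chrom2"], p["pos2"]))
        t = interaction_test(fit2, alpha_joint=config.alpha_interaction_joint,
                             alpha_coef=config.alpha_interaction_coef)
        if t["pass"]:
            candidate_pairs.append(p)

    spec = assemble_model(trait, qtls, candidate_pairs,
                          max_dist=config.locus_match_cM)
    spec, fit = simplify(sub[trait].to_numpy(float), sub, terms, tgrid, spec,
                         alpha_joint=config.alpha_interaction_joint,
                         alpha_coef=config.alpha_interaction_coef,
                         merge_dist=config.locus_match_cM)
    r = TraitResult(trait=trait, base_fit=base, qtls=qtls, threshold=thr,
                    candidate_pairs=candidate_pairs, spec=spec, fit=fit)
    r._data = sub
    r._grid = tgrid
    r._terms = terms
    r._y_raw = sub[trait].to_numpy(float)
    return r


def _report_effects(r: TraitResult, config: RunConfig) -> None:
    base_pss = _base_pss(r)
    sigma2 = r.base_fit.sigma2
    frames = []
    for pair in r.spec.pairs:
        df = conditional_effects(r.fit, pair, standardize_var=sigma2)
        df.insert(0, "pair", [f"{pair.locus1[0]}:{pair.locus1[1]}x"
                              f"{pair.locus2[0]}:{pair.locus2[1]}"] * len(df))
        df.insert(1, "pointwise", pair.pointwise)
        frames.append(df)
        names = pair_term_names(pair, include_loci=False)
        r.variance[f"pair_{df['pair'].iloc[0]}"] = variance_explained(
            r.fit, names, base_pss)
    r.effects = pd.concat(frames, ignore_index=True) if frames else None
    genetic_names = [nm for nm in r.fit.names if nm[0] != "cov"]
    if genetic_names:
        r.variance["all_qtl"] = variance_explained(r.fit, genetic_names, base_pss)


def _base_pss(r: TraitResult) -> float:
    from .modelbuild import fit_mixed_design

    base = r.base_fit
    fitted = fit_mixed_design(base.y, base.X, base.groups,
                              [("cov", i) for i in range(base.X.shape[1])])
    return fitted.pss
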