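# epiqtl

Epistatic QTL mapping for F2 line crosses: line-origin probabilities by
hidden Markov model, mixed-model phenotype adjustment, single-locus and
two-locus permutation-thresholded genome scans, full-model simplification,
and a background-conditional decomposition of epistatic effects — plus a
synthetic cross generator so every stage can be exercised and calibrated
without external data.

## The problem

In a cross between two divergent lines (here labelled E and W, after an
Erhualian × White Duroc pig intercross design), each F2 animal carries at
every genome position 0, 1 or 2 alleles descended from each founder line.
Growth traits are mapped by regressing the adjusted phenotype ỹ on the
expected line-origin scores (Haley–Knott regression),

    ỹ = μ + a·A + d·D + ε,          A = p(WW) − p(EE),  D = p(EW),

in the F∞ parameterization: *a* is half the difference between homozygote
genotypic values, *d* the heterozygote's deviation from their mean. The
posteriors p(·) come from a forward–backward HMM over the ordered pair of
haplotype origins, using sex-specific Haldane maps and partially
informative multi-allelic markers. Pairwise epistasis is scanned with the
nine-parameter two-locus model

    ỹ = μ + a₁′A₁ + d₁′D₁ + a₂′A₂ + d₂′D₂
        + i_aa·A₁A₂ + i_ad·A₁D₂ + i_da·D₁A₂ + i_dd·D₁D₂ + ε,

judged on its residual sum of squares against permutation thresholds: a
genomewide SSE_genome, and per detected QTL a locus-specific SSE_specific
that keeps the known locus tied to the phenotype while the partner's
scores (and the rebuilt interaction columns) are permuted. Surviving pairs
enter a mixed model of the raw phenotype (covariates + random maternal
effect + all loci), which is simplified by sequentially removing
non-significant pairs.

The reporting layer is the package's centrepiece: interaction coefficients
are translated into *background-conditional* additive and dominance
effects — e.g. a₁(WW) = a₁′ + i_aa, the additive effect of locus 1 when
the partner is WW — with standard errors from the coefficient covariance
(SE = √(cᵀVc)), Holm correction within each pair's family of 12 effects,
and standardization by the base model's residual SD. Under linkage
equilibrium the (¼, ½, ¼)-weighted conditional effects average back to the
single-locus coefficients.

## Worked example

`examples/` holds one short script per capability. Running
`python examples/04_epistasis_scan.py` (a mini study: 2 chromosomes ×
100 cM, 400 F2, one additive QTL at 1:30 and an additive-by-additive
interaction 1:30 × 2:70 of 0.5 phenotypic SD) prints:

```
Putative QTL: [('1', 29.0, (22.0, 40.0))]
SSE_genome = 367.9; SSE_specific = {0: 355.7}
9 pairs retained below their thresholds
  1:30 x 2:70  SSE 350.5 (heat 5.3), joint interaction p = 9.9e-06 -> putative epistatic pair
  1:55 x 2:70  SSE 361.4 (heat 6.5), joint interaction p = 2.5e-05 -> putative epistatic pair
```

The single-locus scan finds the additive locus at 29 cM with its QTL span;
the two-locus scan retains pairs whose SSE falls below the governing
threshold ("heat" = threshold − SSE), and the true interaction is
recovered at exactly 1:30 × 2:70 with a joint 4-df interaction p ≈ 1e-5.
`examples/05_full_pipeline_effects.py` carries such a study through model
simplification, cross-age pointwise tests and the conditional-effect
tables with variance explained.

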