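# Methods

## Data model

`ctnet` analyses panel-based single-cell qPCR time courses. The observable
per cell and assay is a cycle threshold Ct ∈ (0, 40]; Ct values above 36
are treated as unreliable and censored to 40 ("undetected"). Analysis
happens on the normalized unit scale

    e = (40 − Ct′) / 8,      Ct′ = Ct − (Ct_ref,cell − median_cells Ct_ref)

which is the unique affine map sending the censored value (40) to 0 and
the reliability cutoff (36) to the detection threshold 0.5. A ×10 display
scale (cutoff at 5) is available as `scale_factor=10`; all internal
statistics use the unit scale. The reference correction subtracts each
cell's *deviation* of the reference gene from the cohort median rather
than the raw reference T: raw subtraction would shift the scale by the
reference gene's own magnitude (~15 cycles) and break the 36 ↦ 0.5
anchor. Detection is boundary-inclusive (e ≥ 0.5), consistent with Ct = 36
not being censored; the boundary has measure zero on continuous data.

Cells whose reference-gene or anchor-gene Ct deviates by more than
`k_sd = 2` sample standard deviations (n − 1 denominator) from the cohort
mean are dropped as unviable; with a Normal reference this removes ≈ 4.6%
of healthy cells by construction, which is the intended strictness of the
viability screen, not an error. After QC, a fixed number of cells per time
point (default 120) is drawn without replacement so all time points are
balanced.

## Synthetic study generator

The generator is a first-class module: it emulates the structure the
analysis stages assume and carries the ground truth that the tests check
against.

Per gene g and time t, a cell detects the transcript with probability
`detect_prob[t]` (Bernoulli, independent of expression level — the
simplest testable null; an expression-dependent dropout is deliberately
not the default because the analysis makes no such assumption). Detected
expression is

    e = mean_expr[t] + Σ_f w_{g,f} · z_{c,f} + ε,   ε ~ N(0, expr_sd)

where z_{c,f} ~ N(0, latent_factor_sd) are per-cell latent factors shared
by module members; equal-sign loadings induce the positive within-module
Spearman correlations that module detection must recover, and a hinge gene
carries opposite-sign loadings on the two module factors. e is clipped to
[0.5625, 5.0]: the lower clip sits half a PCR cycle *inside* the detection
boundary (corrected Ct 35.5) so that the clip atom never lands exactly on
the censoring cutoff, where reference-correction jitter would otherwise
censor it unpredictably and detection would no longer round-trip. Detected
e is mapped back to Ct through the exact inverse of the normalization map
plus the cell's reference offset, so `normalize` recovers the simulated
truth to float precision; undetected reactions read Ct = 40. A floor of
Ct ≥ 0.001 guards the (practically unreachable) negative-Ct corner.

Defaults mirror the published THP-1 differentiation study design: 45
transcription factors, 8 time points at
0/1/6/12/24/48/72/96 h, 120 cells per time point in 3 replicates, a
low-noise reference gene (Ct ~ N(15, 0.25)), and trajectory classes
16 ubiquitous / 11 activated / 7 deactivated / 5 transient / 6 variable.
Module 1 holds 10 fast-activating genes, module 2 holds 8 steadily
low-expressed ubiquitous genes plus the hinge; module loadings default to
0.5 (1.25 × expr_sd), strong enough that within-module correlations are
significant at n = 120 but far from degenerate. SPI1 is included as the
ubiquitous QC anchor gene; the reference gene is named GAPDH.

The layered network generator places nodes so the activating edge-ratio
rule classifies them exactly as requested: upstream nodes receive no
activating edges, each midstream node gets one regulator and one target
(ratio 1; ratio 0.5 in the no-downstream ring fallback), downstream nodes
only receive. Inhibitory edges are sprinkled on top (they do not enter the
rule). The knockdown matrix scores true edges above the threshold τ with
the edge's sign and non-edges below it; the motif table draws posterior
sums from a Gamma with variance = 0.7 × mean — under-dispersed relative to
Poisson, as empirical binding-site posterior sums are — with one motif's
mean multiplied by the enrichment factor in module-1 promoters.

What the generator does **not** emulate: amplification-curve artefacts,
pre-amplification bias, chip failure modes, expression-dependent dropout,
cell-cycle or cell-size covariates, and count-like (non-Gaussian)
expression distributions. Passing recovery tests therefore demonstrates
correctness of the statistical machinery, not robustness to those
real-data pathologies.

## Statistical choices

- **Noise strength** is variance/mean (Fano-type), computed over *all*
  cells including undetected zeros, since on/off heterogeneity is part of
  cell-to-cell variability; a CV alternative would de-emphasise exactly
  the bimodal genes of interest. Zero mean flags the entry as undefined
  (NaN), never silently replaced.
- **COD** = unscaled MAD/|median|. Centered PC scores can have medians
  near zero, where the ratio explodes; |median| < 1e−12 returns NaN as an
  explicit sentinel.
- **MDS** is classical/Torgerson (double-centered Gram matrix,
  eigendecomposition), not SMACOF; eigen-sign is fixed by making the
  largest-magnitude coordinate of each axis positive, so outputs are
  platform-stable. PCA is centered but not variance-scaled because all
  genes share the unit scale; scaling would inflate noisy low expressors.
- **Spearman networks** use average ranks for ties and the t
  approximation for p-values; below n = 9 tie-free samples get the exact
  permutation tail. BH runs within each time point over all tested pairs
  (the networks are presented per time point, so that is the family).
  Genes with zero variance at a time point are excluded there and
  reported.
- **Modules**: adjacency is |ρ| (soft power 1) on FDR-significant edges
  (a signed (1+ρ)/2 variant is available), dissimilarity 1 − TOM,
  average linkage. The tree is cut at the shallowest depth that yields
  the requested number of branches with ≥ 3 genes; smaller branches —
  isolated borderline-edge pairs — stay unassigned, mirroring the grey
  module of weighted-network practice. A fixed 2-way cut proved fragile:
  single spurious edges among background genes otherwise dominate the
  top split.
- **Layer comparison** is a one-sided Mann–Whitney U on per-gene mean η
  (the exact null distribution is used for tie-free groups up to n = 25).
  The test is the package's choice; the statistic being nonparametric
  matches the heavy-tailed per-gene noise summaries.
- **k-means trajectory classes** run on detection-fraction vectors (what
  the class names describe), 50 restarts at a fixed seed. The
  centroid-naming thresholds (min ≥ 0.9 ubiquitous; |Δ| ≥ 0.25 with
  near-monotone trend activated/deactivated; interior peak ≥ 0.15 above
  both endpoints transient) are package defaults, configurable.
- **Rates**: activation is arithmetic (percentage points · h⁻¹),
  enhancement geometric (fold · h⁻¹), matching their respective units;
  interval lengths are the true spacings (1, 5, 6, 12, 24, 24, 24 h).
  Enhancement is undefined when either endpoint has no detected cells.
- **Motif test**: observed = summed module posteriors; rate
  λ = module size × background mean per promoter; p = Poisson upper tail
  with non-integer observations rounded up (the stricter convention; a
  regularized-gamma interpolation is provided). Because posterior sums
  are under-dispersed, the tail is conservative *given* λ; with very
  small background panels the plug-in estimation of λ adds variability
  that can push the empirical level slightly above nominal (~0.07 with a
  28-promoter background in simulation), so backgrounds should be as
  large as the data allows. The default background is all profiled
  non-module promoters.
- **Edge balance**: per module, summed out-degree (targets) vs in-degree
  (targeting) over the knockdown network, with an optional two-sided sign
  test on per-gene out − in differences.

## Determinism

All randomness flows from one integer seed through
`numpy.random.default_rng`; regeneration is bit-identical, k-means uses a
fixed `random_state`, hierarchical clustering input rows are pre-sorted by
gene name so distance ties break alphabetically, and the pipeline manifest
contains no timestamps — two runs with the same seed produce byte-identical
numeric artifacts.

## Problem sizes in the test suite

Recovery tests use 2000 cells per time point on a 5-gene panel (one gene
per trajectory class) with closed-form clipped-normal oracles and
simulation-based standard errors; calibration uses 500 null co-expression
panels (45 genes × 120 cells), 2000 null and 500 powered draws of the
layer comparison, and 500–1000 motif tables. Multi-estimate 3-standard-
error recovery claims are asserted in calibrated form (≥ 98% of z-scores
below 3, none above 5): across hundreds of simultaneous estimates, an
occasional boundary exceedance is the expected behaviour of a correct
sampler, not a failure.

## Known limitations

- The Gaussian expression model on the normalized scale is a modelling
  choice; real single-cell qPCR distributions are often skewed or
  bimodal within the detected fraction.
- The exact-permutation Spearman path handles only tie-free samples;
  tied small samples fall back to the t approximation.
- The hinge-gene ranking requires the cross-module negative edges to
  survive multiple-testing control; in weakly-powered data the ranking
  can be empty even when antagonism exists.
- Layer classification consumes a given network; no network inference
  from the knockdown matrix is attempted beyond thresholding.
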