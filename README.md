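# ctnet

Temporal single-cell qPCR analysis: normalization of censored Ct data,
expression-noise statistics over a regulatory network, and time-resolved
co-expression modules.

## The problem

Multiplexed single-cell qPCR (e.g. microfluidic BioMark panels) profiles a
few dozen transcription factors in hundreds of single cells sampled along a
differentiation time course. The raw readout per cell and assay is a cycle
threshold Ct — low Ct means abundant transcript, and failed reactions are
censored. From such data one wants to know not just *how much* each gene is
expressed, but how expression **heterogeneity** across cells is created,
propagated through the regulatory network, and used during differentiation:

- which genes switch on cell-by-cell (*promoter activation*) versus ramping
  up output in already-active cells (*promoter enhancement*);
- whether cell-to-cell noise concentrates in particular layers of the
  regulatory hierarchy;
- how the co-expression network rewires over time, which gene modules it
  forms, and which "hinge" gene carries the negative edges between
  antagonistic modules.

`ctnet` implements that full analysis as a reusable, tested pipeline, plus a
synthetic-data generator with known ground truth so every stage can be
validated without any external dataset. It is aimed at computational
biologists analysing panel-based single-cell qPCR time courses.

## The statistics

- **Normalization.** Ct values above 36 are censored to 40. Per cell c,
  the reference-gene deviation Δc = Ct_ref,c − median_c(Ct_ref) is
  subtracted from every assay, re-censoring applied, and expression is the
  affine inverse map e = (40 − Ct′)/8, so Ct′ = 36 ↦ e = 0.5 (the detection
  cutoff; ×10 display scale gives 5) and censored values map to 0.
- **Population structure.** Classical (Torgerson) MDS on the cell–cell
  distance 1 − r (Pearson correlation of gene profiles); column-centered
  PCA; per-component, per-time-point coefficient of dispersion
  COD = MAD/|median| of the score distribution.
- **Detection dynamics.** Per gene and time point, the detected fraction
  f = #{e ≥ 0.5}/n and the mean expression of detected cells; k-means
  (k = 5) classes of f-trajectories (ubiquitous / activated / deactivated /
  transient / variable); per-interval rates
  a = 100·Δf/Δt (percentage points · h⁻¹) and
  h = (m_{t+1}/m_t)^{1/Δt} (fold · h⁻¹).
- **Noise topology.** Noise strength η = Var(e)/E(e) per gene per time
  (all cells, zeros included); network layers from the activating edge
  ratio r = out/in (r > 4 or no regulators ⇒ upstream, r < 0.5 ⇒
  downstream); one-sided Mann–Whitney comparison of per-gene mean η across
  layers.
- **Co-expression.** Per time point, Spearman ρ for all gene pairs with
  Benjamini–Hochberg control (FDR < 0.05; raw p < 0.01 as a second
  threshold); topological overlap
  ω_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij); average-linkage
  clustering of 1 − ω cut into modules; hinge genes ranked by incident
  cross-module negative edges.
- **Regulatory integration.** Targets-vs-targeting edge balance of each
  module against a knockdown (RNAi) network; motif enrichment by the
  Poisson tail P(X ≥ obs) of summed binding-site posteriors against a
  background-calibrated rate.

## Worked example

```python
import ctnet

truth = ctnet.make_truth(seed=1)              # 45 TFs, 120 cells x 8 time points
ct = ctnet.generate_ct_table(truth)           # censored Ct table + GAPDH reference
expr = ctnet.normalize(ct, ref_gene="GAPDH")  # unit-scale expression, detection calls

res = ctnet.pca(expr, k=3)
print([round(100 * v, 1) for v in res.var_explained])

prof = ctnet.detection_profiles(expr)
print(ctnet.classify_trajectories(prof, k=5, seed=1).value_counts().to_dict())

nets = ctnet.spearman_networks(expr)
mods = ctnet.detect_modules(nets, 24.0, n_modules=2)
print(mods.modules.value_counts().to_dict())
print(ctnet.hinge_genes(nets, mods, 24.0).gene.iloc[0])

nt = ctnet.noise_strength(expr)
print(round(ctnet.layer_noise_test(nt, truth.network)["p"], 6))
```

prints

```
[37.2, 8.0, 4.7]
{'ubiquitous': 16, 'activated': 11, 'deactivated': 7, 'variable': 6, 'transient': 5}
{2: 10, 1: 10}
HINGE1
6e-06
```

Reading: the first principal component carries 37% of the expression
variance; the 45 genes fall into the five designed trajectory classes
(16 always-detected, 11 switching on, 7 switching off, ...); at 24 h the
co-expression network splits into two 10-gene modules; the planted hinge
gene — negatively correlated with module 1, positively with module 2 — is
ranked first; and downstream-layer genes are significantly noisier than
upstream ones (one-sided p = 6 × 10⁻⁶).

The same analysis runs from the shell:

```bash
ctnet run --seed 1 --out run1          # simulate + all stages, manifest.json
ctnet normalize ct_table.tsv --ref-gene GAPDH --anchor-gene SPI1
ctnet network expression.tsv --time 24 --modules 2
```

## Layout

- `src/ctnet/synthetic.py` — ground-truth study generator
- `src/ctnet/normalization.py` — censoring, inverse normalization, QC
- `src/ctnet/population.py` — MDS, PCA, COD
- `src/ctnet/dynamics.py` — detection profiles, trajectory classes, rates, KDE
- `src/ctnet/noise.py` — noise strength, network layers, cross-layer test
- `src/ctnet/coexpression.py` — Spearman networks, TOM, modules, hinge genes
- `src/ctnet/regulation.py` — knockdown edge balance, Poisson-tail motif test
- `src/ctnet/pipeline.py`, `cli.py`, `config.py`, `io.py` — orchestration
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
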