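# lipidyn

Time-course lipidome dynamics: from targeted-lipidomics peak tables to
developmentally dynamic lipids, trajectory clusters, and matched
lipid–gene trajectories.

## The problem

Developmental time courses of the (mouse heart) lipidome measure hundreds of
lipid species at a handful of stages with few replicates, alongside a denser
reference transcriptome. Turning those tables into biology requires a chain
of well-defined computations:

1. **Quantification** — internal-standard calibration of MRM peak areas
   (`amount = area / IS_area × IS_conc × volume`) and normalization to molar
   fractions of total polar lipids (MFP), the per-sample sum of the 14
   phospholipid + 9 sphingolipid classes;
2. **Dynamic-feature selection** — per feature, OLS on a cubic polynomial of
   the stage code with a global F-test, Benjamini–Hochberg adjustment across
   features (FDR < 0.05), backward stepwise elimination (α = 0.05), and an
   R² > 0.7 filter on the reduced model;
3. **Trajectory clustering** — a hierarchical Gaussian-process mixture:
   cluster means f_j ~ GP(0, K_f) with K_f a Matern-5/2 kernel
   (σ² = 1, ℓ = 2 in stage-code units) and member deviations under
   K_y = Matern-5/2(σ² = 0.7, ℓ = 2) + white(σ² = 0.1), fit by variational
   EM with pruning and merging; membership at responsibility > 0.8;
4. **Inter-omics matching** — Spearman correlation of predicted lipid and
   gene cluster mean curves on the shared 15-stage-code grid, BH-adjusted
   over all pairs; a match requires positive ρ, q < 0.01, and the same
   trajectory label (early / late / peak-at-birth);
5. **Correlation analyses** — stage-wise Spearman edges among lipid classes
   (chord-diagram tables, raw p < 0.05) and cardiolipin-versus-mitochondrial-
   morphology correlations with a three-index sign-consistency rule.

`lipidyn` implements this pipeline with a shorthand-nomenclature parser
(`CL76:12(16:1)`, `SM d18:1/12:0`, `PE36:1p(18:0p/18:1)`, …), membrane
indices (Total PL/SPL, Cho/PL, DPH anisotropy γ = (I_vv − G·I_vh)/(I_vv +
2·G·I_vh)), auxiliary clustering (Ward hierarchical, fuzzy c-means), and a
fully ground-truthed synthetic-data generator so every stage is testable
without downloads. See `docs/methods.md` for the models and their
assumptions.

## Worked example

```python
import lipidyn as L
from lipidyn.simulate import SimulationConfig, simulate_lipidome

# a synthetic 7-stage study: 80 planted dynamic lipids + stable background
cfg = SimulationConfig(seed=1, features_per_archetype={
    "early": 30, "late": 30, "birth_peak": 20, "null": 110})
peaks, matrix, truth = simulate_lipidome(cfg)

mfp = L.normalize_mfp(L.quantify_peak_table(peaks))   # peak areas -> MFP
z = mfp.log_transform().zscore()

sel = L.DynamicFeatureModel(z).fit()                  # cubic + BH + stepwise
print(sel.summary())

res = L.fit_gp_mixture(z.stage_means().loc[sel.dynamic_features],
                       K_init=8, seed=1)              # GP trajectory mixture
print(res.summary())
```

Output:

```
Dynamic feature selection (cubic time-course regression)
==========================================================
features tested          190 of 190
FDR threshold (BH)       0.05
stepwise alpha           0.05
R^2 threshold            0.7
time encoding            stage_code
passing FDR              116
dynamic features         80

GP trajectory mixture
==========================================
clusters (after pruning)  3
features                  80
log-likelihood            -545.0354
EM iterations             18
converged                 True
cluster   weight   members(argmax)
  1       0.250    20
  2       0.375    30
  3       0.375    30
```

All 80 planted dynamic lipids are selected and none of the 110 stable ones
(36 stable features pass the FDR cut but fall below the R² > 0.7 filter —
the filter doing its job), and the mixture recovers the three planted
trajectory groups with
their sizes (30 early, 30 late, 20 birth-peak). `res.predict_cluster_curve(j)`
returns each cluster's mean curve with its 95% band on stage codes 1–15,
ready for `lipidyn.integrate.match_interomics_clusters` against a gene-side
fit.

A command-line interface mirrors the library
(`lipidyn simulate | quantify | select-ddl | cluster-hclust | cluster-fcm |
cluster-gp | integrate | correlate | anisotropy`); every subcommand writes
TSV outputs plus a JSON run manifest.

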