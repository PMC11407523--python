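# Methods

`lipidyn` turns time-course lipidome (and matched transcriptome) abundance
tables from the developing mouse heart design into developmentally dynamic
features, trajectory clusters, and matched inter-omics trajectories. This
note documents the models, their assumptions, the parameters that matter,
and the choices made where the design was genuinely open.

## Study design and time encoding

Samples come from fifteen developmental stages — embryonic days E10.5–E18.5,
then postnatal days P0, P1, P3, P7, P14, P21 — assigned integer *stage codes*
1–15. The lipidome time course samples seven of them (E10.5, E14.5, E17.5,
P0, P1, P7, P21) with replicate counts 5, 5, 5, 4, 4, 3, 3; the reference
transcriptome covers the full grid. Both the polynomial regression and the
GP clustering use the shared 1–15 codes as the time covariate, so curves from
the two omics layers align without resampling. The regression's time
encoding is switchable (`stage_code`, `ordinal`, or approximate chronological
`day`): the choice shifts the spacing of the seven observed points, and
selection counts on real data can be mildly sensitive to it. Stage codes are
the default because they are the encoding under which the two modules share
one axis.

## Quantification and MFP normalization

Single-point internal-standard calibration converts a peak area to an amount:
`amount = area / IS_area * IS_concentration * volume` (µmol, with IS
concentration in µmol/ml and resuspension volume in ml). Each analyte names
its internal standard explicitly; there is no automatic standard matching.
A missing (sample, analyte) record is a missing value, distinct from a
measured zero.

Amounts are normalized per sample to the sum over all *polar* lipids —
the 14 phospholipid classes (PC, PE, PI, PS, PA, PG, CL, LBPA, LPC, LPE,
LPG, LPS, LPI, LPA) plus the 9 sphingolipid classes (SM, Cer, GluCer, GM3,
Gb3, SL, S1P, LacCer, Sph) — giving molar fractions of total polar lipids
(MFP). Neutral lipids (TAG, DAG, Cho, CE, FFA, carnitines, CoAs) are divided
by the same polar denominator but do not enter it, which keeps the Cho/PL
ratio and per-class totals comparable across samples. The polar MFP of each
sample therefore sums to exactly 1.

Membrane indices: Total PL and Total SPL are the two class-list sums above;
Cho/PL is free cholesterol over Total PL (an inverse fluidity proxy); DPH
fluorescence anisotropy is γ = (I_vv − G·I_vh)/(I_vv + 2·G·I_vh) with grating
correction G = I_hv/I_hh, bounded in (−0.5, 1] for physical intensities.

Species present in only part of the samples are handled by an explicit
min-presence filter (default: keep features observed in ≥ 80% of samples).
The default is a documented package choice — the upstream acquisition does
not prescribe one — and no imputation is performed.

## Lipid nomenclature

Shorthand names (`PC32:0`, `CL76:12(16:1)`, `SM d18:1/12:0`,
`PE36:1p(18:0p/18:1)`) are parsed against a CSV class registry (class code,
polar category, expected chain count, aliases; LBPA and BMP are one class).
Annotation levels: class-only, sum composition, partial acyl
(annotated chains sum below the declared totals, as in cardiolipins
annotated by one diagnostic acyl), and full acyl (sums must match exactly —
a mismatch is a validation error, not a warning). Ether (`p`) linkages are
a single plasmanyl-or-plasmenyl flag; isotope-label prefixes on standards
(`d5-`, `d9-`, …) are stored as a tag, not composition. The canonical form
has no space between class code and composition, and chain-list-only inputs
are canonicalized with computed totals (`SM d18:1/12:0` →
`SM30:1(d18:1/12:0)`).

Acyl chains are classified as short (C < 16), long (C16–C21), or very long
(C ≥ 22) and as saturated (0 double bonds), mono/di-unsaturated (1–2), or
polyunsaturated (≥ 3). The two boundary cases (C = 22, n = 3) are assigned
to the upper category so each classification is a total partition; this also
matches the conventional treatment of C22:6 and C20:3 as very-long-chain and
polyunsaturated, respectively. Composition profiles are tallied either
per annotated acyl (species abundance split equally over its annotated
chains; unannotated species skipped) or by sum composition; both modes are
reported because partially annotated species admit no unique apportionment.

## Dynamic-feature selection

Per feature, values are centered and scaled, then regressed by OLS on
{1, t, t², t³} in centered powers of the time covariate (centering keeps the
cubic design well conditioned on codes 1–15; the model space is unchanged).
The global F-test p-value of the polynomial terms is Benjamini–Hochberg
adjusted across features. Survivors of the FDR cut (default 0.05) undergo
backward elimination: repeatedly drop the least significant polynomial term
with partial p > 0.05 and refit. A feature is *developmentally dynamic* when
it passes the FDR cut and the stepwise model's R² exceeds 0.7. Replicates
enter as independent observations at their stage code; zero-variance features
are flagged non-testable and excluded from the adjustment. Because stepwise
models are nested within the full cubic, the reported R² never exceeds the
full model's, and tightening either threshold can only shrink the selected
set.

On the 7-stage, 29-sample design the procedure is well calibrated (null
raw-p rate ≈ 5%, essentially zero null selections after FDR + R²) and has
full power against cubic signals at signal-to-noise 3, whose true R²
(≈ 0.9) clears the 0.7 filter comfortably.

Selected profiles are partitioned by Ward/Euclidean agglomerative clustering
of z-scored per-stage medians (k = 5 by default, mirroring the five
empirical lipid trajectory groups: early-declining ×2, late-rising,
pre-birth peak, birth peak) or by fuzzy c-means (fuzzifier m = 2, 5 seeded
restarts, best objective kept; the objective is monotone non-increasing
within a run). Linkage, metric, k/c and the fuzzifier are all recorded in
the clustering output.

## GP trajectory mixture

Trajectories (per-stage replicate means of z-scored features) are clustered
with a two-level Gaussian-process mixture. Cluster j has a latent mean
function f_j ~ GP(0, K_f) with K_f a Matern-5/2 kernel (variance 1,
lengthscale 2 in stage-code units); a member deviates from its cluster mean
by a second GP, K_y = Matern-5/2 (variance 0.7, lengthscale 2) plus white
noise (variance 0.1). All hyperparameters are fixed by default; optimization
is deliberately not on the default path.

Fitting is coordinate-ascent variational EM on a finite mixture with an
over-specified component count (K_init = 10) and k-means initialization
(seeded, 5 restarts, best final objective kept):

* q(f_j) update (M-step): the hierarchical-GP posterior given the
  responsibility-weighted curve stack — with mass R_j = Σ_n r_nj and
  weighted mean curve ȳ_j, A_j = K_f + K_y/R_j, μ_j = K_f A_j⁻¹ ȳ_j,
  Σ_j = K_f − K_f A_j⁻¹ K_f;
* responsibility update (E-step): r_nj ∝ π_j exp(E_q[log N(y_n; f_j, K_y)])
  = π_j N(y_n; μ_j, K_y) · exp(−½ tr(K_y⁻¹ Σ_j));
* mixing weights π_j = R_j/N.

The tracked objective is the variational free energy (a lower bound on the
log marginal likelihood), which is non-decreasing by construction — this is
why the variational E-step is used rather than the marginal-predictive
responsibility N(y; μ_j, K_y + Σ_j), whose tracked quantity oscillates.
Components whose weight falls below 1/(2N) are pruned (removing a positive
KL penalty, so pruning also raises the bound). Because the kernels are
fixed, EM alone can leave a true cluster split into near-duplicates (a
stable local optimum); a greedy merge phase therefore follows convergence:
every cluster pair is tentatively merged, refined for a few iterations, and
the merge kept only when the free energy improves. The KL(q(f)‖prior) term
makes duplicated clusters strictly worse than their merger, so duplicates
vanish while genuinely distinct clusters survive. On curves simulated from
the model's own kernels (3 archetypes × 30 features), the planted partition
is recovered with adjusted Rand index 1.0 across seeds.

Cluster mean curves are predicted at any query codes (default the full 1–15
grid) by the GP posterior predictive under K_f, with 95% bands at
mean ± 1.96 posterior SD of the latent mean. A feature is a *member* of its
cluster when its maximum responsibility exceeds 0.8; otherwise it is
reported unassigned.

Numerical policy: covariance Cholesky factorizations add escalating diagonal
jitter up to 1e-8 of the mean diagonal; posterior covariances are
symmetrized after each update.

## Inter-omics matching

Lipid and gene cluster mean curves, evaluated on the shared 15-code grid,
are compared pairwise by Spearman correlation with BH adjustment across all
pairs. A pair *passes* at ρ > 0 and q < 0.01 (positive-only by design: an
anti-correlated gene cluster is not a shadow of a lipid trajectory). A pair
is a *match* when it passes **and** both curves carry the same trajectory
label — early (peak in codes 1–3, negative rank trend), late (peak in codes
13–15, positive trend), or peak-at-birth (peak in codes 9–11, lower at both
ends). Identical labels are the operational surrogate for "highly similar
trajectory"; it is needed in practice because a monotone rise and a birth
bump are intrinsically rank-correlated (ρ ≈ 0.5–0.7 on this grid) and can
occasionally slip under the FDR cut alone. Label windows and the birth code
are configurable.

## Correlation analyses

Spearman's ρ is the Pearson correlation of midranks. The default p-value is
the t approximation t = ρ√((n−2)/(1−ρ²)) on n−2 degrees of freedom; an exact
rank-permutation mode is provided for n ≤ 9. With 3–4 replicates per stage
the exact two-sided p can never reach 0.05 (its minimum is 2/n!), so any
stage-wise significance at these depths necessarily rests on the asymptotic
test — which is anti-conservative at such n; this is documented rather than
hidden, and the calibration test shows the approximation is accurate by
n ≈ 10. Stage-wise edges among the CL/PC/PE classes use raw p < 0.05 with no
multiplicity correction (the chord-diagram convention), so absolute edge
counts are inflated; the per-stage *contrast* in counts is the meaningful
output. Cardiolipin-versus-morphology correlations use per-stage summary
abundances (mean by default, median switchable) against three maturation
indices across ≥ 4 aligned stages; a species is *consistent* when all three
correlations are retained with a single sign.

## Synthetic data

The generator emulates the study design end to end without calling any
analysis code. Trajectory archetypes (early, late, pre-birth peak, birth
peak, null) are smooth base shapes scaled to amplitude 2.5 (z-scale) plus a
damped (×0.3) draw from K_f — draws that would displace the archetype's peak
are rejected, so peak positions are guaranteed. Planted features add a
per-feature K_y deviation and i.i.d. replicate noise (SD 0.3, z scale).
Null background features receive replicate noise only: K_y is defined as
deviation from a *cluster mean*, and a flat-truth feature given a smooth
K_y draw would be weakly dynamic by construction, contradicting its role as
the null.

Abundances are built on the log scale (lipidomic abundances are positive and
right-skewed): log10 µmol = baseline + 0.25 × z-signal. Dynamic species sit
at baseline −2.0 ± 0.5 log10 µmol and swing ~4–10-fold across development;
null (stable) species sit near 1 µmol and dominate the polar pool, so the
total polar denominator stays nearly constant — as total phospholipid does
in real developing membranes. This matters: if planted species dominate the
denominator, MFP normalization imprints a shared spurious trajectory on
every feature. Peak tables use one internal standard per class with unit IS
areas (concentration 0.1 µmol/ml, volume 0.5 ml), making the calibration
arithmetic auditable and the quantify→MFP round trip exact to ~1e-15.

The transcriptome is generated on the dense 15-code grid (2 replicates per
stage, 50 genes per cluster). Paired gene clusters share a lipid archetype's
truth curve through the rank-preserving distortion y → y + 0.3y³ (Spearman
ρ = 1 by construction); decoy clusters use a mid-development trough and two
oscillation phases, shapes verified at design time to have no positive rank
correlation with any archetype. Fifty genes per cluster (the curated panel
in the motivating design has ~180 per trajectory) keeps distinct shapes
separable: with fewer members, the smooth component of K_y can absorb the
difference between two shapes more cheaply than a second cluster-mean
penalty.

Default problem sizes (≈200 lipids, ≈300 genes, the stated replicate
design) are chosen so the full simulate→quantify→select→cluster→match
pipeline runs in seconds while preserving the archetype variety of the
motivating study; they are package defaults, not estimates of the real
data's dimensions.

## What passing tests do and do not show

The synthetic data exercise the exact generative assumptions the models fit
(Gaussian deviations from smooth cluster means, fixed kernels, balanced
archetypes). Real lipidomes add features the generator deliberately omits:
batch effects and acquisition drift, detection-limit censoring, correlated
measurement error across co-eluting species, compositional coupling beyond
the shared denominator, and trajectory shapes outside the archetype library.
Passing tests therefore demonstrate correctness of the computations and
calibration/power *under the stated model*, not performance guarantees on
any particular real dataset. Reproducing a specific published selection
count would additionally require the original deposited data and the
original (unstated) stepwise and time-encoding settings.

## Known limitations

* The GP mixture assumes a shared noise model across features; per-feature
  noise variances are not estimated.
* The merge phase is greedy and evaluated at fixed kernels; with learned
  hyperparameters a different model-selection rule would be needed.
* Spearman p-values at n ≤ 4 are anti-conservative (documented above).
* The nomenclature module does not resolve sn-positions, double-bond
  positions, or compute masses/formulas — it covers the shorthand grammar
  actually used in quantitative class-targeted workflows.
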