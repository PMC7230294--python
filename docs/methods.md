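# Methods

This note documents the statistical model behind `pairedpls`, the choices
made where the procedure was genuinely open, and what the synthetic-data
tests do and do not establish.

## Study design and data model

The design is strictly paired: each patient contributes exactly one
in-crisis (IC) and one out-of-crisis (OC) sample from one matrix (plasma or
erythrocytes).  A dataset is a sample × metabolite grid of µM concentrations
with a parallel censoring grid (OK / BELOW_LLOQ / ABOVE_ULOQ) derived from
the panel's quantitation limits.  Invariants enforced at construction: no
missing cells, no duplicate sample keys, one matrix per dataset, and every
patient present with both states.  Metabolite order is canonical panel
order; wide CSV is the only accepted table dialect, written with 17
significant digits so a write→load cycle is bit-identical on float64.

The bundled default panel reproduces the p180 kit's class structure
(free carnitine, 39 acyl-carnitines, hexose sum, 21 amino acids, 21 biogenic
amines, 14 lysoPC, 38 PC aa, 38 PC ae, 15 SM = 188 analytes).  The kit's
per-analyte LLOQ/ULOQ values are proprietary, so the bundled bounds are
synthetic but class-realistic: a fixed-seed draw of each analyte's typical
median concentration from a class-specific log-uniform range, with
LLOQ = median/20 and ULOQ = median·20.

## Quantitation-range filter

A metabolite is excluded when strictly more than 20% of its values fall
outside [LLOQ, ULOQ] (exactly 20% is kept).  Before exclusion, a Pearson
chi-squared test (2×2, 1 df, no continuity correction; degenerate margins
return statistic 0, p 1; expected cells < 5 are logged) asks whether the
out-of-range pattern is associated with crisis status.  **Interpretation
choice:** a *significant* test (p < 0.05 by default) rescues the metabolite —
if censoring tracks the crisis, the censoring itself is discriminant
information and dropping the analyte would discard a feature.  The filter
depends only on flags and state labels, never on concentration magnitudes.

Out-of-range values in retained metabolites are imputed deterministically:
BELOW_LLOQ → LLOQ/2 (the usual left-censoring convention for targeted
assays), ABOVE_ULOQ → ULOQ.  No probabilistic imputation and no
multiple-testing correction across rescue tests are attempted.

## Paired PLS-DA

PLS1 regression of the centered class code (IC = 1, OC = 0) on
unit-variance-scaled data (sample sd, n−1 denominator; scaling parameters
always estimated on the training samples only).  NIPALS sequence per
component a: w_a ∝ X_a′y (unit norm), t_a = X_a w_a, p_a = X_a′t_a/t_a′t_a,
q_a = y′t_a/t_a′t_a, deflation X_{a+1} = X_a − t_a p_a′.  Two components by
default (the score plane is LV1/LV2).  Deflation stops early when
t_a′t_a < 1e-12; weight-vector signs are fixed by making the largest-|entry|
coordinate positive, and the reported oriented loading is the
first-component X-loading multiplied by sign(q_1), so positive always means
elevated in crisis.

"Paired" is honoured two ways, both available: (a) resampling never splits a
patient's two samples across train/validation/test (always on); (b) a
multilevel decomposition replaces each value by value − patient mean + grand
mean before scaling (default on, switchable).  For held-out pairs the
decomposition uses the pair's own mean with the *training* grand mean, so no
between-patient information leaks.  The literature contains both readings of
"paired PLS-DA"; the flag makes the choice explicit rather than silently
picking one.

Inside the resampling ensemble a column occasionally has zero variance
within one training subset (every pair censored and imputed to the same
value) even though the dataset-wide filter passed; such columns are scaled
to all-zeros for that model (they then contribute nothing: w ∝ X′y is zero
there).  Outside the ensemble a constant column is an error.

VIP_j = sqrt(p · Σ_a q_a²(t_a′t_a) w_ja² / Σ_a q_a²(t_a′t_a)), giving
Σ_j VIP_j² = p exactly; VIP ≥ 1 marks discriminant variables.

## AUROC and significance

AUROC is the Mann–Whitney statistic U/(n₊n₋) with ties counted ½.  The
p-value tests AUROC = 0.5, two-sided.  With both class counts ≤ 12 and
tie-free scores, the exact permutation distribution of U is computed by
dynamic programming over rank sums (validation sets here are 10 vs 10); with
ties, a seeded 10,000-draw label permutation is used; larger sets fall back
to the tie-corrected normal approximation with a ½ continuity correction
(agreement with the exact method at 10 vs 10: mean |Δp| < 0.01).  P-values
are clamped into (0, 1].

An unsupervised PCA of the centered, unit-variance-scaled table (SVD) is
run as a sanity check; samples beyond 3 sd on a component are *reported* as
potential outliers, never auto-removed (the one sample removed in the
motivating study was excluded on wet-lab grounds, which a statistical
pipeline cannot reproduce).

## Split ensemble and aggregation

Outer split: a seeded shuffle assigns min(30, ⌈3n/4⌉) pairs to
training-validation and the rest to test, reproducing the 30/10 (40 pairs)
and 30/9 (39 pairs) arms.  Inner splits: the C(30,20) = 30,045,015
combinations of 20 training pairs are conceptually a 20 × 30,045,015 matrix;
it is never materialized — the r-th lexicographic combination is produced by
unranking on demand.  Column sampling starts at offset 0 with stride 1287,
which divides the total exactly and yields 23,345 models (the source
procedure does not state the matrix order or starting column;
offset-0 lexicographic is this package's documented convention).  For
smaller problems the stride auto-scales as max(1, C(n,k)//target) so the
model count stays near the configured target.

Per model: fit on the 20 training pairs, score the 10 validation pairs,
record AUROC and p.  Best models (BMs) are those with validation AUROC ≥
0.95 — selection uses AUROC only, not the p-value.  AUROC is always computed
with IC as positive class; models worse than chance are not flipped.  Each
BM is re-scored on the outer test pairs; the global criterion is median test
AUROC ≥ 0.8 and median test p ≤ 0.05.  Zero BMs is a valid, explicitly
flagged outcome.

Aggregates over BMs are marginal medians: per-metabolite median VIP and
median oriented loading, and per-sample median (LV1, LV2) over the
training-validation samples.  Latent axes are sign-indeterminate across
fits, so before aggregating coordinates every BM's components are sign-
aligned to the lowest-rank BM by the sign of the loading-vector inner
product; VIP is sign-free and oriented loadings already carry the
positive-in-crisis convention.

## Synthetic-data generator

Per metabolite j, log-concentrations are bivariate normal over a patient's
two states: log x = µ_j + δ_j·1[IC] + b_ij + ε, with patient intercept
b_ij ~ N(0, ρσ_j²) and noise ε ~ N(0, (1−ρ)σ_j²), so the within-patient
correlation is exactly ρ (default 0.5, a moderate repeated-measures
correlation).  Concentrations are exponentials — positive and right-skewed,
as concentration data are.  Randomness is counter-split: each metabolite
draws from its own substream of the master seed, so growing the panel never
reshuffles existing columns.

Default baselines put µ_j log-uniformly in the central 40% of the analyte's
quantitation window with σ_j ~ U(0.2, 0.6) (biological CVs of roughly
20–65%).  The study-shaped scenarios plant 60 effects with random sign —
|δ| ∈ [0.5, 0.9] ("strong"), [0.2, 0.8] ("default"), or none ("null") —
mirroring the ~60-metabolite signatures the real analysis reported, and
place 35 metabolites *below* their LLOQ (µ_j = log LLOQ − zσ_j, z ∈
[0.4, 1.2]) to emulate poorly quantified analytes; with 40 pairs this
reproduces the 153-of-188 (81%) QC survival of the plasma arm.  None of
these values were tuned against test outcomes; they are the stated world.

The generator does **not** emulate acquisition noise, batch effects,
cross-metabolite correlation beyond the shared patient intercept, isotope
correction, or calibration-curve error.  A green recovery test therefore
establishes that the pipeline's machinery (filter, paired fitting,
systematic resampling, VIP selection) is correct and well-calibrated — not
that real crisis data would yield any particular AUROC.  In particular the
motivating study's headline numbers (4,277/7,955 best models, median test
AUROC 0.99, 63/61 discriminant metabolites) depend on raw data that are not
publicly accessible and are deliberately not asserted anywhere.

## Numerical choices and limitations

- Deflation tolerance 1e-12 on t′t; scaler requires sd > 0 (see above for
  the within-ensemble exception).
- Exact-p DP distributions are cached per (n₊, n₋); Monte-Carlo p-values use
  a seed derived from the ensemble seed and model rank (< 2³¹).
- Imputation constants (LLOQ/2, ULOQ) are fixed and logged, making the
  pipeline fully deterministic for a given dataset, config, and seed.
- Binary two-class discrimination only; no sparse/orthogonal/kernel PLS.
- The chi-squared rescue is per-metabolite with no multiplicity control, as
  in the source procedure.
- Figures are rendered deterministically (fixed size, no timestamp
  metadata) as SVG and PNG.
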