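# Methods

`netdc` implements a resting-state fMRI analysis chain built around
voxel-wise binarized degree centrality (DC): preprocessing, DC and
seed-based functional connectivity (FC) mapping, voxel-wise group
inference with cluster-level FDR, clinical correlation, and linear-SVM
multivariate pattern analysis (MVPA).  Because clinical imaging cohorts of
this kind are not publicly redistributable, the package ships a synthetic
BOLD cohort generator whose planted group differences provide a known
ground truth for every downstream stage; all statistical claims the test
suite makes are claims about recovery of that planted structure.

## The synthetic cohort generator

Each subject's 4D series lives on a small grid (default 16x16x16 voxels at
3 mm, an ellipsoidal "gray-matter" mask of ~1,300 voxels) with 240 volumes
at TR = 2 s, mirroring a typical 8-minute EPI acquisition.  The in-mask
voxels are partitioned into K = 5 contiguous slab regions, one latent
network each.  Latent signals are unit-variance Gaussian series band-pass
filtered (zero-phase Butterworth, order 5) to 0.01-0.08 Hz — the analysis
passband — so the band the pipeline analyzes carries all planted
structure.  A voxel's signal is

    x_v(t) = sum_k L[v,k] s_k(t) + drift_v * t + w_v' c(t) + noise_sd * eps_v(t)

with L[v,k] = 1 for the voxel's own region.  A contiguous spherical "hub"
region (~70 voxels) additionally loads on *every* network with coupling

    a_i = hub_coupling + group_effect_delta * [patient] + hub_gain_sd * u_i,

where u_i ~ N(0,1) is the subject's hub-gain deviation.  Nuisance series
c(t) are three slow AR(1) confounds with random per-voxel weights w_v;
they are returned alongside the images so the preprocessing stage can
regress them out, playing the role motion/CSF regressors play on real
data.  With `group_effect_delta = 0` the two groups are generated by an
identical process (exchangeable null).  One root `SeedSequence` is spawned
per subject by counter, so any subject's data depend only on the cohort
seed and the subject's index.

### Why the default couplings are what they are

A hub voxel's correlation with an arbitrary gray-matter voxel is
approximately

    rho(a) = a / sqrt(((1+a)^2 + (K-1) a^2 + s2) (1 + s2)),

where s2 is the post-filtering noise variance.  Binarized DC counts
connections with r > 0.25, so what matters is where rho sits relative to
that threshold, and the sampling noise of r (SD ~0.125 at 230 band-limited
frames) smears the count.  The shipped conditions place rho deliberately:

* **default** `hub_coupling = 0.15`: rho ~= 0.10 in both groups — hubs are
  latent, nothing crosses the threshold systematically;
* **strong effect** (`strong_effect_model()`): `delta = 1.6` lifts patient
  hub rho to ~0.35 while controls stay at ~0.10 — the two groups sit on
  opposite sides of the threshold and hub degree separates them with a
  standardized mean difference around 3.  This is the regime used for the
  recovery suites (cluster detection and classification);
* **clinical coupling** (`coupling_model()`): `hub_coupling = 0.5` with
  `noise_sd = 0.6` puts rho essentially *at* the threshold, where degree
  responds most steeply (and still monotonically) to the per-subject gain
  u_i; `hub_gain_sd = 0.25` then creates between-subject DC variation, and
  `CovariateModel.moca_coupling` adds `coupling * u_i` points to the MoCA
  score, making correlation recovery testable.  Note that at much higher
  couplings the *z-scored* hub degree saturates and then declines (global
  standardization compresses an increasingly extreme hub), so couplings
  should stay on the rising flank; the factory defaults do.

Clinical covariates are truncated normals with instrument-plausible ranges
and group means/SDs matching a published lupus cohort of 47+47 (age ~29 vs
27, education ~12 years, SLEDAI ~13 for patients, MoCA ~27 vs 28, BDI-II
~10 vs 6); sex is Bernoulli with a ~1:4 male:female ratio so the
chi-square path sees realistic imbalance.

### What the generator does not emulate

No head motion, slice-timing offsets, scanner drift nonlinearity,
physiological noise spectra, spatial autocorrelation of noise, or
anatomical geometry.  Passing recovery tests therefore demonstrate that
the *estimators* are correct and calibrated under the stated generative
model — not that the pipeline is robust to real-world artifacts, which the
out-of-scope realignment/normalization stages would address.

## Preprocessing

Order: drop initial volumes (default 10) -> per-voxel linear detrend ->
nuisance regression (intercept always included) -> temporal band-pass ->
(for FC inputs only) spatial smoothing.  The band-pass is a zero-phase
forward-backward Butterworth of order 5; zero-phase filtering was chosen
because it leaves inter-voxel correlation structure unchanged, and the
transfer behavior is pinned by single-tone tests (0.04 Hz preserved within
5%, 0.2 Hz attenuated below 5%).  Smoothing uses a Gaussian kernel
specified by FWHM in mm (sigma = FWHM / 2.355 per axis, divided by the
voxel size) with reflect boundaries so constant maps stay constant on
small grids.  Series feeding DC are *not* smoothed; the DC z-map is
smoothed afterwards (6 mm default).  Series feeding seed FC are smoothed
before correlation.  The head-motion exclusion rule (2.5 mm / 2.5 deg) is
carried as configuration metadata and acts only as a phenotype
include-flag, since realignment is upstream of this package.

## Degree centrality and seed FC

DC(i) counts in-mask voxels j != i with Pearson r(i,j) strictly greater
than the threshold (default 0.25), positive correlations only; `|r|` and
weighted variants exist as non-default switches.  Correlations are
computed blockwise on standardized series, which is algebraically the same
dot product the brute-force per-pair oracle computes — agreement is exact
and enforced by test.  A zero-variance in-mask voxel is a hard error that
names the offending indices.  The DC map is standardized against the
gray-matter distribution with the population-SD convention (divide by n):
the z-map is a normalization, not an inference, and the convention is
pinned by a closed-form three-voxel test.

Seed FC correlates the unweighted mean seed series with every gray-matter
voxel and applies Fisher's z = atanh(r); |r| = 1 is clipped to 1 - 1e-7 to
keep maps finite.  Seed voxels remain in the output.

## Group inference

Per voxel, an OLS GLM with intercept, patient indicator (+1/0) and
covariates (age, sex coded F=0/M=1, education); the group coefficient's t
with df = n - rank(X) is the test statistic.  Constant covariates (e.g. a
single-sex toy cohort) are dropped from the design with a warning rather
than allowed to make it singular.

Cluster-level FDR is realized as a permutation procedure: voxels with
two-sided p below the forming threshold (default 0.001) are split by the
sign of t and grouped into connected components (default 26-neighborhood;
6/18 available, behavior pinned by a diagonal-contact toy).  Each observed
cluster's uncorrected p is the add-one proportion of group-label
permutations whose maximum same-sign cluster extent reaches the observed
extent; Benjamini-Hochberg across the observed clusters at q (default
0.05) flags significance.  By default only the group labels are permuted — covariate rows stay
attached to their subjects; a Freedman-Lane variant (permuting residuals
of the covariates-only reduced model) is available as a non-default
scheme.  Calibration is checked
empirically: on null cohorts the family-wise rate of any significant
cluster stays inside the exact binomial band around q.

Cluster peaks are the max-|t| voxel (ties to the smallest linear index)
mapped through the affine to world mm; voxel indices are 0-based
internally and never reported.

Demographic comparisons use the pooled-variance two-sample t (not Welch),
computable from raw columns or printed (mean, sd, n) summaries, a Yates-
corrected 2x2 chi-square for sex, and a Kolmogorov-Smirnov normality flag.

## Clinical correlation

Per-subject unweighted means of the significant clusters are correlated
(Pearson, two-sided p from the t transform at df = n-2) with clinical
scores, patient-group-only by default and uncorrected at p < 0.05; an
optional BH correction across variables is provided and is a deviation
from the mirrored analysis when enabled.

## MVPA

Each subject's in-mask DC z-map is one feature vector (columns in C scan
order of the mask).  A soft-margin linear SVM (C = 1 by default; the
choice is recorded in provenance) is evaluated by leave-one-per-group-out
cross-validation: fold k holds out the k-th patient and k-th control in
subject order (min(n1, n2) folds); a leave-one-subject-out variant is
available.  Metrics come from pooled held-out predictions; AUC uses the
rank (Mann-Whitney) formulation with ties counted 0.5, cross-checked
against an exhaustive pair-count oracle and scikit-learn.  Significance:
whole-sample label permutations re-running the full cross-validation,
p = (#{null >= observed} + 1)/(B + 1) — the add-one convention avoids
p = 0.  No feature scaling is applied by default (DC z-maps are already
per-subject standardized); an optional train-fold-fitted standardization
avoids leakage.  The whole-sample weight vector is mapped back to voxel
space; the top 20% of |weight| voxels (ties to the smaller linear index)
localize the pattern, optionally summarized as percent of total |weight|
per region of a user-supplied integer label image (no atlas ships with
the package).

## Numerical and design notes

* All regressions include an intercept; detrending and nuisance residuals
  are exactly mean-zero, and detrending is idempotent to 1e-10.
* Numerically zero GLM residuals (identical maps across subjects) report
  t = 0 rather than round-off noise.
* Cluster labels are deterministic: descending extent, ties by smallest
  linear voxel index.
* Whether correlations exactly at the DC threshold count is resolved as
  strict `>`; it is a configuration-visible constant.
* Fold pairing, permutation draws and cohort generation all derive from
  explicit integer seeds; identical configuration and seed reproduce
  byte-identical outputs.

## Problem sizes used by the test and acceptance suites

The suites run at desk scale by design: 16^3 grids (~1,300 gray voxels),
10-15 subjects per group, 60-240 volumes, 200 permutations, and 10-50
replicates per calibration/recovery claim.  These sizes were chosen so the
statistical property under test (calibration band, recovery rate) is
decisive at the configured effect sizes while the whole suite stays
desk-runnable; they are stated here so results can be reproduced exactly.

## Known limitations

* Permutation cluster inference assumes exchangeability of subjects under
  the null; covariate imbalance between groups is handled by the GLM but
  not by the permutation scheme itself.
* The generator's slab networks give spatially blocky correlation
  structure; cluster shapes on synthetic data are not representative of
  anatomical clusters.
* The demographics t-test path reproduces printed summary statistics only
  under the pooled-variance convention; heteroscedastic groups would call
  for Welch, which is deliberately not the default here.
* With very small cohorts the sex covariate can be constant and is then
  dropped from the design (with a warning), slightly changing the model
  relative to larger cohorts.
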