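# Methods

`metatrack` implements the analysis chain for a longitudinal, two-arm mouse
serum metabolomics study with complementary tissue imaging: a tumor-bearing
strain (TKO, a triple-mutant model of high-grade serous ovarian carcinoma)
against a genetically matched control strain, bled every two weeks from 8
weeks of age until death, with pooled-QC and blank injections interleaved in
the LC-MS acquisition sequence, plus MALDI mass spectrometry imaging of the
reproductive system. Every stage is exercisable on synthetic cohorts with
planted ground truth; this note records the models, parameter choices and
their limits.

## Time alignment and stage bins

Animals die at different ages, so calendar age is a poor alignment axis.
Each sample is mapped to **percent lifetime**,

    %lifetime = 100 × age / lifespan,

where for controls the denominator is the age at the last blood collection
(so both arms populate the full [0, 100] axis). The axis is divided into
four disease-stage bins: premalignant **PRE** [20, 37), tumor-onset **ET-I**
[37, 61), early-tumor **ET-II** [61, 81), and advanced **AT** [81, 100].
The conventional integer labels (20–36, 37–60, 61–80, 81–100) are realized
as half-open real intervals so that every real %lifetime value has exactly
one stage; values below 20 — possible for a long-lived control's first
samples — map to PRE. Bins are configurable.

Per feature and bin, the effect summary is `log2(mean TKO / mean CTRL)` of
raw post-QC abundances. Its standard error uses the delta method,

    se = (1/ln 2) · sqrt(cv²_TKO/n_TKO + cv²_CTRL/n_CTRL),

with cv the within-bin coefficient of variation; a bootstrap alternative is
easy to wire but the delta method is the default because it is deterministic
and accurate at the per-bin sample sizes that occur here (n ≳ 10). A
class-level trajectory first averages, per sample, the abundances of the
class's statistically significant members, then bins that score like a
single feature.

## QC-based feature curation

Four rules, applied per ion-mode dataset independently:

- **Blank rule**: a feature is background unless its mean study abundance is
  at least 5× its mean blank abundance. The comparison uses means (the rule
  is stated against "the" baseline abundance; mean-vs-mean is the symmetric
  reading); the boundary keeps the feature, and a zero blank mean always
  keeps it.
- **QC presence**: detected (non-missing and > 0) in ≥ 50% of pooled-QC
  injections.
- **QC RSD**: sample (n−1) relative standard deviation over QC injections
  ≤ 30%. Features with fewer than 3 usable QC values are indeterminate:
  kept and flagged rather than silently dropped.
- **Drift correction**: per feature, a LOWESS curve (span 0.75) is fit to
  log QC abundance versus injection order — a least-squares line when fewer
  than 5 QCs are available — normalized to the median QC level, interpolated
  linearly between QC injections (held at the nearest fitted value outside
  their range, with extrapolation flagged), and divided out of every sample.
  The per-feature median QC abundance is preserved exactly by a final
  rescale. Fitting on the log scale makes the linear-fallback path an exact
  projection, hence exactly idempotent; the LOWESS path is idempotent only
  approximately (LOWESS is not a projection operator), which in practice
  means re-correcting corrected data perturbs it at the level of the
  residual QC noise, not systematically.

The three filters are per-feature and mutually independent, so their order
cannot change the surviving set — a property the tests check directly.

## Univariate screening

Two-tailed Welch t-tests (Satterthwaite degrees of freedom) per feature on
raw post-QC abundances, with Benjamini–Hochberg step-up control; features
with q < 0.05 gate all downstream stages. Missing values are dropped
pairwise, with no imputation. Longitudinal samples are treated as
independent observations; this matches the source design but ignores
within-mouse correlation, so a conservative `per_mouse="mean"` option
collapses to one value per animal first. The synthetic generator plants no
mouse-level random effect by default, which is exactly the regime in which
the per-sample test is calibrated; with mouse effects present the per-sample
test would be anticonservative, and the per-mouse option is the remedy.

## Multivariate models

Columns are autoscaled (mean 0, unit sample sd; constant columns zeroed and
flagged). For ratio screening the generalized logarithm
`glog(x) = log2((x + sqrt(x² + λ))/2)` is applied first, with λ defaulting
to the squared minimum positive value of the matrix.

**oPLS-DA.** Classes are coded TKO:+1, CTRL:−1. Orthogonal-signal-correction
components — directions of X-variation uncorrelated with the class vector —
are removed iteratively (Trygg–Wold construction: the orthogonal weight is
the predictive loading minus its projection on the predictive weight), after
which a single predictive PLS component is fit. With zero orthogonal
components the model coincides exactly with 1-component PLS-DA, a reduction
the tests assert at 1e-10. The decision threshold is ŷ = 0 with exact ties
assigned to the control class, so predictions are deterministic. Components:
1 orthogonal for a "2-latent-variable"-style model, 2 for the 3-LV panel
model; always explicit in configuration.

**Venetian-blind cross-validation.** Fold f holds every sample whose
position in a fixed ordering is ≡ f (mod 10); the ordering convention is the
acquisition (injection) sequence. Scaling is refit inside each training fold
to avoid leakage. One practical caveat the null tests exposed: if the class
labels alternate with a period that divides the fold stride, each blind is
single-class and the training intercept systematically anti-predicts the
held-out fold; a class-mixed ordering (e.g. a randomized injection sequence)
avoids this, and the null-calibration checks randomize labels accordingly.

**Permutation test.** The group-separation statistic is the between- over
within-class sum of squares (B/W) of the predictive scores of a model refit
on the given labels — the statistic is scale- and shift-invariant. With
labels permuted uniformly at random, p = (1 + #{B/W_perm ≥ B/W_obs}) /
(1 + n_perm); 1000 permutations give a floor of 1/1001 ≈ 0.000999, i.e. the
"p < 0.001" regime for a clearly separated model.

**GA feature selection.** Binary-inclusion chromosomes; fitness is the
minimum venetian-blind RMSECV of PLS with 1–3 components on the autoscaled
selected submatrix; tournament selection (size 2), double-point crossover,
bit-flip mutation at 0.005, initial inclusion probability 0.15, and elitism
(the best chromosome always survives), which guarantees a monotone
non-increasing fitness trace. Defaults (population 64, ≤ 100 generations,
early stop when half the population equals the elite) mirror common GA-PLS
practice; the published tooling does not disclose its internals, so no
setting-level equivalence is claimed. Recovery experiments in the
acceptance suite run population 48 / ≤ 40 generations, which the fixtures
saturate (accuracy 1.0 before generation 40).

## Ratio biomarkers

All C(p, 2) unordered pairs, computed per sample on the natural scale
(ratios first, then glog and autoscale — the stated processing order),
oriented lexicographically by feature id. Ranking is by Welch p-value on the
glog scale; since autoscaling is affine per variable it cannot change the
ranking and is applied only where it matters (the logistic step). The top
ratios are evaluated by univariate logistic regression under stratified
10-fold CV; pooled out-of-fold probabilities give the ROC AUC, with
sensitivity/specificity read at the Youden-optimal pooled threshold, and
95% percentile-bootstrap CIs over samples (default 2000 resamples). The
reported orientation always has AUC ≥ 0.5 (inversion maps AUC to 1 − AUC).
The published tables' convention for sensitivity CIs whose lower bound
equals the point estimate could not be identified and is not reproduced.

## Mass annotation

Monoisotopic masses from a fixed most-abundant-isotope table (C 12 exact,
H 1.00782503207, N 14.0030740048, O 15.9949146196, P 30.97376163,
S 31.97207100, plus Na/K/Cl). Protonation and deprotonation use the proton
mass (1.00727647 Da); the ammonium adduct subtracts one electron mass; the
acetate and formate adducts are neutral-gain-minus-proton. Electron mass is
otherwise neglected — a < 0.002 Da effect, below the 4-decimal m/z
reporting precision. Matching is exact-mass only within a ppm tolerance
(default 5), candidates ranked by |ppm error|; such matches carry
confidence level 3, levels 1–2 require external MS/MS or standard evidence,
and unmatched observations are level 4. The 36 published annotation rows
shipped with the package (polar panel + lipid panel) act as a regression
suite: all agree within 5 ppm (max 4.13), three at exact 4-decimal
rounding. Isotope-pattern scoring, fragment matching and decoy-based FDR
are out of scope.

## MSI

Processed-mode centroid spectra per pixel (strictly ascending m/z), read
and written as imzML. TIC normalization divides each pixel by its summed
intensity (all-zero pixels excluded and reported). Ion images sum intensity
in an absolute ±0.001 Da window (the window is Da, not ppm, per the imaging
convention used). Segmentation clusters the pixel × feature matrix built
from a user-supplied reference m/z list — typically annotated features; the
original acquisition software's internal peak processing is not emulated —
by bisecting k-means: repeatedly 2-means-split the cluster with the largest
within-cluster SSE, on L2-normalized rows (cosine geometry; Euclidean
optional), best of 10 restarts, seeded, recording the split tree with SSE
before/after each bisection. The cluster-selection rule (largest SSE rather
than largest cardinality) and the cosine metric are configurable choices.
No hot-spot clipping is applied by default.

## Synthetic data: what it emulates, and what it does not

The cohort generator reproduces the *statistical structure* the analysis
assumes: 15 + 15 animals, two-week sampling from 8 weeks, TKO lifespans
uniform on 24–40 weeks, controls followed to 40 weeks; ~10³ features across
19 annotation classes (17 lipid classes plus a steroid and a polar-
metabolite group) with log-normal baselines (log10-uniform in [4, 7]) and
20% multiplicative measurement noise; pooled QCs every 10 injections at 15%
RSD; blanks at 2% of baseline; 2% missingness completely at random.
Temporal effects are multiplicative, `2^(effect_scale · template(%lifetime))`,
with piecewise-linear class templates anchored at 0 at 20 %lifetime:
monotone rises (Cer, HexCer, PC, PE, PS, PI, TG, DG, VLCFA), monotone falls
(SM, ether phospholipids, short-chain FA), an inverted-U for the
lyso-species, a mid-course wave for polar metabolites, and a late spike
(+0.99 from onset through 80 %lifetime) followed by a drop (−0.43) for the
steroid class, matching the two published magnitudes for
20α-hydroxyprogesterone; other class magnitudes are free parameters, not
source claims. The MSI phantom nests a healthy core inside a tumor ring
with a necrotic lobe, region-specific per-feature mean intensities
(log-normal contrast, sd 1.5 in log2), multiplicative noise and pixel-level
TIC variation.

Deliberately **not** simulated: chromatographic or retention-time drift
beyond the smooth QC trend, isotope patterns, MS/MS spectra, informative
missingness, and within-mouse serial correlation. Passing recovery tests
therefore demonstrates that the pipeline recovers planted structure under
its own assumptions — not that real acquisitions satisfy those assumptions.

## Problem sizes and numerical conventions

Recovery experiments use 20 cohort replicates at 1000 features for null
calibration, a 300-feature / 80-sample fixture with 22 planted
discriminants for the GA panel, 46-feature ratio screens (1035 pairs, 20
replicates; AUC recovery at n = 300 over 10 replicates), and a 30 × 30 ×
50-feature phantom for segmentation. Ties at the oPLS-DA threshold go to
the control class; zero-variance columns scale by 1; BH q-values clip at 1;
zero control means raise errors rather than propagate infinities; all
stochastic steps take explicit seeds and the pipeline derives per-stage
seeds from one global seed.
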