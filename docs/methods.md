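# Methods

## Design model

A clip of length 660 s is sampled on a 15-s grid whose first legal slot is
75 s (no probing during the first minute), giving 40 slots. Jitter windows
are consecutive 120-s intervals starting at the first legal slot; every
schedule places exactly one probe per window. The first half of the orders
is built as a per-window assignment of distinct slots to orders, so the
8 first-block orders are pairwise disjoint and, when each window holds
exactly 8 slots, their union is the whole grid. Each second-block order
re-uses one first-block slot per window, with the first-block partners
chosen by distinct cyclic offsets: consequently every slot is covered by
exactly two orders, and any pair of orders shares at most one probe time.
A stricter reading — a later order sharing a time with *only one* earlier
order in total — is arithmetically impossible once the first block tiles
the grid and the second block re-covers it, since then every probe of a
later order coincides with some earlier order's probe; the pairwise
at-most-once constraint is the strongest consistent version and is what the
constructor enforces.

Order-to-participant assignment uses a cyclic Latin-rectangle: after seeded
shuffles of participants and order labels, participant *i* receives order
τ[(i + c_m) mod 16] for movie *m* with distinct shifts c_m. Within a
participant all orders are distinct and each (movie, order) cell holds
⌊n/16⌋ or ⌈n/16⌉ participants. With 120 participants a slot is therefore
observed 14–16 times (mean 15); exact equality at 15 would require pairing
the two covering orders across the 7/8 split and is not attempted.

## Thought space

Items are z-scored with stored means and sample standard deviations; the
decomposition is the eigendecomposition of the item correlation matrix
(unrotated; varimax available behind a flag but off by default, consistent
with a strictly decreasing variance profile). Loadings are unit-norm
eigenvectors with the sign convention that each component's
largest-|loading| item loads positively. Scores are projections of the
standardised items onto the loadings; scoring the fitting set yields
exactly zero-mean, mutually uncorrelated columns, and new data reuse the
stored standardisation constants. Missing items are an error — no
imputation.

Split-half reliability: per bootstrap iteration the probes are randomly
halved, each half is decomposed independently, and homologous components
are matched by the assignment maximising summed |loading correlations|
(Hungarian algorithm; exact). The similarity is the mean matched |r|;
1000 iterations and a percentile 95% CI by default. Even noiseless rank-4
data sits marginally below 1 (≈0.998 at n = 20 000) because each half's
eigenvectors rotate slightly within the planted span under sampling; the
tests treat "fully reliable" as 1.00 at two printed decimals.

## Experience time series

Bin means are arithmetic means over all participants probed at a slot;
probes must lie exactly on the grid. Interpolation to TR resolution is
piecewise-linear between slot onsets with constant extrapolation to the
section edges (cubic natural spline available). The analysis window is the
final 10 minutes (600 TRs from 60 s), since minute 1 is never sampled.
Experience regressors are not convolved with an HRF by default — they vary
on a scale of tens of seconds, far slower than the hemodynamic response — 
and probe scores are anchored at the probe slot itself (the report
describes experience just before the probe); a lag/convolution sensitivity
path exists in the library.

## Voxel-space mapping

First level: per-unit OLS with intercept on the four experience regressors;
the design is rejected if its condition number exceeds 1e6, naming the most
collinear pair. No temporal prewhitening by default (slow regressors);
residual variance uses dof = TR − p − 1. Group level: one-sample t across
subject betas (per movie, or betas averaged within subject across movies),
mapped to z through the exact tail correspondence, two-sided
cluster-forming threshold z = 3.1, clusters as connected components of a
supplied adjacency (6-connectivity for voxel grids, k-nearest-neighbour
edges for parcels). Family-wise inference sign-flips whole subject maps and
compares each observed cluster's |z| mass against the null distribution of
the maximum mass, with the (count+1)/(n_perm+1) estimator. This replaces
the Bayesian mixed-effects estimator of classical fMRI packages with a
distribution-free scheme preserving the same random-effects, cluster-FWE
logic; output metadata records the substitution. The corrected alpha
defaults to 0.0125 (= 0.05/4 regressors); units with zero between-subject
variance are flagged ±inf and excluded from clustering.

Simulated movie BOLD contains shared (stimulus-driven) variance beyond the
planted couplings, so regressors for uncoupled components can also yield
significant clusters: shared signal correlates non-trivially with any slow
regressor and survives a random-effects test. This mirrors the real
analysis situation rather than a defect of the inference, and the type-I
calibration suite therefore uses exchangeable zero-mean subject maps.

## State space

Each subject's unit time series is z-scored (constant units become zero
with a warning); subjects are averaged elementwise. The group map at every
TR is Spearman-correlated (average ranks) with each gradient inside the
mask (mask = units nonzero in all five maps when derived from values). The
numerator of the correlation uses the same pairwise reduction as the sums
of squares, so a map identical to a gradient scores exactly 1.0. Zero-
variance maps yield NaN coordinates, never a silent zero. Probe-level
coordinates average the TRs in [t − 15 s, t) by default (window
configurable; 0 gives the single TR at t).

A caution for interpreting the zero-noise limit: a perfectly rank-1
signal s(t)·pattern produces a *two-valued* coordinate series, because the
parcel rank order depends only on the sign of the z-scored latent. Any
spatial noise breaks the ties, after which the coordinate is a near-perfect
monotone image of the latent.

## Behavioural models

Random-intercept linear mixed models are fitted by REML (statsmodels
MixedLM); a singular random-effects fit falls back to a fixed-intercept
model with a logged note. Omnibus and family tests are Wald F statistics on
the fixed-effect covariance; denominator dfs are residual-based
(n − p − groups + 1) rather than Satterthwaite — fractional Satterthwaite
dfs are not reproduced, which affects dfs but not estimates, and the fixed
effects are cross-checked against lme4 in the test suite. Least-squares
means come from design rows at covariate means; pairwise contrasts use the
Tukey studentized-range adjustment. The comprehension model sum-codes the
movie factor so pattern main effects are average slopes across movies; its
FDR family is the nine fixed-effect terms (movie, four pattern mains, four
interactions), and FDR-significant interactions are followed by per-movie
simple slopes, themselves FDR-corrected. Partial eta-squared is
F·df1/(F·df1 + df2).

## Spin test

Parcel centroids live on a unit sphere. Per permutation a uniform random
rotation (scipy `special_ortho_group`) is applied — mirrored about the
sagittal plane for the opposite hemisphere — and units are re-assigned
one-to-one to rotated positions by a cosine-similarity assignment, i.e. a
genuine permutation of locations that never duplicates or invents values
(a whole-mask "cluster" therefore has an exactly constant null). Landed
units outside the mask inherit the nearest in-mask value; a permutation
that strands the entire cluster outside the mask is redrawn, with redraws
capped and counted. Two-tailed p = 2·min(P(null ≥ obs), P(null ≤ obs))
with the (count+1)/(n_perm+1) estimator, capped at 1; 2500 permutations by
default.

## Synthetic studies

The generator emulates the full two-cohort design with explicit ground
truth. Defaults: 120 mDES participants, 20 fMRI subjects, 3 movies of
660 s at TR 1 s, 16 items, 4 components, 400 parcels.

* **Latents.** White noise smoothed with a circular Gaussian kernel
  (sd 30 s; model autocorrelation exp(−τ²/4sd²)), then orthogonalised and
  standardised within each movie. Orthogonalisation reflects that the
  planted components are *dimensions* of experience — mutually
  uncorrelated by construction; without it, a smooth 660-s trajectory
  carries so few effective samples that chance inter-latent correlations
  of 0.3–0.6 occur and the planted structure becomes unidentifiable to any
  decomposition.
* **Items.** Loadings are orthogonal unit-norm blocks of unequal size
  (6/5/3/2 items), giving the well-separated, strictly decreasing
  eigenvalue profile seen in real mDES decompositions; equal blocks would
  produce tied eigenvalues and arbitrary component mixing. Item response =
  5.5 + 2·(L·f(t)) + participant intercept (sd 0.5) + noise (sd 0.5),
  clipped to [1, 10].
* **Brain.** Parcels on a Fibonacci lattice of one sphere; gradients are
  five standardised low-order real spherical harmonics (smooth, pairwise
  |r| < 0.1). Parcel signal = Σ_k Σ_g C[k,g]·f_k(t)·G_g(p) with planted
  couplings C[Sensory, G1] = −0.5 and C[Episodic, G4] = +0.5, plus shared
  stimulus-like noise (sd 0.5) and subject noise (sd 1.0).
* **Comprehension.** score = 2.5 + effects·(mean latent exposure at the
  participant's probe times) + noise (sd 0.8), rounded into 0–4, with
  planted effects −1 (Intrusive Distraction) and +1 (Sensory Engagement).
  The effect sizes are set so the planted signs are recoverable at the
  default cohort size despite the attenuation that participant intercepts
  and score rounding introduce.

What the generator does **not** emulate: hemodynamics, motion or
physiological artifacts, inter-subject spatial variability, item-level
response styles, and the two-hemisphere surface geometry of real cortex
(the synthetic sphere is a single hemisphere for the spin machinery).
Passing recovery tests therefore demonstrate the pipeline's correctness
under its own assumptions, not robustness to those realities.

## Problem sizes of the heavier checks

The calibration suite uses 200 null datasets for the sign-flip test
(16 subjects × 60 units, 199 permutations, cluster-forming z = 1.5 so the
mass statistic is non-degenerate) and 200 rotation-drawn clusters for the
spin test (100 parcels, 199 permutations), asserting the empirical type-I
rate inside the 2σ binomial band around 0.05 and uniformity of the
family-wise p by a Kolmogorov–Smirnov bound. The end-to-end recovery study
runs 200 simulated studies at the default cohort sizes with 100 parcels
(spatial resolution is a free choice; the couplings act identically at any
parcel count) and requires a significant negative gradient-1 term for
Sensory Engagement in at least 95% of runs.

## Known limitations

* Satterthwaite dfs and lme4/FLAME numerics are not reproduced; statistics
  agree in estimate and direction, dfs only approximately.
* The sign-flip scheme assumes symmetric subject effects under the null;
  it is exact for exchangeable sign-symmetric errors only.
* Parcel-level spins with one-to-one reassignment are a desk-scale stand-in
  for vertex-level surface spins; volumetric clusters must first be mapped
  to parcels.
* With heavily clipped responses (very large item noise or effects) the
  linear item model is misspecified; the generator's defaults keep clipping
  rare (<0.1%).
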