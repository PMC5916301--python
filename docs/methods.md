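# Methods

This note documents the models, defaults and numerical choices behind
`trapstat`, and what the synthetic-data tests do and do not demonstrate.

## Detection histories and occasions

Daily records are truncated to the first 120 days per station (limiting
closure violations over a year-long deployment) and pooled into occasions
of 15 days by default. An occasion scores 1 if any active day recorded a
detection; *effort* is the count of active days and enters detection as a
standardized per-occasion covariate. Occasions with zero active days are
treated as missing, not zero — zero effort carries no information and the
likelihood must skip such cells. `select_occasion_length` fits the global
model at each candidate pooling length and accepts the smallest length
whose parametric-bootstrap goodness of fit gives p > 0.05 and ĉ ≤ 1.5;
this adequacy rule is this package's own operationalization of "choose the
pooling that makes the global model fit".

Continuous covariates are z-standardized with the sample (n−1) standard
deviation; the training means/SDs are retained and reapplied to prediction
grids. The collinearity screen removes one member of every pair with
|r| ≥ 0.6 (strictly: 0.59 keeps both), resolving pairs in descending |r|
and keeping the member with the lower univariate-model AICc; a covariate
already dropped cannot eliminate further covariates.

## Maximum-likelihood occupancy

The marginal likelihood is the usual zero-inflated product over occasions,
maximized by BFGS from 10 jittered starts (ties broken by log-likelihood).
Gradients are finite-difference, so the convergence tolerance is set at
gtol = 1e−5, just above the difference-noise floor; standard errors come
from the inverted central-difference Hessian. AICc uses n = number of
stations; this convention reproduces published detection-model rows
(logLik −684.45, K = 2, n = 849 → 1372.91) exactly, which fixes two
reading ambiguities at once: the "−2logLik" column of such tables is in
fact the log-likelihood, and station count is the effective sample size.
Model averaging is *full* (absent terms count as zero) over the ΔAICc < 2
set with the standard unconditional-variance formula. Ranking tables always
recompute ΔAICc and weights arithmetically from the AICc column rather than
accepting externally supplied deltas, which published tables occasionally
print inconsistently.

The goodness-of-fit test cohorts stations by missingness pattern,
enumerates all 2^k possible histories per cohort, accumulates expected
counts site-by-site from the fitted ψ_i, p_ik, and sums (O−E)²/E over
cells with non-negligible expectation. The parametric bootstrap refits
each replicate from the observed MLE (single start); ĉ is the observed
statistic over the bootstrap mean. Refit failures above 10% raise a
warning rather than silently biasing p.

## Restricted spatial regression

Stations within 8.7 km are neighbours (closed boundary; the threshold
matches the movement scale σ estimated by capture–recapture). The Moran
operator Ω = (n/1'A1)·PAP is projected by P = I − X(X'X)⁻¹X' so its
eigenvectors are orthogonal to the fixed effects; the basis keeps the top
q = round(0.1·n) eigenvectors (round half up: 84.9 → 85). The spatial
precision prior Gamma(0.5, 0.0005) is read as shape–rate (prior mean
shape/rate = 1,000), which weights large precision — weak spatial
correlation — so a posterior spatial effect is data-driven.
β, and the detection coefficients γ, take Normal(0, 10⁶) priors.

Both probit layers are sampled exactly by truncated-normal (Albert–Chib)
augmentation; (β, α) update jointly from one Gaussian solve per iteration
(W'W is precomputed; only the τ-dependent q×q block changes), τ from its
conjugate Gamma full conditional, and the latent z for undetected stations
from its Bernoulli conditional. The default schedule is a single chain of
50,000 iterations, 10,000 burn-in, thinning 5; multiple chains are
supported (run with different seeds) and recommended for production use.
The q = 0 basis reduces the sampler to the ordinary nonspatial model; a
test pins the two posteriors together by KS distance.

PPLC is Gelfand–Ghosh squared-error loss: G = Σ(y − m)² plus predictive
variance P = Σ m(1−m) over observed cells, with m the posterior-predictive
cell mean marginalized over occupancy and detection.

Prediction maps are covariate-only: the spatial effect is defined on the
surveyed stations' graph and is not extrapolated to unsurveyed pixels.
Equal-tailed credible intervals summarize occupancy parameters; HPD
intervals are reserved for the SCR posterior.

## Spatially explicit capture–recapture

The mask is a regular lattice (default 500-m spacing, 0.25-km² pixels)
clipped to the union of 25-km discs around the traps, intersected with a
0/1 suitability grid; a warning fires when the buffer is under three times
a supplied σ hint. The ML fitter maximizes the Poisson point-process
likelihood with Bernoulli proximity detectors (independent per
trap-occasion), integrating activity centres over mask pixels, on
transformed scales (log D, logit g₀, log σ); intervals are Wald on the
transformed scale, back-transformed.

The Bayesian fitter embeds the n detected animals among M = n + 10n
all-zero histories with inclusion indicators w_i ~ Bernoulli(ψ_aug),
ψ_aug ~ U(0,1), and a Poisson encounter model y_ij ~ Poisson(K_j λ₀
exp(−d²/2σ²) w_i). The "augmentation value" convention is *added*
individuals (19 detected → M = 209); it is configurable. λ₀ and σ move by
multiplicative random walks (implied 1/λ₀, 1/σ priors within wide bounds);
activity centres are continuous over the suitable region, updated by
tuned random walks (20–40% acceptance), with excluded individuals
resampled uniformly — their exact conditional.

One numerical finding shaped the sampler: with sparse data (1–3 captures
per individual) σ and the centre cloud are so strongly coupled that
componentwise updates can take 10⁵+ iterations to leave a bad region —
each centre's conditional spread is ~σ, so σ cannot shrink until all
centres contract, and vice versa. The sampler therefore adds a joint move
that proposes σ' = σe^ε and rescales every detected centre about its
capture centroid by σ'/σ, accepted with the (σ'/σ)^{2n} Jacobian. A
regression test compares the resulting σ marginal with a brute-force
integration of the posterior over a (λ₀, σ, N) grid; they agree to a few
percent where the naive sampler was off by a factor of eight.

The Bayesian p-value uses a Freeman–Tukey discrepancy Σ(√y − √μ)² on
individual×trap totals (the published analysis names only the p-value, not
its statistic). Geweke scores compare the first 10% and last 50% of each
chain with Newey–West (Bartlett) spectral variance estimates. The density
surface counts included activity centres per pixel across stored draws; it
integrates to the posterior mean of N_super by construction.

## Synthetic data

The generator is the package's study stand-in, because the original
survey's coordinates are withheld. Stations sit on a jittered grid whose
pitch-minus-jitter guarantees the 2-km minimum spacing; covariates are a
deterministic gradient (elevation), a Gaussian random field smoothed to a
15-km length scale (forest), and distance to a random polyline (river),
evaluated consistently at stations and prediction pixels. Occupancy
histories are generated from the *same* truncated Moran-basis model the
fitter assumes — this makes recovery tests well-posed but means passing
tests show correctness of the inference machinery, not robustness to
model misspecification (a full GP, anisotropy, or detection-level spatial
correlation are not emulated). Camera dropout is independent per-day
Bernoulli (rate 0.1); real outages are temporally blocked, which the tests
do not emulate. SCR populations follow the augmented model exactly, with
undetected individuals retained in the truth objects for N-recovery
checks.

The bundled fixture reproduces the study's marginal counts — 849 stations,
exactly 114 with ≥ 1 detection, 120-day windows, seven survey areas — with
a covariate-weighted but seeded assignment of detections; only the
marginals are faithful, the spatial pattern is synthetic.

Default truth values at study scale: probit site-use coefficients
(−0.47, −0.244, 0.235, 0.265) for (intercept, elevation, forest, river);
SCR density 0.40/100 km², σ = 8,698 m, λ₀ = 0.0025 per trap-occasion.
The per-occasion reading of λ₀ follows the published table; the same
study's text prints 0.26, which is only consistent with a rate accumulated
over the ~100-day survey and would contradict the reported 1–3 captures
per individual if taken per occasion.

## Problem sizes in the test suite

The recovery studies run at reduced scale, chosen to keep the full chain
exercised end-to-end: occupancy coverage at 300 stations × 8 occasions ×
20 replicates (4,000-iteration chains); the spatial-vs-nonspatial
comparison at 300 stations × 20 replicates with sparse, strongly clustered
detections (daily detection probit intercept −2.6, τ = 0.02 — the regime
the spatial correction is for); SCR recovery on a 7×7 trap grid with a
3σ/1-km mask and 10 replicates. The directional and coverage claims these
tests make are statements about those regimes; effect sizes at full survey
scale are demonstrated by the analysis drivers, not asserted by tests.

## Known limitations

- Single-season models only; no dynamic occupancy, no behavioural
  (trap-response) or time-varying detection in SCR, no sex-specific
  density.
- The RSR spatial effect is not kriged beyond surveyed stations.
- ML SCR assumes a homogeneous density surface; the Bayesian surface is
  descriptive (posterior centre placement), not a density regression.
- PPLC is a relative comparison tool; it does not measure absolute fit.
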