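# Methods

This note documents the models, estimators and numerical choices behind
stabnet, what the synthetic-data generator does and does not emulate, and the
design decisions taken where more than one reasonable convention exists.

## Gaussian graphical model and the adaptive estimator

The data model is a p-variate Gaussian with precision matrix Θ; an edge
between variables i and j means Θ_ij ≠ 0, with partial correlation
ρ_ij = −Θ_ij/√(Θ_ii Θ_jj). All estimation happens on transformed,
standardized columns, so S is a correlation-scale matrix with unit diagonal.

**Graphical lasso solver.** The core solver maximises
log det Θ − tr(SΘ) − Σ_{i≠j} P_ij |Θ_ij| for an arbitrary symmetric
nonnegative penalty matrix P with zero diagonal (the diagonal is never
penalised). It is a proximal-gradient method with backtracking line search
and FISTA momentum, made monotone by falling back to a plain proximal step
whenever the momentum step would decrease the objective; iterates stay
positive-definite because the line search rejects any point whose Cholesky
factorization fails. The step size is initialised each iteration at the
local Lipschitz bound eigmin(Θ)². Convergence is declared when the maximum
absolute change between successive iterates falls below `tol` (default 1e-6;
tighter for oracle comparisons). The inner loop is numba-compiled, with the
identical pure-NumPy path as fallback. Correctness anchors, all in the test
suite: zero penalty reproduces S⁻¹; a scalar penalty ≥ max off-diagonal |S|
gives an exactly diagonal estimate; the p=2 solution matches the
soft-thresholding closed form; KKT residuals vanish at the solution; and the
solution matches scikit-learn's scalar-penalty implementation.

**Random-penalty stability selection.** The support is estimated by an
ensemble of B fits (default 1000), each on a full-size bootstrap resample of
the rows with a freshly drawn penalty. The default draw is a single scalar λ,
log-uniform on the **absolute** interval [0.05, 0.5], broadcast to all
off-diagonal entries; an entrywise variant multiplies each entry by
independent U[floor, 1] factors. The absolute scale is a deliberate choice:
on standardized data λ is commensurable with correlations, the lower end
(0.05) sits just above sampling noise at a few hundred subjects and the
upper end (0.5) above the largest partial correlations such studies report.
A range tied to the largest |S| entry of each resample was evaluated and
rejected: on pure-noise data that anchor is itself noise-scale, so the
ensemble densely scans the noise range and the strongest spurious
correlations pass any vote threshold — with the absolute default, null data
(p=10, n=300) yields essentially zero spurious edges while planted |ρ| ∈
[0.2, 0.4] edges at n=400 are recovered with sensitivity ≈ 0.88 and
specificity ≈ 0.96 (both re-measured in the acceptance suite). Entries with
|Θ| > 1e-8 count as nonzero; failed ensemble members are dropped (an error
is raised if more than 10% fail).

**Threshold and refit.** Edge-vote proportions strictly exceeding τ = 0.65
form the support (a proportion of exactly 0.65 is *not* an edge). The final
model is the support-constrained Gaussian MLE, realised as a graphical lasso
with zero penalty on supported entries and a prohibitive penalty
(1e6 × max |S_ij|) elsewhere, which drives off-support entries below 1e-8;
they are then zeroed exactly. An empty support returns the diagonal model
with a warning. The merged step-2/3 (refit directly on the thresholded
support rather than averaging the ensemble precision first) is one of the
two readings the three-step description admits; it is the simpler and fully
reproducible one.

## Node measures

Predictability is R²_i = 1 − 1/Θ_ii (×100) on the standardized scale, the
variance share of node i explained by its neighbours; tiny negative values
from solver round-off are clipped to zero. Hold-out predictability applies
the implied coefficients β_ij = −Θ_ij/Θ_ii to a test table standardized with
the *training* parameters, and reports 1 − SSE/SST about the test mean — it
can be legitimately negative.

Centralities and the spanning tree run on |partial correlation| weights of
supported edges: shortest-path measures use distance 1/|w| (closeness is
component-local, without the small-component inflation correction);
current-flow measures use |w| as electrical conductance, with current-flow
closeness computed from the component Laplacian pseudoinverse as
(m−1)/Σ_t R_eff(v,t) and isolated nodes scored 0. Whether such studies use
signed or absolute weights for flow measures is rarely stated; absolute
weights are assumed here and signs are preserved in all reported edge lists.
The maximal spanning tree is Prim's algorithm with deterministic
lexicographic tie-breaking on node-label pairs, returning a forest on
disconnected graphs; exactness is checked against exhaustive spanning-tree
enumeration and Kruskal.

## Stability suite

Edge-weight CIs are percentile 2.5/97.5 intervals over B bootstrap resamples
(default 1000), each re-running the full adaptive procedure with a reduced
inner ensemble (default 100) — the diagnostics exercise the actual
estimator, not a surrogate. Per-edge sensitivity (reference-present edges)
is the fraction of bootstraps containing the edge; specificity
(reference-absent) the fraction without it. Difference tests for edges and
centralities are paired: both models must be bootstrapped with the same
resample indices (enforced via a pairing key), and the two-sided p-value is
2·min(frac ≤ 0, frac ≥ 0) of the paired differences, floored at 1/B; no
multiple-testing correction is applied. Measured coverage of the percentile
CIs for a planted |ρ|=0.5 edge at n=500 is ≈ 90% — the familiar mild
undercoverage of percentile intervals; the estimator itself is unbiased with
bootstrap SD matching the sampling SD.

Network similarity uses Pearson r (with p-value) on the vectorised
upper-triangle weighted adjacency and Hamming similarity
1 − mismatches/compared entries on the binarized support; the row scope
restricts both to one node's incident edges. Pearson r on short near-binary
vectors is reported but flagged as fragile; Hamming is the more reliable of
the two. Case-dropping stability draws subsamples without replacement at
retained fractions 0.9…0.3, re-estimates, and correlates node measures with
the full-sample values; the CS coefficient is the largest dropped proportion
at which ≥95% of subsamples correlate ≥ 0.7.

## ERP quantification

Component amplitude is the mean signal inside a fixed response-locked window
(default 0–100 ms), averaged over trials. Latency is 50% fractional-area
latency with rectification restricted to the declared polarity (negative for
error/correct-related components), cumulative trapezoid area and linear
interpolation between samples; zero windowed area yields a missing value.
Within-subject variability is the SD of trial-level windowed means,
between-subject variability the SD of subject means (both n−1).

The dependability coefficient uses a one-way random-effects decomposition:
σ²_b = var(subject means) − mean(σ²_w,i/n_i), and per subject
dep_i = σ²_b/(σ²_b + σ²_w,i/n_i), clipped to [0, 1], with a warning and 0
when σ²_b is non-positive. The reliability literature offers several
estimators (trial-weighted, Bayesian); this moment-based per-subject form is
fixed here for reproducibility and may differ numerically from others.
Exclusion rules are strict inequalities — fewer than 5 scoreable trials, or
dependability below .70 — so boundary subjects are kept.

## Transforms

Pipeline order is fixed: Box-Cox per variable → non-normality screen →
standardize. Box-Cox shifts by 1 − min(x) when the minimum is non-positive
(shifted minimum exactly 1, keeping the λ likelihood well-behaved for
negative-valued ERP amplitudes) and maximises the profile log-likelihood over
λ ∈ [−5, 5] (scipy's boxcox_llf under a bounded scalar optimizer, tolerance
1e-4). The screen drops variables whose post-transform |skewness| exceeds 2
— a configurable stand-in for the judgment call of excluding irreparably
non-normal scales. Standardization uses population (ddof=0) SDs so the
covariance passed to the solver has exactly unit diagonal. Transforms are
fitted on the training split only and applied unchanged to the test split;
test values that undercut the training positivity shift are clipped to a
small positive floor rather than erroring.

## Synthetic-data generator

`make_precision` plants a G(p, m) random support (m = round(density·C(p,2)))
with edge partial correlations uniform in the requested magnitude range and
Rademacher signs, on a unit-diagonal precision matrix. Positive-definiteness
is enforced by boosting the diagonal until the smallest eigenvalue reaches
0.05 and rescaling back to unit diagonal; when a boost fires it shrinks the
realised partial correlations below the requested range, so
`true_partial_corr` (computed from the final matrix) is always the ground
truth to score against. `make_study` emulates the target study design: ~30
trait scales, two ERP amplitude nodes, two latency nodes and two scalar
covariates, with independent 236/107 train/test samples from one population
and optional monotone-exponential marginal skewing (which leaves rank
correlations untouched) to exercise the transforms.

Epochs are a Gaussian-shaped peak (SD 20 ms) on a 256 Hz, −100..600 ms
response-locked axis; each subject gets a latent amplitude
N(amp_mean, amp_sd_between²) and latency N(latency_mean, latency_sd²), each
trial jitters the amplitude by N(0, amp_sd_within²) and adds white noise.
Defaults (−8 µV mean, 4 µV between, 8 µV within, ~28 trials) reproduce the
reliability regime of error-trial ERPs, where dependability around .85–.9 at
a few dozen trials is realistic. The generator does **not** simulate
continuous EEG, artifacts, channel structure, oscillatory background or the
go/no-go task; passing tests therefore demonstrate correctness of the
quantification and network machinery under the stated generative model, not
robustness to real-EEG nuisances (filter distortion, non-Gaussian artifact
residue, latency-amplitude confounds).

All generators take explicit integer seeds and never touch global RNG state;
derived seeds come from `numpy.random.SeedSequence` spawning and stay below
2³¹.

## Problem sizes and numerical defaults

The validation suite uses desk-scale sizes chosen to estimate each property
with useful precision: planted-support recovery at p=12, n=400, B=200 over
10 seeds; null control at p=10, n=300; CI coverage over 200 replicates at
n=500 with outer B=100 and inner ensemble 50; replication similarity over 10
seed pairs. Ensemble fits use tol 1e-5, refits 1e-7, oracle comparisons down
to 1e-12. Nonzero detection is |Θ| > 1e-8 throughout; bootstrap resamples
are full-size with replacement; subsampling (without replacement) is used
only for case-dropping curves.

## Known limitations

- Gaussian-only: no ordinal/mixed graphical models, no nonparanormal
  rank-based transform (Box-Cox plus a skew screen stands in).
- Percentile CIs mildly undercover (~90% at nominal 95% in the planted-edge
  benchmark); BCa or basic intervals are not implemented.
- The Pearson similarity p-value treats upper-triangle entries as i.i.d.
  observations, which they are not; treat it as descriptive.
- Single-channel ERP abstraction; channel selection happens upstream.
- The stability suite re-runs the full estimator inside bootstraps, so wall
  time scales as outer B × inner B × glasso cost; the reduced inner ensemble
  trades a little vote resolution for tractability.
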