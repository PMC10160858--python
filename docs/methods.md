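# Methods

## Setting and notation

Deaths fall into one of `C` broad causes. Two data sources are available:

- an **unpaired** (survey) dataset of `n` deaths, each carrying one
  predicted cause per CCVA algorithm `k = 1..K` (possibly inconclusive);
- a **paired** (reference-standard) dataset of `m` deaths carrying a
  reference cause `b` plus the same algorithms' predictions.

The quantity of interest is the population CSMF `p`, a point on the
`C`-simplex. Algorithm `k`'s misclassification matrix `M^(k)` is
row-stochastic: `M^(k)_ij = Pr(prediction = j | true cause = i)`. The raw
CSMF of an algorithm estimates not `p` but the predicted-cause marginal
`q = M^(k)ᵀ p`.

Broad cause lists are fixed per age group: seven causes for children aged
1–59 months (pneumonia, malaria, diarrhea, severe malnutrition, hiv, other
infections, other) and five for neonates (congenital malformation,
infection, ipre, prematurity, other), in that canonical order everywhere.
Aggregation to few broad causes is what makes `M` estimable from a few
hundred paired deaths: `C²` rates must be learned. Fine causes are mapped
to broad ones by a user-extensible total map; unmapped labels are an error,
never silently dropped.

## Deterministic calibration and why it is not enough

Given an estimated `M` and an observed marginal `q`, calibration solves the
linear system `q = Mᵀ p`. With two causes this is the textbook correction
(sensitivities 95%/65% turn a 53%/47% raw split into 30%/70%). With more
causes the system is often ill-conditioned and the solution routinely exits
`[0, 1]` — on our 7-cause synthetic study both algorithms' back-solves are
infeasible (entries like −463% appear). `backsolve_csmf` therefore returns
the solution *unclipped* with a feasibility flag, and refuses matrices with
condition number above a configurable bound (default 1e8). The failure is
reported, not papered over: it is the motivation for the probability model.

## The Bayesian joint model

For each unpaired death `d`: latent true cause `z_d ~ Categorical(p)`;
observed predictions `a_dk | z_d = i ~ Categorical(M^(k) row i)`,
conditionally independent across algorithms given `z_d`. For each paired
death with observed reference cause `b`: predictions follow the same rows.
Priors: `p ~ Dirichlet(p_prior)` (default all 1) and each row `i` of each
`M^(k)` Dirichlet with concentration `M_prior_diag` (default 5) on entry
`i` and `M_prior_offdiag` (default 0.5) elsewhere.

Design notes on the priors and structure, decided here as the package's
choices:

- **Identity-shrunk `M` rows.** Reference causes with few paired deaths get
  rows pulled toward "the algorithm is right", which keeps calibration
  stable when a cause is rare in the paired data; rows with zero paired
  deaths are entirely prior-driven. A flat option (both concentrations 1)
  is available. The shrinkage strength (prior weight ≈ 5 + 0.5·(C−1)
  pseudo-records per row) is deliberately weak relative to the tens of
  records per row a real study provides.
- **Conditional independence across algorithms** given the true cause is
  the simplest joint model supporting an ensemble; it is an assumption, and
  the generator's `shared_confusion` option exists precisely to stress it.
- **Individual-record likelihood** (rather than aggregated counts) is used
  so each death contributes a pointwise term to WAIC; for exchangeable
  records the posterior is identical either way.

Inference is a Gibbs sampler with closed-form conditionals:

1. `z_d | p, M` is categorical with mass ∝ `p_i · Π_k M^(k)[i, a_dk]`.
   Deaths sharing a prediction pattern share this conditional, so the
   update is blocked over unique patterns (≤ `C^K`) and drawn with one
   vectorised multinomial; per-iteration cost is independent of `n`.
2. `p | z ~ Dirichlet(p_prior + latent-cause counts)`.
3. `M^(k)` row `i` `| · ~ Dirichlet(row prior + paired cross-tab row +
   latent unpaired cross-tab row)`.

Latent causes start at algorithm 1's observed prediction (a warm start near
the data). Chains draw from independent streams spawned from one seed;
fixed seed and config reproduce draws bit-identically on one platform.
Defaults are 4 chains × 10,000 iterations with 5,000 burn-in; the analysis
scripts use 4 × 3,000/1,000, which on these problem sizes (≤ 1,589 unpaired
deaths, ≤ 49 patterns) runs in seconds and yields split-R-hat ≤ ~1.08 on
the 7-cause ensemble. Summaries are posterior means and equal-tailed
credible intervals from pooled draws; diagnostics report classic split-chain
R-hat (degenerate chains: identical constants → 1, different constants → ∞)
and arviz effective sample sizes.

With `K = 1` the model is single-algorithm calibration; with `K > 1` the
shared `p` makes it an ensemble that automatically weights the algorithms
whose misclassification structure explains the data best — in synthetic
checks, adding a near-uniform (uninformative) algorithm to an accurate one
leaves the ensemble close to the truth, while calibrating with the noisy
algorithm alone does not.

## Model comparison by WAIC

For every posterior draw `s`, each unpaired death contributes
`log Σ_i p_i^(s) Π_k M^(k,s)[i, a_dk]` and each paired death
`log Π_k M^(k,s)[b, a_k]`. Then `lppd = Σ_d log mean_s exp(·)` (via
log-sum-exp), `p_waic = Σ_d var_s(·)` with sample variance, and
`waic = −2(lppd − p_waic)`. The **uncalibrated comparator** keeps the same
likelihood but fixes `p` at the raw point estimate (ensemble: the equally
weighted average of per-algorithm raw CSMFs) while `M` is drawn from its
conjugate posterior given only the prior and the paired cross-tab. This
reading — "the raw CSMF is incompatible with the observed misclassification
rates" — is one of two defensible choices; the alternative, modelling each
unpaired prediction by its algorithm's raw marginal directly, is provided
as `comparator="fixed_marginal"`. When the true `M` is far from identity
the calibrated model wins decisively on synthetic data; when `M` is the
identity the two arms fit equally well and the WAIC gap is within noise.

## Synthetic data: what it does and does not emulate

The generator draws unpaired deaths generatively (true cause, then
per-algorithm predictions, then inconclusive masking at a per-algorithm
rate) and paired deaths with *fixed* per-reference-cause counts — matching
the fact that calibration does not depend on the reference deaths' cause
composition, which in real studies is hospital-based and unrepresentative.

Presets encode study-scale conditions: `child_like` has 7 causes, 1,589
unpaired deaths, two algorithms, 56 paired deaths per cause (≈ 394 total,
the scale of a multi-site reference study after exclusions), true CSMF
(0.08, 0.27, 0.19, 0.04, 0.03, 0.36, 0.03) and misclassification matrices
with low-to-moderate sensitivities (0.10–0.60) and heavy leakage among the
infectious categories; `neonate_like` has 5 causes, 632 deaths, 90 per
cause, true CSMF (0.04, 0.62, 0.22, 0.08, 0.04), one algorithm
over-diagnosing prematurity (sensitivity 0.85) and the other confusing
intra-partum events with infection. `two_cause_worked_example` encodes the
textbook case at large n (20,000 unpaired; 2,000 paired per cause).

What passing tests on these data do **not** show about real studies: real
CCVA errors are correlated across algorithms (both read the same
questionnaire) — the independence assumption is only stress-tested via the
`shared_confusion` option, whose default strength is arbitrary; real
misclassification varies by site and time while the model assumes one `M`
per algorithm; inconclusive predictions are missing at random here but
plausibly informative in reality; and reference-standard causes are treated
as error-free.

## Numerical choices and degenerate inputs

- Simplex and row-stochasticity are validated to 1e-9; back-solve
  round-trips are tested to 1e-8.
- Dirichlet row draws use normalised gamma variates (exact, vectorisable).
- Zero-count reference rows in the empirical `M` become uniform rows
  flagged by `row_counts = 0` so linear algebra stays defined; the Bayesian
  module instead lets the prior own such rows.
- A cause with no evidence in either dataset triggers a warning and is
  listed in `CSMFPosterior.prior_driven_causes`.
- Cause labels match case-insensitively after whitespace trimming; missing
  predictions are an empty CSV cell or the literal `NA`.
- Reported percentages round to one decimal; all computation is full
  precision.

## Problem sizes used in the shipped checks

The test suite and analysis scripts size the MCMC to the information
actually present: 1–4 chains and 1,500–4,000 iterations recover two-cause
truths to ±0.02 and give stable interval coverage on the 7-cause study
(50-replicate pooled coverage checked against a 0.90–0.99 band fixed in
advance around the nominal 0.95, widened for within-replicate correlation
of simplex coordinates). WAIC ordering is checked over 10 replicates.

## Known limitations

Single-cause predictions only (no probabilistic multi-cause output); no
sampling weights; no site- or covariate-dependent CSMFs or
misclassification; the ensemble assumes conditional independence of
algorithms given the true cause.
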