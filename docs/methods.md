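# Methods notes

This note records the models implemented by `trialwise`, the defaults and
why they were chosen, the numerical decisions that are not visible in the
API, and what the synthetic-data tests do and do not establish.

## Preprocessing

The stage order is fixed: average reference → band-pass filter → epoching →
baseline correction → artifact flagging. Ocular correction is deliberately
out of scope (the surrogate-source method commonly used for it is
proprietary); the hook in the pipeline is the place to insert your own.

**Average reference.** With n recorded channels referenced against a
reference electrode, the reference's own time course is recovered as a data
channel: every channel value becomes `x − mean`, the recovered reference
`0 − mean`, with the mean taken over all n+1 scalp channels. The per-sample
mean of the output is therefore exactly zero (asserted to 1e-9 µV). EOG
channels are excluded from the average and passed through.

**Filter.** The band edges (0.5 and 40 Hz) are the scientific parameters;
the realization is a 4th-order Butterworth high-pass and low-pass cascade
applied forward–backward (`sosfiltfilt`), i.e. zero-phase, which preserves
component latencies (a symmetric pulse stays symmetric within one sample).
The 0.5 Hz high-pass has an edge transient of roughly two seconds; tests
that measure passband gain therefore use RMS amplitude over the central 80%
of a 10 s probe.

**Epoching.** Windows are half-open `[start, end)`: at 500 Hz the default
(−200, 800) ms window yields exactly 500 samples, with t = 0 the first
post-stimulus sample and the baseline [−200, 0) excluding it. Events whose
window would cross a recording edge are dropped with a logged warning and
their indices recorded — padding would fabricate data. Per trial this
leaves 400 post-stimulus samples; over a 65-channel montage, 26,000
analyzable values.

**Artifact flags.** A trial is invalid iff any checked channel exceeds
±150 µV at any sample or steps by more than 50 µV between consecutive
samples (2 ms at 500 Hz); the gradient step size is a convention choice and
configurable. Thresholds are applied to re-referenced, filtered,
baseline-corrected data. Flags never delete data: the trial store keeps
every trial in recording order, and only ERP extraction masks invalid ones.

## The trial store

The matching key between EEG and behavior is (participant, ordinal position
in recording), never trial content — content-based joins would hide
misalignment, which is precisely the failure mode order preservation is
meant to expose. A count mismatch between a participant's epochs and
behavioral rows is a hard error naming the participant.

Deviant position is stored with all four levels; the left/right dichotomy
used by the analyses is produced by the analysis filters (stage
`"accuracy"`: drop center-top/bottom deviants and misses; stage `"rt_erp"`:
additionally drop error trials and EEG-invalid trials), not at ingestion.

## Cluster-based permutation test

Implemented for the paired (within-subject) two-condition design.
Choices the procedure's description leaves open, and what this package does:

- **Adjacency.** Channels are neighbors iff their Euclidean distance is
  positive and ≤ a threshold; temporal adjacency is ±1 sample. There is no
  minimum-neighbor count. The packaged montage is an idealized
  azimuthal-equidistant 10-10 scheme computed in code (a synthetic stand-in,
  adequate for adjacency and ROIs, not a digitized head model).
- **Zero-variance points** (only arising in degenerate synthetic data) are
  treated as suprathreshold with the sign of the mean difference.
- **Two-sided testing** clusters positive and negative t-values separately
  and refers both to one shared max-|mass| permutation distribution.
- **p-values** include the observed statistic: p = (1 + b) / (m + 1) with b
  the count of null values ≥ the observed |mass|. This keeps the
  Monte-Carlo test valid at any permutation count; p can never be 0.
- **Exhaustive mode** enumerates all 2ⁿ sign patterns whenever that is
  cheaper than the requested Monte-Carlo count (or on request), and the
  Monte-Carlo path reproduces the exhaustive multiset in that regime
  (tested).
- Permutation t-maps are computed for blocks of sign patterns with a single
  matrix product (the per-point second moment is invariant under sign
  flips), which is what makes 200-experiment calibration studies cheap.

Calibration: on 200 simulated null experiments (12 participants, 16
channels, 50 samples, spatially smoothed pink noise, 500 permutations) the
family-wise rate of any significant cluster is ~0.03–0.06, below the 0.081
acceptance bound (α plus two binomial standard errors). Power: a 2 µV
effect over an 8-channel patch and a third of the epoch (n = 20, noise SD
1 µV) is detected with ≥ 50% member overlap in ≥ 95% of runs.

## Mixed models

The solver backend is statsmodels. Gaussian models use `MixedLM`; crossed
participant × item random effects are realized through the
variance-component formulation (indicator-expanded random-effect design,
one variance per (grouping, term), single statistical group). Random-effect
covariances are therefore diagonal — no intercept–slope correlations — the
`||` convention of mixed-model practice; random-effect correlation analysis
is out of scope. Binomial models use `BinomialBayesMixedGLM` (variational
Bayes); see limitations below.

- **Optimizer.** Powell search (with Nelder–Mead and L-BFGS fallbacks).
  Gradient-based optimizers reproducibly stall in flat regions of the
  profiled REML surface when a variance component is near zero; Powell
  reproduces an independent mixed-model implementation's estimates, standard
  errors and log-likelihood to ~3 decimals on crossed test problems (this
  cross-check is part of the test suite, via Rscript/lme4).
- **Contrasts.** Sliding-difference coding: effect j is level j+1 minus
  level j; columns sum to zero, so the intercept estimates the unweighted
  grand mean of cell means. For two levels the codes are ∓½.
- **p-values.** The backend provides no Satterthwaite degrees of freedom;
  Wald statistics use the normal approximation, and every fit logs that
  flag. At the trial counts this package targets (hundreds to thousands per
  fit) the difference is negligible; small-sample users should interpret
  p-values near threshold with care.
- **REML vs ML.** Variance components and the reported REML deviance come
  from REML fits; likelihood-ratio comparisons of fixed effects refit both
  models by ML, and the final model of a reduction is re-reported under
  REML.
- **Singularity.** A random term is "explaining zero variance" when its
  variance falls below 1e-6 × the residual variance (SD ratio 1e-3). The
  threshold is on the variance scale because the optimizer parks boundary
  solutions at tiny positive values rather than exactly zero. Pruning
  removes one singular term per refit (smallest SD first), slopes before
  their grouping's intercept, and is fully deterministic. Note the
  statistical fact (verified against lme4 on identical data): the REML
  estimate of a truly-zero variance lands on the boundary in only about
  half of datasets, so pruning of a null term is expected in ~50% of
  replications, while truly nonzero components are essentially never
  pruned at adequate sample sizes.
- **Stepwise reduction.** Removable terms are those not contained in a
  retained higher-order interaction. At each step the least significant
  removable term (largest Wald p; ties favor higher-order terms) is
  dropped; the smaller model is kept if the LRT against the larger one is
  non-significant, and ΔAIC/ΔBIC are reported per step. For binomial fits
  the decision uses the Wald test because the variational backend provides
  no marginal likelihood; the LRT fields are NaN there.
- **Nested follow-ups** refit the model identically except that the inner
  factor's main effect and its interaction with the outer factor are
  replaced by per-outer-level inner contrasts, yielding the inner effect at
  each outer level. On balanced data the mean of the nested estimates
  equals the main effect (tested).
- **Partial effects** subtract the fitted contributions of de-selected
  fixed terms and, optionally, the BLUP-weighted random terms from the
  observed response; keeping everything returns the data, removing
  everything returns the residuals. BLUPs are computed as
  u = G Zᵀ V⁻¹(y − Xβ) via the Woodbury identity, with zero-variance
  components contributing u = 0.
- **Amplitude rescaling** divides a µV column by 10 so that slopes read
  "per 10 µV", which also conditions the optimization better.

## Synthetic ground truth

The generator emulates the target study design: 40 participants × 1920
trials in 5 blocks (defaults), a 2 (perceptual certainty) × 4 (deviant
position) crossing balanced within participant, item identifiers crossed
with participants, an N2 (negative, fronto-central, 250–350 ms) and a P3b
(positive, centro-parietal, 400–550 ms) component. Amplitude models carry
fixed condition effects plus by-participant and by-item intercepts and
slopes; defaults are magnitudes typical of visual-search ERP data (N2
intercept −3.42 µV, certainty effect −0.87 µV; P3b 4.20 / 1.17 µV; RT
intercept 470 ms, certainty effect −30 ms, subject intercept/slope SDs
50/15 ms, residual 90 ms).

Design choices:

- **Epoch-level generation** (component template × spatial weight map +
  noise per epoch) is the default for speed; a continuous mode embeds the
  same epochs in an ongoing noise stream with stimulus markers and writes
  genuine BrainVision triplets, exercising the full I/O + preprocessing
  path.
- **Temporal kernel** is a raised cosine over the component window, scaled
  so the window *mean* is 1 — the nominal amplitude is then exactly the
  ROI-window mean of a noise-free trial.
- **Noise** is a 70/30 mix of 1/f (pink) and white noise, spatially
  smoothed across channels with a Gaussian kernel on the sensor positions.
  Spatio-temporal correlation is essential: it is the structure the cluster
  test exploits, and calibration under white noise would be too easy.
- **Behavior**: RT is gaussian around a linear predictor (optionally
  including per-trial component amplitudes), truncated at the 2 s timeout —
  truncated trials become misses; accuracy is Bernoulli with a logistic
  link.
- **Artifacts** are injected as 200 µV square pulses at a configurable
  trial rate, so flag counts can be checked against binomial bounds.

What the synthetic tests do *not* establish: the generator contains no
ocular or muscle artifacts with realistic morphology, no component-latency
jitter, no drifts or electrode pops, and its items are four exchangeable
identifiers, not real stimuli. Passing recovery tests demonstrates that the
pipeline's statistics are correct under their assumptions, not that those
assumptions hold for any particular recording.

## Problem sizes

Unit and calibration tests run at reduced scale — typically 6–20
participants, 16–32 channels, 32–256 trials, 100 or 250 Hz — chosen so the
full suite completes in about a minute while keeping every statistical
check at the sample sizes its property needs (e.g. 200 experiments for
FWER calibration, 50 seeds for reduction specificity). The generator's
defaults remain the full study design (40 × 1920 at 500 Hz), which is what
`trialwise simulate` produces when no overrides are given.

## Known limitations

- The binomial GLMM backend reports posterior-based z statistics but no
  marginal log-likelihood, AIC/BIC, or LRT; variational posteriors can
  also shrink between-subject intercept estimates somewhat. Within-subject
  effect recovery is tested; if calibrated binomial likelihoods matter,
  export the long table and fit with a dedicated GLMM package.
- The CBPT operates on participant × condition averages (as is standard);
  it does not weight participants by trial counts and is conservative for
  small, focal effects.
- BrainVision support covers the dominant dialect only: multiplexed
  INT_16 / IEEE_FLOAT_32. Vectorized orientation is rejected with a clear
  error.
- One analysis-stage assumption: epochs of all participants share one
  channel set and time axis; heterogeneous montages must be harmonized
  upstream.
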