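# Methods

`tdconnect` implements, end to end and on synthetic data, the analysis
chain that links dorsolateral-prefrontal → ventromedial-prefrontal
effective connectivity to individual differences in temporal
discounting: behavioral discount-rate estimation, value-modulated
first-level GLMs, a two-region dynamic causal model (DCM) with
family-level Bayesian model selection, and out-of-sample elastic-net
prediction of discount rates from connectivity parameters.

## Choice model and behavioral fitting

Each trial offers $A in D days against a constant immediate reference
(default $25). Subjective value is hyperbolic, `dSV = A / (1 + kD)`
with discount rate `k` per day, and acceptance follows the softmax
psychometric `P(accept) = 1 / (1 + exp(b (25 − dSV)))` with slope
`b ≥ 0`. The offer design is the fixed 18-delay × 6-amount grid
($25–54, 7–200 days); a session presents each of the 108 pairs twice
(216 trials) in seeded random order across two runs, with a 3 s
response window, 250 ms feedback, and uniform 2–6 s inter-trial
fixation.

Fitting maximizes the Bernoulli likelihood over responded trials in
`(log k, log b)` with bounded L-BFGS-B from a 3×3 grid of starts.
Search bounds are `k ∈ [1e−6, 1]` per day — outside this range the
7–200-day grid is uninformative — and `b ∈ [1e−3, 100]`. Missed trials
(~2% in the generator) are excluded from the likelihood and from GLM
modulators. One-sided data or a fitted slope with `b·sd(dSV) < 0.05`
(a flat psychometric, under which `k` is unidentified) sets the
boundary/degenerate flags instead of raising. A subject is "wait
group" (WG) iff strictly more than 50% of responded trials were
accepts; a tie goes to the "now group" (NG). The relative value
recoding is `rdSV = dSV − 25` for WG and `25 − dSV` for NG.

## Synthetic cohort

The generator emulates the study design: 27 subjects × 2 runs × 323
volumes at TR 2.5 s. Defaults, chosen once as realistic for this task
and documented here:

- `log k ~ N(−4.5, 1.0)` (per-day units), spanning mostly-wait to
  mostly-now behavior on this grid with both groups represented
  (realized splits lean toward the now group, e.g. 7/20 at seed 0);
  `log b ~ N(log 0.5, 0.3)`.
- Reaction times: truncated lognormal (≤ 3 s, log-sd 0.25) with the
  group-by-choice interaction in sign only — choices congruent with
  the subject's overall tendency average 1.13 s, incongruent 1.28 s.
- BOLD noise: AR(1) with ρ = 0.2 and marginal sd 1.0 in percent-signal
  units, a realistic level for ROI-averaged series (simulated signal
  sd is ~2–3%).
- Ground-truth coupling (`BASE_DCM_PARAMS`, Hz): choice-period d→v
  modulation 0.3 with a further later-choice modulation 0.2, value
  drive to vmPFC 0.3, accept drive to dlPFC 0.5, small positive fixed
  d→v (0.05), zero v→d paths, plus N(0, 0.05) inter-subject jitter on
  couplings.
- The planted prediction effect sets the later-choice d→v modulation
  to a linear function of standardized `−log k` with slope
  `effect_size` (default 0.15 Hz/SD) plus N(0, 0.05) noise; effect 0
  gives a null cohort. Planted-effect validation cohorts use 0.4
  Hz/SD, chosen so the planted between-subject spread dominates the
  ~0.2 Hz single-run posterior uncertainty of that parameter.

Ground truth (true `k`, `b`, group, coupling vector) is stored beside
the generated data and never read by any estimation path; estimation
rebuilds inputs from *fitted* discount rates and groups.

What the generator does not emulate: voxel-level structure, motion,
physiological noise, scanner drifts beyond AR(1)+white noise, RT
magnitude calibration. Passing tests therefore certify the estimation
machinery against its own generative class, not performance on real
fMRI.

## First-level GLM

Per run, three task regressors are built on a 0.1 s microtime grid and
downsampled to the TR grid after convolution with a canonical
double-gamma HRF (gamma shapes 6 and 16, undershoot ratio 1/6, unit
peak, 32 s support; no derivatives): the decision-screen indicator
(duration = RT), the indicator by the value modulator (dSV or rdSV),
and the indicator by Accept. Modulators are mean-centered per run
before convolution; the convolved Accept column is orthogonalized
against the condition and value columns, assigning shared variance to
value. Nuisance terms: per-run intercept, linear trend, and a discrete
cosine high-pass basis with 128 s cutoff. Head-motion columns are
accepted but absent in synthetic data. Orthogonalization before versus
after convolution is a convention choice; the sign/|t| invariance is
unit-tested either way.

Fitting is feasible GLS with an AR(1) error model (rho from OLS
residuals, then prewhitened refits — statsmodels GLSAR). Log model
evidence is approximated by `llf − k/2 · ln n` (−BIC/2); the
full-versus-reduced value-model comparison feeds the per-subject
evidence pairs to random-effects BMS. The approximation preserves the
two invariances that matter here: modulator sign flips and positive
rescalings leave |t| and evidence unchanged. Subjects whose Accept
modulator is constant (one-sided choosers) contribute no Accept
contrast; their design drops that column.

## Two-region DCM

Neural dynamics are bilinear, `dz/dt = (A + Σⱼ uⱼ Bⱼ) z + C u`, over
regions d (dlPFC-BA46) and v (vmPFC). Condition streams: fixation,
all-choice periods, later-choice (accepted) periods; driving streams:
the rdSV-scaled event stream (standardized per run) and the Accept
event stream. Couplings and modulations are in Hz. Self-connections
are `−0.5·exp(θ)` (always stable); modulatory diagonals are additive.
Observation is a balloon–windkessel model per region (κ=0.64, γ=0.32,
τ=2.0, α=0.32, E₀=0.4, V₀=4.0 — fixed at literature values rather than
estimated, keeping the two-region inversion well conditioned) with RK4
integration on the microtime grid; the generator integrates at 0.1 s,
the fast inversion mode at 0.25 s (RK4 self-convergence < 1e−4 RMS).

Inversion is variational-Laplace: zero-mean Gaussian priors (variance
1/16 on couplings/modulations, 1 on input gains), iterated
Gauss–Newton on the penalized least-squares objective with a
finite-difference Jacobian and Levenberg-style damping, an EM update
of the observation noise, and free energy
`F = accuracy − complexity = −N/2·ln(2πσ²) − ‖r‖²/2σ² − ½eᵀP₀e +
½ln|Σ_post·P₀|`. Data and prediction are mean-centered per region, so
baselines are not modeled. Non-convergence after the iteration cap is
flagged, not silent.

The model space crosses four driving-input families (value/accept into
v&d, both→v, both→d, swapped) with 16 modulation patterns: the four
cross-connection switches (d→v, v→d during all-choices and
later-choices) toggled freely, with fixed coupling, self-modulations
and drives in every model. This composition matches the full model's
12-parameter table exactly (fixation-period coupling is carried by the
fixed matrix; there are no fixation-modulation parameters). The
enumeration policy is a pluggable function, so alternative readings of
the 16-model composition can be swapped in.

Random-effects BMS uses the hierarchical Dirichlet model (variational
updates over subject-level model assignments); exceedance
probabilities come from 10⁶ seeded Dirichlet draws (Monte-Carlo error
~1e−3). Family comparison splits the Dirichlet prior mass evenly
within families and aggregates draws by family. Bayesian parameter
averaging multiplies subject posteriors and removes the (n−1)-fold
repeated prior; it is exact for the Gaussian case and reduces to the
single posterior at n=1. Group coupling tests report BPA posterior
probabilities next to classical one-sample t-tests.

## Prediction

Features are the 12 full-model parameters per run (24 columns at two
runs; hemodynamics are fixed, hence excluded), target `log k` from the
behavioral fit. For each held-out subject, predictors are z-scored on
the N−1 training subjects, the elastic net (mixing α = 0.3; objective
`1/(2n)‖y−b₀−Xβ‖² + λ(α‖β‖₁ + (1−α)/2‖β‖²)`) is fit with λ chosen by
an inner seeded 5-fold cross-validation over a 20-point log-spaced
path (configurable to a fixed λ), and the subject is classified
against the training-set mean of log k — all without the held-out row.
Balanced accuracy is `(sensitivity + specificity)/2` with a
Beta-posterior Monte-Carlo 95% interval; rank agreement is Spearman's
rho over held-out predictions. The classification threshold uses the
log scale (the target variable's scale); mean-of-k thresholding is a
one-line change.

Ablations drop named column groups (vmPFC-local, dlPFC-local, d→v,
v→d — the "local" groups are the region's drive gain plus its
self-modulations, following the parameter table's grouping) from the
regression only; parameters are never re-estimated. The region-swap
harness replaces the dlPFC series (both runs) with a supplied series
and re-inverts before predicting.

## Validation design and two findings

`validation.py` holds the planted-truth experiments: offer-session
statistics, 50-subject discount-rate recovery, GLM sign-flip
invariance and a 2000-simulation type-I-error calibration, 50-run
posterior coverage of a 0.3 Hz planted modulation, family selection on
a 27-subject cohort, and the prediction sweep (50 planted cohorts, 20
null cohorts, ablations on 15, region swap on 6). The reproduction
script trims the sweep (25/12/5) to stay inside a desk-scale runtime;
all scales are stated in the function signatures.

Two structural findings from these experiments are worth knowing:

1. **Null cohorts are not perfectly at chance.** Even with zero planted
   effect, posterior shrinkage of behavior-conditioned parameters
   (accept drive, later-choice modulation) scales with each subject's
   accept count, which tracks log k — so the feature table carries a
   weak behavioral trace (null MBA centers near 0.53 rather than
   0.50). This is inherent to any design whose regressors and DCM
   input streams are defined by behavior, not a code artifact.
2. **A planted d→v modulation cannot be erased by swapping region d.**
   The modulation's expression *is* a vmPFC response, so its trace
   survives in the retained v series and swap accuracy stays well
   above chance on such cohorts. The swap harness therefore uses
   cohorts whose predictive signal is dlPFC's local accept-response
   gain with all d→v couplings zeroed (`swap_harness_config`) — there
   the intact prediction is strong and the noise-swap collapses to the
   shrinkage-leak floor.

## Known limitations

- The evidence for GLM comparison is a BIC approximation, not a full
  variational treatment; it is used only through differences and
  rankings.
- Hemodynamic parameters are fixed, not estimated; systematic
  hemodynamic variability across subjects would be absorbed into
  coupling estimates.
- The inversion's noise model is white after mean-centering, while the
  generator adds AR(1) noise; posterior coverage is nevertheless
  calibrated at the simulated noise level (checked, not assumed).
- Runtime-oriented scales (iteration caps, 0.25 s inversion step,
  sweep sizes) are package defaults; all are arguments.
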