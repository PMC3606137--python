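# Methods

This note records the scientific assumptions, parameter choices and
numerical conventions behind the package, including the places where a
design decision was genuinely open and what was chosen.

## Synthetic MT population

The decision models consume population-averaged MT firing rates. The
package generates these from a parametric stand-in population rather than
recordings, with the minimal structure the models rely on:

* **Rate model.** Each neuron fires at
  `max(0, baseline + 1[latency ≤ τ < offset+latency] · (g_dir c_dir + g_dep c_dep) · (1 + A e^{−(τ−latency)/τ_t}))`
  in spikes/s (converted to spikes/ms internally). Strengths `c_dir`,
  `c_dep` ∈ [−1, 1] are expressed in the neuron's preferred frame (positive
  = preferred direction/depth). The evoked term switches on at the response
  latency (~100 ms) and off one latency after stimulus offset; the optional
  multiplicative transient models the onset burst. Rates are clipped at
  zero, which makes them monotone non-decreasing in each strength.
* **Parameter distributions** (`TuningConfig` defaults): baseline
  Gamma(shape 4, mean 20 sp/s); gains lognormal with mean 40 ± SD 20 sp/s
  (direction) and 20 ± 15 sp/s (depth); latency Normal(100, 8) ms clipped
  to [60, 160]; transient amplitude U(0, 0.5), decay U(30, 80) ms. The
  lognormal choice matters twice: tuning strengths in cortex are broad and
  right-skewed, and the balanced-readout analysis (below) needs a
  subpopulation whose depth sensitivity matches its direction sensitivity,
  which requires heavy overlap of the two gain distributions even though
  direction tuning is stronger on average. `TuningConfig.balanced()` (both
  gains 30 ± 3) is available for control experiments.
* **Preference quadrants** are assigned round-robin so all four types exist
  from n = 4 upward.
* **Spiking** is Bernoulli per 1-ms bin with probability min(rate·Δτ, 1) —
  the 1-ms discretization of a Poisson process, with at most one spike per
  bin. No noise correlation between neurons and no temporal correlation
  within trains; both are known to matter for choice-probability magnitude,
  so absolute CP levels here should not be read as predictions for cortex.
* **Rate estimation.** Spike trains are smoothed with a Gaussian kernel,
  SD 20 ms, truncated at ±60 ms and *not* renormalized (the truncation
  discards 0.27% of the mass), evaluated on the 1-ms grid. The population
  table is the mean over neurons of each neuron's mean smoothed rate per
  preferred-frame condition, built separately per task. The reduction
  "per-trial KDE → per-neuron condition mean → population mean" is a
  reconstruction of the usual averaging procedure; because the kernel is
  linear, the per-neuron mean is computed by smoothing the per-bin mean
  spike indicator, which the fast path samples directly as
  Binomial(n_trials, p)/n_trials.
* **Default stimulus grid**: signed strengths
  {0, ±0.0625, ±0.125, ±0.25, ±0.5} for both features; the default
  "recording" uses 10 trials per condition per task and N = 117 neurons.
  Because the grid is symmetric and rates are defined in the preferred
  frame, the recording is simulated directly on the preferred-frame grid;
  lab-frame re-signing happens only in the readout bank.

## Readout bank and differential signals

Eight simulated neurons, two per quadrant, with fixed task routing:
congruent neurons (1, 2, 7, 8) feed both readouts at half weight; 4 and 6
feed direction only; 3 and 5 feed depth only. For a lab-frame stimulus
(C_dir, C_dep), neuron rates are looked up at sign-flipped strengths so
positive always means preferred (no interpolation off the grid — exact
levels are required). The differential-signal formulas in the README are
the unique assignment consistent with the bank's routing table and the
halved congruent weights; they are antisymmetric under swapping opposing
neuron groups, and both signals are bounded in [−2, 2] spikes/ms.

## Integration and decision

Evidence is integrated in 1-ms steps over [τ0, τ1) = [100, 600) ms with
per-step decay factor `exp(−k Δτ)` — the exact discrete solution, not a
forward-Euler approximation. The convention is add-then-decay: evidence
arriving in bin τ enters the decision variable with weight
`exp(−k(τ1 − τ)) · w(τ)`. This convention is what makes the double-leaky
and time-varying-gate models (shared k) bitwise identical in their
effective evidence weights, hence identical in every choice, which the
package asserts as an exact invariant rather than a statistical one. A
time constant of T ms corresponds to k = 1/T per ms. At I = 0 exactly
(measure-zero in practice) the choice is a fair coin from the trial's
seeded stream.

The batch engine evaluates the closed-form weights as a dot product per
trial; `integrate_trial` is the loop-form reference implementation, and the
two are tested to agree to 1e-9.

## Late task commitment

When the task is identified only at time t_c inside the trial, both
accumulators run either *open* (both features integrated at weight 1, no
leak) or *closed* (nothing integrated) until t_c, after which the variant's
own regime applies. Two reconstructed details, flagged as such:

* Under the double-leaky model, irrelevant evidence stored before t_c
  decays by `exp(−k(τ1 − t_c))` — leak applies from commitment onward.
* The time-varying gate re-anchors its schedule to the commitment time,
  `w(τ) = exp(k(τ − (t_c + (τ1 − τ0))))`. A schedule fixed to τ1 would
  leave late-committing trials with a nearly open gate throughout,
  contradicting the defining behavior of this model (weight small shortly
  after integration starts, switch ratio growing with commitment delay);
  re-anchoring restores it.

t_c below τ0 is clamped to τ0 (pre-committed); at t_c = τ1 with open
accumulators every variant degenerates to the plain unweighted integrator
(SR ≈ 0). Both regimes are available for all variants. The default sweep
grid is t_c ∈ {0, 50, …, 600} ms.

## Behavioral analyses

* **Logistic fits** (per task): binomial GLM (IRLS, via statsmodels) of
  p_up on [1, C_dir, C_dep, C_dir·C_dep]; the two tasks jointly form the
  eight-parameter model. Log-likelihoods are recomputed in Bernoulli form
  so that the eight- and nine-parameter models are compared on the same
  scale. Perfect separation is flagged on the result, never silently
  clipped.
* **Wrong-task mixture** (nine parameters): one shared p_err ∈ [0, 1]; with
  probability p_err the choice follows the *other* task's logistic at the
  same stimulus. Fitted by bounded L-BFGS-B with five starts, always
  including the eight-parameter solution at p_err = 0, which guarantees
  lnL(9) ≥ lnL(8). The shared-p_err structure is a reconstruction pinned
  down by the parameter count. AIC = 2·9 − 2 lnL.
* **Switch ratio**: mean over the two features of the normalized
  relevant-vs-irrelevant sensitivity difference — the unique simple form
  with the printed endpoints (1 for perfect switching when the irrelevant
  sensitivities vanish; 0 when the tasks are indistinguishable). A
  delta-method SE from the two fit covariances accompanies it.
* **75% thresholds**: accuracy (zero-relevant-strength trials excluded,
  correctness undefined there) pooled over irrelevant levels per absolute
  relevant level, ML cumulative-Weibull fit p = 1 − 0.5 exp(−(c/α)^β),
  threshold α(ln 2)^{1/β}. Accuracy never reaching 75% is reported as an
  above-max flag; a fitted threshold below the smallest tested level is
  returned with a below-min flag. The 75% criterion is used for both
  behavioral and neurometric curves for internal consistency.
* **Neurometrics and balanced selection**: per neuron and feature, ROC
  area between the preferred- and null-sign count distributions at each
  level, Weibull-fitted, threshold at 75%; degenerate (flat) response
  profiles are excluded with a log entry. `select_balanced` sorts neurons
  by their direction/depth threshold ratio and picks the contiguous run of
  k (default 40) whose *average* direction and depth thresholds are closest
  to equal (ratio of window means, log scale) — the goal of the procedure
  is equal sensitivity on average, and optimizing the mean of ratios does
  not reliably deliver that. The selected subset can be fed back through
  `build_rate_table` to produce a sensitivity-matched rate table.

## Choice probability

Counts in eight 100-ms bins (starts −100 … 600 ms) are z-scored within each
(neuron, task, condition, bin) cell with the n−1 SD convention; cells with
fewer than two trials or zero variance are dropped with a log note.
Conditions whose up-choice fraction is strictly below 1/4 or above 3/4 are
excluded before pooling (boundary values retained). Standardized counts are
pooled across neurons and conditions — congruent neurons per task,
incongruent neurons per relevant/irrelevant relation, with each neuron's
preferred choice derived from its preference in the current task — then
split by choice, and CP is the ROC area computed by the Mann–Whitney rank
identity (midranks, i.e. half-weight ties). Confidence intervals are
2.5/97.5 percentile bootstrap over independent resampling with replacement
from the two pooled distributions (default 10 000 replicates; resampling
after pooling is one of two defensible readings of the procedure and is the
one implemented).

## Calibration

The gated weight is grid-searched 0 … 1 in steps of 0.02, the gate time
constant line-searched 10 … 500 ms, each to match a behavioral switch-ratio
target (0.70). All candidates are evaluated on one shared set of spike
trains (common random numbers): the gated decision variable is affine in w
and the gate's is a matrix product with per-candidate weight columns, so
the whole curve costs one simulation and the curve's shape carries no
simulation jitter. The selected value is then re-simulated with fresh seeds
for an unbiased SR estimate. Targets outside the achievable SR range raise
with that range attached. The calibrated values depend on the synthetic
population (with the defaults they land near w ≈ 0.16 and T ≈ 90–110 ms);
they are reported, never asserted against any fixed number.

## Problem sizes and reproducibility

Default simulations use 1000 trials per condition; the packaged analyses
and tests use 150–600 trials per condition and 5–7 grid levels per feature,
sizes at which the assertions' Monte-Carlo error (reported as 3·SE bands)
is a few percent. Every stochastic stage takes an explicit seed; batch runs
spawn per-cell child streams from a master `SeedSequence`, so results are
bit-reproducible for a fixed seed and independent of cell order. The CLI
writes a manifest (config hash, seed, package version) next to every
output.

## What passing tests do and do not show

The synthetic population reproduces the *structural* features the models
need (latency, joint tuning, direction > depth sensitivity on average,
Poisson variability, congruent/incongruent split) but none of the
data-dependent quantities of any particular recorded dataset: calibrated
parameters, absolute thresholds, CP magnitudes and fitted AICs here
characterize the synthetic conditions only. Known limitations: no noise or
temporal correlations; no reaction-time (free-response) decisions or
collapsing bounds; the rate model is piecewise-stationary rather than fit
to recordings; and the late-commitment regimes are reconstructions of
prose-level descriptions, as flagged above.
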