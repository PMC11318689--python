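# Methods

This note documents the models and procedures implemented in `phocoena`,
the defaults and why they were chosen, what the synthetic data generator
does and does not emulate, and the numerical decisions that matter for
reproducing results.

## Sensor preparation

Input series are depth (m, positive down) and triaxial acceleration
(m s⁻², tag frame: x forward, y left, z up) at a common rate. Processing:

- **First-hour removal** (default 3600 s): tagging and handling perturb
  behavior; all samples and events before the cut are dropped and times
  are *not* re-zeroed, so event tables remain aligned with the raw
  record.
- **Decimation** to 25 Hz via polyphase resampling
  (`scipy.signal.resample_poly`, line-padded). Rational rate ratios are
  supported; equal rates are the identity.
- **MSA** = | ‖a‖₂ − g | with g = 9.81 m s⁻². It is rotation-invariant,
  hence insensitive to tag placement, and bounds the specific
  acceleration magnitude from below. Values above the 95th percentile are
  **winsorized** (capped, not deleted) so the MSA series stays
  time-aligned with depth. The percentile uses linear interpolation
  between order statistics and is computed once per deployment: transient
  spikes are a record-level artifact. Note winsorizing is idempotent only
  up to this interpolation convention — re-capping can lower the cap by a
  fraction of one order-statistic gap, which is negligible in practice.
- **Pitch/roll** from the low-passed (5 s moving average) acceleration:
  pitch = −asin(aₓ/‖a‖), roll = atan2(a_y, a_z). Five seconds comfortably
  separates orientation from porpoise stroking (~1–2 Hz). Only *circular
  variances* of these angles enter the state model, which makes the
  results insensitive to the sign convention up to reflection.
- **Circular variance** is 1 − R̄ (mean resultant length), in [0, 1].

## Event detection

**Respirations.** Maximal segments with depth < 0.5 m are surfacings;
the breath is placed at the minimum-depth sample (earliest on ties), and
candidates closer than 0.4 s to the previous breath are dropped. Both
constants are standard audit-derived values for this tag placement.

**Clicks.** The canonical pipeline input is a pre-detected click-time
list (porpoise clicks at 100–240 kHz cannot be stored at scale in most
workflows). When an envelope is supplied, the detector picks local maxima
above max(noise + margin, −60 dB re clip), with a 1 ms blanking window to
dismiss surface reflections. The running noise estimate is a median over
0.5 s — robust to the clicks themselves; the margin (default +15 dB) and
window are configurable because the exact dynamic-threshold statistic in
field systems varies. A 4-pole Butterworth band-pass plus Hilbert
envelope helper covers the raw-audio path.

**Buzzes.** Clicks partition into maximal runs with all internal ICIs
< 10 ms; runs need ≥ 5 clicks to be candidates, and are retained with
duration ≥ 0.2 s *and* > 100 clicks; retained runs separated by < 1 s
merge into one buzz (prolonged chases would otherwise double-count).
Thresholds are applied *before* merging; the alternative order is not
distinguishable from published descriptions, so this choice is stated
rather than inferred. Merged buzzes count as one everywhere downstream.

## Dives versus apneas

IBIs (respiration-to-respiration, half-open [start, end)) tile the
record. A full-covariance Gaussian mixture on log duration, log maximum
depth, and log mean MSA — all three logged, the standard treatment for
right-skewed positive dive metrics — is fitted for 2–5 components with 10
initializations each and selected by BIC. The component whose mean is
maximal in all three features is the dive class (dominance rule); if no
component dominates, the deepest-mean component is used, depth being the
least noisy separator. Zeros are offset to half the smallest positive
value before logging; zero-variance features are rejected.

With strongly state-structured records the mixture may split the dive
cloud and the dominance rule then retains only the dominating subgroup —
a conservative failure mode. Real (and realistically simulated) records
have enough between-dive activity variability that the dive cloud
coheres.

## Dive metrics

Eight per-dive quantities feed the state model (missing values are
simply omitted from the likelihood — missing-at-random marginalization;
buzz presence itself is carried by the Bernoulli term):

| metric | emission | notes |
| --- | --- | --- |
| log mean MSA | Gaussian | winsorized MSA averaged over the dive |
| relative buzz depth | beta | median over buzzes of depth/max-depth; missing if no buzz |
| circ. var. pitch, roll | beta | over dive samples |
| prop. bottom | beta | depth within one body length of max depth |
| prop. surface | beta | depth within two body lengths of the surface |
| circ. var. pitch at bottom | beta | over bottom-band samples; missing if none |
| buzz present | Bernoulli | ≥ 1 buzz midpoint in the dive |

Proportions are squeezed onto the open unit interval by
x ↦ (x(n−1) + ½)/n with n the pooled non-missing count per metric, the
standard compression for boundary-observed beta responses. Buzzes belong
to the dive containing their midpoint. Dive cycles run from each dive
start to the next dive start; respiration rate uses cycle duration, buzz
rate uses dive duration (both min⁻¹) — the denominators used in field
reports.

## The mixed hidden Markov model

K behavioral states share emission parameters across C "behavioral
contexts"; contexts differ only in their K×K transition matrix Γ_c, and
each animal's sequence follows one latent context with prior weight π_c.
The per-animal likelihood is the context mixture of standard HMM
likelihoods (scaled forward recursion); initial distributions δ_c are
tied to the stationary distribution of Γ_c, appropriate for records much
longer than the mixing time.

**Fitting.** Direct maximization of the exact marginal log-likelihood on
an unconstrained working scale: means free; log standard deviations and
log beta shapes; logit Bernoulli probabilities; row-wise multinomial
logits for Γ_c; softmax context weights. Gradients are analytic:
forward–backward posteriors give ∂ℓ/∂log b and expected transition
counts; the stationary initial distribution is differentiated implicitly
via δ' = 1'(I − Γ + 11')⁻¹, so dδ = δ'(dΓ)(I − Γ + 11')⁻¹; the context
mixture weights each animal's contributions by its context posterior.
The gradient is verified against finite differences in the test suite.
L-BFGS-B runs with relative tolerance 1e-10, gradient tolerance 1e-6, up
to 500 iterations, from 50 (default) random restarts; restarts draw
quantile-split emission initials with seeded perturbations and
diagonal-dominant Dirichlet TPMs. Model choice over (K, C) is by AIC
with exact ties broken toward smaller K, then C.

**Numerical guards.** Each metric's log density is floored at −700 nats
(with matching zero gradient) so boundary observations cannot produce
infinities. Working parameters carry box bounds (log shapes in [−10, 12],
log sd in [−10, 10], logits ±30). The bounds matter: when a metric is
nearly constant within a state the beta/Gaussian likelihood is unbounded
(the mixture variance-collapse phenomenon), and the bounds convert that
into a well-defined boundary optimum. Per-row emission likelihoods are
max-shifted before exponentiation; forward scaling handles the rest.

**Decoding and naming.** The context posterior is π_c L_c normalized;
decoding is Viterbi under each animal's maximum-posterior context (local
smoothing decoding is available). States are named by structure:
nonfeeding = lowest Bernoulli buzz probability; of the rest, bottom
feeding = higher mean of the relative-buzz-depth beta (buzzes
concentrated at maximum depth), pelagic feeding = the remainder.

Recursions are numba-jitted with a pure-Python fallback; results are
identical either way, only speed differs.

## Energy budgets

All bioenergetics start from a daily FMR supplied as a parameter
(default 15 MJ day⁻¹ for a representative 40 kg adult; estimating FMR
from respiration physiology is out of scope). Defaults: assimilation
efficiency 0.90, prey energy density 4.2 kJ g⁻¹, SDA fraction 0.125 of
FMR.

- **Activity-specific FMR** solves base · Σ f_s m_s = FMR/24 for the base
  hourly rate, with f_s fractions of *total* time (this reading, not
  fractions of diving time, reproduces the standard worked example) and
  m_s respiration-rate elevations relative to nonfeeding; returns
  base·m_s (kJ h⁻¹). Energy is conserved exactly by construction.
- **Foraging efficiency** = energy acquired while foraging / marginal
  cost of foraging, the latter being (time-weighted foraging FMR −
  nonfeeding FMR) × daily foraging hours. Published field estimates of
  this ratio are not exactly derivable from their own printed inputs, so
  the intake convention (gross vs assimilation-discounted) is an explicit
  flag and no specific value is asserted in tests.
- **Energy balance**: total deployment FMR split evenly per respiration
  (cost) and, after assimilation, per buzz (gain); the cumulative balance
  closes at zero by construction, making the *trajectory* (when the
  animal runs a deficit) the informative output. The implied gross prey
  mass per buzz is reported alongside.
- **20-min intervals**: contiguous windows; the majority state must
  occupy > 75 % of the window for retention (guards against costing mixed
  behavior); event counts use raw timestamps, not proration.
- **Metabolic scope** = VO₂max/FMR rounded half-away-from-zero to one
  decimal, matching the convention of published comparative tables
  (whose porpoise row sits on a rounding boundary and is excluded from
  regression tests).
- **SDA scenario**: concentrating the daily digestion cost into the
  foraging hours elevates foraging FMR by sda_fraction /
  foraging_time_fraction relative to average.

Sunrise/sunset are configuration inputs (no ephemeris computation);
night is the half-open [sunset, next sunrise).

## Synthetic deployment generator

Simulation is dive-level: the state chain is drawn per dive from a
(context-sampled) TPM, and sensor traces are rendered around the
schedule. Defaults mirror the day-time field regime of wild harbor
porpoises in shallow coastal water:

| state | dive dur. (s) | depth (m) | surface (s) | buzz min⁻¹ | resp min⁻¹ | MSA | bottom frac. |
| --- | --- | --- | --- | --- | --- | --- | --- |
| nonfeeding | 50.7 ± 15 | 4.4 ± 1.5 | 25.1 | 0.1 | 2.4 | 1.8 | 0.10 |
| pelagic | 44.4 ± 14 | 8.2 ± 2.5 | 35.7 | 2.6 | 3.0 | 2.3 | 0.15 |
| bottom | 77.5 ± 20 | 11.6 ± 3.5 | 34.4 | 1.6 | 2.7 | 1.9 | 0.50 |

Durations/depths are moment-matched truncated lognormals (minimums 6 s,
2 m); surface means are the field dive-cycle means minus the dive means.
The default TPM is a diagonal-dominant free parameter (no fitted field
TPM is publicly printed) and context machinery defaults to C = 1. Night
(sunset–sunrise, clock anchored by a start hour) multiplies buzz rates
by 2.5 (matching the reported ~151 % nocturnal elevation) and pelagic
entry probability by 2.4 (matching the reported odds ratio), both
renormalized and configurable.

Rendering details that make the detectors exactly testable:

- Depth is piecewise linear: descent–bottom–ascent trapezoids with phase
  boundaries snapped to the sample grid (so maximum depth is attained
  exactly), V-notches to ~0.1 m at each scheduled breath, and ~0.9 m
  submersion bumps between breaths so each breath owns its own surfacing
  — these bumps are precisely the near-surface "apneas" real records
  show. Respirations per cycle follow a shifted Poisson
  (1 + Pois(λ−1) for λ > 1) so every surfacing has a breath while the
  mean matches the configured rate; breaths are spaced ≥ 2 s.
- Buzz intervals (0.4–0.8 s) are scheduled inside the dive — within the
  bottom phase for bottom feeding, throughout for pelagic — with ≥ 1.2 s
  separation so the 1 s merge rule never fuses distinct true buzzes.
  Click trains fill each interval at a fixed ICI (default 3 ms), giving
  floor(len/ICI)+1 clicks and guaranteed detectability.
- Acceleration is built as (g + s(t))·u(t): u the unit gravity direction
  from the profile-implied pitch (vertical speed over a nominal 1.8 m s⁻¹
  swim speed) and an AR(1) roll with state-dependent spread; s(t) a
  half-normal specific acceleration scaled so E|s| equals the dive's
  activity level. The norm construction makes ground-truth MSA exactly
  |s| regardless of orientation. Each dive's activity level is drawn
  around the state mean with a mean-preserving lognormal multiplier
  (cv 0.20) — real per-dive activity varies, and without it the
  dive/apnea mixture sees implausibly crisp subclusters.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: no sensor noise or drift, no tag slippage,
no hydrodynamics or prey fields, no acoustic propagation or false-click
clutter, piecewise-linear (not stroked) dive profiles, independent
lognormal dive parameters rather than the full joint structure of real
dives, and breath timing more regular than real ventilation. Detector
exactness (recall = precision = 1) is a property of the rendered
separability conditions, not a field performance claim.

## Problem sizes in validation

The validation suite and acceptance script use reduced problem sizes
chosen to give stable statistics: 3–24 h deployments, 5000 simulated
dives for parameter recovery with 4 restarts, 20 (suite) or 10 (script)
replicates of AIC selection at 600 dives with 3 restarts, 8 restarts for
end-to-end runs, 100 random parameterizations for the likelihood oracle
(T ≤ 8 so exhaustive enumeration stays exact), and 1000 random click
trains for the buzz oracle. Monte-Carlo tolerances use batch-mean or
cluster-robust standard errors where sequences are autocorrelated
(state-frequency checks, the diel buzz-rate ratio).

## Known limitations

- Standard errors/CIs for HMM parameters are not computed (as in the
  motivating analyses, which report point estimates).
- The context random effect is validated for C ≤ 2 against enumeration
  and by degeneracy checks; large-C fits on few animals are weakly
  identified by nature.
- The dive/apnea dominance rule can under-select dives on data with
  crisp within-dive clustering (see above).
- GLMM-based inference on the stratified outputs (odds ratios,
  autocorrelation structures) is deliberately out of scope; the pipeline
  emits the tables such models would consume.
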