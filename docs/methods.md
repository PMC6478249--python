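# Methods

## Task model

The coin game is modeled as a discrete-time stochastic process on the
horizontal screen coordinate x ∈ [0, 1], stepped at the monitor frame rate
(Δt = 1/60 s) for the 5-s response period; the 1-s preview admits no
responses, and vertical motion is purely cosmetic, so only the final
horizontal position matters for the outcome. Each frame applies

    x ← x_def + (x − x_def)·e^(−λΔt) + ε + p·s·δ,

where x_def is the default target column (the undesired target on Go
trials, the desired one on NoGo trials), ε ~ N(0, σ_w²Δt) is walk noise,
p ∈ {0, 1} indicates a key press in that frame, s = ±1 points away from the
default target, and δ ~ N(μ_k, σ_k²) is the press displacement. Positions
are clamped to [0, 1]; the exponential-relaxation form is the simplest
process with a negative exponential drift toward a fixed point. Press
displacements are signed draws, so a press can under- or overshoot; at most
one displacement is applied per frame (two presses inside the same 1/60-s
frame coalesce in the dynamics, though both are counted in the response
rate). The trial outcome depends only on the final position: win inside the
desired window, lose inside the punitive window (both inclusive), otherwise
incomplete. Geometry: machine at x = 0.5, dot at x = 0.9; the coin starts
in the default target's column (bottom-middle for machine-default trials,
bottom-right for dot-default ones), so without presses the default route is
realized and NoGo trials are won by withholding.

## Parameters and calibration

| parameter | default | meaning |
|---|---|---|
| Δt | 1/60 s | frame duration |
| response period | 5.0 s | task window per trial |
| λ | 0.25 1/s | drift relaxation rate |
| σ_w | 0.008 | walk noise scale (units/√s) |
| μ_k | 0.0217367 | mean press displacement (screen units) |
| σ_k | 0.30·μ_k | press displacement SD |
| window width | 4·μ_k | target window (≈ four presses to cross) |
| press-rate cap | 8 /s | fastest sustained pressing |

The free dynamics parameter μ_k was calibrated by bisection on a fixed-seed
Monte-Carlo estimate so that the *ideal responder* — a bang-bang controller
pressing at the rate cap whenever the coin is outside the desired window —
needs 32.12 ± 0.5 key presses on average (among winning trials) to bring
the coin home within one trial; the window is pegged at four mean presses
throughout. λ is held fixed during calibration: the calibration target is
one scalar, so one knob (μ_k) is bisected; λ was chosen so that the drift
at full target separation (λ·0.4 = 0.1 units/s) roughly balances the press
inflow of a typical human rate (6.4/s·μ_k ≈ 0.14 units/s), which makes
open-loop responders end near the target rather than at a screen edge.
σ_w was chosen so the unpressed coin stays inside the default window with
probability ≫ 0.99 over a trial (Ornstein–Uhlenbeck stationary SD ≈ 0.011
versus half-window 0.043); σ_k/μ_k = 0.30 puts the emergent press-count SD
near the observed ±1.8. The SD is *emergent* — only the mean is targeted
by calibration. `calibrate_params` reports non-convergence as an error
after a bounded number of bisection steps.

## Synthetic cohorts

`make_design` encodes the two experiments' exact trial counts: Experiment 1
— phase 1: 64 trials (16 per Approach/Withdraw × Go/NoGo condition, two
analysis blocks), phase 2: 32 CS+ (16 reinforced) + 32 CS−, phase 3: 64
trials (8 per CS × frame × Go type); Experiment 2 shifts Go:NoGo to 3:1
(phase 3: two blocks of 6 trials per Go type and 2 per NoGo type).
Within-block order is an independent uniform permutation per subject.

Subject random effects: Go press rate ~ N(6.4, 0.8²) presses/s (truncated
to [0.5, 7.5]), NoGo rate ~ N(0.05, 0.05²) clipped at 0, first-press
latency lognormal with frame-specific medians (0.45 s approach, 0.55 s
withdraw — approach is initiated faster). Responders are *open-loop*: per
trial the press count is Poisson(rate·5 s) and press times are uniform
between the latency and trial end. A closed-loop "press until inside the
window" responder would saturate the press count at the required number and
erase any CS-driven rate difference; open-loop pressing preserves it, at
the cost that simulated Go accuracy is not calibrated to human levels.

The PIT effect is a CS+ rate increment confined to Withdraw-Go trials,
with between-subject SD τ = 0.25 presses/s. The population increment δ is
derived analytically from the target paired effect size d: the observed
per-subject CS difference has variance τ² + 2·rate/(5·m) (m = trials per
cell), so δ = d·√(τ² + 2·rate/(5·m)); replicate simulations confirm the
pipeline re-estimates the configured d without detectable bias. Other
conditions' CS deltas default to zero and are configurable.

Psychophysiological amplitudes (one per subject × measure × CS level)
emulate condition-level model estimates: the CS− baseline is Gaussian
across subjects (SD from printed SEMs at n = 35) and the within-subject
CS difference is Gaussian with mean and SD set by the configured CS-level
means and paired d (defaults: SCR 0.39/0.30 µS, d = 0.673; pupil 3.16/3.02
mm, d = 0.52; heart period 13.86/−15.52 ms, d = 0.78). Raw physiological
time series are *not* simulated. Consequently, passing tests show that the
statistical pipeline is correct and well calibrated for data with this
random-effects structure; they cannot show robustness to features of real
recordings (non-Gaussian subject effects, drifting rates within a session,
motivational drop-out, artifact-driven missing data).

Shock-intensity calibration interpolates current as a piecewise-linear
function of the 0–100 painfulness rating and reads it at 85 (i.e., 85% of
the rating scale — the alternative reading, 85% of the threshold current,
is available as `mode="current"`); non-monotone rating curves are resolved
by the first upward crossing, the conservative (lower-current) choice, and
results are clamped to the tested range.

## Inferential layer

The repeated-measures ANOVA implements the classical univariate partition
for balanced, fully within-subject designs (up to three factors): every
effect is tested against its own subject × effect interaction mean square.
Greenhouse–Geisser ε is computed per effect from the covariance of
orthonormal contrast scores (Kronecker contrasts for interactions) and is
exactly 1 for single-df effects; the corrected p-value is reported
alongside the uncorrected one, which is primary for df = 1 effects.
Generalized η² follows the Olejnik–Algina/Bakeman convention with all
error strata — including the subject stratum — in the denominator.
Cohen's d for paired contrasts is mean(diff)/sd(diff), hence d = t/√n
identically. Degenerate inputs are explicit errors: missing or duplicated
cells, zero-variance differences; a flat factor yields F = 0.

## Model comparison

The reversed regression codes CS as a centered ±1 indicator (coding does
not affect RSS ordering) and regresses it on the measure plus per-subject
intercepts; n = 2·S observations, r = S + 1 regressors for S subjects.
AIC uses the natural logarithm; RSS below numerical precision (perfect
separation) maps to AIC = −∞ with an explicit warning. Because all
measures share (n, r), LBF differences reduce to (n/2)·log RSS ratios and
the AIC ranking coincides with the |paired t| ranking — both are verified
as properties in the test suite. Cross-measure association is assessed by
Pearson correlations of per-subject CS differences and by residual
correlations after removing each CS level's grand mean (pooled over
subject × CS rows).

## Power

Paired-t power is exact under the noncentral t model (df = n − 1,
noncentrality d√n) — the same model standard power software uses — with a
Monte-Carlo estimator (`mc_power`) as an internal cross-check.
`required_n` returns the minimal integer n by bracketing + bisection on
the monotone power curve.

## Problem sizes used in the shipped checks

Simulator calibration statistics use ≥ 5000 Go trials; effect-size
recovery averages 8 replicate cohorts of 300 subjects (the sampling SE of
a single paired d at realistic n is larger than the tolerance of
interest); the type-I calibration of the a-priori contrast uses 2000
null-generator cohorts of 12 subjects; the predictive-validity ordering
check uses 200 replicate cohorts at the confirmation experiment's n = 35.

## Known limitations

* Open-loop responders make simulated Go accuracy lower than human
  accuracy; accuracy and latency are structurally valid but their levels
  are not calibrated.
* The ANOVA supports balanced complete within-subject designs only — no
  between-subject factors, missing cells, or Huynh–Feldt correction.
* The AIC→LBF shortcut is implemented as defined; it is not a marginal
  likelihood.
* Press counts are Poisson; real inter-press intervals have a refractory
  floor, so very high rates are slightly over-dispersed here.
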