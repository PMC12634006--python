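# Methods

## The measurement problem

Contrast sensitivity — the reciprocal of the lowest grating contrast a
viewer can detect, as a function of spatial frequency — characterizes
spatial vision more completely than letter acuity, but classical staircase
measurement is far too slow for preschool children, and verbal or
button-press responses are unreliable at ages 3–6. This package implements
the computational core of a gaze-based pediatric instrument: a Bayesian
adaptive engine chooses maximally informative stimuli, and the child's
*looking behaviour*, recorded by a remote eye tracker, serves as the
response. Everything needed to study the instrument end to end without
hardware — simulated observers, synthetic gaze, and the test–retest
statistics used to validate such a tool — is included as first-class,
tested code.

## CSF model

Sensitivity is modeled as a truncated log-parabola with four parameters:
peak sensitivity γ_max (> 1, linear units), peak frequency f_max (cpd),
full bandwidth at half maximum β (octaves), and low-frequency truncation δ
(log₁₀ units). With β′ = β·log₁₀2,

S′(f) = log₁₀ γ_max − 4 log₁₀2 · ((log₁₀ f − log₁₀ f_max)/β′)²,

floored at log₁₀ γ_max − δ for f < f_max. The truncation applies only
below the peak; above it the parabola is used unmodified.

Two scalar outcomes summarize a fitted curve:

* **AULCSF** — ∫ max(S′(f), 0) d log₁₀f over 1.5–18 cpd, by trapezoidal
  rule on ≥ 512 log-spaced points (1024 by default; doubling the grid
  changes the result by < 1e-4 log units across the engine's parameter
  ranges). Negative log-sensitivity is clipped at zero: frequencies the
  viewer cannot see at full contrast contribute no area. The integral is
  **not** clamped to the protocol's stimulus range — the fitted curve may
  extend beyond the highest frequency actually presented.
* **CSF acuity** — the high-frequency cutoff where S′(f) = 0, available in
  closed form: log₁₀ f_c = log₁₀ f_max + (β′/2)·√(log₁₀ γ_max / log₁₀ 2).
  It is converted to a logMAR equivalent as log₁₀(30 / f_c), anchoring
  30 cpd to logMAR 0 (the conventional cpd ↔ Snellen-decimal
  correspondence). The exact conversion convention deployed clinically is
  not fixed by any single standard; this anchor is the common one and is
  stated explicitly so results are interpretable.

## Adaptive engine

The posterior lives on a fixed 4-D grid: 20 log-spaced γ_max in
[1.05, 1000] × 20 log-spaced f_max in [0.2, 20] cpd × 12 linear β in
[1, 9] octaves × 8 linear δ in [0.02, 2] — 38,400 points, uniform prior by
default (an informative prior can be supplied in the engine config; the
uniform prior is what all tests and the acceptance run use). Candidate
stimuli are 12 log-spaced frequencies across the protocol range × 30
log-spaced Michelson contrasts in [0.001, 1].

The response model is a Weibull psychometric function on contrast·S(f):

p(correct) = g + (1 − g − λ)(1 − exp(−(c·S(f))^η))

with guess rate g = 0.5 (two-alternative left/right looking task), lapse
λ = 0.04, slope η = 3. These constants are not identifiable from the
instrument's published description; they are standard values for this task
class and are config-exposed.

Each trial the engine evaluates, for every one of the 360 candidates, the
one-step-ahead expected Shannon entropy of the posterior — the entropy
after a correct and after an incorrect response, weighted by their
predictive probabilities — and presents the minimizer (equivalently, the
maximal expected information gain). The search is exhaustive and
deterministic; ties break toward the lowest (frequency, contrast) index.
Side (fair coin) and orientation (uniform [0°, 180°)) are drawn from the
session RNG and play no role in the optimization, since detection, not
orientation discrimination, is the task. Bayes updates renormalize after
every trial; a response that annihilates all posterior mass raises an
error rather than renormalizing silently, since it can only arise from a
misconfigured grid/likelihood pair.

For speed, the session-grade engine precomputes the likelihood table P and
the entropy table P log₂P + (1−P) log₂(1−P) over (grid × stimulus space)
once, reducing each trial's selection to two matrix–vector products; this
is numerically identical (float64 throughout) to the reference
implementation, and a test asserts agreement with naive enumeration to
1e-10 bits.

Final metrics are posterior expectations of the per-grid-point closed
forms, with 95% credible intervals taken as weighted quantiles of the
metric's distribution over grid points. Note a structural caveat: for
observers whose cutoff frequency lies above the protocol's stimulus
ceiling, CSF acuity is posterior extrapolation and is correspondingly
uncertain; AULCSF, integrated over 1.5–18 cpd, is much better constrained.

## Gaze adjudication

Gaze CSVs use the remote-tracker convention (pixels, top-left origin, y
down, nominally 65 Hz with a validity flag); all science-side geometry is
in degrees of visual angle from the screen centre (x right, y up). The
conversion is a per-axis flat-screen tangent mapping assuming square
pixels, built from the display's resolution, diagonal size and viewing
distance (defaults: 2560×1440, 27 in, 60 cm).

The stimulus AOI is a square of side 4.4° centred on the target at ±7°
eccentricity ("rectangular area … 4.4 degrees" is read as a square, the
single printed dimension; the half-extents are configurable). A trial is

* **correct** when a run of valid in-AOI samples spans ≥ 0.8 s before the
  4 s deadline. A run requires *consecutive* fixation — a tracked sample
  outside the AOI always breaks it — but tracker dropouts and blinks up to
  100 ms inside a run are bridged. Each sample covers one nominal sample
  period (the stream's median inter-sample interval, falling back to
  1000/65 ms), so the span of a run from t_first to t_last is
  t_last − t_first + period and exactly 52 consecutive 65 Hz samples meet
  the 0.8 s criterion. The reported latency is the time at which the
  criterion is met.
* **incorrect** otherwise, adjudicated at the deadline. The deadline is
  read as a per-trial timeout measured from stimulus onset: failing the
  dwell criterion within 4 s scores incorrect. (The alternative reading —
  4 s of *cumulative* outside-AOI time — would interact badly with a fixed
  trial pacing and is not used.)
* **invalid** when the stream is empty (flagged distinctly) or more than
  half its samples are untracked. Invalid outcomes take precedence: a
  stream that is mostly tracking loss is not trusted even if a nominal
  dwell appears in the tracked remnant. The session re-presents such
  trials with a freshly selected stimulus and leaves the posterior
  untouched, so sessions always end with the protocol's valid-trial count.

A brute-force oracle (explicit enumeration of all dwell windows) is kept
in the test suite and in the acceptance script; the adjudicator agrees
with it exactly on 1,000+ randomized streams per run.

## Session protocols and cues

Two presets mirror the instrument's deployments: **exp1** (baseline, 60
valid trials, 0.5–32 cpd) and **exp2** (optimized pediatric, 30 valid
trials, 0.5–15 cpd). Every presentation emits an attention cue; each valid
outcome earns reward (correct) or motivation (incorrect) feedback; a bonus
cue fires when a streak of consecutive correct responses reaches every
multiple of 3, and a task re-instruction cue likewise for incorrect
streaks. Streaks are counted over valid outcomes only; invalid trials
neither extend nor reset them. Actual animations are out of scope — cues
are event markers in the trial log.

The Gabor raster is a sine-phase grating (so the patch mean equals the
background, exactly by symmetry on the odd-sized pixel grid) windowed by a
2°-radius disc whose outer 0.5° is attenuated by a half-Gaussian ramp with
σ = 0.5°/2.5, placing the disc edge at 2.5σ (~1.5% residual). Frequencies
below 2 px/cycle at the given geometry raise an aliasing error — on the
default display this rejects 32 cpd, the concern that motivated narrowing
the protocol range to 15 cpd.

## Simulated observers

A simulated child holds a ground-truth CSF plus behavioural nuisance
parameters: per-trial lapse probability (on a lapse the response is a pure
guess at g = 0.5), fixation jitter (SD 0.5°), lognormal fixation latency
(median 500 ms, σ = 0.3 log units, clipped at 2 s so the dwell can
complete), per-sample tracking dropout (2%), and between-session Gaussian
jitter on the log₁₀ parameters (SD 0.05) standing in for biological
test–retest variability. The generative response marginal is exactly
lapse·g + (1 − lapse)·p_correct(λ=0) — the engine's own likelihood with
the lapse folded in — which a Monte-Carlo test verifies against the closed
form.

Synthetic gaze realizes an intended outcome: centre fixation, latency,
then sustained jittered fixation at the target AOI (intended correct), or
a waypoint-interpolated wander that avoids both candidate AOIs (intended
incorrect). The intended→adjudicated channel is ≥ 95% faithful at default
noise, itself a tested property. What the simulator does **not** model:
saccade dynamics and main-sequence kinematics, calibration drift, head
pose, developmental trajectories, or any amblyopia-specific deficit
structure. Passing tests therefore demonstrate the *pipeline's*
correctness and statistical behaviour under plausible noise, not claims
about real children.

Cohorts are drawn from plausible preschool ranges: log₁₀ γ_max ~
N(1.4, 0.2) truncated to the grid, f_max log-normal (median 2.5 cpd,
σ = 0.15 log₁₀), β ~ N(3.5, 0.8) truncated to [1, 9], δ ~ U(0.2, 1.0),
lapse ~ U(0, 0.15). All draws are seeded and bit-reproducible.

## Reliability battery

For paired test–retest scores: ICC is the two-way, absolute-agreement,
single-measures form ICC(A,1) = (MSR − MSE)/(MSR + (k−1)MSE +
k(MSC − MSE)/n) with k = 2, with the F-based 95% CI of McGraw & Wong
(1996) (cross-checked against pingouin in the tests); Bland-Altman bias
and 1.96·SD limits of agreement; CoR = 1.96·SD of the differences
(identically half the LoA width); a one-sample t test of the differences
for learning effects; Fisher-Z comparison of two independent ICCs,
z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)), operand order
caller-specified since published comparisons use both sign conventions;
and fractional rank precision, implemented as pairwise rank concordance
(ties count ½), which is 1.0 for preserved ordering, 0.0 for a full
reversal, and 0.5 in expectation for independent scores.

## Problem sizes and numerical choices

The validation suite runs at desk scale on one CPU: engine exhaustive
search over 360 candidates × 38,400 grid points per trial; adjudicator
oracle equivalence on 1,000 randomized streams; parameter recovery with
100 prior-drawn lapse-free observers at 60 and 10 trials; simulated
test–retest with 28 subjects × 60 trials (exp1) and 52 × 30 (exp2), two
sessions each; FRP null calibration with 1,000 replicates at n = 52.
Tolerances: posterior normalization 1e-12 per trial; closed-form metric
oracles 1e-9 to 1e-3 as appropriate to the oracle; statistics vs
mean-squares oracle 1e-10.

## Known limitations

* With the default cohort (lapse up to 0.15), per-session AULCSF
  estimation error roughly doubles relative to lapse-free observers; the
  simulated test–retest ICC under those defaults (~0.6, per the acceptance
  run) sits below what a clinic population with wider between-subject
  spread would produce, because ICC depends on that spread as much as on
  instrument precision. Lapse-free simulations reproduce a 60-trial CoR
  near 0.33 log units.
* CSF acuity is extrapolated for observers whose cutoff exceeds the
  stimulus ceiling and is then substantially noisier than AULCSF.
* The engine's psychometric constants are assumed, not estimated; a lapse
  mismatch between observer and engine biases sensitivity downward
  (lapses read as genuine misses), mirroring the instrument's known
  behaviour with inattentive children.
* Real-time concerns — rendering latency, tracker calibration, examiner
  interaction — are entirely out of scope.
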