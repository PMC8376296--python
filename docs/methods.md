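# Methods

`vpvigor` implements an analysis of how cue-evoked firing in the ventral
pallidum relates to the vigor of the cued approach movement in a rat
discriminative-stimulus (DS) task, together with a synthetic-session
generator that provides ground truth for every stage. This note documents
the models, the defaults and their rationale, the numerical choices, and the
known limitations.

## Movement segmentation

**Locomotor index (LI).** For head position tracked at 30 frames/s, the LI
at frame *t* is the sample SD (n−1 denominator) of the nine frame-to-frame
displacement magnitudes *d*(t−4) … *d*(t+4), where *d*(k) is the Euclidean
distance between head positions at frames k and k−1. The half-window of 4
(nine displacements over ten position frames) follows the formula rather
than the accompanying "11-frame" prose count; `half_window` is configurable.
A frame's LI is valid only when all ten positions it depends on are valid;
frames near tracking gaps or series edges are invalid and fail every
threshold comparison downstream.

**Thresholds.** A three-component Gaussian mixture is EM-fitted to the
session's LI distribution (k-means++ initialization, 10 restarts,
log-likelihood tolerance 1e−6, deterministic per seed, on a random subsample
of at most 20,000 valid values — the thresholds' estimator variance at that
size is far below the component separation, and the fit stays fast).
Components are sorted by mean; the *offset* threshold is the weighted
equal-density intersection of components 1 and 2 and the *onset* threshold
that of components 2 and 3. The intersection solves a quadratic in closed
form; if no root falls between the component means (one component dominates
throughout), the argmin of the absolute density difference on a dense grid
is returned and flagged.

**Bouts and trials.** A movement bout starts at the first frame of ≥ 4
consecutive frames with LI strictly above the onset threshold, provided
≥ 70% of the 30 preceding frames are strictly below the offset threshold;
it ends at the first subsequent frame below the offset threshold (a bout
reaching the end of the session is closed there and flagged truncated).
Trials where the cue-onset frame falls inside a bout are excluded
("moving at cue"). For responded trials (active lever press before cue
offset) the movement window runs from the first bout onset after cue onset
to the first press or receptacle entry; the bout onset must not postdate the
trial-ending press — without that constraint the classifier can latch onto
post-consumption locomotion. Non-responded trials end at the first
sub-offset-threshold frame.

## Kinematics

Head position is the midpoint of the two LEDs and heading the rear-to-front
LED direction; single-LED or short two-LED dropouts (≤ 5 frames) are
linearly interpolated, longer gaps stay invalid (no other smoothing is
applied). Radial velocity is the negative rate of change of head-to-lever
distance (positive = approaching); angular velocity is the frame difference
of the head's polar angle about the lever (the allocentric tangential
component). Angular-velocity summaries (mean/max/SD) use the magnitude;
radial-velocity summaries use the signed value. Net heading change is the
cumulative (unwrapped) sum of signed heading increments, so |net| may exceed
π; turn efficiency = Σ|Δheading| / |net| is undefined (missing) when
|net| < 1e−3 rad, and missing features drop a trial listwise in the GLM.
Path efficiency = straight start-to-end distance / path length. State
variables (lever distance, egocentric bearing to lever folded into [0, π],
elapsed times since reward / press / cue) are read at the cue-onset frame.

## Spike responses

Spikes are counted in half-open 20-ms bins aligned to cue onset. The
baseline is the 1-s precue window: mean and SD of the 50 trial-averaged
baseline bin rates. A neuron is cue-excited when ≥ 3 consecutive bins in
40–180 ms exceed baseline mean + 3.2905 × baseline SD (upper limit of a
two-sided 99.9% normal interval — the construction is not uniquely
determined by the criterion's verbal description; a Poisson-exact variant on
pooled counts is available via `criterion="poisson"`). Response windows are
40–400 ms (overall), 40–180 ms (early peak) and 180–400 ms (late tail); a
50–500 ms variant can be requested where a single overall window is wanted.
Z-scores divide the window rate's deviation from baseline mean by baseline
SD. DS-vs-NS comparisons use the paired Wilcoxon signed-rank test (exact
null for ≤ 25 nonzero differences).

## Regressor selection

On complete rows of the movement-variable table over correct, still-at-cue
DS trials: (1) squared multiple correlations (R² of each variable on the
rest) are computed and variables iteratively dropped, highest first, while
any SMC exceeds 0.8; (2) the number of factors is the count of
correlation-matrix eigenvalues above 1; (3) maximum-likelihood factor
analysis with varimax rotation (rotation is configurable; the published
loading table's simple structure is consistent with an orthogonal rotation);
(4) each variable's *rep score* is its largest-magnitude loading minus the
signed sum of its other loadings, and each factor's representative is its
highest-rep-score member with |loading| ≥ 0.6, while variables with max
|loading| < 0.4 enter as independent regressors. The 0.6/0.4 cutoffs are
configuration values chosen to reproduce the published independent set; a
manual-override map exists because the published factor-3 choice (SD rather
than mean of angular velocity) does not follow from the rep-score rule as
stated.

## Encoding model and population inference

Per neuron, the response-window spike count is fit by maximum-likelihood
Poisson regression with log link on the unstandardized regressors
(intercept included; Wald SEs). Comparability across regressors comes from
the IDR Firing Difference, IFD = (e^(β·IDR) − 1) × 100%, with IDR the 90th
minus 10th percentile (linear interpolation) of the regressor over that
neuron's retained trials. Retained trials are correct-response, still-at-cue
DS trials with complete features; a neuron needs at least regressors + 10 of
them. Sessions with DS response ratio < 0.80 are excluded from encoding
analysis. Population inference is a two-sided one-sample t test of IFDs
against zero per regressor, Holm-adjusted within each response window's
regressor family; cross-subject consistency uses a one-way ANOVA over
animals (subjects with one neuron excluded).

## Epoch comparison

With an infusion marker at time *T*, Q1 = [T − 45 min, T) and
Q2 = [T, T + 45 min). Per neuron and window, the response Z is recomputed
within-epoch (same statistic as above; ≥ 10 DS trials required per epoch,
complete pairs only), and Q2 Z-scores are regressed on Q1 Z-scores by OLS.
t tests for intercept = 0, slope = 0 and slope = 1 use the residual variance
with n − 2 degrees of freedom.

A caveat this package makes explicit: because the Q1 Z-score is itself a
noisy estimate, OLS suffers regression dilution — under genuinely unchanged
firing the expected slope is slightly below 1 (≈ 0.95 at ~25 trials per
epoch and the simulated population spread), and the slope-vs-1 test
over-rejects relative to its nominal level. This matches the sub-unity
slopes reported for untreated populations. The test's nominal 5% calibration
therefore holds — and is verified — under classical conditions (effectively
noise-free regressor, homoscedastic errors); attenuation estimates
themselves are recovered within 2 SE at realistic trial counts.

## Synthetic sessions

The generator emulates the statistical structure the analysis assumes, with
all randomness flowing from one master seed through named substreams
(schedule / behavior / spikes); regeneration is bit-identical.

**Schedule.** One interleaved cue stream: each gap from a cue's offset to
the next onset is exponential with mean 30 s, and each cue is DS or NS with
equal probability; DS ends at the press (or 10 s), NS after 10 s. This
reading reproduces both the stated 30-s mean ITI and the realized per-session
cue counts of the recorded data (~131 DS + ~134 NS per 3 h); a dual-stream
variant (independent exponential inter-onset processes per cue type) is
available via `schedule_mode="dual"`. Response probabilities default to 0.92
(DS) and 0.10 (NS); movement-onset latencies are lognormal (median 0.8 s,
σ = 0.5), matching ~1.2 ± 1.5 s summaries.

**Behavior.** Between trials the head alternates quiet stillness
(exponential, mean 4.5 s), occasional small-amplitude fidgeting (20% of
still segments, 2.5-mm steps — this supplies the middle LI mode the
3-Gaussian fit expects), and roaming toward random waypoints at 120–300 mm/s.
Approaches are quadratic Bezier paths to the lever with a trapezoidal speed
profile (brisk attack, as real locomotor initiations), per-frame lognormal
displacement jitter (σ = 0.45, giving locomotion its high-LI signature), and
a drawn peak speed (lognormal, median 420 mm/s) from which the duration
follows the start distance. After a rewarded press the head visits the
receptacle and pauses 3 s to consume. The two LEDs sit ± 20 mm along the
heading axis with isotropic 1.5-mm Gaussian noise at 30 frames/s; arena
300 × 250 mm with lever and receptacle on one wall.

**Spikes.** Each neuron has a constant baseline (uniform 2–15 Hz). Excited
neurons carry a two-phase evoked kernel: an early component over 40–180 ms
(amplitude uniform 15–40 Hz) and a late component over 180–400 ms (5–15 Hz),
each scaled by a per-trial gain exp(Σᵥ βᵥ (vᵥ − cᵥ)) computed from the
trial's noise-free features (defaults: +0.00075 per mm/s of maximum radial
velocity, +1.0 per unit path efficiency, −0.0019 per mm lever distance,
centered at typical values and capped at ×8 — scaled so population mean
IFDs fall in the ±20–35% range reported for real cue-excited populations). Inside its window the kernel
*replaces* the baseline rate, so the window count is exactly log-linear in
the features — an additive baseline would give every neuron in a session the
same curvature misspecification, which a pooled population test then
rejects against; outside the windows the baseline Poisson process is
untouched. NS trials scale the gain by 0.6; after an optional infusion time
the evoked gain is multiplied by an attenuation factor.

**What the generator does not emulate.** No refractoriness or bursting, no
learning or satiety drift across the session, no lens distortion or frame
drops beyond optional NaN injection, no reward-consumption microstructure,
and approach paths are smooth Bezier arcs rather than compound movements.
Passing recovery tests therefore demonstrate correctness of the analysis
pipeline under the assumed statistical structure, not robustness to every
property of real tracking and spike data.

## Verification at a glance

Problem sizes were chosen so the full suite runs comfortably on one CPU.
Key checks: the LI and the bout scanner match literal brute-force oracles
exactly; mixture thresholds recover stated generating parameters; the
excitation detector's false-positive rate is ≤ 1% on 10,000 homogeneous
Poisson neurons with ≥ 95% sensitivity at 3× baseline; rep scores reproduce
the published factor-table column within printed rounding; Poisson-GLM
closed forms are exact; and an end-to-end recovery study (20 replicates,
each pooling twenty 2-h synthetic sessions into a population of ~125
excited neurons — many sessions with a few neurons each, as in the real
dataset) recovers the generative
coupling signs with Holm-significant population tests while uncoupled
regressors stay non-significant. The pooled multi-session design mirrors how
the recorded population spans many sessions; within a single session all
neurons share one trial realization, so shared feature-measurement error
would dominate an across-neuron test no matter how many neurons are
recorded — a constraint worth remembering when interpreting single-session
population statistics.

The recovery study's null probe uses the two regressors that are null by
construction: movement-onset latency (an independent draw) and net heading
change (sign-symmetric). Time since the last cue is fitted in the model but
is not a clean null in this behavior model — consumption ends at the
receptacle, so short cue intervals start the animal near the lever, and in
finite sessions that positional correlation entangles the variable with the
lever-distance pathway and its measurement error; across replicates it
occasionally reaches spurious significance through exactly that route.
Even so, the across-neuron one-sample t test remains mildly anti-conservative
for any session-clustered population, because neurons within a session share
one trial realization and therefore one realization of the
feature-measurement error.

Onset-detection accuracy is quantified under a generator setting with brisk,
well-separated initiations (≥ 1 s of true stillness, mean approach speed
≥ 250 mm/s): ≥ 95% of such initiations are found within ± 3 frames. Under
the fully realistic default parameterization the within-±3-frames rate is
~70%, limited by slow or short movements whose LI hovers near the onset
threshold and by fidgeting inside the stillness window; the press-bounded
trial classifier keeps those mismeasurements from contaminating the GLM.
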