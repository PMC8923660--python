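# Methods

This note documents the models, conventions, and design choices behind
`sacattn`: what the synthetic generator simulates, how each analysis stage
is defined, which numerical policies are fixed, and what the passing test
suite does and does not establish about real recordings.

## The task being modeled

A covert spatial-attention experiment: a head-fixed subject holds central
fixation and a joystick. A cue ring flashes for 133 ms in the periphery;
500 ms later two colored patches appear, one at the cued location and one
at the mirror-symmetric foil location. 1–4 s after patch onset the
saturation of one patch may change (cue : foil in a 3 : 1 ratio); the
subject must release the joystick within 150–750 ms for cued changes and
hold for foil changes. Cue side is blocked (70 trials per block,
alternating sides), with 18 single-patch transition trials marking each
upcoming cued location. Extracellular units with response fields (RFs)
over one patch location are recorded together with 1 kHz monocular eye
position.

All times in the package are milliseconds relative to color-patch onset
(t = 0), bins are half-open `[a, b)`, positions are degrees of visual
angle, and angles use the mathematical convention with cue-relative
angles wrapped to (−180, 180].

## Synthetic sessions (`sacattn.synthetic`)

The generator produces complete sessions with ground truth so every
downstream stage has a parameter-recovery test.

**Eye traces.** Position is an Ornstein–Uhlenbeck drift (diffusion
0.001 deg²/s, reversion time constant 0.5 s — slow fixational wander of a
few hundredths of a degree per second) plus white tremor (SD 0.005° per
sample; the detection benchmarks also run at 0.01°, a conservative
tracker-noise level). Microsaccades are drawn from a piecewise-constant
hazard: base 1.5 events/s, a 150 ms near-zero dip after patch onset, then
a 2 events/s rebound for 500 ms before returning to base — the classic
microsaccadic inhibition/rebound profile. A refractory period (150 ms plus
the event duration) spaces events. Each event is a minimum-jerk
displacement profile; amplitudes are gamma-distributed (shape 4, mean
0.4°) clipped to [0.1°, 1°], and the main-sequence slope of 100 s⁻¹
(peak speed = 100 × amplitude per second) fixes the duration at
1.875/slope ≈ 19 ms, in the conventional microsaccade range. Cue-relative
directions come from a mixture of von Mises lobes at 0° and 180°
(κ = 4, weight 0.25 each) plus a 0.5 uniform component, giving the
roughly balanced toward/away statistics seen during sustained attention.
No published amplitude or main-sequence statistics constrain these
choices; they are conventional values, exposed in `EyeModel`.

**Spike trains.** Each unit's rate is

    r(t) = baseline
         + visual transient        (when a patch is in the RF)
         + attention delta         (cue-in-RF, from 200 ms on)
         ± peri-microsaccadic terms,

with the transient an exponential decay (amplitude 60 sp/s, latency
50 ms, decay 80 ms — a strong collicular phasic response, chosen so the
18-trial single-patch responsiveness screen has realistic power), baseline
20 sp/s, and attention delta 5 sp/s. After every true microsaccade onset
the rate is suppressed for 60 ms starting 20 ms after onset, either
multiplicatively (rate × (1 − depth), default depth 0.5) or additively
(rate − depth × baseline) — the additive variant exists because it
preserves the attention delta through suppression exactly, giving the
"modulation preserved" property a generative counterpart. Optional
RF-direction-dependent terms (a pre-microsaccadic bias over [−40, 0) ms
and a motor burst over [0, 100) ms after toward-RF events, both default
0) support the motor-control analyses. Spikes are drawn by thinning an
inhomogeneous Poisson process, which is exact for bounded rates.

**Behavior.** Hits occur with probability 0.83 on cued changes, false
alarms with 0.05 on foil changes; reaction times are normal (350 ± 80 ms)
clipped to the response window, with a +30 ms penalty when a microsaccade
directed away from the cue falls within ±50 ms of the change — so
microsaccade-conditioned behavioral analyses have a known effect to
detect.

Units are distributed as evenly as possible over each monkey's sessions;
baseline and transient amplitudes are jittered across units (×0.7–1.4 and
×0.8–1.2) while the attention delta and suppression parameters stay at
the template values, so recovery tests have a single truth.

**What the generator does not emulate:** blinks, pupil dynamics,
tracker dropouts, binocular disparity, overshoot dynamics of real
saccades, bursty or history-dependent spiking, unit nonstationarity, and
any fitting to real recordings. Passing tests therefore demonstrate that
the *analysis code* is correct under a known model at realistic scales —
not that the model captures every property of real data.

## Microsaccade detection (`sacattn.eye`)

The standard 2D velocity method. Velocity comes from a 5-point
moving-window derivative, `v_n = (x_{n+2}+x_{n+1}−x_{n−1}−x_{n−2})/(6Δt)`
(a 3-point option is exposed); two boundary samples at each end are
invalid. Per-axis thresholds are `η = λ·σ` with λ = 4 and the
median-based robust scale `σ = sqrt(median(v²) − median(v)²)` — note this
scale is 0.6745 × SD for Gaussian noise; λ is calibrated to it, not to
the SD. A sample is suprathreshold when `(vx/ηx)² + (vy/ηy)² > 1`;
maximal suprathreshold runs of at least 6 ms are events. Runs closer than
20 ms are fused (suppressing double-detection of overshoots) and events
with displacement above 2° are discarded; these two rules are the
automated surrogate for manual screening, are configurable, and make no
claim about any original manual procedure. Onset/offset are the first and
last suprathreshold samples; the displacement is offset-minus-onset
position; direction is `atan2(dy, dx)`.

Events within ±90° of the cue direction are labeled *toward*, the rest
*away*; the boundary is resolved by the half-open interval [−90°, 90°),
so each label covers exactly half the circle and flipping the cue side
swaps labels exactly.

Measured on synthetic traces at the default detector settings: recall
≈ 0.999 for events ≥ 0.2° at tremor 0.01°, mean onset lag ≈ 3 ms (the
threshold is crossed slightly after true onset), false positives ≈ 0/s.
The detector is verified sample-for-sample against an independent
exhaustive scan of the same criterion.

## Rates and screening (`sacattn.spikes`)

Spike counts use non-overlapping 20-ms bins. Each unit is z-scored with
the mean and *population* SD of its binned counts across all trials and
conditions of the normalization span; the span is not fully determined by
the source analyses, so this package fixes it to −100…1000 ms around
patch onset and records it (with the constants) in the matrix provenance.
Event-aligned matrices re-bin counts around each alignment time and apply
the *stored* patch-aligned constants, so all analyses share one z scale
per unit. Events whose window crosses the trial bounds are dropped and
counted, never padded.

Unit inclusion mirrors the published screen: visual responsiveness
(50–150 ms vs −100–0 ms, two-sided rank-sum p < 0.01, required on both
two-patch and in-RF single-patch trials) and attention modulation
(delay-period 200–1000 ms mean rate, cue-in-RF vs cue-out-of-RF,
two-sided rank-sum p < 0.01 *plus* the sign requirement cue-in > cue-out,
implementing "significantly higher"). Under the null the directional
screen therefore passes at α/2, which is what the calibration tests
assert.

## Matching controls (`sacattn.matching`)

**Timing match.** The delay period (200–1000 ms) is tiled by eight 100-ms
bins. Candidates per bin: toward events, away events (each split by cue
condition when the attention factor is present — six conditions jointly),
and trials with no detected onset within ±200 ms of the bin center (the
bin center then serves as the alignment time). Every condition is
subsampled without replacement to the per-bin minimum across *all*
conditions, with one seeded generator consumed in documented
condition-then-bin order. When one trial holds several events in a bin,
event-level sampling is the default and trial-level sampling is a config
switch recorded in provenance; the original study counted "trials" and
does not say which was used.

**Eye-position match.** Average eye position over the −60…0 ms window
before each aligned event is histogrammed on a 0.25° × 0.25° grid and
the same per-bin minimum scheme equalizes the 2D distributions across
conditions.

Both controls assert their defining invariant — exactly equal post-match
per-bin counts — on every run, and store pre/post counts, selections, and
the seed.

## Analyses (`sacattn.analysis`)

* **Outcome split:** per-unit Δ = mean delay z (cue-in) − (cue-out),
  separately for hit and miss cue-change trials; paired two-sided
  signed-rank across units.
* **Behavior by microsaccade:** cue-change trials classed by detected
  onsets within ±50 ms of the change (none/toward/away; both-direction
  trials excluded and counted); Clopper–Pearson 95% intervals on hit
  rates, pairwise 2×2 chi-square (no continuity correction) on hit rates,
  two-sided rank-sum on hit RTs.
* **Epoch analysis:** five epochs (200–300, 350–450, 500–600, 650–750,
  800–900 ms); per epoch each trial is none / toward / away / mixed by
  its onsets inside the epoch (mixed excluded, counted — the source is
  silent on this case); the measurement is the mean z in the 100-ms
  window immediately after the epoch (offset configurable for robustness
  sweeps). Note this "no microsaccade in the epoch" rule is deliberately
  weaker than the ±200 ms rule of the timing-matched control; the two are
  never mixed.
* **Peri-microsaccadic analysis:** refuses to run without matched-set
  provenance. Aligned z over ±200 ms; windows before = −60…0 ms,
  after = 40…100 ms; Δ_attention and Δ_suppression are recomputable
  differences of the stored cell means. The companion eye-speed trace is
  averaged over the same events.
* **Motor control:** ipsilateral single-patch trials (no stimulus in the
  RF), events relabeled toward/away relative to the *RF*, three-condition
  timing match, same windows.
* **Position-matched variant:** toward/away × cue-in/out delay events,
  position-matched, then window × attention × direction ANOVA.

## Statistics (`sacattn.stats`)

The factorial ANOVA is fixed-effects and full-factorial on *unit-level
cell means* — unit identity is not a factor. This convention is what
makes the degrees of freedom come out as published: e.g. 68 units ×
5 × 2 × 3 cells gives total d.o.f. 2039 and error d.o.f. 2010; the
before/after design gives 815/804; the two delta designs and the motor
control give 407/402; the position-matched design (two-level microsaccade
factor) gives 543/536. (The source text lists "microsaccade conditions
d.o.f. = 2" for that last two-level factor, which is inconsistent with
its own totals; the totals govern here and the listed factor d.o.f. is
treated as a typo.) Sums of squares are computed from marginal means by
inclusion–exclusion (Type I; identical to II/III on balanced data);
unbalanced or incomplete designs are rejected rather than silently
reweighted, because the matching stage is what guarantees balance. The
d.o.f. and SS identities are asserted on every fit (relative tolerance
1e−8).

Tukey–Kramer: SE = sqrt(MSE/2 · (1/n₁ + 1/n₂)), q = |m₁ − m₂|/SE,
adjusted p from the studentized-range distribution with the full family's
group count and the error d.o.f. (scipy's `studentized_range`
implementation provides the tail probability); with equal cell sizes this
reduces exactly to Tukey's HSD, which the tests verify against an
independent implementation. Directional conclusions (e.g. "cue-in
higher") add a sign requirement on top of the adjusted p.

Rank tests use the exact null distribution for small tie-free samples and
the tie-corrected normal approximation otherwise (scipy `method="auto"`;
verified against full enumeration for n ≤ 8). Fully tied data return
p = 1 with a warning. Binomial intervals are Clopper–Pearson via beta
quantiles.

## Numerical policies and degenerate inputs

Seeded `numpy` Generators everywhere; a run's child seeds derive from one
root `SeedSequence`, so the whole pipeline is reproducible from a single
integer and byte-identical across runs. Degenerate traces (zero velocity
variance) raise an error naming the trial. Zero-variance units are
excluded from normalization with a logged reason. Empty matching bins
contribute no selections (logged, not an error). Analyses whose factors
lose all levels (e.g. an eye model with no microsaccades) are skipped
with an explicit report entry; the no-microsaccade analyses still
complete. Angles exactly at ±90° are deterministic by the half-open
grouping rule; ±180° wraps to +180°.

## Verification scale and what it shows

The recovery runs use the full study scale — 68 units, ten sessions,
~1,900 trials — and check that (i) the measured delay-period modulation
matches a brute-force oracle that integrates each unit's true generative
rate over its actual trials and converts to z with the stored constants;
(ii) the suppression depth estimated from timing-matched aligned counts
(referenced to the no-microsaccade ratio, measured over the sub-window
that tolerates the ~3 ms detection lag) recovers the injected depth
within its 95% Monte-Carlo interval; and (iii) with additive generative
suppression, Δ_attention(before) ≈ Δ_attention(after). Null calibrations
run the screens on 600 null units and the full z-scoring → epoch →
ANOVA → Tukey chain on 500 null replicates of a reduced size (4 units,
120 trials each) — a deliberate choice to keep replicate counts high; the
chain is identical to the full-scale path from binned counts onward.

## Known limitations

Fixed-effects ANOVA on unit-level means ignores within-unit correlation
across cells and session-level clustering; a mixed-effects treatment is
out of scope (as in the source analyses). The suppression-depth estimator
assumes the multiplicative generative form and known latency/duration
when choosing its window. Real-data loaders (tracker and acquisition
formats, blink handling) are not provided; the canonical CSV schemas are
the interchange surface.
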