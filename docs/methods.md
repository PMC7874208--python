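# Methods

## The assay and what the package computes

A head-embedded zebrafish larva (5–6 dpf) is rotated about its yaw axis,
±75° at 0.53 Hz, and filmed at 30 fps in the dark. The illumination pauses
for 16 ms once per stimulus cycle, recording an all-black marker frame, so
cycle boundaries are recoverable from the video alone. One recording is up
to 1,280 frames (~42 s); multi-epoch protocols concatenate several such
recordings with rest periods (which contain no frames) in between.

`vsrkit` computes, in order: the per-frame tail angle (from video, or read
from a trace CSV), the difference signal after rolling-median subtraction,
cycle segmentation with exclusion rules, the per-cycle metric triple,
trial-level temporal statistics, and group statistics.

### Frame-count conventions

`frames_per_cycle = floor(fps / frequency)` = 56 at the standard settings.
The nominal cycle period (1/0.53 Hz ≈ 1.89 s) and the commonly quoted
1.84 s are mutually inconsistent with 56 frames at 30 fps; the frame count
is taken as authoritative throughout because segmentation is frame-based,
so one cycle lasts 56/30 ≈ 1.867 s.

Segmentation forms cycles between consecutive black frames. Frames after
the final black frame form the final (usually partial) cycle when more
than one frame remains; a lone trailing black frame is not a cycle. The
first cycle and the final complete-or-partial cycle of **each epoch** are
excluded, which reproduces the standard count: 1,280 frames with markers
every 56 frames → 22 complete cycles + one 48-frame partial → 21 retained.
Cycles whose difference signal exceeds 45° anywhere are excluded as
startles (the historically manual rule, automated). Exclusion from the
metric analyses is not the same as unobservability: metrics are computed
for first/last cycles too (only startle cycles carry NaN), because epoch
*activity* — used by the recovery-interval statistic — is legitimately
observable in them.

## Tracking

The tracker mirrors the measurement definition rather than porting any
existing implementation: threshold the frame at 40% of its peak intensity,
keep the largest connected component (frames whose region touches three or
more image borders, or that have no region — black frames — fail
individually and are interpolated), skeletonize it, take the longest
geodesic path through the skeleton, orient it by local body width
(distance transform), place the swim-bladder centre at the widest point of
the path, extend the tip by the local half-width to undo skeleton
retraction, and resample to 10 points equally spaced by arc length. The
tail angle is the signed angle between the body axis and the
bladder-centre → tip chord, in (−180°, 180°].

The body axis is estimated once per recording, from the proximal midline
of the first trackable frame, and reused for every frame; for an
axis-aligned mounting it coincides with the image X axis, but the
body-axis definition keeps the measurement meaningful for tilted
mountings. Black-frame detection thresholds each frame's mean intensity at
10% of the recording's median frame mean. A recording in which more than
20% of illuminated frames fail tracking is rejected as unusable. Failed
and black frames are linearly interpolated so cycle frame counts stay
fixed.

On rendered synthetic recordings the full render → track round trip
recovers angles at ≈ 0.5° RMS (acceptance bound 2°) and the black-frame
schedule exactly.

## Metric definitions and numerical choices

* **Rolling median**: centred, window 5 frames (odd windows only); at the
  series edges the window shrinks symmetrically, so the output length
  equals the input length. Implemented directly because library median
  filters pad rather than shrink.
* **Difference signal**: `|α − median₅(α)|`, with invalid frames set to 0.
  The difference is computed on the whole trace first and windowed into
  cycles afterwards, so cycle boundaries do not perturb the median.
* **Normalized integral**: the per-frame mean of the difference over the
  cycle's valid frames (degrees). The per-frame normalization makes the
  quantity duration-invariant, hence comparable across partial cycles.
* **Percent above threshold**: strictly greater than the 5° threshold; a
  frame at exactly 5.000° counts as not above.
* **Active cycle**: `max_tail_angle > threshold`. Under these definitions
  `pct_above_threshold > 0` is equivalent.
* Metric invariants maintained: `0 ≤ normalized_integral ≤ max_tail_angle
  ≤ 45°` for retained cycles, and `pct_above_threshold` is non-increasing
  in the threshold.

## Temporal statistics

* **Half-time**: baseline B = mean normalized integral of the first three
  retained cycles (undefined when B = 0, as in null phenotypes — reported
  as absent). The per-cycle series is smoothed with a centred 3-cycle
  moving average (per-cycle integrals are bursty; a raw first-crossing is
  noise-dominated), and the half-time is the linear interpolation, between
  cycle midpoints, of the first crossing to ≤ B/2 that persists for the
  following cycle.
* **Pauses**: maximal runs of at least two consecutive inactive retained
  cycles (a single skipped cycle is not a pause), duration = run length ×
  cycle duration; rest epochs neither break nor count toward a run.
* **Minimal recovery interval**: over epochs 2…n of a defined-interval
  protocol, an epoch *resumed* if it contains at least one active cycle
  while the preceding epoch's final three cycles were inactive. The
  statistic is the smallest preceding rest over resumed epochs; 0 when no
  epoch ever loses activity (a sustained responder needs no recovery
  time); absent when activity is lost and never resumes. The
  defined-interval protocol uses rests of 20/15/10/5/0 s between six 42-s
  stimuli (equal 5-s steps spanning the 0–20 s range; total 302 s), and
  the prolonged protocol six consecutive 42-s stimuli (252 s).

## Group statistics

Per metric: an omnibus fixed-effects two-factor OLS ANOVA
(genotype × cycle, type-II sums of squares, larvae as replicates), plus
per-cycle contrasts — Welch t-tests for two genotypes, one-way F
otherwise — with Benjamini–Hochberg adjustment across the cycles of that
metric (each metric is its own family; metrics are not pooled).
Significance stars at q < 0.05/0.01/0.001. The BH step-up rule is
implemented from its definition and cross-checked in the tests against
both a literal brute-force evaluation and statsmodels. The
repeated-measures structure (one larva contributes all cycles) is
deliberately ignored to match the fixed-effects analysis standard for
this assay; p-values for the cycle effect should therefore be read as
descriptive, and a mixed-effects treatment is out of scope. Normality
screening reports Anderson–Darling, D'Agostino–Pearson, Shapiro–Wilk and
Kolmogorov–Smirnov (sample-moment) p-values without gating anything.

Under the global null (two groups simulated from identical parameters),
the fraction of 200 replicates with any per-cycle q < 0.05 measures
3–4%, within the ≤ 10% acceptance bound.

## The synthetic generator

The generator produces what the analysis assumes about real recordings: a
slow sinusoidal sway baseline locked to the stimulus (default 5°, the
platform-induced artifact that the rolling median represents), Gaussian
frame noise (0.8° SD), stimulus-evoked bouts, rare startles (>45°,
excursions up to ~110°), black markers every 56 frames, and an epoch/rest
schedule.

Evoked activity follows a phenomenological releasable-resource model,
R ∈ [0, 1]: in each cycle a bout fires with probability `bout_prob`
provided `R ≥ response_threshold`; a fired bout has peak amplitude
`bout_amplitude_deg × R × (1 − adaptation_rate)^c` (c = cycle within the
epoch) and consumes `depletion_per_cycle` (δ) of the pool; during rests R
relaxes toward 1 as `R ← 1 − (1 − R)·exp(−Δt/τ_rec)`. Recovery runs only
during rests — stimulation is treated as continuously depleting — which
encodes the observed need for rest to restore the reflex. Adaptation is a
within-recording gain effect and resets at each epoch; only the pool
carries across epochs (otherwise a compounding gain would silence
sustained responders over multi-epoch protocols, contrary to observation).
No claim is made about vesicle pools or calcium dynamics; the model exists
so the estimators have a ground truth to recover. Pectoral-fin motion and
eye movements are not simulated.

Waveforms: a bout is a half-sine envelope of 6–12 frames carrying a 10-Hz
tail-beat oscillation. The carrier matters: a smooth 6–12-frame hump is
largely absorbed by the 5-frame rolling median (the difference signal
would retain only ~20% of the amplitude), whereas the oscillating bout
survives subtraction — which is precisely the premise of the
median-subtraction design. A startle is a 3-frame C-bend with counter-bend
(relative amplitudes 0.35/1.0/−0.45, peak 85–110°) for the same reason.
All per-cycle random draws are consumed whether or not a bout fires, so
traces with different δ but the same seed share one random stream — this
is what makes activity counts provably monotone in δ at `bout_prob = 1`.

Phenotype presets (the study conditions):

| preset | amplitude | bout_prob | adaptation | δ | τ_rec | threshold |
|---|---|---|---|---|---|---|
| `wild_type` | 25° | 0.95 | 0.02/cycle | 0 | 5 s | 0.1 |
| `mechanotransduction_null` | 0° | 0 | 0 | 0 | – | – |
| `synj1_like` | 25° | 0.95 | 0 | 0.25 | 15 s | 0.2 |

With these defaults the pipeline reproduces the qualitative phenotype
triad: the depletion phenotype is active in its initial cycles, shows a
far lower percentage of active cycles than wild type (~14% vs ~90–95%), a
half-time of ~8 s, and pauses of ≥ 3 cycle durations; the null phenotype
reports zero active cycles; wild type under the defined-interval protocol
reports a minimal recovery interval of 0 s.

The renderer draws a bright larva on a dark background: a head disk
centred on the swim-bladder position and a quadratic-Bézier tail whose
control point lies on the body axis — so the tail's tangent at the
bladder is the body axis for every α, which is what makes the one-shot
axis estimate from the first frame valid — and whose bladder → tip chord
makes exactly the trace's angle α with the axis. Black frames render as
all-zero images. Geometry that would push the tail outside the image
raises an error rather than clipping.

## Validation experiments and their scale

Real group values from animals are not reproducible without the animals;
validation is by parameter recovery and oracle equivalence, at sizes
chosen to keep the whole suite fast on one core:

* **Oracle equivalence** — rolling median, difference signal, per-cycle
  metrics and BH adjustment against independent brute-force
  implementations on ~2,000 random instances; agreement is exact up to
  float summation order (≤ 4 × 10⁻¹⁵).
* **Phenotype separation** — wild type vs null, n = 8 per group, one
  standard recording each: genotype effect and ≥ 15/21 per-cycle
  contrasts significant at q < 0.05. Null calibration: 200
  identical-parameter replicates, any-q rate ≤ 10%.
* **Recovery-constant recovery** — τ_rec ∈ {2, 5, 10, 20, 40} s × 20
  seeds under the defined-interval protocol, with full per-bout depletion
  (δ = 1) and a high response threshold (0.8) so each epoch resets the
  pool and resumption is governed by recovery alone; trials that never
  resume are right-censored at max rest + 5 s for the rank correlation.
  Spearman ρ ≈ 0.97 (bound 0.8). The 5-s rest granularity and the
  accumulation of unspent recovery across consecutive short rests are the
  two resolution limits of this estimator; both are visible in the
  experiment and both would apply to the real assay.
* **Tracking round trip** — an 8-cycle wild-type recording rendered and
  re-tracked: ≈ 0.5° RMS (bound 2°), exact black-frame schedule.

## Known limitations

* The per-cycle contrasts ignore within-larva correlation across cycles
  (fixed-effects convention); group-level inferences are calibrated under
  the simulation's independence across larvae, which the null-calibration
  experiment verifies, but real repeated-measures data would warrant a
  mixed model.
* The generator's bouts are stylized (single burst per cycle, fixed beat
  frequency); passing tests demonstrate correctness of the estimators
  under the stated statistical structure, not robustness to every
  real-world artifact (fin contamination, focus drift, partial
  occlusions).
* AVI decoding requires an ffmpeg-capable imageio plugin; PNG frame
  directories are the always-available input path.
* The tracker assumes a single connected bright larva; multi-animal
  scenes and eye/fin tracking are out of scope.
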