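# Methods

This note documents the models, conventions and numerical choices behind
`baitswitch`, and what the synthetic validation data can and cannot show.

## Data model and conventions

A recording is a dense per-frame pose table (one row per mouse per frame:
ellipse center `x, y` in cm, axial orientation `θ ∈ (−π, π]`, semi-axes
`a ≥ b > 0`, nose position) plus a behavior-event table and an arena
specification. Frames are 0-based; event spans are inclusive
`[start, end]`, so duration = `(end − start + 1)/fps` and an event's end
*time* is the trailing frame edge `(end + 1)/fps`. The arena origin is the
lower-left corner, +x east, +y north. The nose is authoritative for
heading; the ellipse orientation is treated as axial (undirected). The
reader rejects non-dense pose tables rather than interpolating: silent
imputation hides tracking failures, and the generator always emits dense
data. Role conventions for aggressive bouts are fixed: the chasing or
fled-from male is the *aggressor*, the chased or fleeing male the
*aggressed*.

## Social-interaction detection

The social ellipse extends the body ellipse 3 cm along the major axis in
both directions; the minor axis is unchanged (a literal reading of "in
front and behind"). Frame-wise overlap uses the conic-pencil root test:
with both 3×3 ellipse matrices normalized so interiors are negative,
`f(λ) = det(λE₁ + E₂)` is a cubic with `f(0) < 0` and negative leading
coefficient, and the ellipses are disjoint exactly when `f` has two
distinct positive real roots. Tangency (a positive double root) counts as
overlap because closed interiors share a point; numerically, roots closer
than a 10⁻⁷ relative gap are treated as coincident. Cheap bounds
(center distance vs the sums of semi-minor/semi-major axes) short-circuit
most frames; ambiguous frames are solved in batch via companion-matrix
eigenvalues. The test was validated against a 10⁴-point boundary-sampling
oracle (tests reproduce this check) and, in the test suite only, against
an independent polygonal-geometry library.

Bouts are maximal runs of consecutive overlapping frames; runs under
6 frames (0.2 s) are discarded as passing encounters. One-frame gaps are
not bridged. Initiation: speed below 0.023 cm/s at the bout's first frame
marks a mouse stationary, and the other mouse initiates; with both moving,
the mouse whose ellipse front point first enters the partner's social
ellipse initiates, with piercings within 6 frames of each other — or
neither front piercing within the 30-frame scan — labeled mutual. Both
mice stationary is not covered by the source rules; such bouts are labeled
mutual and flagged (`both_stationary`) so initiator-proportion analyses
can exclude them. A center-distance fallback detector (within a threshold
for ≥ 0.2 s) is available behind `method="distance"` for sensitivity
analyses, since proximity-based definitions of interaction also appear in
the literature; the ellipse definition is the operational default.

## Triggered sequences and the difference index

A trigger of a given class (aggression = chase/flee; walking;
investigation) is paired with the earliest male–female interaction whose
start lies strictly after the trigger's start and before the next
same-class trigger's start. Pairing is greedy and one-to-one; a
`pair_with="all"` variant keeps every qualifying interaction, and
`max_window_s` can cap the look-ahead. Latency is defined as interaction
start minus trigger end — positive when the interaction follows the
trigger, negative when it starts while the trigger is still running. (The
opposite sign convention would contradict the reported positive medians
for following interactions, so the reported-value convention is used.) An
interaction already in progress at trigger *start* is not a sequence.

The difference index `(n_first − n_second)/(n_first + n_second)` counts
sequences by the male partner's state (aggressor/aggressed,
walker/non-walker, investigator/investigated); negative values mean the
second-listed state interacted more. The identity-permutation null
re-flips the two males' roles independently per trigger with a fair coin,
keeping order and durations fixed, and recomputes the index per
permutation; `z = (observed − null mean)/null sd`, with an empirical
two-sided p. A whole-recording swap scheme is available as a sensitivity
variant. The subsampling distribution draws k = 50 sequences per recording
per repeat (1,000 repeats) and reports the distribution, the fraction of
repeats below zero, and a z-test of the distribution mean against zero
computed as mean/sd of the distribution — the source's description of this
test ("comparing the data to a normal distribution (mean 0, sd 1)") is
ambiguous, and mean/sd is the reading that makes the test scale-free.

## Circular statistics and zones

Heading angle to target: `θ = atan2(|v₁ × v₂|, v₁ · v₂)` in degrees,
`v₁` the center→nose vector, `v₂` the male→female center vector; the
result is unsigned in [0°, 180°] and snapshotted at the trigger's last
frame. Orientation differences are minimal absolute angular differences
on the full circle. The circular median minimizes the mean circular
absolute deviation over the sample points (ties broken by the circular
mean of the minimizers); circular variance is 1 − R̄. The two-sample
Watson U² statistic is computed from the pooled empirical CDF differences
with the mean-correction that makes it rotation-invariant; p-values come
from label permutation (default 1,000), which is valid at any sample size
and reproducible by seed, rather than from asymptotic tables.

Zone latency measures, per aggressive-bout end, the time until the chosen
male's nose first enters a 6-cm disc. The five default zones sit at
North-central (W/2, 3H/4), South-central (W/2, H/4), West-central
(W/4, H/2), center, and East-central (3W/4, H/2) — a symmetric placement
consistent with the compass names, which are the only placement
information available. Events with no entry before the next trigger (or
recording end, per config) are excluded and counted. Both mean (default)
and median aggregation are exposed, since the source describes averaging
but tests medians.

## Decoding harnesses

Every decoder follows one protocol: repeated unstratified uniform 75/25
train/test splits; held-out accuracy in percent; chance = 100/n_classes;
`z = (mean − chance)/sd` over iterations with a one-sided normal p, and
z > 1.96 read as above chance. Binary tasks use an axis-aligned decision
tree with impurity splits, no depth cap and leaf size 1 (no
hyperparameters are specified by the source; these are the common
defaults). Multiclass tasks use a linear-kernel SVM with standardized
features and one-vs-one aggregation. Per-iteration model seeds derive from
the master seed. Degenerate training splits containing one class predict
that class; test splits missing a class are allowed (no stratification).
Controls: size matching undersamples majority classes to the minority
count; randomization redraws trigger start times uniformly (durations and
roles kept, non-overlap within the class enforced by rejection) and
re-runs sequence extraction, which empirically returns state decoding to
chance on biased synthetic data.

## Three-step sequences

si1 is the trigger's paired interaction; si2 is the next male–female
interaction starting after si1 ends, with no window bound by default
(a configurable cap exists) — the source gives no bound. An si2 by the
same male is excluded and counted. Types: (aggressed, F) → (aggressor,
same F) = 1; (aggressor, F) → (aggressed, same F) = 2; same male states
with the other female = 3 and 4 respectively. Type proportions are
compared to the trigger-time-randomized null by per-type z-scores.

Distance profiles split each sequence into trigger, latency gap, si1 and
a 5-s post window, and resample each phase linearly to that phase's
dataset-wide maximum length (per-phase maxima rather than one global
maximum: the four phases have incommensurate natural lengths, and a
single-global-max option would distort short phases; endpoints are
preserved exactly, and an empty gap contributes its boundary value).
Snapshots are taken at si1 start + 1 s and si1 end + 1/2/3 s. Fights are
attributed to the most recent typed sequence whose si2 ended before the
fight starts, provided no new aggressive trigger intervened; earlier
fights and fights with an intervening trigger are counted as
unattributed. The attribution window is a documented choice — the source
only says fights were counted "after" sequences.

## Synthetic recordings

The generator's defaults are the canonical study conditions: 2 males + 2
females, 76.2 cm square arena, 30 fps; post-aggression approach latencies
log-normal with medians 0.73 s (aggressed) and 3.15 s (aggressor);
interaction durations 0.81 s / 1.06 s; heading-to-female angles folded von
Mises with centers 41.34° / 75.94° (κ = 8); three-step type mix
0.53/0.21/0.09/0.17; fight probability 0.1 after type-1 and 0.6 after
other sequences; control (walk/investigation) approaches with a common
~3.85 s latency and ~1.2 s duration for both roles. The aggressed male
performs the first approach with probability `type₁ + type₃ = 0.62` by
default; setting `p_aggressed_first_approach` overrides this while keeping
the same-female conditionals. Per-encounter roles are exchangeable between
the two males by default (`dominance_bias = 0.5`): the phenomenon under
study is state-dependent, not identity-dependent, so the parsimonious
generative model carries no identity effect; a bias parameter exists for
asymmetric groups. Only medians are matched for latencies and durations —
the source reports medians and IQRs, not full distributions, so log-normal
shapes (σ = 0.55 and 0.25) are an assumption and recovery tests target
medians only.

Movement: each mouse wanders around a home anchor (smoothed-noise walk
with a transit interpolator capped at 60 cm/s); anchors are ≥ 45 cm apart
so unscripted pairs never overlap. Scripted segments override the wander:
chases run through the central zone with the aggressor trailing the
aggressed by ~0.27 s; approaches move the male radially toward the target
female, whose pose is frozen during the approach and contact so that the
first overlapping frame — solved by bisection against the package's own
overlap test — lands exactly on the scheduled interaction start, and the
overlap run has exactly the scheduled duration. The freeze also makes the
male the unambiguous initiator. The nose leads the center along the
velocity (or scripted approach) direction; at the trigger's last frame the
approaching male's heading is set at the sampled von Mises angle from the
male→female vector, so heading analyses measure the configured bias
exactly. After each contact the male is scripted to retreat well clear of
the female, preventing re-entry artifacts. Fights are placed ~1 s after
si2 with the per-type probability; they are events only (no scripted
grappling kinematics).

What passing tests on this data do and do not show: they demonstrate that
detection, extraction, permutation, decoding and typing recover the
generating parameters through the full pipeline (end-to-end recovery is
≥ 95% exact per trigger, and type labels match ground truth), and that all
null calibrations hold. They do not demonstrate robustness to real
tracking artifacts — identity swaps, missing frames, ellipse-fit noise,
three-mouse contacts, or females that keep moving through contact — none
of which the generator emulates. Exploration coverage of anchored
wanderers is also far below that of real mice; coverage is validated on
constructed trajectories instead.

## Problem sizes and tolerances

Default simulations are 10-minute recordings with 30 aggressive events
plus 8 walks and 8 investigations; statistical validation uses 36-trigger
recordings across 20 seeds per bias level (approach-bias recovery), one
500-trigger run (type mix and fight rates, checked at 3 multinomial /
binomial SE), 150-trigger runs for decoding, 500 decoder iterations for
chance calibration (|z| < 3), and 500/200 simulation runs for Watson U²
type-I error and power. Circular-median ties use the circular mean of tied
candidates; the overlap test resolves tangency as contact; permutation
p-values use the add-one convention `(1 + #extreme)/(P + 1)`. All
randomness flows from explicit seeds; the pipeline derives per-stage seeds
from the master seed and stage name so stages can be re-run in isolation.

## Known limitations

Interactions among three or more mice are treated pairwise; contact-type
classification (nose-to-nose vs anogenital) is out of scope; dominance
ties raise an error by default (a total-aggressive-time tie-break is
opt-in); the reader supports only the documented CSV dialects; and the
generator's movement model is deliberately schematic — it exists to carry
the statistical structure of the behavioral sequences, not to imitate
mouse locomotion.
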