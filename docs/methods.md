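# Methods

## Model and numerical realization

The network model maps four stimulus channels (motion left/right as
coherence fractions, luminance left/right as normalized hemifield
brightness) to a left-swim probability through three parallel leaky
pathways, a contralaterally wired repulsive change pathway, and a final
multifeature integration stage. Leaky integration is convolution with the
30-second kernel `K(t) = (1/τ) e^{−(t−15)/τ}` for t > 15 s and 0 otherwise.
The zero first half makes a centered (same-length) convolution strictly
causal; we implement it directly as a causal FIR filter and test the
equivalence of the two constructions. Two numerical choices matter:

- **Kernel normalization.** A plain Riemann sum of the sampled kernel has
  a gain bias of order dt/(2τ) (≈5 % at τ = 1, dt = 0.1 s), which leaks a
  spurious steady offset into the rectified change detectors. The discrete
  causal weights are therefore rescaled so that their sum times dt equals
  the exact continuous integral `1 − e^{−15/τ}`. The kernel's 15 s
  truncation itself is part of the model: a constant input leaves a
  residual `e^{−15/τ}` on the change detectors, which acts as a small
  sustained load on both multifeature nodes.
- **Stationary history.** Each input channel is padded at the front with
  15 s (one kernel memory) of its initial value before convolution and
  cropped afterwards. Physically, the pre-stimulus background has been on
  for a long time; without the padding the 10 s pre-phase cannot settle
  the integrator baselines and the pre-stimulus window of the imaging
  analysis is contaminated by a start-up ramp.

Where both multifeature nodes are numerically zero (below 1e−12) the swim
ratio is defined as 0.5 — chance is the only symmetric choice. The 2 s
rolling mean over the ratio is a trailing window (the window holds the
past), matching the behavioral windowing. Halving dt changes the readout
by < 1e−2 sup-norm (tested).

The behavioral fitting loss targets the rolling percent-left timecourse,
so the fitting path uses a vectorized batch implementation of the readout
(`swims_left_batch`), verified against the reference simulation to 1e−9.

Simulation for the imaging grid runs at dt = 0.1 s and is resampled to the
0.5 s imaging discretization; simulating directly at 0.5 s under-resolves
the change-pathway transients.

## Stimulus encoding

Left/right are fish-centric; mirroring of behavioral data happens in the
behavior module only. A lateral luminance cue sets the bright hemifield's
channel to `bright_level` and the dark one's to `dark_level`; homogeneous
backgrounds set both channels to the background level (black 0, gray 0.5,
white 1). The behavioral battery mixes the three semicircle pair types
used experimentally — black-and-white, gray-and-white, black-and-gray —
across backgrounds; the battery composition (10 stimuli per class: sides ×
coherences 0.25/0.5/1.0 × background/pair variants) is configurable, with
only the total of 40 and the four-class structure fixed.

The nine imaging stimuli (3 motion × 3 luminance sides; 10 s pre, 30 s
stimulus, 20 s post) use the measured projector brightness ratios of the
imaging setup, bright : background : dark = 4 : 2 : 1 in lux, encoded as
1.0 / 0.5 / 0.25. This asymmetry around the background is load-bearing:
the classifier statements that compare contralateral against ipsilateral
onset responses (with factors 1.25–1.5) hold on the model's own
change-pathway nodes only because a bright cue deviates from background by
+0.5 while a dark cue deviates by −0.25.

## Side-labeling convention

Integrator nodes are labeled by their own side. The change-family nodes
(change/increase/decrease detectors) are repulsive and wired
contralaterally, so they are labeled by the side they *drive behavior
toward*: the "leftward luminance change detector" is the node monitoring
the right hemifield. Functional maps in this preparation show leftward
driving stimuli represented in the left hemisphere, and under this
convention — and only under it — the logical statements are satisfied by
the model's own nodes (12/12 self-consistency, tested).

## Generative defaults (the synthetic study conditions)

The synthetic cohorts define the conditions under which every downstream
stage is validated. Defaults, chosen once:

- `ModelParams`: w_m = 1.0, w_ll = 0.15, w_lc = 0.7; τ_m = τ_ll = 4 s,
  τ_lc = 5 s, τ_mf = 2 s. Constraints honored: all time constants of the
  same order with the change pathway slightly slower; motion carries the
  strongest weight, the change weight close to it, the level weight minor;
  steady-state single-feature following around 65–80 % rather than
  saturated (luminance responses transient-dominated with a slight
  sustained preference); and silencing motion degrades held-out prediction
  more than silencing either luminance pathway. Because the swim ratio is
  invariant to a common scaling of the three weights, only their relative
  magnitudes are identified and recovery checks compare sum-normalized
  weights.
- Behavioral emission: bouts are a renewal process at 2 bouts/s (typical
  free-swimming rate); each turn's direction is Bernoulli in the model's
  *instantaneous* ratio (the 2 s mean exists to match the windowed bout
  analysis and must not enter the generative draw a second time). Turn
  magnitudes are |N(20°, 10°)| clipped to stay turns; 25 % of bouts are
  forward (|Δθ| ≤ 2°). These emission values are fixtures, not claims.
  Optional swim-drive modulation uses rate = base·(1 + g·max(MF_L, MF_R)):
  under convergent initiation the *winning* multifeature unit reaches the
  initiation threshold, and the bilateral sum — identical for congruent
  and conflicting arrangements in an additive model — could not produce
  the shorter congruent interbout intervals the modulation is meant to
  emulate. g defaults to 0.
- Per-fish heterogeneity: lognormal jitter (σ = 0.1) on all weights and
  time constants.
- Calcium traces: min-max-normalized node activity plus Poisson spikes
  (0.05 events per 0.5 s bin, amplitude 1 — the rate is a documented
  default, configurable), convolved with a unit-sum causal exponential
  GCaMP kernel (τ = 2.4 s), plus i.i.d. Gaussian noise (benchmark scales
  0.3–2.0). Synthetic traces are treated as dF/F0-scale signals directly;
  `dff0` (baseline = 0–10 s mean, nonpositive baselines flagged and
  excluded) applies to raw-fluorescence inputs.

What the generator does *not* emulate: arena geometry and wall-following,
image-based tracking noise, slow behavioral state drift, correlated noise
across neurons, or the real cohort's variance structure. Passing tests
therefore demonstrate the internal consistency and recoverability of the
analysis under its own assumptions, not its performance on real data.

## Fitting protocol

Data are split 50/50 into training and validation groups: either all
single-feature stimuli train and all combinations validate (unifeature
mode), or half the fish train across all stimulus types (multifeature
mode). Each training round splits the training group's fish 2/3–1/3,
draws restarts — each restart subsamples 20 stimuli as its fitting target
(the subsample semantics are configurable; per-restart is the default
reading) and a uniform-random initial guess inside the bounds — and runs
bounded trust-region least squares (τ ∈ [0.1, 100] s, w ∈ [0.1, 25]); the
restart with the best inner-test MSE survives. The loss is the MSE between
the model's percent-left timecourse and the pooled observed one, at
defined (non-missing) time points only. All randomness flows through one
seeded generator. Ablations fix the silenced weight at 0, which also
removes its time constant from the free set, and refit.

Problem sizes in the validation suites (15 fish × 4 trials per stimulus,
5 rounds × 3 restarts over 10 cohorts for recovery; 12 fish and 3 × 3 for
the ablation comparison; 25 neurons per type and 4 noise levels × 3 rounds
for the classifier benchmark) are the package's reduced-scale defaults for
routine validation; the full protocol (25 × 5, 100 neurons, 5 repeats)
remains the default of the public API.

## Behavior analysis choices

Bout detection thresholds the 50 ms rolling orientation variance with
hysteresis (start: > 1 deg² for ≥ 20 ms, end: < 0.5 deg² for ≥ 50 ms).
Positive orientation change is a leftward turn (the convention is
arbitrary and cancels in mirrored metrics). The orientation-change filter
uses the absolute value; the interbout interval is start-to-start and is
undefined for a trial's first bout. The trial-drop rule (> 5 % flagged
bouts) counts tracking-error flags only (long gaps, oversized contours,
implausible speed, head-tail swaps); edge proximity is an analysis
exclusion, not a tracking error. Windows with no binarized bouts yield
missing values, never zeros.

## Classifier engine

The logical statements are pure data: each rule is a conjunction of atoms
(stimulus selector over motion/luminance sides relative to a hemispheric
hypothesis, window(s), comparator, optional factor/offset constants, and
an optional cross-referenced right-hand stimulus). A bracketed selector
expands to its Cartesian set and the atom must hold for every member and
window pair (universal quantification — the set-average reading is the
open alternative). "Any" covers {ipsi, contra, off}. Types are evaluated
under both hemispheric hypotheses; a neuron may carry multiple labels, and
one passing both hypotheses for the same type is ambiguous and excluded
from maps by consumers. The canonical stimulus order a–i is row-major
motion {left, right, off} × luminance {left, right, off}.

## Known limitations

- Weight magnitudes are identified only up to scale (ratio readout).
- τ_ll is the weakest-identified time constant at the default truth (its
  weight is small); recovery meets the 25 % criterion in the median but
  individual cohorts can exceed it.
- The WTA steady-state model's "weaker stimulus" is defined as the feature
  with the smaller absolute contribution to the sigmoid argument at the
  current parameter iterate; the fit surface is therefore piecewise and
  the optimizer's covariance estimate is meaningless (suppressed).
- The exact 40-stimulus composition and the clutch sensitivity factors are
  configurable defaults (sensitivity 1.0), not reproductions.
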