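# Methods

This note documents the models implemented in `vibrafall`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions a maintainer would want to know.

## 1. Event model and features

An event is one `AccelRecord`: an `n_samples × n_sensors` matrix of floor
acceleration in g at a fixed sampling rate (default 1,652 Hz, the
acquisition rate of the laboratory design the presets replicate). Records
need at least two sensors because the correlation view is built on sensor
pairs. Continuous streams can be cut into events with a threshold trigger
(`segment_event`), but the canonical workflow is one event per record.

Three views are extracted per event:

| view   | definition                              | width (n sensors) |
|--------|------------------------------------------|-------------------|
| peak   | `max |a(t)|` per channel                 | n                 |
| energy | `∫|a(t)| dt`, trapezoidal at step `1/fs` | n                 |
| corr   | Pearson ρ per unordered channel pair     | n(n−1)/2          |

Notes:

* The energy statistic integrates the **rectified** signal, not its square;
  the name is kept for continuity with the detector it implements.
  Trapezoidal integration is declared normative for tests (the integral
  itself has no canonical discretisation).
* A zero-variance channel makes ρ undefined; `sensor_correlation` returns
  0 with a `RuntimeWarning` — the uninformative value of the statistic —
  so degenerate synthetic channels cannot produce NaNs downstream.
* Each view is z-scored with mean/SD of the **labelled training rows
  only**, stored with the model. RBF kernels need comparable scales, and
  restricting the statistics to labelled rows keeps unlabelled and test
  data out of the transform.

## 2. The detector

One `SVC(kernel="rbf")` per view. `C` defaults to 1; `gamma` defaults to
the median-pairwise-distance heuristic `1/(2·median²)` computed on the
standardised labelled rows of each view. Pseudo-labelled rows enter the fit
with `sample_weight = C*/C` (default `C* = 0.5·C`), which is exactly the
reduced-penalty term of the semi-supervised objective.

Tri-training, per iteration and per view *j*:

1. **Candidates**: unlabelled rows with decision value `0 < |y_j| ≤ 1`
   (the margin band — the only rows that can move the hyperplane), ranked
   by `||y_j| − 1|` ascending, i.e. nearest the margin edges first, where
   pseudo-labels are most reliable.
2. **Labelling**: a candidate is accepted only if the *other two* views
   agree on its label, and (by default) both place it **outside their own
   margin bands** — confident agreement. View *j* never trains on labels
   derived from its own predictions; each view keeps its own pseudo-label
   set. A shared pool was tried and rejected: wrong peer-agreed labels
   feed back into the classifiers that produced them, and on overlapping
   data the minority (fall) class collapses.
3. **Balance**: additions are capped per iteration (`add_cap`, default
   10 % of the pool) and held at the labelled class ratio, scaled down to
   the scarcer class. One-sided additions otherwise walk the boundary into
   the minority class — the same pathology the balance constraint of
   transductive SVMs guards against.
4. **Flip removal**: a pseudo-labelled row whose peer endorsement changes
   (peers now disagree, or agree on the other label) returns to the pool.
5. **Stopping**: no additions and no removals, or `max_iter` (default 20).
   `max_iter=0` is the purely supervised three-view vote.

Two error-control mechanisms are on by default and can be disabled:

* **Error-rate gate** (`error_gate`): view *j* accepts pseudo-labels only
  if the joint error of its two peers — estimated by stratified 5-fold CV
  on the labelled rows, on the subset where the peers agree — is below the
  view's own CV error. Training-set errors are useless here (an RBF-SVM
  nearly interpolates); CV is the cheapest honest estimate.
* **Validated acceptance** (`validate`): after co-training, the co-trained
  and supervised ensembles are compared by per-fold refits on the labelled
  rows, and the co-trained model is kept only if a paired sign test on the
  discordant rows shows net wins exceeding `2·√(wins+losses)`. Chance-level
  improvements are rejected; the detector then falls back to its
  supervised baseline (`stop_reason_ == "reverted"`). This makes the
  semi-supervised step "help or do no harm" by construction, at the cost
  of forgoing gains too small to distinguish from CV noise.

Fusion is the majority vote of the three views; three binary voters cannot
tie, so no tie-break rule exists. The labelled subset used in experiments
is sampled stratified by class so both classes survive low labelling rates.

## 3. Fall load model

The vertical floor force of an unconscious backward fall is assembled in
four stages over a 2 s window (boundaries 0.25 / 0.75 / 1.75 / 2.0 s,
rescaled proportionally for other record durations):

1. **standing** — `F = M g`;
2. **falling** — parabola `M g ((t_fall − t)/(t_fall − t_stand))²`: value
   `M g` at the stage start, zero value *and slope* at lift-off, so the
   force dips smoothly to zero;
3. **impact** — the supine body as three independent damped oscillators
   (hip, back, head): `m_i ẍ_i + c_i ẋ_i + k_i x_i = 0` with
   `ẋ_i(0) = √(2 g h)` (free fall of the centre of gravity from standing
   height `h`) and `ẍ_i(0) = g`. These two initial conditions
   over-determine a second-order ODE unless the initial displacement is
   back-solved from the equation of motion at `t = 0`:
   `x_i(0) = −(m_i g + c_i √(2 g h)) / k_i`, the only choice making both
   hold. The floor force is
   `F = Σ m_i (ẍ_i + g) + (M − Σ m_i) g` — per-mass dynamic reaction plus
   the static weight of mass not carried by the oscillators. (The same
   balance is sometimes written `F = Σ m_i ẍ_i − m_i g` with the axis
   pointing down; that form is negative at rest, so the axis-up convention
   is used here.) The jump at impact onset is physical shock; `F ≥ 0` is
   *not* enforced — the oscillation legitimately crosses zero, and
   clipping is deliberately not applied.
4. **resting** — `F = M g`.

The free vibration is solved in closed form for any damping ratio
(under-, critically and over-damped branches), so profiles are exact at any
sampling rate — no integration error, verified against an adaptive
Runge–Kutta integrator to 1e−6 relative over random parameter draws.

**Default body parameters.** The standard vertical-impedance body model the
impact stage idealises publishes its parameters in a separate standards
document; this package therefore ships its own documented default set at a
75 kg reference — hip/back/head masses (27, 33, 5.5) kg, per-DOF natural
frequencies (4, 6, 12) Hz, damping ratios (0.35, 0.30, 0.25) — scaled
linearly with body mass (frequencies and damping ratios invariant), with
`h = 0.55 ×` standing height. All tests are written against this config,
not against literature values, and every entry is overridable through
`BodyModelParams`.

## 4. Synthetic floor and scenario generator

The floor is a simply-supported rectangular plate (default 4 m × 5 m,
surface density 480 kg/m² ≈ a 0.2 m concrete slab) reduced to its first
5 × 5 closed-form modes. Modal frequencies follow the plate law anchored at
a configurable fundamental (default 16.7 Hz, a stiff slab floor); damping
is 3 % on every mode. The acceleration at a sensor is the modal
superposition of each mode's response to the point force, computed by
discrete convolution with the sampled unit-impulse response (FFT-based,
kernels cached per record length). Responses are linear in the force and
exactly match the closed-form damped sinusoid for a one-sample impulse.

Activity force generators (per event):

* **fall** — the four-stage model above; forward falls apply a ×1.3 impact
  damping multiplier (a single documented knob; no separate forward-fall
  model exists);
* **walk** — a moving source along a straight path: per-step 0.45 s
  half-sine support force (peak 1.3 × body weight) plus a 20 ms heel-strike
  transient; each footstep excites the plate at its own position and the
  responses superpose;
* **free_jump** — 2–4 landing impulses at random times, landing velocity
  from jump heights of 0.05–0.25 m, 60 ms half-sine carrying the landing
  momentum `m·v`;
* **rhythmic_jump** — the same landing pulse at a metronome rate (default
  1.5 Hz = 90 bpm, jitter configurable, default 0);
* **bag_drop / ball_drop** — a single impulse with peak proportional to
  `mass · √(2 g h_drop)`; the bag lands dead (25 ms pulse), the ball
  (15 ms pulse) rebounds with restitution 0.6 for up to three bounces.

Pulse durations were calibrated once so that the *relative* per-class
feature magnitudes match the published laboratory examples (fall peaks
roughly twice bag-drop peaks, free jumps below bag drops, walking smallest
— drops and falls being the classes a detector confuses). Event-to-event
variability: lognormal force-amplitude factor (σ = 0.3), excitation-position
scatter (SD 0.6 m around the nominal points, clipped to the plate — a
falling body is itself ~1.7 m long, so sub-metre scatter is realistic), and
zero-mean Gaussian sensor noise of SD 0.001 g, the order of a walking peak.
With these settings the supervised detector at a 20 % labelling rate
reaches ≈ 91 % accuracy with headroom to ≈ 94 % at full labelling — the
regime in which a semi-supervised method has something to gain, matching
the accuracy span the laboratory study reports.

Two presets replicate published experiment inventories exactly:
`lab_table1` (520 falls: 75/48 kg × 2 positions × 2 directions; 130 walks;
260 each of free jumps, rhythmic jumps, bag drops at 5/10 kg from 0.6 m,
ball drops at 0.6 kg from 1.45/2.10 m; 4 sensors, 1,652 Hz) and
`benchmark_table8` (1,725 falls at 60/70/80 kg plus 7,475 daily events;
the source publishes only the daily-event total, split here near-equally:
2,492 bag drops, 2,492 ball drops, 2,491 free jumps). List-valued
parameters are cycled across events for a balanced design. Identical
(design, floor, seed) produce bit-identical datasets. Note the laboratory
description gives the bag-drop height as 0.6 m in the text and 6 m in the
summary table; the preset uses 0.6 m. Similarly the dummies are described
as both 70 kg and 75 kg in different places; the preset uses 75 kg.

**What the generator does not emulate.** Real floors are not simply
supported plates: beams, walls and non-uniform slabs shape mode patterns;
sensor mounting, cable noise and environmental vibration are absent; human
falls vary far beyond an amplitude factor and a damping multiplier; and the
generator's classes are, by construction, separable by the very features
the detector uses. A passing suite therefore shows that the pipeline is
correct and that the semi-supervised machinery helps (or provably does no
harm) *under these conditions* — it does not predict detection accuracy on
a real building.

## 5. Evaluation

Falls are positive. `sensitivity = 100·TP/(TP+FN)`,
`specificity = 100·TN/(FP+TN)`, `miss = 100 − Se`,
`false alarm = 100 − Sp`, `accuracy = 100·(TP+TN)/n` (defined explicitly
because summary tables often leave it implicit). The false-alarm rate is
also broken down per non-fall activity. A test set with no positives makes
sensitivity *undefined* (reported as the string `"undefined"`, never NaN).
Metrics are reported to 2 decimals; tests compare exact counts.
`relative_change(new, old) = 100·(new − old)/old` (2 decimals) is the
single normative definition of a percentage gain.

The autocorrelation baseline classifies an event by the Euclidean distance
between the normalised autocorrelation of its strongest channel (up to
`lag_window` lags) and per-class mean autocorrelation templates from the
training data. It is a deliberately simple stand-in for
autocorrelation-difference activity classifiers used as comparison
baselines, documented as such — not a re-implementation of any specific
published detector.

## 6. Numerical and design notes

* Gravity is fixed at 9.81 m/s².
* Closed-form branches switch at `|ζ − 1| ≤ 1e−12`; energies, forces and
  responses are float64 throughout.
* `infer_n_sensors` inverts `d = 2n + n(n−1)/2`; stacked matrices with any
  other width are rejected rather than guessed.
* Experiment problem sizes: the labelling-rate study in the test suite
  runs the full 1,690-event laboratory design with 15 repeats per rate —
  about half a minute — chosen as the smallest replication that averages
  out split noise. The benchmark design (9,200 events) is generated once
  to verify its inventory.
* HDF5 round trips are bit-exact; CSV round trips are exact to ≤1e−9
  relative (17-significant-digit decimal text).
* Model archives (`save_model`) carry a schema version; loading any other
  version fails loudly.
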