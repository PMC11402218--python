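# Methods

This note documents the models and procedures implemented in `wfopto`,
the parameters that matter, the assumptions behind the synthetic-data
generator, and the numerical choices made where the design was open.

## Task and session model

Trials of a delayed two-alternative visual task are sampled on a 20 Hz
frame grid over a window of −1.0 to +3.0 s around visual-stimulus onset
(80 frames): a 500 ms lateralised stimulus, a 1500 ms memory delay, and
a 500 ms response window starting at 2.0 s in which the animal licks the
left or right spout. All times are stored in seconds relative to
stimulus onset; epochs are half-open `[start, end)` so shared boundaries
never double-count. Sides are labelled `contra`/`ipsi` relative to the
optogenetically stimulated hemisphere, which occupies the left half of
the pixel grid.

Optogenetic trials are tagged with a stimulation-onset epoch (baseline
−0.5 s, visual 0 s, delay 1.0 s, response 2.0 s) and the stimulation is
modelled as a 1 s boxcar from that onset. The physical pulse train
(tens of hertz, ~10 ms pulses) is faster than the frame period, so an
epoch-level boxcar is the finest structure the imaging could resolve;
pulses are deliberately not modelled.

## Synthetic-data generator

Raw fluorescence is additive over a baseline `f0 = 1`:

```
F(y,x,t,trial) = f0
  + Σ_events  beta_map(y,x) · (event impulses ⊛ calcium kernel)(t)
  + memory-trace term during the late delay (below)
  + opto_effect_map(y,x) · stimulation boxcar(t)
  + coupling_map(y,x) · continuous traces(t)
  + N(0, noise_sd)
```

- **Calcium kernel**: causal difference of exponentials (rise 50 ms,
  decay 400 ms), unit area, truncated at 2 s. Any causal kernel would
  do; this one is configurable.
- **Event maps**: Gaussian blobs centred on ROIs — stimulus responses in
  V1 of the hemisphere contralateral to the stimulus, lick responses in
  M1 of the hemisphere driving the movement. Peak weight
  `amplitude = 0.2` (with the unit-area kernel this yields ~4–5% ΔF/F
  transients). The default pixel noise `noise_sd = 0.02` is 10% of the
  peak map amplitude.
- **Memory trace**: two fixed templates (M2 + PPC blobs, amplitude
  0.04 ΔF/F) — the contra template in the stimulated hemisphere, the
  ipsi template mirrored. During the late delay (1.2–1.9 s) the pixel
  pattern is `½(T_c+T_i) + ½·m·(T_c−T_i)` with per-trial strength
  `m = ±1 (stimulus side) + N(0, memory_noise_sd) + opto bias`.
- **Choice model**: the simulated decision variable is the rendered
  late-delay pattern projected onto `T_c − T_i` (recovering `m` plus a
  small sensor-noise term), plus downstream motor noise
  `N(0, decision_noise_sd)`; the choice is its sign. Omissions are
  drawn independently (5%) and produce no response-window licks.
  Defaults `memory_noise_sd = 0.8`, `decision_noise_sd = 1.3` put task
  accuracy near the ~74% of trained mice while keeping the stimulus
  decodable from the late delay even on error trials — most errors
  arise downstream of the trace, which is what lets a late-delay
  stimulus decoder generalise across outcomes.
- **Optogenetic regimes**: `global_excite` adds a non-negative map over
  the whole grid (strongest over the stimulated hemisphere);
  `local_suppress` a non-positive map confined to it. Both additionally
  bias the memory strength by `±opto_memory_bias/template_amplitude`
  (default ratio 0.75) on stimulated trials — global excitation pushes
  the trace toward the contra template, local suppression erodes it.
  This term is what makes early stimulation detectable in late-delay
  activity and gives the cross-condition transfer test its signed
  structure.
- **Licks**: piecewise-homogeneous Poisson trains. In the response
  window only the chosen side licks (6 Hz); afterwards both sides lick
  at 1 Hz; stimulated trials add a 3 Hz contraversive (excitation) or
  ipsiversive (suppression) increment during the boxcar. The outcome
  label is derived from the first response-window lick, so
  `omission ⇔ no lick in the response window` holds exactly.
- **Nuisance traces**: body and eye movement are AR(1) processes
  (ρ = 0.95 / 0.85) run across the concatenated session, min-max
  normalised to [0, 1], coupled into every pixel with small random
  positive maps (peak 0.02 ΔF/F).
- **Seeding**: one master seed feeds named independent substreams
  (schedule, truth, continuous, memory, noise, outcomes, licks), so
  perturbing one stage leaves the others bit-identical.

What the generator does **not** emulate: hemodynamic contamination,
photobleaching, motion artifacts, camera quantisation, pulse-resolved
opto waveforms, or anatomically realistic area shapes. Tests passing on
synthetic sessions therefore validate the statistical machinery, not
robustness to those real-data nuisances.

## Preprocessing

ΔF/F is computed per trial and pixel against the mean (optionally
median) fluorescence in a 300 ms window ending at the trial's reference
event — the earlier of stimulus onset and optogenetic onset. Pixels
with a non-positive baseline in any trial are flagged invalid, never
silently zeroed. Smoothing is a per-frame 2-D Gaussian (σ = 2 px
default) with masked renormalisation so invalid pixels neither receive
nor contribute mass. ROI traces are unweighted means over the valid
pixels of each mask. The pipeline order is fixed: ΔF/F → smooth →
aggregate.

The engagement filter includes a trial when accuracy (omissions
excluded) exceeds 55% for each stimulus side within a centred 50-trial
window, truncated at session edges; a side absent from the window makes
the criterion undefined and the trial is excluded (conservative).
Whether omissions belong in the filter's denominator is ambiguous in
the field; they are excluded here for consistency with the accuracy
definition.

## Encoding model

Every event predictor is time-expanded: an event occurring at frame k
of a trial contributes lagged indicator columns covering frames k to
the end of the trial (configurable `kernel_len`); all-zero lag columns
are pruned. Stimulus side enters as two sub-predictors (contra/ipsi
onsets) forming one `stimulus_side` group; optogenetic stimulation and
each lick side are their own groups. Continuous predictors enter as
single columns, re-baselined per trial (their mean over the same
pre-event window used for ΔF/F is subtracted) before min-max
normalisation — the response variable is per-trial baseline-subtracted,
and an un-rebaselined nuisance column would leave per-trial offsets
unexplainable by construction. This re-baselining can be disabled.

Ridge solutions use the eigendecomposition of the centred Gram matrix,
which handles the whole α grid and per-pixel penalties in one pass; the
intercept is unpenalised via the exact centering equivalence (a strict
mode penalising all columns, including the intercept, is available).
Near-zero eigendirections are dropped, so α = 0 coincides with the
pseudo-inverse least-squares solution and rank deficiency cannot
produce exploding coefficients. `ridge_solve` itself checks rank
explicitly at α = 0 and raises.

α is selected per pixel on a grid of 0 to 50 in steps of 0.5 (101
values, both ends inclusive) by holding out one-third of the training
trials; ties go to the smallest penalty. R² is pooled over trial-wise
3-fold cross-validation — residual and total sums of squares are summed
across folds, the total taken around each fold's own test mean — rather
than averaging per-fold R², which is unstable for small folds. Folds
are whole trials, seeded and recorded.

ΔR² rotates a group's per-trial event assignment circularly across the
trial sequence (offsets sampled without replacement from 1..n−1 when
possible), preserving the within-trial lag structure, and recomputes
the full cross-validated fit, including α re-selection, per rotation.
ΔR² is the intact R² minus the mean rotated R²; significance compares
the intact R² with the 95th percentile of the rotated distribution.
Note what this null tests: for predictors present on every trial (the
stimulus), rotation randomises the side assignment, not event presence,
so the side-independent response component remains explained under the
null — ΔR² isolates the side information, which is the quantity of
interest. The default 500 rotations are reduced (to 100) in the
calibration studies for runtime, which leaves the rank-based test exact.

## Decoding

Features are epoch-mean ΔF/F per valid pixel, optionally
block-averaged, z-scored with training-fold statistics only. Trials
are balanced to equal correct/error × contra/ipsi counts (the smallest
cell sets the count; omissions never enter), and folds are stratified
over those four cells.

The dirty model minimises
`Σ_t ‖X w_t − y_t‖² + λ_B Σ_rows ‖B_row‖_∞ + λ_S ‖S‖₁` with
`W = B + S`, solved by monotone accelerated proximal gradient: the
ℓ∞-prox is computed through the Moreau identity with a row-wise ℓ1-ball
projection, the step is 1/L with L = 4·σ_max(X)² (the exact Lipschitz
constant of the coupled gradient), and momentum steps that would raise
the objective fall back to plain proximal-gradient descent, so the
objective is non-increasing by construction. The penalty pair is
selected per epoch by an inner 3-fold grid search over a log-spaced
grid anchored at the smallest penalty that zeroes all weights; ties
prefer the sparser model. Squared loss on ±1 labels keeps the solver
convex and the objective comparable with the exact block-coordinate
reference minimiser used in the tests (cyclic exact row minimisation is
valid here because each nonsmooth term is block-separable).

Bootstrap significance re-runs the balanced cross-validation with
labels randomised within the balanced subset — i.i.d. resampling with
replacement from the empirical labels by default, plain permutation as
an option — reusing the observed fold layout and penalties so each of
the (default 1000, reducible) draws differs only in its labels. The
reported percentile counts strictly smaller null accuracies, so a
single draw yields 0 or 100.

The cross-condition test trains the stimulus decoder on balanced
opto-off late-delay activity, reports opto-off proportions from
out-of-fold predictions, and scores stimulated trials (pooled over
baseline/visual/delay stimulation onsets) with the model refit on all
balanced opto-off trials. The output is the fraction of trials
predicted "contra" per (condition × true stimulus side).

## Study designs used by the acceptance script and tests

Problem sizes were chosen so each study carries its point at desk scale:
encoding recovery uses the generator defaults (64×64 pixels, 200
trials, noise at 10% of the peak map amplitude, smoothing on) and
scores the fitted lag×pixel blocks against the generative truth after
projecting both onto the predictor's own time course; its "noiseless
variant" switches off both pixel and memory noise, since either is
unexplainable variance by construction. Null-test calibration runs 200
small single-target regressions (120 trials, 15 frames, 100 rotations).
The "separable" decoding regime keeps the behavioural error rate (via
motor noise) but makes the memory trace trial-stable, lowers sensor
noise and doubles the response lick rate — the regime in which decoding
accuracy should saturate. Cross-condition studies use 400-trial
sessions so the per-cell proportions are stable.

## Known limitations

- The engagement filter's window alignment (centred, edge-truncated) is
  one of several defensible readings of a sliding 50-trial window.
- ΔR² uses the mean of the rotated distribution; a single-rotation
  variant would be noisier but is implied by some formulations.
- The dirty model's loss and penalty-selection protocol are standard
  choices for the "least dirty" family, not a bit-level match to any
  particular toolbox.
- ROI masks are synthetic circles; no atlas registration is attempted,
  and masks are supplied with the session rather than fit to anatomy.
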