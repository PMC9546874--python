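# Methods

## Scope

`ktrcycle` implements the computational side of a live/fixed-cell study of
cell-cycle entry: quantification of kinase-translocation-reporter (KTR)
activities with cross-talk correction, nuclear segmentation with the derived
cytoplasmic-ring and whole-cell measurement regions, frame-to-frame tracking
with gap bridging and live-to-fixed mapping, event calling (CDK4/6-on,
CDK2-on, APC/C-off), two-window proliferative-fate classification, the
logistic commitment-boundary estimate, and the population statistics used for
fixed-cell snapshots (thresholds, sigmoid time courses, 2D activity maps,
EdU/Hoechst phase gating, Welch's t-test). Because the original imaging data
are not publicly deposited, every stage is exercised against a synthetic
generator whose defaults encode the study conditions.

## The commitment circuit generator

The generator is a deliberately minimal, phenomenological model of the
CDK4/6 → Rb → E2F → CDK2 axis in mitogen-stimulated quiescent cells. It is a
model of the qualitative circuit logic — sequential activation, a bistable
commitment latch, delayed inactivation under mitogen withdrawal — not a
fitted mass-action model of cyclin–CDK biochemistry.

Per cell:

1. **CDK4/6.** With probability `p_active` the cell activates CDK4/6 at an
   onset drawn uniformly from `[onset_min, onset_min + onset_scale]`
   (default 3–13 h post-stimulation). Activity rises as
   `a46_max · (1 − exp(−(t − onset)/rise_tau))`. A perturbation switches
   production off — immediately for a CDK4/6 inhibitor or a DNA-damage pulse,
   after a per-cell `Uniform(4, 5)` h lag for mitogen withdrawal (activity
   hysteresis) — after which activity decays exponentially with
   `fast_decay_tau`.
2. **Rb.** Rb is inactive while CDK4/6 activity is at least `theta_rb`, OR
   once the running maximum of CDK2 activity has reached `theta_commit`
   (the CDK2–Rb positive-feedback latch; commitment is irreversible).
3. **E2F and CDK2.** An E2F driver integrates constant production while Rb
   is inactive, with first-order decay. CDK2 activity integrates
   `cdk2_rate · E2F` while Rb is inactive and relaxes first-order toward the
   quiescent baseline `a2_baseline` (0.1 reporter units; the quiescent level
   is not pinned down by published reporter scales, 0.1 is our choice).
   Gating CDK2 production on Rb state is what makes the fate boundary sit at
   `theta_commit` itself: when CDK4/6 is lost before commitment, production
   ceases and activity decays back, rather than overshooting on residual
   E2F.
4. **APC/C.** The APC/C(Cdh1) degron rises linearly (rate `degron_rate`)
   after CDK2 activity first crosses `theta_apc`; only the onset time is
   meaningful downstream.
5. **Observation.** The CDK4/6 reporter reads `A46 + 0.35 · A2` (cross-talk),
   the CDK2 reporter reads `A2`; all samples get i.i.d. Gaussian noise
   (`noise_sd`, default 0.05) at a 12-min interval (`dt = 0.2 h`).

Integration is forward Euler with four substeps per sampling interval; the
substeps matter only for the switch at treatment time, where a full 0.2-h
step would overshoot the commitment threshold by several hundredths of a
reporter unit.

### Calibrated defaults (`data/calib_paper.yaml`)

The packaged parameter file transcribes the reported study conditions:
cross-talk 0.35, commitment threshold 1 reporter unit, earliest onset 3 h,
withdrawal delay 4–5 h, 12-min sampling, 14-h fixation horizon. Two knobs are
calibrated once so the cohort composition matches the reported ~40% of
CDK4/6-activating cells without CDK2 activation at fixation: the onset window
width (`onset_scale = 10 h`) and the E2F production rate
(`e2f_rate = 0.97 /h`), which jointly set the onset→CDK2-on lag to ≈4.8 h.
`theta_rb = 0.98` (a fraction of the CDK4/6 plateau `a46_max = 1`) introduces
the ≈0.8-h delay between detectable CDK4/6 onset and Rb inactivation that
this lag requires, while keeping the *detection* latency of CDK4/6 onset
itself (threshold 0.3 on a `rise_tau = 0.2 h` rise) below half a frame, and
making Rb re-activation nearly instantaneous after inhibitor addition.

**Onset distribution.** We use a bounded uniform onset window rather than an
unbounded heavy-tailed one. With an unbounded tail, a fixed-horizon cohort
always contains activators too late to be observable by any
threshold-plus-persistence rule, so the "fraction of high cells without
CDK2-on" among *observed* cells diverges from the same fraction among *true*
activators — the two quantities the validation compares. A bounded window
matches a stimulation time course in which activation is spread over the
observation period, and makes truth and pipeline cohorts coincide.

**What the generator does not emulate.** Cell growth, motility beyond small
Brownian jitter, division and lineages, p21-dependent differences between
inhibitor and DNA-damage responses, segmentation-adversarial morphologies
(non-circular nuclei, debris), and temporally correlated reporter noise.
Passing tests therefore demonstrate correctness of the algorithms under the
stated model, not robustness to every pathology of real microscopy.

## Virtual microscopy

Cells are rendered as a nuclear disk (radius 8 µm) inside a cytoplasmic
annulus (outer radius 16 µm) at 0.65 µm/px (typical 20×, 2×2 binning), placed
on a jittered grid so cytoplasm disks never overlap, with per-frame Brownian
jitter (0.5 µm sd). For each KTR channel a fixed per-cell reporter total is
split between nucleus and annulus so that (cytoplasm mean)/(nucleus mean)
equals the reporter signal — the CDK4/6 channel renders the cross-talk-
containing signal, so the full correction pipeline is exercised. The degron
channel scales nuclear intensity with the degron level. An optional
multiplicative quadratic illumination surface and Poisson + Gaussian camera
noise complete the model; ground-truth nuclear/cytoplasm label masks and
positions are returned per frame. FISH fields render each transcript as a
2-px-σ Gaussian spot of fixed amplitude placed uniformly in the cell's
whole-cell region.

## Segmentation and measurement geometry

* Illumination correction divides by a unit-mean bias surface (given, or
  fitted as a quadratic to 10th-percentile block quantiles on an 8×8 grid)
  and rescales to preserve the image mean exactly.
* Nuclei: Otsu threshold (256 bins) → hole filling → marker-based watershed
  on the distance transform (markers = distance maxima separated by at least
  a nuclear radius) → removal of components below `min_nucleus_area_um2`;
  labels are renumbered in raster order of their centroids.
* Cytoplasmic ring: pixels 2–10 µm (Euclidean, pixel grid, distance to the
  nearest nucleus pixel) outside the cell's nucleus, farther than 10 µm from
  every other nucleus, outside all nuclei, and — when an intensity image is
  supplied — at least background median + 2·MAD ("distinguishable from
  background"; the floor is configurable). Sub-pixel boundary effects are
  ignored; tests compare against a brute-force per-pixel oracle exactly.
* Whole-cell region: pixels within 50 µm of the nucleus for which it is the
  nearest nucleus (ties broken toward the lower label), plus the nucleus.
* Measurements: background (median over pixels in no whole-cell region) is
  subtracted from nuclear and ring means with a floor at zero; KTR activity
  is ring mean / nuclear mean; corrected CDK4/6 activity subtracts
  `rho ·` (CDK2 reporter) with `rho` from an OLS regression of
  inhibitor-treated calibration pairs (the regression intercept is reported
  but not subtracted). FISH puncta: white top-hat with a 4-µm disk, absolute
  threshold (default top-hat median + 5·MAD — the original threshold value is
  unpublished), per-cell puncta-pixel count and connected-component count.

## Tracking

Frame-to-frame linking is a gated optimal linear assignment on squared
displacement; leaving a detection unmatched costs the squared gate (15 µm
default), so the optimum never forces distant pairs. Gap bridging joins track
ends to starts (gap ≤ 2 frames, displacement ≤ gap · gate, relative
nuclear-mass change ≤ 0.3) with a single global assignment over all
end/start pairs — this re-evaluates links disturbed by appearing/disappearing
neighbors as one optimization rather than a per-pair repair loop. Tracks with
an abrupt mass change (e.g. transient merges) are flagged, never silently
re-identified; division handling is out of scope for G0→S experiments. The
final live frame is mapped to the fixed-cell image by the same gated
assignment with a 15-µm radius; unmatched fixed cells are reported unmapped.

## Event calling and fate

Onsets use a threshold-plus-persistence rule: the first frame at which the
signal stays beyond the threshold for `persistence_w = 3` consecutive frames
(36 min). Defaults: corrected CDK4/6 ≥ 0.3, CDK2 ≥ 0.6 (the reported
selection gate), degron ≥ 0.1; inactivation uses the same rule below 0.3.
The generator's ground-truth CDK2-on time uses the same 0.6 level and
requires the crossing to be sustained for 0.4 h, so a grazing of the level in
the final samples before fixation does not count as activation for either
truth or pipeline.

Fate after a perturbation at `t_treat` is classified among cells with CDK2
≥ 0.6 at treatment, from two windows: `window1 = (0, 2) h` and
`window2 = (6, 10) h` after treatment. `inc` requires mean CDK2 over window2
≥ 0.8 and no decrease from window1; `low` requires mean over window2 ≤ 0.5;
the exact window placements and cutoffs used originally are unpublished, so
these are declared package defaults (chosen so that noise-free synthetic
fates reproduce the generative outcome exactly) and are fully configurable.

The commitment boundary is the activity at which a logistic regression of
(fate = inc) on CDK2-at-treatment crosses probability 0.5, with a seeded
1000-resample bootstrap CI; completely separated data return the midpoint of
the class extremes with a separation flag.

## Population statistics

Thresholds: Otsu on a 256-bin histogram, or the equal-likelihood crossing of
a two-component normal mixture initialized at the 25th/75th percentiles
(degenerate mixtures fall back to Otsu, flagged), or manual — the original
thresholds were set by inspection and are not numerically published. Channel
polarity is configurable (the degron channel counts "inactive APC/C" as
*above* threshold). Sigmoid fits are four-parameter logistic least squares
with a deterministic multi-start over the half-rise time. Activity maps bin
cells on corrected CDK4/6 × CDK2 activity (default 30×30 over [0, 2.5]²,
bins with < 5 cells masked) and color-code percentage positive or a mean.
Phase gating: S = EdU above threshold; EdU-negative cells split into 2N/4N
Hoechst bands by a two-component mixture. Group comparisons use Welch's
unequal-variance two-sample t-test with Satterthwaite degrees of freedom;
confidence intervals of means are t-based 95% two-sided. No multiple-testing
correction is applied, matching the original analysis convention of raw
t-test p-values.

## Problem sizes and numerics

The validation suite runs cohorts of 300–2000 cells (71–111 frames), a
20-cell/60-frame rendered movie for tracking, and 512²–640² rendered fields;
these sizes give sampling error comfortably below the acceptance tolerances
while keeping the full suite under a minute of simulation time plus ~30 s of
rendering/segmentation. The bootstrap uses 1000 resamples; logistic fits that
fail on a resample (separation) fall back to the midpoint rule for that
resample. All randomness flows through `numpy.random.default_rng` seeds;
identical seeds give byte-identical trace sets.

## Known limitations

* The deflection-bridging tracker of the original MATLAB pipeline is not
  publicly specified line-by-line; our tracker is specified by contract
  (optimal gated assignment + global gap bridging + flags) and validated by
  truth-link recovery, not by transcription.
* Whether the original ring was further restricted beyond the background
  rule is unspecified; only the stated rules are implemented.
* The fate windows, FISH threshold, and fixed-cell thresholds are declared
  defaults, not reconstructions (the originals are unpublished).
* Corrected CDK4/6 activity may be negative (no clipping); downstream
  thresholds are defined on the corrected scale.
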