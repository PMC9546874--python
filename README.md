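# ktrcycle

Single-cell analysis of cell-cycle entry from kinase-translocation-reporter
(KTR) microscopy: reporter quantification with cross-talk correction,
segmentation and tracking, activation/inactivation event calling,
proliferative-fate classification, and the population statistics used for
fixed-cell snapshots — together with a synthetic generator of the
CDK4/6 → Rb → E2F → CDK2 commitment circuit (and a virtual microscope) so the
entire pipeline is testable end to end without raw imaging data.

## Who this is for

Groups doing live-cell imaging of cell-cycle commitment with translocation
reporters (CDK2/DHB-type sensors, Rb-fragment CDK4/6 sensors, APC/C-degron
reporters), who need a tested, scriptable re-implementation of the standard
analysis chain, or a ground-truthed synthetic benchmark for developing their
own.

## The model and the measurements

A KTR reports kinase activity as the ratio of cytoplasmic to nuclear mean
intensity. Per cell:

```
CDK2 activity      = ring_mean / nuc_mean                  (DHB reporter)
CDK4/6 activity    = raw CDK4/6 ratio − ρ · CDK2 ratio     (ρ = 0.35)
```

where the cytoplasmic ring is 2–10 µm outside the nuclear mask (excluding
pixels within 10 µm of another nucleus or indistinguishable from background)
and ρ comes from an OLS regression of the two reporters under full CDK4/6
inhibition. Events are called by threshold + persistence (3 frames at 12-min
sampling); after a perturbation at time *t*, cells with CDK2 ≥ 0.6 are
classified `inc` (continued rise) or `low` (reversal) from two
post-treatment windows, and the **commitment boundary** is the CDK2 activity
at which a logistic regression of fate crosses P = 0.5 — operationalizing the
observation that cells above ≈1 reporter unit at the time of CDK4/6
inhibition continue through the cell cycle.

The synthetic generator encodes that circuit: heterogeneous CDK4/6 onsets
(earliest 3 h post-stimulation), Rb inactivation above a CDK4/6 threshold,
E2F-driven gradual CDK2 rise, an irreversible commitment latch at CDK2 ≈ 1,
APC/C-degron onset after CDK2 activation, rapid (inhibitor/DNA-damage) versus
4–5-h-delayed (mitogen-withdrawal) CDK4/6 inactivation, and observation noise
plus reporter cross-talk. See `docs/methods.md` for the equations, defaults
and limitations.

## Worked example

```python
import numpy as np
import ktrcycle as kc

params = kc.paper_calibration()            # packaged study-condition defaults

# 1) cross-talk calibration (inhibitor-treated cells)
pairs = kc.simulate_calibration_pairs(rho=0.35, n=500, noise_sd=0.05, seed=7)
model = kc.estimate_crosstalk(pairs)
print(f"rho = {model.rho:.3f}")

# 2) cohort composition at the 14-h fixation point
traces = kc.simulate_population(params, n_cells=2000, seed=1)
events = kc.call_events(traces)
high = events[events.class46 == "high"]
print(f"CDK4/6-high: {100 * len(high) / len(events):.1f}%")
print(f"... of which without CDK2 activation: {100 * high.onset2.isna().mean():.1f}%")

# 3) commitment boundary from an inhibition-at-11-h experiment
pert = kc.PerturbationSpec(mode="rapid_inhibitor", t_treat=11.0)
cohort = kc.simulate_population(params.replace(horizon=22.0), pert,
                                n_cells=1000, seed=3)
fates = kc.classify_fate(cohort, t_treat=11.0)
sel = fates[fates.selected & fates.fate.isin(["inc", "low"])]
est = kc.estimate_commitment_boundary(sel.cdk2_at_treatment.to_numpy(),
                                      sel.fate.to_numpy(), seed=3)
print(f"boundary = {est.boundary:.2f} [{est.ci_low:.2f}, {est.ci_high:.2f}]")
```

Output:

```
rho = 0.349
CDK4/6-high: 70.4%
... of which without CDK2 activation: 39.7%
boundary = 0.98 [0.96, 0.99]
```

Reading: the calibration regression recovers the generative cross-talk
coefficient (0.35); at the fixation horizon about 70% of cells have activated
CDK4/6 and roughly 40% of those have not yet activated CDK2; and the logistic
50% point of continued cell-cycle entry sits at CDK2 ≈ 1 — the commitment
threshold of the generating circuit.

A command-line interface mirrors the stages
(`ktrcycle simulate | render | segment | measure | track | calibrate-crosstalk |
events | commitment | maps | report`); run `ktrcycle --help`.

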