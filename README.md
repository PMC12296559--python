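# bindwave

Sensor-to-source EEG analysis of **event-file binding** in prime–probe
(S1–S2) tasks.

When a stimulus and the response it triggers co-occur, their features are
bound into a transient *event file*. If some — but not all — of those
features repeat at the next stimulus, the old event file is retrieved and
must be reconfigured, which costs time and accuracy (*partial repetition
costs*). `bindwave` implements the full analysis chain used to study this
process with EEG in clinical and healthy cohorts (e.g. Gilles de la
Tourette syndrome vs. controls):

* **Behavior** — per-participant trial filtering (S1-accuracy, 200 ms floor,
  Tukey upper fence Q3 + 1.5·IQR), the binding score
  `((RRFA − RRFR) + (RAFR − RAFA))` for reaction times and error rates,
  one-sample *t*/dz, Welch *t*, Yates χ², and a mixed
  2 (group) × 2 (response relation) × 2 (feature relation) ANOVA with
  generalized η².
* **Sensor level** — Morlet wavelet time–frequency analysis (width 5),
  theta/alpha/beta band power, paired feature-repetition vs.
  feature-alternation *t*-tests per channel × time bin with
  Benjamini–Hochberg FDR control.
* **Source level** — DICS beamforming (Hanning-taper CSD, common spatial
  filter `w = (lᵀC_r⁻¹l)⁻¹ lᵀC_r⁻¹`, orientation-optimized, unit gain) for
  pre-trial power maps (neural activity index) and the post-trial contrast
  `ratio = (P_FR − P_FA)/(P_FR + P_FA)`; DBSCAN clustering of the top 1 %
  of labelled voxels (minPts 2, ε = 1.5 × grid spacing); LCMV
  reconstruction of cluster band-power time courses.
* **Pre/post coupling** — time-resolved Pearson correlation matrices
  between pre-trial (post-S1, pre-S2) and post-trial (post-S2) cluster
  power across participants, with BH *q*-values.

Because raw cohort EEG is typically unavailable, every stage is exercised
end to end on **forward-modelled synthetic data**: an analytic
homogeneous-sphere head model supplies closed-form lead fields, and the
`synthdata` module plants known binding costs, condition-dependent
oscillatory sources, and a pre/post power coupling ρ, so each analysis
stage has a ground truth to recover.

## Worked example

```python
from bindwave.behavior import filter_trials, participant_binding, one_sample_t_data
from bindwave.synthdata import BehaviorSimParams, generate_behavior

params = BehaviorSimParams(n_participants=62, binding_cost_ms=35.0, seed=7)
table = generate_behavior(params, group="HC")          # 62 x 96 trials
filtered, report = filter_trials(table)                # S1/floor/Tukey filters
binding = participant_binding(filtered)                # per-participant scores
t, df, dz, p = one_sample_t_data(binding["rt_binding"])
print(f"mean RT binding score: {binding['rt_binding'].mean():.2f} ms")
print(f"one-sample t({df}) = {t:.2f}, dz = {dz:.2f}, p = {p:.2g}")
```

prints

```
mean RT binding score: 63.94 ms
one-sample t(61) = 13.11, dz = 1.66, p = 2.2e-19
```

A binding cost of δ = 35 ms is added to the two partial-repetition
conditions, so the expected binding score is 2δ = 70 ms; the simulated
cohort recovers 63.9 ± SE ms and the group-level test detects it.

The full chain runs from a single config:

```sh
bindwave run --config config.yaml --out runs/demo --seed 1
bindwave verify --seed 1          # reference statistics + property suites
```

`run` writes TSV tables (binding scores, sensor contrasts, source maps,
cluster reports, correlation matrices), a `metrics.json`, and a provenance
log into the run directory; each stage is also available as its own
subcommand (`simulate`, `preprocess`, `behavior`, `tfr`, `dics`, `cluster`,
`lcmv`, `xcorr`).

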