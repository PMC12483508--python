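# popcode

Population-coding analysis for two-photon calcium imaging of visual cortex,
built for studies that compare a control and a manipulated (e.g. knockout)
condition. The package covers the full chain from raw fluorescence to group
statistics, together with a ground-truth synthetic session generator so that
every stage is verifiable without the original recordings:

* **Preprocessing** — neuropil correction (F_ROI = F_raw − 0.7·F_neuropil),
  baseline F0 as the KDE mode, ΔF/F = (F − F0)/F0, and exact nonnegative
  deconvolution against an exponential calcium kernel.
* **Response metrics** — trial tensors, visual responsiveness, direction
  tuning and OSI = (R_pref − R_orth)/(R_pref + R_orth), maximal response,
  trial-to-trial reliability (mean pairwise trial correlation), and
  spontaneous / signal / noise pairwise correlations.
* **Encoding GLM** — lasso (λ = 10⁻³) regression of each neuron's trace on
  stimulus-onset lag indicators over [0, 2] s plus z-scored pupil and running,
  10-fold contiguous cross-validated R², and per-predictor-group significance
  by full-vs-partial model comparison with Holm correction; plus a
  population-activity GLM with weight binning at 0.05 / 0.1.
* **Decoding** — linear SVM on class-balanced 33%-holdout trial responses,
  C grid-searched over 10⁻³..10³, one-vs-rest macro AUROC with paired
  shuffle nulls, population-size sweeps (5..25 neurons), and a two-way
  group × size ANOVA.
* **Group statistics** — mixed-effects comparisons of neuron-level metrics
  with an animal random intercept (guarding against pseudoreplication), and
  Mann–Whitney / Kolmogorov–Smirnov / t wrappers.
* **Synthetic sessions** — Poisson populations with von Mises tuning,
  log-normal trial gain jitter, behavioral coupling, shared latent
  variability, and calcium/neuropil fluorescence generation, under gray,
  drifting-grating (16 trials × 8 directions) and natural-movie
  (32 trials × 7 clips) protocols at 16 Hz.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Simulate a control and a knockout grating session and compare them through
the pipeline (abridged from `examples/05_decoding.py`; all examples run in
seconds to minutes):

```python
import popcode as pc

cfg = pc.DecodingConfig(n_iterations=5, seed=0)
for name, factory in (("control", pc.SimulationConfig.control),
                      ("knockout", pc.SimulationConfig.knockout)):
    session = pc.simulate_session(factory(60, seed=6), "gratings")
    dff = pc.compute_dff(session.recording)
    sweep = pc.population_sweep(dff.dff, session.protocol, cfg)
    print(name, [round(m, 3) for m in sweep.mean_auroc],
          "null", round(sweep.auroc_shuffled.mean(), 3))
```

prints

```
control [0.819, 0.92, 0.951, 0.962, 0.967] null 0.508
knockout [0.718, 0.755, 0.762, 0.796, 0.824] null 0.502
```

Decoding accuracy (macro AUROC over the 8 grating directions) grows with
population size, sits far above the ~0.5 label-shuffle chance level, and is
lower at every size for the knockout population, whose generator plants
lower evoked gain and larger trial-to-trial gain jitter. The other examples
walk through preprocessing (`02`), tuning/correlation metrics (`03`), the
encoding GLM (`04`) and the mixed-effects group comparison (`06`).

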