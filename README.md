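# flavokit

Quantitative analysis of flavonoid supramolecular assembly, for researchers
studying how polyphenols such as quercetin and its glycosides
(isoquercitrin, quercitrin) aggregate into π-stacked fibers — and how that
assembly confounds and explains enzyme-inhibition screens.  Flavonoids are
notorious pan-assay actives; the package implements the analysis chain
used to connect their promiscuous screening behaviour to supramolecular
self-assembly:

* **Dose–response fitting** — four-parameter logistic fits of percent
  inhibition vs log10 concentration, IC50 read at the 50 % crossing,
  and three-way fit categorisation (in-range / extrapolated / baseline).
* **Efficacy ranking** — per-enzyme Z-scores of log10 IC50,
  z<sub>i</sub> = (log₁₀ IC50<sub>i</sub> − X̄<sub>i</sub>)/s<sub>i</sub>, with z = 2 imputed for
  missing readouts, readout-count weights w<sub>i</sub> = N<sub>i</sub>/ΣN<sub>i</sub>, and the
  weighted mean z̄ = Σ w<sub>i</sub> z<sub>i</sub> / 7 ranking compounds (low z̄ = potent).
* **RGYR statistics** — mass-weighted radius of gyration over tagged
  trajectories, late-window quartile summaries, and Levene /
  Brown–Forsythe variance-heterogeneity tests with duplicate pooling.
* **Assembly graphs** — geometric π-stacking detection (centroid distance,
  interplanar angle, lateral offset), molecule-level graphs, and
  primary (linear) / secondary (branched) / cyclic fiber classification.
* **Weighted ensemble** — a desk-scale engine with a variation-maximising
  (REVO-style) clone/merge resampler over an RGYR distance, walker
  lineage tracing, and −ln(p) free-energy profiles in kT units.
* **Synthetic generators** — a 58-compound × 7-enzyme screen emulator,
  self-assembly collapse trajectories, ideal stacked-ring fibers, and a
  double-well Langevin toy, so every stage runs without external data.

See `docs/methods.md` for the models, conventions and their assumptions.

## Worked example

```python
import numpy as np
import flavokit as fk

# emulate the screen: 58 compounds x 7 enzymes, 10 concentrations, 2 reps
spec, truth = fk.study_panel_spec(seed=1)
table = fk.gen_inhibition_panel(spec)

fits = fk.fit_panel(table)
print({k: round(v, 1) for k, v in fk.summarize_categories(fits).items()})

ranked = fk.rank_compounds(fits)
print(ranked[["zbar", "rank"]].head(3))

# weighted-ensemble run on the double-well toy, study resampler parameters
prop = fk.make_double_well_propagator(fk.DoubleWellSpec(barrier=3.0))
params = fk.REVOParams(n_walkers=50, n_cycles=300, steps_per_cycle=100)
res = fk.run_weighted_ensemble(prop, np.full(50, 1.0), params, seed=1)
print("max |sum w - 1|:", float(np.abs(res.weights.sum(axis=1) - 1).max()))
```

prints

```
{'IN_RANGE': 26.1, 'EXTRAPOLATED': 11.8, 'BASELINE': 62.1}
                 zbar  rank
compound_id
C038        -0.032563     1
C020        -0.015908     2
C022         0.016514     3
max |sum w - 1|: 2.220446049250313e-16
```

The category split says 26.1 % of the 406 compound–enzyme fits crossed
50 % inhibition inside the assayed 5 nM – 100 μM window, 11.8 % crossed
only above it (IC50 extrapolated), and 62.1 % stayed at baseline.  C038
carries the lowest weighted mean Z-score and ranks as the most efficacious
inhibitor of this synthetic screen.  The weight sum shows the resampler
conserves total probability to machine precision.

A command-line surface wraps the same stages
(`flavokit simulate-panel | fit-ic50 | rank | gen-traj | rgyr | variance |
stacking | we-run | we-profile`), each taking `--config`, `--seed` and
`--out` and emitting a reproducibility manifest.

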