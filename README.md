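# hyperkinetics

Simulation and kinetic analysis of ratiometric H₂O₂-biosensor (HyPer)
recordings in living cells.

HyPer is a genetically encoded hydrogen-peroxide sensor: a circularly
permuted YFP inserted into the regulatory domain of bacterial OxyR.
Oxidation by H₂O₂ forms a disulfide bond that shifts the excitation
spectrum, so the 490/420 nm excitation ratio R = F₄₉₀/F₄₂₀ reads out the
oxidized sensor fraction independently of expression level. Because the
cpYFP chromophore is pH sensitive, baseline ratios and pulse responses
depend on intracellular pH — but the **recovery rate** after oxidant
washout does not, which makes it the robust readout of a cell's
disulfide-reduction (antioxidant) capacity. This package is for cell
biologists and imaging labs who want to quantify that capacity from
single-cell time-lapse traces, and to validate the estimator against a
mechanistic simulator with known ground truth.

## Model

Per cell, with time in minutes and concentrations in µM:

```
dHi/dt = perm·(He(t) − Hi) + prod − cons_eff(t)·Hi      intracellular H2O2
dθ/dt  = k_ox·Hi·(1 − θ) − k_red·θ                      oxidized sensor fraction
F_ch   = gain_ch·(base_ch + amp_ch·θ)·10^−(pKa_ch − pH)/(1 + 10^(pKa_ch − pH))
```

`He(t)` is the scheduled extracellular pulse profile (e.g. 20 min
baseline, 50 µM submaximal pulse, washout, 500 µM saturating pulse).
After washout `Hi` clears quickly, leaving `θ(t) ≈ θ₀·e^(−k_red·t)`; the
analysis chain therefore fits the post-washout signal with a
three-parameter exponential

```
y(t) = y0 + A·exp(−k·(t − t0))
```

and reports k as the recovery rate. Signals are normalized to the
sensor's dynamic range (0% at the basal ratio, 100% at the maximum under
the saturating pulse), which cancels per-cell gain differences; k itself
is scale invariant. Compartment presets (cytosol, mitochondrion, ER),
pharmacological perturbations (auranofin, PX-12, EUK-134, NAC), pH
clamps, and a ten-cell-line migration cohort are built in — see
`docs/methods.md` for parameter meanings and calibration details.

## Worked example

```python
import hyperkinetics as hk

schedule = hk.default_two_pulse_schedule()          # 20 min baseline, 50 then 500 µM
preset = hk.compartment_preset("cytosol").with_k_red(1.35)  # fast-reducing line
experiment = hk.simulate_experiment(preset, None, schedule,
                                    n_cells=30, cell_cv=0.15, seed=8)
table, excluded = hk.analyze_experiment(experiment.traces, schedule)
k = table["recovery_k_per_min"]
print(f"recovery rate k: {k.mean():.3f} +/- {k.sem():.3f} per min "
      f"(truth {experiment.truth.k_red.mean():.3f})")
print(hk.analyze_trace(experiment.traces[0], schedule).fit.summary())
```

prints

```
recovery rate k: 1.341 +/- 0.045 per min (truth 1.316)
Exponential recovery fit: y(t) = y0 + A·exp(−k·(t − t0))
  n = 36 frames, t0 = 39.333 min
  k  = 1.04 /min  (SE 0.0227)
  A  = 71.93       (SE 0.85)
  y0 = 0.05203      (SE 0.198)
  r (fitted vs observed) = 0.9982
  converged = True, identifiable = True
```

The cohort mean (1.341 ± 0.045 /min) recovers the true mean reduction
rate of the simulated cells (1.316 /min; individual cells vary with 15%
lognormal heterogeneity — the first cell here happens to sit at 1.04).
`r` is the correlation between fitted and observed recovery points, the
per-cell fit-quality score used to gate group statistics.

The same pipeline runs from a shell:

```
hyperkin full --config cfg.yaml --out run/     # traces.csv, results.csv, stats
hyperkin analyze --traces t.csv --protocol p.yaml --out run/
```

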