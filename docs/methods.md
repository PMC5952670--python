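# Methods

## The measurement being modeled

A HyPer-expressing cell is imaged alternately at 420 and 490 nm
excitation every 20 s. The 490/420 ratio rises when H₂O₂ oxidizes the
sensor's OxyR domain (disulfide formation) and falls back as cellular
thiol systems (thioredoxin/thioredoxin-reductase, glutathione) re-reduce
it. The standard protocol is a 20 min baseline, a submaximal 50 µM H₂O₂
pulse, a washout, a saturating 500 µM pulse, and an unperturbed recovery.
Three quantities are extracted per cell: the basal ratio (steady-state
oxidation), pulse response amplitudes (peak − basal), and the recovery
rate k of the post-washout exponential decay. Only the last is
independent of intracellular pH, so it is the preferred readout of
reducing capacity.

## Mechanistic simulator

State per cell: intracellular H₂O₂ `Hi` (µM), oxidized sensor fraction
`θ`, and an optional adaptive-consumption component `C`:

    dHi/dt = perm·(He(t) − Hi) + prod − (cons + C)·Hi
    dθ/dt  = k_ox·Hi·(1 − θ) − k_red·θ
    dC/dt  = cons_induction·Hi − induction_decay·C

Assumptions: the sensor pool is well mixed within the compartment
(single ROI, no spatial gradients); oxidation is second order in
(Hi, reduced sensor) and reduction first order in oxidized sensor;
sensor abundance does not perturb H₂O₂ handling; membrane transport is
first order. With `cons_induction = 0` the H₂O₂ balance is a linear ODE
whose step responses have closed forms used as test oracles (e.g. a held
500 µM pulse with perm = 10, cons = 2 /min plateaus at
perm·He/(perm + cons) = 416.7 µM). The adaptive term is used only by the
mitochondrion preset: under a sustained pulse the consumption capacity
ramps up, `Hi` falls after an initial rise, and θ peaks and then
declines while oxidant is still present — the characteristic
mitochondrial behavior that a fixed-coefficient linear balance cannot
produce under a constant external concentration.

Rendering: each channel is
`gain·(base + amp·θ)·hh(pH, pKa)` with `hh` the Henderson–Hasselbalch
deprotonated fraction and `amp420 < 0 < amp490` (reciprocal channel
response). With pKa₄₉₀ = 7.8 > pKa₄₂₀ = 6.8 the ratio baseline rises
with pH while θ kinetics are untouched; these pKa values are calibration
constants chosen to give a strongly pH-dependent baseline over pH
6.5–7.5, not literature measurements. Noise is multiplicative Gaussian
per frame per channel (default cv = 0.02), a stand-in for shot and
camera noise; a Poisson option was deliberately omitted. pH clamps relax
intracellular pH to the commanded value with a 0.5 min time constant
(fast relative to sampling, as ionophore clamps are).

## Parameters that matter

| parameter | units | meaning | default (cytosol) |
|---|---|---|---|
| k_ox | /µM/min | sensor oxidation rate by H₂O₂ | 0.04 |
| k_red | /min | disulfide-reduction (recovery) rate | 1.0 |
| perm | /min | membrane H₂O₂ equilibration | 15 |
| prod | µM/min | basal H₂O₂ production | 0.5 |
| cons | /min | H₂O₂ consumption (peroxidases etc.) | 5 |
| cell_cv | – | lognormal per-cell spread of k_red and gains | 0.15 |
| noise_cv | – | per-frame multiplicative channel noise | 0.02 |

Two kinetic regimes are provided because published recovery rates span
two scales. Compartment presets (k_red = 1.0, 2.5, 0.15 /min for
cytosol, mitochondrion, ER) operate at the cell-line scale (~0.3–1.4
/min), resolvable at 20 s sampling. `fast_kinetics_preset` (perm = 2000,
cons = 100, k_ox = 2) serves the fast scale (~14–90 /min) reported for
pH-clamp and drug experiments; such rates need sub-second sampling, so
the fine schedules sample at 0.5 s over a few minutes. The two scales
are treated as independent ground-truth regimes; no attempt is made to
reconcile them (reported units in the source experiments are mutually
inconsistent by ~50×, and rates of tens per minute are simply not
identifiable from 20 s frames).

Perturbation presets act multiplicatively: auranofin 100 nM scales k_red
by 13.7/41.8 (whole recording, modeling a 24 h pre-incubation); PX-12
scales k_red by 38.8/88.5 (1 µM) or 25.8/88.5 (10 µM) during washout
only (the drug is cytotoxic under prolonged exposure); EUK-134 scales
prod by 0.3 and leaves k_red alone (an SOD/catalase mimetic lowers basal
H₂O₂ but not disulfide reduction); NAC scales k_red by 1.7, reverting at
`treatment_end` to model its reversibility.

Compartment photophysics (base/amp/gain constants in `presets.py`) were
calibrated once, by solving the affine ratio model against the target
compartment responses under the noiseless single-pulse protocol: a 300%
basal-relative ratio increase for cytosol, 85% with an absolute ΔR of
0.93 for mitochondria, 25% with ΔR of 1.13 (hence the highest basal
ratio, 4.52) for the ER. The 420-channel amplitude is kept small
(|amp420| ≤ 0.03): the ratio of two affine functions of θ is not a pure
exponential in time, and a large 420 amplitude would bias the fitted
rate by several percent.

## Analysis chain

1. `compute_ratio` — frame-wise F₄₉₀/F₄₂₀ (optional constant background
   offsets, default 0; ROI/background handling is assumed upstream).
2. `estimate_baseline` — mean ratio over the 2 min before the first
   pulse (configurable; the long 20 min baseline exists to verify
   stability, the quantitative window is short).
3. `dynamic_range` — within-pulse maximum of the raw ratio during the
   saturating pulse (no fit; an optional 3-frame median filter, off by
   default, guards single-frame spikes). Cells with span ≤ 0 or < 5% of
   basal are excluded as degenerate and counted.
4. `normalize` — percent of dynamic range (0 basal, 100 at saturation).
5. `fit_exponential_recovery` — bounded trust-region least squares of
   y0 + A·e^(−k(t−t0)), k ∈ [0, 1000] /min, tolerances 1e−10,
   deterministic initialization from a log-linear regression (no random
   restarts). t0 is fixed at the recovery's first frame, leaving three
   free parameters. The fit uses frames *strictly after* the final
   pulse_end: a frame acquired at the washout instant still sees the
   oxidant and would bias fast rates low by several percent. Fit quality
   is r, the correlation between fitted and observed points; cells with
   r < 0.8 or unconverged fits are retained in output but excluded from
   group statistics by default.

Per-cell fitting is primary; `pooled_recovery_curve` (mean ± SE over
cells) is provided for figure parity but not used for statistics, since
cohort reporting conventions are per-cell means ± SE.

Group comparisons (`compare_groups`) screen each group with Shapiro–Wilk
at α = 0.05 and branch to one-way ANOVA + Bonferroni-adjusted pairwise
t-tests (all normal) or Kruskal–Wallis + Dunn's rank post-hoc
(otherwise); the decision rule is this package's choice, as source
conventions state both branches without a rule. Dunn's test is
implemented in-package (rank z-statistics with tie correction) because
none of the installed statistics libraries ships it. The migration
correlation is Pearson's r between per-line mean recovery rates and
migration efficiencies (ten points, not per-cell).

## What the generator does and does not emulate

It emulates: reciprocal 420/490 responses, 20 s (or finer) sampling,
two-pulse protocols, compartment-specific kinetics including the
mitochondrial decline, pH-dependent baselines with pH-independent
recovery, per-cell lognormal heterogeneity, multiplicative channel
noise, washout-only drug application, and a ten-line cohort whose
migration efficiencies are linearly coupled to k_red
(efficiency = 2 + 30·k_red %, Gaussian noise sd 8.647 truncated to
[0, 100], calibrated by Monte-Carlo so the expected 10-line sample
Pearson r is 0.77).

It does not emulate: photobleaching, focus drift, cell movement or
segmentation error, shot-noise statistics (noise is Gaussian, not
Poisson), peroxiredoxin relay chemistry, nitrosative stress, or
correlated per-cell parameter variation. Passing parameter-recovery
tests therefore shows the estimator is unbiased under the stated noise
and heterogeneity model — not that real recordings are free of the
systematic effects above.

## Numerical choices and degenerate inputs

ODE integration is LSODA (stiff-capable) at rtol 1e−8 / atol 1e−10,
integrated piecewise between protocol events so concentration steps are
exact, then sampled on the acquisition grid; θ is clipped to [0, 1] and
Hi to ≥ 0 against solver round-off. Initial conditions are the pre-pulse
steady state (fixed point including the adaptive term). Constant traces
yield A ≈ 0 fits flagged not-identifiable rather than an error; a fitted
k at the upper bound clears the converged flag. All random draws flow
from a single `numpy` Generator per simulated experiment, so equal seeds
give bit-identical traces.

## Problem sizes

Validation scenarios use 30 cells per condition (matching typical
cohort sizes of ~30–50 cells), 200 cohorts for the migration
correlation, and 2000 replicates for the type-I-error calibration of
the group test; these sizes give Monte-Carlo error comfortably inside
the stated tolerances while keeping a full run in tens of seconds.

## Known limitations

- The fitted k is the *apparent* recovery rate: H₂O₂ clearance and
  disulfide reduction are confounded in principle. The simulator
  separates them (clearance ≥ 10× k_red in all presets) so the apparent
  rate ≈ k_red; in real cells with slow clearance the estimate would be
  an underestimate of reducing capacity.
- Single-exponential only; no bi-exponential or stretched models.
- No mixed-effects treatment of experiment-level clustering (cells are
  pooled, mirroring standard practice).
- Migration efficiencies per line are synthetic by construction; only
  their coupling to k_red and the resulting correlation are anchored.
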