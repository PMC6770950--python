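# rennetmon

In-line monitoring of enzymatic milk renneting from time-resolved FT-NIR
spectra. During renneting, chymosin cleaves κ-casein, destabilized casein
micelles aggregate, and a gel network forms; the scatter- and
chemistry-driven evolution of the NIR spectrum tracks these phases in
real time. `rennetmon` implements the complete chemometric chain a
process analyst needs to turn a 30-minute series of spectra into phase
kinetics and a go/no-go decision:

* **Preprocessing** — spectral-range reduction to 12,500–5,824 cm⁻¹ and
  Standard Normal Variate (SNV) row standardization.
* **Rank selection** — SVD-based PCA of the batch matrix; the component
  count F is the number of singular values above a ratio threshold, and
  drops by one under column mean-centering when the phase fractions obey
  a closure relation.
* **Curve resolution (MCR-ALS)** — the bilinear model **D** = **C S**ᵀ +
  **E** solved by alternating least squares under non-negativity and
  per-column unimodality constraints, started from SIMPLISMA
  pure-spectrum picks, stopped when the lack of fit
  LOF(%) = 100·√(Σe²⁄Σd²) stabilizes to within 0.1% relative change.
* **Kinetics** — the sol-gel transition time CP2 (parabola-refined
  maximum of the transition-phase profile) compared with the rheological
  acceleration time AT_G′ = b − c·ln(2+√3) from a logistic fit
  G′(t) = a ⁄ (1 + e^−(t−b)/c) of the elastic modulus.
* **MSPC control charts** — PCA of in-control concentration profiles
  with Hotelling T² (F-distribution limit) and Q/SPE (Jackson–Mudholkar
  limit) statistics at 99% confidence, flagging faulty batches point by
  point.
* **Synthetic study generator** — rank-3 bilinear batches with
  sigmoid/pulse/sigmoid phase kinetics, band-shaped nonnegative spectra
  (water band near 6,900 cm⁻¹, lipid C–H bands near 8,600 and
  10,800 cm⁻¹), additive noise, paired rheology curves, and three fault
  archetypes (half rennet, heating off, half CaCl₂), so the entire chain
  is testable end to end against known ground truth.

The package also bundles the published 15-batch comparison of CP2 vs
AT_G′ across cheese-making conditions (temperature 30–40 °C, pH 6.3–6.7,
fat 0.1–5 g/100 mL) as `renneting_transition_times()`.

## Worked example

```python
import rennetmon as rm

# one in-control batch: transition at 7 min, realistic noise
kin = rm.KineticParams(transition_time=7.0)
truth = rm.make_ground_truth(kin, noise_sd=0.003)
batch = rm.simulate_batch(truth, seed=1)

# component count from the singular spectrum
sel = rm.select_rank(rm.simulate_batch(
    rm.make_ground_truth(kin, noise_sd=0.0), seed=1).absorbance)
print(sel.F, sel.F_centered)          # -> 3 2

# SIMPLISMA start + constrained alternating least squares
picks = rm.select_pure_spectra(batch.absorbance, F=3)
print(batch.times[picks.selected_indices])   # -> [ 1. 19.  6.]
model = rm.fit(batch.absorbance, picks.initial_S,
               rm.ConstraintConfig(nonneg_S=True, max_iterations=150),
               times=batch.times)
print(round(model.explained_variance_pct, 3))  # -> 99.993
tt = rm.transition_time(model)
print(round(tt.time, 2))              # -> 6.94
```

The three SIMPLISMA picks land at the start of monitoring (liquid
milk), near the transition, and well into the gel plateau; the resolved
transition-phase profile peaks within a fraction of a minute of the true
sol-gel transition.

The full study — 12 NOC batches, 3 center-point replicates, 3 fault
batches, per-batch resolution, kinetics, and control charts — runs from
the command line:

```bash
rennetmon demo --seed 1 --out report/
```

which logs, among other things

```
CP2 vs AT_G' r = 0.959 (p = 1.65e-08); rank 3 uncentered / 2 centered
t2 chart: sensitivity 0.83 specificity 0.97
q chart: sensitivity 0.97 specificity 1.00
```

— the spectroscopic and rheological transition clocks agree strongly
(the rheological one lagging by ~2–3 min, since gel stiffness responds
after micelle aggregation), and the Q chart catches essentially every
monitored point of the fault batches while leaving the held-out
in-control replicate clean. The same experiment is available as numbered
scripts under `analysis/` (01 simulate → 02 resolve → 03 kinetics →
04 monitoring), each writing its tables under `results/`.

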