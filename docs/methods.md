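# Methods

## The monitoring problem

A renneting batch is observed as a matrix **D** (M × N): M = 30 FT-NIR
absorbance spectra taken once per minute after rennet addition, N = 1730
wavenumbers over 12,500–5,824 cm⁻¹ (the region below 5,824 cm⁻¹ is
discarded as noisy and saturation-prone). Coagulation proceeds through
three overlapping phases — liquid milk while κ-casein is cleaved, a
transient aggregation phase of destabilized micelles, and gel-network
growth — and the analysis assumes the bilinear mixture model

    D = C Sᵀ + E,

where the columns of C (M × F) are the phase fractions over time, the
rows of Sᵀ (F × N) the phase spectra, and E measurement noise. F = 3
throughout.

## Preprocessing

Range reduction keeps the closed wavenumber interval [low, high]
(defaults 5,824–12,500 cm⁻¹). SNV standardizes each spectrum (row) to
mean 0 and sample (n−1) SD 1, suppressing multiplicative scatter
changes; it is applied after range reduction and is row-local, so its
result is independent of batch grouping. Column mean-centering is used
only inside exploratory PCA, never before curve resolution: subtracting
the mean spectrum removes the offset component and lowers the effective
rank by one.

One deliberate exception: the *monitoring* stage (augmented fit feeding
the control charts) resolves range-reduced **raw** absorbance rather
than SNV-treated data. In renneting, the scatter-driven intensity
growth *is* the gel-development signal, and SNV — a per-spectrum
standardization — would erase precisely the weak-gel intensity deficit
(a multiplicative effect) that distinguishes a failed batch at the end
of its run. Per-batch kinetic extraction (CP2) uses the SNV pathway,
where timing, not intensity, carries the information.

## Component count

`select_rank` returns the smallest F such that every singular value
after the F-th falls below `threshold` (default 10⁻³) times the first,
for both the given matrix and its column-centered version. On data with
an offset-plus-low-rank (closure) structure the centered count is one
lower; the simulator reproduces this exactly (below). The threshold rule
replaces the judgment call of inspecting scores and loadings by hand; an
explicit F can always be passed downstream. A ratio rule of this form is
only meaningful for spectra with a genuine low-rank gap: an i.i.d. noise
matrix has a flat Marchenko–Pastur singular spectrum and falls through
to (near) full rank, which the tests document.

## SIMPLISMA initialization

ALS needs non-random starting spectra. Purity of row i is
sd_i / (mean_i + α·max_j mean_j) with α = 0.01 by default; after the
first pick, each candidate's purity is weighted by the determinant of
the correlation-around-origin matrix of the selected rows plus the
candidate (rows scaled by √(mean² + (sd + offset)²)), so near-collinear
candidates score ≈ 0. Selection runs over rows (spectra at given times)
so the picks are directly usable as the initial Sᵀ. The denominators
use means of **absolute** values: identical on nonnegative raw spectra,
and still meaningful on SNV rows, whose plain means are identically
zero (the literal sd/mean statistic degenerates there).

## MCR-ALS

Each cycle solves C given Sᵀ and Sᵀ given C:

* **C-step**: per-row active-set nonnegative least squares
  (`scipy.optimize.nnls`), then a unimodality projection per
  concentration column — pool-adjacent-violators up to the column's
  current argmax (ties to the earlier time) and down after it. With the
  peak at the maximum the two half-fits share the peak value and their
  concatenation is the exact least-squares unimodal projection; for an
  arbitrary forced peak the shared peak value is found by a convex
  scalar search over clipped PAVA fits. In multi-set (row-wise
  augmented) data, unimodality is enforced within each batch segment
  separately while Sᵀ is shared.
* **S-step**: ordinary least squares (optionally NNLS per column when
  `nonneg_S` is on); rows of Sᵀ are scaled to unit Euclidean norm with
  the inverse scale absorbed into C, fixing the intensity ambiguity
  without changing C Sᵀ.

Convergence: the lack of fit LOF(%) = 100·√(Σe²/Σd²) is tracked per
cycle; iteration stops when its relative change drops below
`lof_rel_tol` = 0.1% (an absolute-difference mode is available), when
LOF falls below an absolute floor of 0.1% (on noise-free data the
relative criterion chases a geometrically shrinking LOF forever, and a
fit at 0.1% LOF already explains > 99.9999% of the sum of squares), or
at `max_iterations` (default 50; the bundled experiments use 150). Five
consecutive LOF increases abort the fit with the partial model attached
to the raised error.

`nonneg_S` defaults to off because the default pipeline input is SNV
data, which is legitimately negative; fits on raw absorbance should turn
it on — spectra are physically nonnegative, and the constraint is also
what pins the rotational ambiguity (below).

## Identifiability of the factorization

Non-negativity and unimodality alone do not make the rank-3 model
unique: a transition pulse can be *added* to either sigmoid profile
(still unimodal) if the compensating spectral change stays nonnegative,
and *subtracted* from it if the mixed profile stays monotone and
nonnegative. The simulator's study conditions are chosen so both leaks
are closed, which is also the regime in which the recovery tests are
meaningful:

* the transition-phase spectrum carries only trace-level lipid bands, so
  it has near-zero channels where the liquid and gel spectra are strong
  — adding pulse to a sigmoid would drive the compensated transition
  spectrum negative (blocked by `nonneg_S` on raw fits);
* the sol-gel sigmoids are sharp (logistic scale 0.8 min) while the
  pulse is wide (Gaussian SD 2.5 min), so the sigmoid tails die much
  faster than the pulse tails and subtracting any appreciable pulse
  fraction would push a sigmoid profile negative (blocked by
  non-negativity of C).

Under these conditions noiseless recovery of all three profiles exceeds
|r| = 0.999 and noisy recovery (SD 0.003) averages ≈ 0.998. With a fully
overlapped transition spectrum, or slow sigmoids, a one-parameter family
of equally well-fitting solutions exists and recovered sigmoid profiles
correlate with truth only at ≈ 0.98 — a property of the constraint set,
not of the optimizer.

## Kinetics

The transition-phase component is identified operationally (component
order out of ALS is arbitrary): among columns whose segment profile
peaks at an interior time point and both rises to and falls from the
peak, take the one with the greatest relative interior prominence. CP2
is the peak time refined by a three-point parabola, giving fractional
minutes on the 1-min grid; a monotone (boundary-peaked) profile returns
the boundary time with a warning flag instead.

The curing curve is modelled as G′(t) = a/(1 + exp(−(t−b)/c)) — scale
parameter in the denominator, so b and c are in minutes — fitted by
`scipy.optimize.curve_fit` initialized at a₀ = max G′, b₀ = the first
half-maximum crossing, c₀ = (t₇₅ − t₂₅)/(2 ln 3) (the exact quartile
spread of a logistic). Derivative critical times are closed-form:
maximum rate at b, acceleration/deceleration (second-derivative
extrema) at b ∓ c·ln(2+√3); the tests verify them against dense finite
differencing. Pearson correlation between CP2 and AT_G′ uses the
two-sided t-transform p-value with n−2 degrees of freedom, and is
cross-checked against a permutation null.

## Control charts

Charts are PCA models of in-control behavior: mean-center the training
observations, retain K components (default 1), store sample (n−1)
covariance eigenvalues. Limits at confidence 1−α (default 99%):
T² ≤ K(n−1)(n+1)/(n(n−K))·F_{K,n−K}(1−α) (small-sample form; a χ²
variant is available) and Q from the Jackson–Mudholkar approximation on
the discarded eigenvalues, falling back to a moment-matched χ² when the
approximation degenerates and pinning the limit at 0 when the training
data have no residual variance.

**Observation construction.** A renneting batch is a transient process:
the expected phase-fraction vector changes every minute, and a batch
whose only defect is delay retraces the same curve in (c₁,c₂,c₃) space
— pooled raw time points cannot see it. The pipeline therefore monitors
*deviations from the time-matched mean in-control trajectory* (the mean
over the training replicates at each minute), the standard device of
batch-process MSPC. Training observations are the replicates' own
deviations (60 points from 2 × 30); monitored batches are differenced
against the same mean trajectory. In-control deviations reflect
replicate-to-replicate jitter and noise; a delayed or weakened batch
deviates by whole phase-fraction units and is flagged within the first
few minutes. Sensitivity/specificity pool time points across monitored
batches (every point of a fault batch counts positive), reported per
chart and for the either-flag rule.

## The synthetic study

Defaults (one place: `KineticParams`, `StudyConfig`) are the study
conditions used by every test and by `scripts/acceptance.py`:

| parameter | default | meaning |
|---|---|---|
| M, Δt | 30, 1 min | spectra per batch |
| N | 1730 over 12,500–5,824 cm⁻¹ | analysis grid (simulation extends to 4,000 cm⁻¹; reduction recovers exactly 1730 points) |
| transition_time | U(5.5, 17) min across NOC batches | spread of sol-gel times across temperature/pH/fat conditions, matching the bundled reference table |
| steepness | 0.8 min | logistic scale of the sol-gel switch |
| transition_amplitude | 0.18 | pulse peak; keeps row sums ≤ 1.2 without rescaling |
| pulse_width | 2.5 min | Gaussian SD of the aggregation pulse |
| noise_sd | 0.003 AU | additive i.i.d. Gaussian noise |
| replicate jitter | SD 0.3 min on transition_time | reproducibility of the center-point batch |
| rheology lag | U(1.3, 5.2) min | AT_G′ − CP2, matching the reference table's spread |
| fault severity | 0.5 | scaling of the three fault archetypes |

The liquid and gel fractions are complementary logistics (c₁ + c₃ = 1
for in-control batches), so the noiseless matrix is exactly rank 3 and
exactly rank 2 after column centering — the closure structure behind
the rank-drop rule. The half-CaCl₂, half-rennet and heating-off faults
all delay the transition (by ≥ 2 min at severity 0.5) and reduce the
gel plateau; severity 0 is the identity. The fault scaling rules are
this package's own contract, asserted in tests, not measured values.

What the generator does *not* emulate: multiplicative scatter and
baseline drift (the very effects SNV exists for — SNV is exercised for
correctness, not benefit), wavelength-dependent noise, temperature/pH
acting on spectra other than through kinetics, and rheological
syneresis (the G′ collapse seen in very fast batches). Passing tests
therefore validate the algorithmic chain against a faithful bilinear
world, not instrument physics.

## Numerical choices and limitations

* SNV uses the sample (n−1) SD; constant rows are rejected.
* PCA loading signs are fixed by making each loading's
  largest-magnitude element positive.
* Delimited-text writes keep 17 significant digits, so read(write(b))
  round-trips bit-exactly.
* The transition-time parabola is clipped to its three-point support;
  an upward/flat parabola falls back to the grid point.
* Sub-seeds for pipeline stages are drawn from one root generator and
  kept below 2³¹.
* Problem sizes in the bundled experiments (10-batch recovery runs,
  5 study repetitions, 10⁴ calibration draws) were chosen to make the
  Monte-Carlo spread of each reported statistic small relative to its
  acceptance margin.
* Known limitations: monitored batches must come from the same
  augmented fit as the training replicates (cross-model monitoring is
  refused rather than column-matched); no rotational-ambiguity range
  analysis (MCR-BANDS) is provided; the mapping from operating
  conditions to kinetic parameters is illustrative, as no quantitative
  kinetic law links temperature/pH/fat to profile timing.
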