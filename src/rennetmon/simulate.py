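"""Synthetic renneting-batch generator.

Emulates the statistical structure the analysis chain assumes: each batch
is a rank-3 bilinear absorbance matrix D = C S^T + E where the three
columns of C are the phase fractions of enzymatic milk coagulation over
time — a decreasing sigmoid (liquid milk, kappa-casein proteolysis), a
unimodal pulse (paracasein aggregation, the sol-gel transition), and an
increasing sigmoid (gel network growth) — and the rows of S^T are
nonnegative band-shaped NIR profiles with features near the water band at
6,900 cm^-1 and the lipid C-H bands at 8,600 and 10,800 cm^-1.

The liquid and gel sigmoids are exact complements (same midpoint and
time-scale), so for an in-control batch the phase fractions of phases 1
and 3 sum to one at every time point. The noiseless absorbance matrix is
then exactly rank 3, and exactly rank 2 after column mean-centering — the
offset-plus-low-rank structure that makes the component count drop by one
under centering.

Default study conditions: 30 spectra at 1-min intervals, 1730 wavenumbers
spanning 12,500-5,824 cm^-1, additive i.i.d. Gaussian noise with SD 0.003
absorbance units.

Fault archetypes (scaling rules are this module's own contract; severity 0
is the identity):

====================  =====================================================
kind                  effect on kinetics at severity ``s``
====================  =====================================================
``half_rennet``       transition_time x (1 + s); transition_amplitude
                      x (1 - 0.5 s); gel_plateau x (1 - 0.6 s) — slower,
                      weaker transition and an underdeveloped gel
``heating_off``       transition_time + 6 s min; steepness x (1 + 2 s);
                      gel_plateau x (1 - 0.5 s) — delayed, sluggish
                      kinetics after the heater stops
``half_cacl2``        transition_time + 5 s min; transition_amplitude
                      x (1 - 0.7 s); gel_plateau x (1 - 0.5 s) — delayed
                      transition and a weaker final gel
====================  =====================================================

At severity 0.5 every rule moves the transition-pulse peak by >= 2 min,
which is what makes the downstream control charts able to see the fault.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .preprocess import SpectralBatch

__all__ = [
    "KineticParams",
    "GroundTruth",
    "FaultSpec",
    "RheologyCurve",
    "FAULT_KINDS",
    "default_times",
    "default_wavenumber_grid",
    "make_concentration_profiles",
    "make_spectral_profiles",
    "make_ground_truth",
    "simulate_batch",
    "apply_fault",
    "simulate_rheology",
    "logistic_gprime",
    "draw_noc_kinetics",
    "rheology_params_for",
]

#: Paper-grid constants: 30 one-minute acquisitions, 1730 wavenumbers.
DEFAULT_M = 30
DEFAULT_N = 1730
GRID_HIGH = 12500.0
GRID_LOW = 5824.0

FAULT_KINDS = ("half_rennet", "heating_off", "half_cacl2")

# ln(2 + sqrt(3)): offset (in units of the logistic scale c) between the
# midpoint and the extrema of the second derivative of a logistic curve.
ACCEL_FACTOR = float(np.log(2.0 + np.sqrt(3.0)))


@dataclass(frozen=True)
class KineticParams:
    """Kinetic parameterization of one renneting batch.

    transition_time : minutes
        Center of the sol-gel transition (peak of the phase-2 pulse and
        midpoint of the liquid/gel sigmoids). Must lie in (0, 30).
    steepness : minutes
        Time-scale of the sol-gel phase change (logistic scale).
    transition_amplitude : dimensionless, (0, 1]
        Peak height of the phase-2 pulse.
    pulse_width : minutes
        Gaussian SD of the phase-2 pulse.
    gel_plateau : dimensionless, (0, 1]
        Final level of the gel-phase sigmoid; 1 for in-control batches,
        reduced by the half-CaCl2 fault.
    """

    transition_time: float
    steepness: float = 0.8
    transition_amplitude: float = 0.18
    pulse_width: float = 2.5
    gel_plateau: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.transition_time < 30.0 + 1e-9:
            # fault scalings may push past 30; allow up to the window end +
            # a margin so a delayed transition stays representable
            if not 0.0 < self.transition_time < 60.0:
                raise ValueError(
                    f"transition_time {self.transition_time} out of range"
                )
        if self.steepness <= 0:
            raise ValueError("steepness must be positive")
        if not 0.0 < self.transition_amplitude <= 1.0:
            raise ValueError("transition_amplitude must be in (0, 1]")
        if self.pulse_width <= 0:
            raise ValueError("pulse_width must be positive")
        if not 0.0 < self.gel_plateau <= 1.0:
            raise ValueError("gel_plateau must be in (0, 1]")


@dataclass(frozen=True)
class FaultSpec:
    """A deliberate process failure injected into a batch."""

    kind: str
    onset: float = 0.0
    severity: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in FAULT_KINDS:
            raise ValueError(
                f"unknown fault kind {self.kind!r}; expected one of {FAULT_KINDS}"
            )
        if not 0.0 <= self.onset <= 30.0:
            raise ValueError("onset must be in [0, 30] minutes")
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError("severity must be in [0, 1]")


@dataclass
class GroundTruth:
    """The simulator's true factorization, kept for recovery testing."""

    C_true: np.ndarray  # (M, F) nonnegative, unimodal columns
    S_true: np.ndarray  # (F, N) nonnegative spectral profiles
    noise_sd: float
    times: np.ndarray
    wavenumbers: np.ndarray
    kinetics: KineticParams | None = None
    fault: FaultSpec | None = None


@dataclass
class RheologyCurve:
    """Oscillatory time-curing data: elastic and viscous moduli vs time."""

    times: np.ndarray
    G_prime: np.ndarray
    G_double_prime: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.G_prime = np.asarray(self.G_prime, dtype=float)
        self.G_double_prime = np.asarray(self.G_double_prime, dtype=float)
        if not (self.times.size == self.G_prime.size == self.G_double_prime.size):
            raise ValueError("times, G_prime, G_double_prime must share length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


def default_times(m: int = DEFAULT_M) -> np.ndarray:
    """1..m minutes at 1-min intervals (acquisition starts 1 min after rennet)."""
    return np.arange(1, m + 1, dtype=float)


def default_wavenumber_grid(
    n: int = DEFAULT_N, low: float = GRID_LOW, high: float = GRID_HIGH
) -> np.ndarray:
    """Decreasing grid of n evenly spaced wavenumbers from high to low cm^-1."""
    return np.linspace(high, low, n)


def make_concentration_profiles(
    kinetics: KineticParams, times: np.ndarray
) -> np.ndarray:
    """Phase-fraction matrix (M, 3) over the acquisition grid.

    Column 0: liquid phase, logistic decreasing through ``transition_time``.
    Column 1: transition phase, Gaussian pulse peaking at ``transition_time``.
    Column 2: gel phase, logistic increasing, plateau ``gel_plateau``.

    Columns 0 and 2 share midpoint and scale, so for ``gel_plateau == 1``
    they sum to exactly one at every time point. All entries lie in [0, 1];
    if a row sum would exceed 1.2 the whole matrix is rescaled by a single
    factor (which preserves unimodality and peak placement).
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 5:
        raise ValueError("times must be a 1-D grid with at least 5 points")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    k = kinetics
    u = (times - k.transition_time) / k.steepness
    liquid = 1.0 / (1.0 + np.exp(u))
    gel = k.gel_plateau / (1.0 + np.exp(-u))
    pulse = k.transition_amplitude * np.exp(
        -0.5 * ((times - k.transition_time) / k.pulse_width) ** 2
    )
    C = np.column_stack([liquid, pulse, gel])
    max_row_sum = C.sum(axis=1).max()
    if max_row_sum > 1.2:
        C *= 1.2 / max_row_sum
    return C


# Band centers (cm^-1): water O-H stretch combination and lipid C-H bands.
_BAND_CENTERS = (6900.0, 8600.0, 10800.0)


def make_spectral_profiles(grid: np.ndarray, seed: int) -> np.ndarray:
    """Nonnegative spectral profiles (3, N): sums of Gaussian bands.

    Each phase's profile carries bands near all three characteristic
    positions — 6,900 (water O-H), 8,600 and 10,800 cm^-1 (lipid C-H) —
    with a distinct, seeded pattern of relative heights. The liquid and
    gel profiles are broad-band; the transition-phase profile is dominated
    by its water-band feature, with only trace-level lipid bands. Those
    near-zero regions give the transition component partial spectral
    selectivity, which is what makes the bilinear factorization
    identifiable under non-negativity and unimodality alone (a fully
    overlapped transition spectrum would leave a rotational-ambiguity
    family of equally well-fitting solutions).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.min() > GRID_LOW or grid.max() < GRID_HIGH:
        raise ValueError(
            f"grid must cover {GRID_LOW:g}-{GRID_HIGH:g} cm^-1 "
            f"(got {grid.min():g}-{grid.max():g})"
        )
    rng = np.random.default_rng(seed)
    profiles = np.zeros((3, grid.size))
    # phase 0 = liquid, 1 = transition, 2 = gel; dominant band per phase
    dominant = {0: 0, 1: 0, 2: 2}  # liquid/transition: water band; gel: 10800
    for f in range(3):
        if f == 1:
            # transition phase: strong, narrow water-band feature shifted a
            # little off-center; lipid bands only at trace height
            heights = rng.uniform(0.002, 0.008, size=3)
            heights[0] = rng.uniform(0.6, 0.8)
            widths = rng.uniform(120.0, 200.0, size=3)
            shift = rng.uniform(120.0, 220.0)
        else:
            heights = rng.uniform(0.15, 0.45, size=3)
            heights[dominant[f]] += 0.6
            widths = rng.uniform(250.0, 450.0, size=3)
            shift = rng.uniform(-40.0, 40.0)
        for c, h, w in zip(_BAND_CENTERS, heights, widths):
            center = c + (shift if c == _BAND_CENTERS[0] else rng.uniform(-40, 40))
            profiles[f] += h * np.exp(-0.5 * ((grid - center) / w) ** 2)
        if f != 1:
            for _ in range(2):  # minor bands anywhere in range
                c = rng.uniform(GRID_LOW, GRID_HIGH)
                h = rng.uniform(0.02, 0.10)
                w = rng.uniform(150.0, 350.0)
                profiles[f] += h * np.exp(-0.5 * ((grid - c) / w) ** 2)
    sv = np.linalg.svd(profiles, compute_uv=False)
    if sv[2] <= 1e-6 * sv[0]:  # pragma: no cover - construction prevents this
        raise RuntimeError("generated spectral profiles are nearly collinear")
    return profiles


def make_ground_truth(
    kinetics: KineticParams,
    *,
    times: np.ndarray | None = None,
    wavenumbers: np.ndarray | None = None,
    noise_sd: float = 0.003,
    spectra_seed: int = 0,
    fault: FaultSpec | None = None,
) -> GroundTruth:
    """Assemble the true C, S^T pair for one batch."""
    if times is None:
        times = default_times()
    if wavenumbers is None:
        wavenumbers = default_wavenumber_grid()
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    C = make_concentration_profiles(kinetics, times)
    S = make_spectral_profiles(wavenumbers, spectra_seed)
    return GroundTruth(
        C_true=C,
        S_true=S,
        noise_sd=noise_sd,
        times=np.asarray(times, dtype=float),
        wavenumbers=np.asarray(wavenumbers, dtype=float),
        kinetics=kinetics,
        fault=fault,
    )


def simulate_batch(truth: GroundTruth, seed: int) -> SpectralBatch:
    """D = C_true S_true + i.i.d. Gaussian noise of SD ``truth.noise_sd``."""
    C, S = truth.C_true, truth.S_true
    if C.ndim != 2 or S.ndim != 2 or C.shape[1] != S.shape[0]:
        raise ValueError(
            f"dimension mismatch: C_true is {C.shape}, S_true is {S.shape}"
        )
    rng = np.random.default_rng(seed)
    D = C @ S
    if truth.noise_sd > 0:
        D = D + rng.normal(0.0, truth.noise_sd, size=D.shape)
    meta: dict = {"seed": int(seed), "noise_sd": float(truth.noise_sd)}
    if truth.kinetics is not None:
        meta["kinetics"] = vars(truth.kinetics).copy()
    if truth.fault is not None:
        meta["fault"] = vars(truth.fault).copy()
    return SpectralBatch(
        times=truth.times.copy(),
        wavenumbers=truth.wavenumbers.copy(),
        absorbance=D,
        meta=meta,
    )


def apply_fault(kinetics: KineticParams, fault: FaultSpec) -> KineticParams:
    """Kinetic parameters of a faulted batch (rules in the module docstring)."""
    s = fault.severity
    if fault.kind == "half_rennet":
        return replace(
            kinetics,
            transition_time=kinetics.transition_time * (1.0 + s),
            transition_amplitude=kinetics.transition_amplitude * (1.0 - 0.5 * s),
            gel_plateau=kinetics.gel_plateau * (1.0 - 0.6 * s),
        )
    if fault.kind == "heating_off":
        return replace(
            kinetics,
            transition_time=kinetics.transition_time + 6.0 * s,
            steepness=kinetics.steepness * (1.0 + 2.0 * s),
            gel_plateau=kinetics.gel_plateau * (1.0 - 0.5 * s),
        )
    if fault.kind == "half_cacl2":
        return replace(
            kinetics,
            transition_time=kinetics.transition_time + 5.0 * s,
            transition_amplitude=kinetics.transition_amplitude * (1.0 - 0.7 * s),
            gel_plateau=kinetics.gel_plateau * (1.0 - 0.5 * s),
        )
    raise ValueError(f"unknown fault kind {fault.kind!r}")  # pragma: no cover


def logistic_gprime(t: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    """Elastic-modulus model G'(t) = a / (1 + exp(-(t - b) / c))."""
    t = np.asarray(t, dtype=float)
    return a / (1.0 + np.exp(-(t - b) / c))


def simulate_rheology(
    a: float,
    b: float,
    c: float,
    times: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> RheologyCurve:
    """Time-curing curve from the logistic gel-growth model plus noise.

    G' follows ``a / (1 + exp(-(t-b)/c))`` (monotone increasing for c > 0);
    G'' is emulated as a scaled-down copy of G' — it is carried for
    completeness, not modeled.
    """
    if a <= 0:
        raise ValueError("plateau a must be positive")
    if c == 0:
        raise ValueError("scale c must be nonzero")
    times = np.asarray(times, dtype=float)
    g = logistic_gprime(times, a, b, c)
    g2 = 0.35 * g
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        g = g + rng.normal(0.0, noise_sd, size=g.shape)
        g2 = g2 + rng.normal(0.0, 0.35 * noise_sd, size=g.shape)
    return RheologyCurve(times=times, G_prime=g, G_double_prime=g2)


def draw_noc_kinetics(rng: np.random.Generator) -> KineticParams:
    """Kinetics of a normal-operating-condition batch.

    Operating conditions (temperature, pH, fat) act only through the
    kinetic parameters; transition times are drawn uniformly over
    5.5-17 min, the spread of sol-gel transition times observed across
    NOC-style temperature/pH/fat combinations.
    """
    return KineticParams(
        transition_time=float(rng.uniform(5.5, 17.0)),
        steepness=float(rng.uniform(0.7, 0.95)),
        transition_amplitude=float(rng.uniform(0.14, 0.2)),
        pulse_width=float(rng.uniform(2.2, 2.8)),
    )


def jitter_kinetics(
    kinetics: KineticParams, rng: np.random.Generator, sd_minutes: float = 0.3
) -> KineticParams:
    """Replicate-to-replicate variability: small shift of the transition time."""
    return replace(
        kinetics,
        transition_time=float(
            kinetics.transition_time + rng.normal(0.0, sd_minutes)
        ),
    )


def rheology_params_for(
    kinetics: KineticParams, rng: np.random.Generator
) -> tuple[float, float, float]:
    """Logistic (a, b, c) for the rheology curve paired with a batch.

    The curing midpoint is placed so the acceleration time
    AT = b - c ln(2 + sqrt(3)) lags the spectroscopic transition by a
    random 1.3-5.2 min — gel stiffness responds a few minutes after the
    micelle-aggregation signature seen in the NIR.
    """
    a = float(rng.uniform(60.0, 140.0))
    c = float(rng.uniform(1.2, 2.0))
    lag = float(rng.uniform(1.3, 5.2))
    b = kinetics.transition_time + lag + c * ACCEL_FACTOR
    return a, b, c
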