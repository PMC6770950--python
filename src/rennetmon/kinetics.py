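"""Gelation kinetics: transition times from resolved profiles and rheology.

Two clocks time the sol-gel transition of renneted milk:

* **CP2** — the time at which the second (transition-phase) resolved
  concentration profile peaks; the casein-micelle aggregation signature
  seen by the spectrometer.
* **AT_G'** — the acceleration time of the elastic modulus: the maximum of
  the second derivative of a logistic fit G'(t) = a / (1 + exp(-(t-b)/c)),
  i.e. the onset of fast gel stiffening seen by the rheometer.

For the logistic model the derivative critical points are closed-form:
the first derivative peaks at the midpoint b, and the second derivative
has its maximum / minimum at b -/+ c ln(2 + sqrt(3)).

Profiles are sampled once per minute, but the transition peak rarely sits
exactly on a grid point; a three-point parabola through the peak and its
neighbors refines CP2 to fractional minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .mcr import MCRModel
from .simulate import ACCEL_FACTOR, RheologyCurve, logistic_gprime

__all__ = [
    "SigmoidFit",
    "KineticTimes",
    "TransitionTime",
    "SigmoidFitError",
    "identify_transition_component",
    "transition_time",
    "fit_sigmoid",
    "critical_times",
    "pearson",
]


@dataclass(frozen=True)
class SigmoidFit:
    """Logistic parameters of a time-curing curve."""

    a: float  # plateau, Pa
    b: float  # midpoint, minutes
    c: float  # time scale, minutes
    rss: float  # residual sum of squares, Pa^2

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("plateau a must be positive")
        if self.c == 0:
            raise ValueError("scale c must be nonzero")
        if self.rss < 0:
            raise ValueError("rss must be nonnegative")


@dataclass(frozen=True)
class KineticTimes:
    """Derivative critical times of a fitted curing curve (minutes)."""

    max_rate_time: float
    acceleration_time: float
    deceleration_time: float
    cp2: float | None = None  # spectroscopic transition, if paired


@dataclass(frozen=True)
class TransitionTime:
    """Spectroscopic sol-gel transition estimate for one batch."""

    time: float  # minutes
    component: int  # index of the transition-phase profile
    on_boundary: bool  # peak sat on the first/last time point


class SigmoidFitError(RuntimeError):
    """Logistic fit failed; carries the initialization used."""

    def __init__(self, message: str, init: tuple[float, float, float]):
        super().__init__(f"{message} (initialization a={init[0]:.4g}, "
                         f"b={init[1]:.4g}, c={init[2]:.4g})")
        self.init = init


def identify_transition_component(
    model: MCRModel, batch_index: int = 0
) -> int | None:
    """Index of the transition-phase (unimodal pulse) profile.

    Resolved component order is arbitrary, so the transition profile is
    found operationally: among components whose concentration column
    within the batch's segment peaks at an interior time point and both
    rises to and falls from that peak, pick the one with the greatest
    relative interior prominence. Returns None when no component
    qualifies (e.g. all profiles monotone).
    """
    seg = model.segments()[batch_index]
    best, best_score = None, 0.0
    for j in range(model.n_components):
        col = model.C[seg, j]
        p = int(np.argmax(col))
        if p == 0 or p == col.size - 1 or col[p] <= 0:
            continue
        if not (col[p] > col[0] and col[p] > col[-1]):
            continue
        score = (col[p] - max(col[0], col[-1])) / col[p]
        if score > best_score:
            best, best_score = j, score
    return best


def transition_time(
    model: MCRModel,
    batch_index: int = 0,
    component: int | None = None,
) -> TransitionTime:
    """CP2: time of the transition profile's maximum, parabola-refined.

    If the selected column peaks on the segment boundary (a degenerate,
    monotone profile) the boundary time is returned with
    ``on_boundary=True``.
    """
    if model.n_components < 2:
        raise ValueError("need at least 2 components to identify a transition")
    if model.times is None:
        raise ValueError("model carries no time axis")
    seg = model.segments()[batch_index]
    times = model.times[seg]
    if component is None:
        component = identify_transition_component(model, batch_index)
    if component is None:
        # no pulse-like profile: report the most prominent interior-free
        # column's argmax as a boundary case
        col = model.C[seg, :].max(axis=1)
        p = int(np.argmax(col))
        return TransitionTime(time=float(times[p]), component=-1, on_boundary=True)
    col = model.C[seg, component]
    p = int(np.argmax(col))
    if p == 0 or p == col.size - 1:
        return TransitionTime(
            time=float(times[p]), component=component, on_boundary=True
        )
    # 3-point parabola vertex through (t_{p-1..p+1}, y_{p-1..p+1})
    t3, y3 = times[p - 1 : p + 2], col[p - 1 : p + 2]
    coeffs = np.polyfit(t3, y3, 2)
    if coeffs[0] >= 0:  # degenerate (flat or upward) — keep the grid point
        refined = float(times[p])
    else:
        refined = float(-coeffs[1] / (2.0 * coeffs[0]))
        refined = float(np.clip(refined, t3[0], t3[2]))
    return TransitionTime(time=refined, component=component, on_boundary=False)


def _first_crossing(times: np.ndarray, y: np.ndarray, level: float) -> float:
    """Linear-interpolated first upward crossing of ``level``."""
    above = y >= level
    if above[0] or not above.any():
        return float(times[0])
    i = int(np.argmax(above))
    t0, t1, y0, y1 = times[i - 1], times[i], y[i - 1], y[i]
    if y1 == y0:
        return float(t1)
    return float(t0 + (level - y0) * (t1 - t0) / (y1 - y0))


def fit_sigmoid(curve: RheologyCurve) -> SigmoidFit:
    """Nonlinear least-squares logistic fit of G' versus time.

    Initialization: a0 = max(G'); b0 = first half-maximum crossing;
    c0 = (t75 - t25) / (2 ln 3), the exact quartile spread of a logistic.
    Raises :class:`SigmoidFitError` on flat curves or non-convergence.
    """
    t, g = curve.times, curve.G_prime
    if t.size < 4:
        raise ValueError("need at least 4 points to fit a sigmoid")
    span = float(g.max() - g.min())
    if span <= 0 or span < 1e-9 * max(1.0, abs(float(g.max()))):
        raise SigmoidFitError("flat curve: no dynamic range", (0.0, 0.0, 0.0))
    a0 = float(g.max())
    b0 = _first_crossing(t, g, 0.5 * a0)
    t25 = _first_crossing(t, g, 0.25 * a0)
    t75 = _first_crossing(t, g, 0.75 * a0)
    c0 = max((t75 - t25) / (2.0 * np.log(3.0)), 1e-3)
    init = (a0, b0, c0)
    try:
        popt, _ = optimize.curve_fit(
            logistic_gprime, t, g, p0=init, maxfev=10000
        )
    except RuntimeError as exc:
        raise SigmoidFitError(f"logistic fit did not converge: {exc}", init)
    a, b, c = (float(v) for v in popt)
    if a <= 0 or c == 0:
        raise SigmoidFitError("fit collapsed to a degenerate logistic", init)
    rss = float(np.sum((g - logistic_gprime(t, a, b, c)) ** 2))
    return SigmoidFit(a=a, b=b, c=c, rss=rss)


def critical_times(fit: SigmoidFit, cp2: float | None = None) -> KineticTimes:
    """Closed-form derivative critical times of the logistic fit.

    max_rate_time = b; acceleration_time = b - c ln(2 + sqrt(3));
    deceleration_time = b + c ln(2 + sqrt(3)). Requires c > 0 (a growing
    gel).
    """
    if fit.c <= 0:
        raise ValueError("critical times require c > 0")
    offset = fit.c * ACCEL_FACTOR
    return KineticTimes(
        max_rate_time=fit.b,
        acceleration_time=fit.b - offset,
        deceleration_time=fit.b + offset,
        cp2=cp2,
    )


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with the two-sided t-transform p-value (n - 2 dof)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
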