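"""Multivariate curve resolution by alternating least squares (MCR-ALS).

Factorizes a time-resolved absorbance matrix D (M x N) into concentration
profiles C (M x F) and spectral profiles S^T (F x N),

    D = C S^T + E,

by alternating constrained least-squares steps: given S^T solve for C,
given C solve for S^T, until the lack of fit stabilizes. Constraints:
non-negativity on C (per-row active-set NNLS), unimodality on each
concentration column (pool-adjacent-violators projection about the
column's current peak), optional non-negativity on S^T, and unit-length
normalization of the spectral profiles with the inverse scale absorbed
into C (the bilinear model fixes C S^T only up to per-component scale).

Multi-set data — several batches stacked row-wise sharing one S^T — are
handled through a layout of sub-matrix boundaries; unimodality is then
enforced within each batch segment separately.

Lack of fit (percent): LOF = 100 * sqrt(sum(e_ij^2) / sum(d_ij^2)).
Iteration stops when the relative LOF change between consecutive cycles
drops below ``lof_rel_tol`` percent (default 0.1%), or diverges if LOF
rises five cycles in a row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import isotonic_regression, nnls

__all__ = [
    "ConstraintConfig",
    "MCRModel",
    "McrDivergenceError",
    "lof",
    "enforce_unimodality",
    "solve_C",
    "solve_S",
    "fit",
    "match_components",
]


@dataclass(frozen=True)
class ConstraintConfig:
    """Constraint and convergence settings for the ALS optimization.

    ``lof_rel_tol`` is in percent: with the default 0.1 and relative mode
    the loop stops when |LOF_k - LOF_{k-1}| / LOF_{k-1} < 0.001. Absolute
    mode (``stop_mode="absolute"``) compares |LOF_k - LOF_{k-1}| < 0.1
    percentage points instead.

    ``nonneg_S`` defaults to off: the resolution is typically run on
    SNV-standardized spectra, which are legitimately negative. Turn it on
    when fitting raw absorbance, where spectra are physically nonnegative
    — it is also what pins the rotational ambiguity on well-separated
    data.

    ``lof_floor`` (percent) declares convergence outright once the LOF
    falls below it: on noise-free data the relative criterion can chase a
    geometrically shrinking LOF forever, and a fit below 0.1% LOF already
    explains >99.9999% of the sum of squares.
    """

    nonneg_C: bool = True
    unimodal_C: bool = True
    nonneg_S: bool = False
    s_normalization: str = "unit_length"  # or "none"
    lof_rel_tol: float = 0.1
    stop_mode: str = "relative"  # or "absolute"
    lof_floor: float = 0.1
    max_iterations: int = 50

    def __post_init__(self) -> None:
        if self.lof_rel_tol <= 0:
            raise ValueError("lof_rel_tol must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.s_normalization not in ("none", "unit_length"):
            raise ValueError("s_normalization must be 'none' or 'unit_length'")
        if self.stop_mode not in ("relative", "absolute"):
            raise ValueError("stop_mode must be 'relative' or 'absolute'")


@dataclass
class MCRModel:
    """Resolved bilinear model with fit diagnostics."""

    C: np.ndarray  # (sum M_b, F)
    S_T: np.ndarray  # (F, N)
    lof_history: list[float]
    explained_variance_pct: float
    residual_sd: float
    iterations: int
    converged: bool
    layout: list[int] = field(default_factory=lambda: [0])
    times: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.C.shape[1]

    def segments(self) -> list[slice]:
        edges = list(self.layout) + [self.C.shape[0]]
        return [slice(edges[i], edges[i + 1]) for i in range(len(self.layout))]

    def reconstruct(self) -> np.ndarray:
        return self.C @ self.S_T


class McrDivergenceError(RuntimeError):
    """ALS aborted after the lack of fit rose five cycles in a row."""

    def __init__(self, message: str, model: MCRModel):
        super().__init__(message)
        self.model = model


def lof(D: np.ndarray, D_hat: np.ndarray) -> float:
    """Lack of fit in percent: 100 sqrt(sum (d - d_hat)^2 / sum d^2)."""
    D = np.asarray(D, dtype=float)
    D_hat = np.asarray(D_hat, dtype=float)
    if D.shape != D_hat.shape:
        raise ValueError(f"shape mismatch: {D.shape} vs {D_hat.shape}")
    denom = float(np.sum(D**2))
    if denom == 0:
        raise ValueError("lack of fit undefined for an all-zero data matrix")
    return 100.0 * float(np.sqrt(np.sum((D - D_hat) ** 2) / denom))


def enforce_unimodality(
    column: np.ndarray, peak_index: int | None = None
) -> np.ndarray:
    """Least-squares projection onto unimodal sequences with a given peak.

    Output is non-decreasing up to ``peak_index`` and non-increasing after
    it; among all such sequences it minimizes the squared distance to the
    input for the chosen peak. Default peak is the input's argmax, ties
    broken toward the earlier time point. Idempotent.

    Implementation: pool-adjacent-violators (isotonic regression) per
    segment. When the chosen peak holds the column maximum, ascending
    PAVA up to the peak and descending PAVA from it both leave the peak
    value unchanged, so their concatenation solves the joint problem.
    For an arbitrary forced peak the two half-fits are coupled through
    the shared peak value v; each side's optimum given v is its PAVA fit
    clipped at v, and the total squared error is convex in v, minimized
    by a bounded scalar search.
    """
    x = np.asarray(column, dtype=float)
    if x.ndim != 1:
        raise ValueError("column must be 1-D")
    if not np.all(np.isfinite(x)):
        raise ValueError("column contains non-finite entries")
    p = int(np.argmax(x)) if peak_index is None else int(peak_index)
    if not 0 <= p < x.size:
        raise ValueError(f"peak_index {p} out of range")
    if x[p] == x.max():  # fast path: the two half-fits agree at the peak
        out = x.copy()
        if p > 0:
            out[: p + 1] = isotonic_regression(x[: p + 1], increasing=True).x
        if p < x.size - 1:
            out[p:] = isotonic_regression(x[p:], increasing=False).x
        return out
    from scipy.optimize import minimize_scalar

    left = x[:p]
    right = x[p + 1 :]
    asc = isotonic_regression(left, increasing=True).x if left.size else left
    desc = (
        isotonic_regression(right, increasing=False).x if right.size else right
    )

    def cost(v: float) -> float:
        total = (v - x[p]) ** 2
        if left.size:
            total += float(np.sum((np.minimum(asc, v) - left) ** 2))
        if right.size:
            total += float(np.sum((np.minimum(desc, v) - right) ** 2))
        return total

    res = minimize_scalar(
        cost, bounds=(float(x.min()), float(x.max())), method="bounded",
        options={"xatol": 1e-12},
    )
    v = float(res.x)
    out = np.empty_like(x)
    out[:p] = np.minimum(asc, v)
    out[p] = v
    out[p + 1 :] = np.minimum(desc, v)
    return out


def _check_segments(layout: Sequence[int] | None, m: int) -> list[slice]:
    edges = list(layout) if layout else [0]
    if edges[0] != 0 or any(b >= m for b in edges[1:]) or sorted(edges) != edges:
        raise ValueError(f"invalid layout boundaries {edges} for {m} rows")
    edges.append(m)
    return [slice(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]


def solve_C(
    D: np.ndarray,
    S_T: np.ndarray,
    config: ConstraintConfig = ConstraintConfig(),
    layout: Sequence[int] | None = None,
) -> np.ndarray:
    """Constrained least-squares concentration step.

    Each row of C minimizes ||d - S c||^2, subject to c >= 0 when
    ``nonneg_C`` (active-set NNLS per row); unimodality is then enforced
    column-wise within each sub-matrix segment.
    """
    D = np.asarray(D, dtype=float)
    S_T = np.asarray(S_T, dtype=float)
    f = S_T.shape[0]
    if np.linalg.matrix_rank(S_T) < f:
        raise ValueError("S_T is rank-deficient; cannot solve for C")
    S = S_T.T  # (N, F)
    m = D.shape[0]
    C = np.empty((m, f))
    if config.nonneg_C:
        for i in range(m):
            C[i], _ = nnls(S, D[i])
    else:
        C = np.linalg.lstsq(S, D.T, rcond=None)[0].T
    if config.unimodal_C:
        for seg in _check_segments(layout, m):
            for j in range(f):
                C[seg, j] = enforce_unimodality(C[seg, j])
    return C


def solve_S(
    D: np.ndarray,
    C: np.ndarray,
    config: ConstraintConfig = ConstraintConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Spectral step: least-squares S^T given C, plus rescaled C.

    Returns ``(S_T, C_out)``. With ``s_normalization="unit_length"`` each
    row of S^T is scaled to Euclidean norm 1 and the inverse scale is
    absorbed into the corresponding column of C, leaving C S^T unchanged.
    """
    D = np.asarray(D, dtype=float)
    C = np.asarray(C, dtype=float)
    f = C.shape[1]
    if np.linalg.matrix_rank(C) < f:
        raise ValueError("C is rank-deficient; cannot solve for S_T")
    if config.nonneg_S:
        S_T = np.empty((f, D.shape[1]))
        for j in range(D.shape[1]):
            S_T[:, j], _ = nnls(C, D[:, j])
    else:
        S_T = np.linalg.lstsq(C, D, rcond=None)[0]
    C_out = C.copy()
    if config.s_normalization == "unit_length":
        norms = np.linalg.norm(S_T, axis=1)
        if np.any(norms == 0):
            raise ValueError("a spectral profile collapsed to zero")
        S_T = S_T / norms[:, None]
        C_out = C_out * norms[None, :]
    return S_T, C_out


def fit(
    D: np.ndarray,
    initial_S_T: np.ndarray,
    config: ConstraintConfig = ConstraintConfig(),
    layout: Sequence[int] | None = None,
    times: np.ndarray | None = None,
) -> MCRModel:
    """Run the alternating least-squares optimization to convergence.

    Starting from spectral estimates ``initial_S_T`` (e.g. SIMPLISMA
    picks), alternates the C and S^T steps, tracking the lack of fit per
    full cycle. Stops when the LOF change criterion in ``config`` is met
    or ``max_iterations`` cycles have run; raises
    :class:`McrDivergenceError` (carrying the partial model) if the LOF
    rises five cycles in a row.
    """
    D = np.asarray(D, dtype=float)
    S_T = np.asarray(initial_S_T, dtype=float).copy()
    f = S_T.shape[0]
    if np.linalg.matrix_rank(S_T) < f:
        raise ValueError("initial_S_T rows are linearly dependent")
    if config.s_normalization == "unit_length":
        S_T = S_T / np.linalg.norm(S_T, axis=1, keepdims=True)

    lof_history: list[float] = []
    converged = False
    rises = 0
    C = np.zeros((D.shape[0], f))
    for it in range(1, config.max_iterations + 1):
        C = solve_C(D, S_T, config, layout)
        S_T, C = solve_S(D, C, config)
        current = lof(D, C @ S_T)
        if current < config.lof_floor:
            lof_history.append(current)
            converged = True
            break
        if lof_history:
            prev = lof_history[-1]
            rises = rises + 1 if current > prev else 0
            delta = abs(current - prev)
            if config.stop_mode == "relative":
                done = prev > 0 and delta / prev < config.lof_rel_tol / 100.0
            else:
                done = delta < config.lof_rel_tol
            if done:
                lof_history.append(current)
                converged = True
                break
        lof_history.append(current)
        if rises >= 5:
            model = _build_model(
                D, C, S_T, lof_history, it, False, layout, times
            )
            raise McrDivergenceError(
                f"LOF rose for 5 consecutive cycles (last {current:.4g}%)",
                model,
            )
    return _build_model(
        D, C, S_T, lof_history, len(lof_history), converged, layout, times
    )


def match_components(
    C: np.ndarray, C_ref: np.ndarray
) -> tuple[tuple[int, ...], list[float]]:
    """Match resolved to reference profiles by best absolute correlation.

    Component order out of a bilinear factorization is arbitrary; this
    finds the permutation ``perm`` maximizing the summed |Pearson r|
    between column j of ``C`` and column ``perm[j]`` of ``C_ref`` and
    returns it with the per-component |r| values.
    """
    from itertools import permutations

    C = np.asarray(C, dtype=float)
    C_ref = np.asarray(C_ref, dtype=float)
    f = C.shape[1]
    if C_ref.shape[1] != f:
        raise ValueError("component counts differ")
    corr = np.abs(np.corrcoef(C.T, C_ref.T)[:f, f:])
    best = max(
        permutations(range(f)),
        key=lambda p: sum(corr[j, p[j]] for j in range(f)),
    )
    return best, [float(corr[j, best[j]]) for j in range(f)]


def _build_model(
    D: np.ndarray,
    C: np.ndarray,
    S_T: np.ndarray,
    lof_history: list[float],
    iterations: int,
    converged: bool,
    layout: Sequence[int] | None,
    times: np.ndarray | None,
) -> MCRModel:
    E = D - C @ S_T
    ev = 100.0 * (1.0 - float(np.sum(E**2)) / float(np.sum(D**2)))
    return MCRModel(
        C=C,
        S_T=S_T,
        lof_history=lof_history,
        explained_variance_pct=ev,
        residual_sd=float(E.std(ddof=1)),
        iterations=iterations,
        converged=converged,
        layout=list(layout) if layout else [0],
        times=None if times is None else np.asarray(times, dtype=float),
    )
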