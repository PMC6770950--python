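"""SIMPLISMA pure-spectrum selection for curve-resolution initialization.

The alternating least-squares resolution needs a non-random initial guess
of the spectral profiles. SIMPLISMA picks the F most mutually independent,
highest-purity rows of the data matrix: purity of a row is its standard
deviation over its mean (plus a noise offset), and after the first pick
each candidate's purity is down-weighted by the determinant of the
correlation-around-origin matrix of the already-selected rows plus the
candidate — so a row nearly collinear with previous picks scores ~0.

Selection runs over *rows* (spectra at given times) so the picks are
directly usable as the initial S^T estimate. On well-separated renneting
data the three picks land at the start of monitoring (liquid milk), near
the sol-gel transition, and at the end (formed gel).

Purity denominators use the mean of absolute values; on nonnegative raw
spectra this equals the plain mean, and it keeps the statistic meaningful
on SNV-standardized rows, whose plain means are identically zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PurityResult", "purity", "select_pure_spectra"]


@dataclass
class PurityResult:
    """Outcome of iterative pure-spectrum selection."""

    selected_indices: list[int]
    purity_per_round: list[np.ndarray] = field(repr=False)
    initial_S: np.ndarray = field(repr=False)  # (F, N), verbatim rows of X
    alpha: float = 0.01


def _row_stats(X: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray, float]:
    mu = np.abs(X).mean(axis=1)
    sd = X.std(axis=1)  # population SD; only the common scale matters
    offset = alpha * mu.max()
    return mu, sd, offset


def purity(X: np.ndarray, alpha: float = 0.01) -> np.ndarray:
    """First-round purity of each row: sd_i / (mean_i + alpha * max mean)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    mu, sd, offset = _row_stats(X, alpha)
    denom = mu + offset
    if np.any(denom == 0):
        raise ValueError("zero purity denominator; provide alpha > 0")
    return sd / denom


def select_pure_spectra(
    X: np.ndarray, F: int, alpha: float = 0.01
) -> PurityResult:
    """Iteratively select F mutually independent high-purity rows.

    Round 1 takes the global purity maximizer. Later rounds weight each
    candidate's purity by the determinant of the correlation-around-origin
    matrix of (selected rows, candidate), built from rows scaled by
    sqrt(mean^2 + (sd + offset)^2) — the classic SIMPLISMA recursion.
    Deterministic: ties break toward the lower row index.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    m, n = X.shape
    if not 1 <= F <= m:
        raise ValueError(f"F={F} must be in [1, {m}]")
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    mu, sd, offset = _row_stats(X, alpha)
    base_purity = sd / (mu + offset)
    # correlation-around-origin of offset-scaled rows
    scale = np.sqrt(mu**2 + (sd + offset) ** 2)
    scale[scale == 0] = 1.0
    Z = X / scale[:, None]
    coo = (Z @ Z.T) / n

    selected: list[int] = []
    rounds: list[np.ndarray] = []
    for _ in range(F):
        weighted = np.empty(m)
        for i in range(m):
            if i in selected:
                weighted[i] = -np.inf
                continue
            idx = selected + [i]
            w = float(np.linalg.det(coo[np.ix_(idx, idx)])) if selected else 1.0
            weighted[i] = max(w, 0.0) * base_purity[i]
        rounds.append(weighted.copy())
        selected.append(int(np.argmax(weighted)))
    return PurityResult(
        selected_indices=selected,
        purity_per_round=rounds,
        initial_S=X[selected].copy(),
        alpha=alpha,
    )
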