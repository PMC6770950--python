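"""PCA-based multivariate statistical process control (MSPC) charts.

A control chart is a PCA model of in-control behavior: each observation
is the vector of F resolved phase fractions at one time point of a
healthy renneting batch. New batches are monitored with two statistics
per time point:

* **Hotelling T²** — Mahalanobis distance of the observation's scores
  within the retained K-component subspace; flags shifts the in-control
  model can express.
* **Q (squared prediction error)** — squared residual distance from the
  model plane; flags behavior outside the in-control correlation
  structure.

Limits at confidence 1-alpha: T² from the small-sample F-distribution
formula K(n-1)(n+1) / (n(n-K)) * F_{K, n-K}(confidence) (a chi-squared
large-sample limit is available), and Q from the Jackson-Mudholkar
approximation built on the discarded eigenvalues, falling back to a
moment-matched chi-squared when the approximation degenerates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = [
    "ControlChart",
    "MonitoringResult",
    "ChartPerformance",
    "build_chart",
    "monitor",
    "performance",
]


@dataclass
class ControlChart:
    """Trained PCA monitoring model with T² and Q control limits."""

    train_mean: np.ndarray  # (F,)
    loadings: np.ndarray  # (F, K)
    eigenvalues: np.ndarray  # (K,) retained sample-covariance eigenvalues
    discarded_eigenvalues: np.ndarray
    t2_limit: float
    q_limit: float
    confidence: float
    n_train: int
    K: int
    t2_limit_method: str = "f"
    q_degenerate: bool = False  # no residual variance: Q limit pinned at 0
    explained_variance_pct: np.ndarray = field(
        default_factory=lambda: np.array([])
    )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "train_mean": self.train_mean.tolist(),
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "discarded_eigenvalues": self.discarded_eigenvalues.tolist(),
            "t2_limit": self.t2_limit,
            "q_limit": self.q_limit,
            "confidence": self.confidence,
            "n_train": self.n_train,
            "K": self.K,
            "t2_limit_method": self.t2_limit_method,
            "q_degenerate": self.q_degenerate,
            "explained_variance_pct": self.explained_variance_pct.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ControlChart":
        d = json.loads(Path(path).read_text())
        return cls(
            train_mean=np.array(d["train_mean"]),
            loadings=np.array(d["loadings"]),
            eigenvalues=np.array(d["eigenvalues"]),
            discarded_eigenvalues=np.array(d["discarded_eigenvalues"]),
            t2_limit=d["t2_limit"],
            q_limit=d["q_limit"],
            confidence=d["confidence"],
            n_train=d["n_train"],
            K=d["K"],
            t2_limit_method=d["t2_limit_method"],
            q_degenerate=d["q_degenerate"],
            explained_variance_pct=np.array(d["explained_variance_pct"]),
        )


@dataclass
class MonitoringResult:
    """Per-time-point statistics and off-control flags for one batch."""

    t2: np.ndarray
    q: np.ndarray
    t2_flags: np.ndarray  # bool, True = off-control
    q_flags: np.ndarray
    batch_id: str = ""


@dataclass
class ChartPerformance:
    """Pooled confusion-matrix rates; positives = points of fault batches."""

    sensitivity: float  # tp / (tp + fn); NaN when no positives
    specificity: float  # tn / (tn + fp); NaN when no negatives
    tp: int
    fp: int
    tn: int
    fn: int


def _jackson_mudholkar(
    discarded: np.ndarray, confidence: float, scale: float
) -> tuple[float, bool]:
    """Q limit from discarded eigenvalues; (limit, degenerate?).

    ``scale`` is the total eigenvalue mass, used to recognize training
    data with no meaningful residual variance (Q limit pinned at 0).
    """
    theta1 = float(np.sum(discarded))
    theta2 = float(np.sum(discarded**2))
    theta3 = float(np.sum(discarded**3))
    if theta1 <= 0 or theta2 <= 0 or theta1 <= 1e-12 * scale:
        return 0.0, True
    h0 = 1.0 - 2.0 * theta1 * theta3 / (3.0 * theta2**2)
    z = stats.norm.ppf(confidence)
    if h0 <= 0:
        # moment-matched chi-squared fallback: Q ~ g * chi2(h)
        g = theta2 / theta1
        h = theta1**2 / theta2
        return float(g * stats.chi2.ppf(confidence, h)), False
    term = (
        z * np.sqrt(2.0 * theta2 * h0**2) / theta1
        + 1.0
        + theta2 * h0 * (h0 - 1.0) / theta1**2
    )
    if term <= 0:
        g = theta2 / theta1
        h = theta1**2 / theta2
        return float(g * stats.chi2.ppf(confidence, h)), False
    return float(theta1 * term ** (1.0 / h0)), False


def build_chart(
    train_C: np.ndarray,
    K: int,
    confidence: float = 0.99,
    t2_limit_method: str = "f",
) -> ControlChart:
    """Train a control chart on stacked in-control concentration profiles.

    ``train_C`` has one row per in-control time point and one column per
    resolved phase. PCA is run on the mean-centered rows with sample
    (n-1) covariance eigenvalues; the first K components are retained.
    """
    X = np.asarray(train_C, dtype=float)
    if X.ndim != 2:
        raise ValueError("train_C must be 2-D (observations x phases)")
    n, f = X.shape
    if n <= f:
        raise ValueError(f"need more than {f} training observations, got {n}")
    if not 1 <= K <= f:
        raise ValueError(f"K={K} must be in [1, {f}]")
    if K >= n:
        raise ValueError("K must be smaller than the training size")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    if t2_limit_method not in ("f", "chi2"):
        raise ValueError("t2_limit_method must be 'f' or 'chi2'")
    mu = X.mean(axis=0)
    Xc = X - mu
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = s**2 / (n - 1)  # sample-covariance eigenvalues
    loadings = Vt[:K].T
    retained = eigvals[:K]
    discarded = eigvals[K:]
    if t2_limit_method == "f":
        t2_limit = (
            K * (n - 1) * (n + 1) / (n * (n - K))
        ) * stats.f.ppf(confidence, K, n - K)
    else:
        t2_limit = float(stats.chi2.ppf(confidence, K))
    q_limit, degenerate = _jackson_mudholkar(
        discarded, confidence, float(eigvals.sum())
    )
    total = float(eigvals.sum())
    ev_pct = 100.0 * eigvals / total if total > 0 else np.zeros_like(eigvals)
    return ControlChart(
        train_mean=mu,
        loadings=loadings,
        eigenvalues=retained,
        discarded_eigenvalues=discarded,
        t2_limit=float(t2_limit),
        q_limit=float(q_limit),
        confidence=confidence,
        n_train=n,
        K=K,
        t2_limit_method=t2_limit_method,
        q_degenerate=degenerate,
        explained_variance_pct=ev_pct,
    )


def monitor(
    chart: ControlChart, test_C: np.ndarray, batch_id: str = ""
) -> MonitoringResult:
    """Score a monitored batch's concentration profiles against a chart.

    Columns of ``test_C`` must align with the training phases — in
    practice both must come from the same augmented curve-resolution fit
    (shared spectral profiles), which aligns them by construction.
    """
    X = np.asarray(test_C, dtype=float)
    if X.ndim != 2 or X.shape[1] != chart.train_mean.size:
        raise ValueError(
            f"test_C must have {chart.train_mean.size} phase columns "
            f"(got shape {X.shape})"
        )
    Xc = X - chart.train_mean
    scores = Xc @ chart.loadings
    safe_eig = np.where(chart.eigenvalues > 0, chart.eigenvalues, np.inf)
    t2 = np.sum(scores**2 / safe_eig, axis=1)
    resid = Xc - scores @ chart.loadings.T
    q = np.sum(resid**2, axis=1)
    return MonitoringResult(
        t2=t2,
        q=q,
        t2_flags=t2 > chart.t2_limit,
        q_flags=q > chart.q_limit,
        batch_id=batch_id,
    )


def performance(
    results: list[MonitoringResult], labels: list[bool]
) -> dict[str, ChartPerformance]:
    """Pooled sensitivity/specificity per chart and for the either-flag rule.

    ``labels[i]`` is True when batch i is a fault batch; every time point
    of a fault batch counts as a positive. Returns performances keyed
    ``"t2"``, ``"q"`` and ``"either"``.
    """
    if len(results) != len(labels):
        raise ValueError("results and labels must have equal length")
    out: dict[str, ChartPerformance] = {}
    for name in ("t2", "q", "either"):
        tp = fp = tn = fn = 0
        for res, is_fault in zip(results, labels):
            if name == "t2":
                flags = res.t2_flags
            elif name == "q":
                flags = res.q_flags
            else:
                flags = res.t2_flags | res.q_flags
            pos = int(flags.sum())
            neg = int(flags.size - pos)
            if is_fault:
                tp += pos
                fn += neg
            else:
                fp += pos
                tn += neg
        sens = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
        spec = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
        out[name] = ChartPerformance(
            sensitivity=sens, specificity=spec, tp=tp, fp=fp, tn=tn, fn=fn
        )
    return out
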