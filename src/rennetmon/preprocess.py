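"""Spectral batch containers, text I/O, and spectral preprocessing.

A renneting batch is a time-resolved absorbance matrix: one FT-NIR spectrum
per minute of coagulation (rows), one column per wavenumber. This module
holds the batch container, delimited-text round-trip I/O, spectral-range
reduction, Standard Normal Variate (SNV) row standardization, column
mean-centering, and row-wise augmentation of several batches into one
multi-set matrix sharing a wavenumber grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np

__all__ = [
    "SpectralBatch",
    "BatchSet",
    "read_batch",
    "write_batch",
    "reduce_range",
    "snv",
    "mean_center",
    "augment",
]


@dataclass
class SpectralBatch:
    """One batch's absorbance matrix with time and wavenumber axes.

    Parameters
    ----------
    times : (M,) array
        Acquisition times in minutes, strictly increasing.
    wavenumbers : (N,) array
        Wavenumber axis in cm^-1, strictly monotone (either direction).
    absorbance : (M, N) array
        Absorbance, one spectrum per row.
    meta : dict
        Free-form metadata (batch id, operating conditions, fault spec,
        simulation seed ...).
    """

    times: np.ndarray
    wavenumbers: np.ndarray
    absorbance: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 2:
            raise ValueError("absorbance must be a 2-D matrix")
        m, n = self.absorbance.shape
        if self.times.shape != (m,):
            raise ValueError(
                f"times has length {self.times.size}, absorbance has {m} rows"
            )
        if self.wavenumbers.shape != (n,):
            raise ValueError(
                f"wavenumbers has length {self.wavenumbers.size}, "
                f"absorbance has {n} columns"
            )
        dw = np.diff(self.wavenumbers)
        if not (np.all(dw > 0) or np.all(dw < 0)):
            raise ValueError("wavenumbers must be strictly monotone")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")

    @property
    def n_times(self) -> int:
        return self.times.size

    @property
    def n_wavenumbers(self) -> int:
        return self.wavenumbers.size


@dataclass
class BatchSet:
    """Several batches stacked row-wise on one shared wavenumber grid."""

    batches: list[SpectralBatch]
    boundaries: list[int]  # start row of each sub-matrix in the stack

    @property
    def stacked(self) -> np.ndarray:
        return np.vstack([b.absorbance for b in self.batches])

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.batches[0].wavenumbers

    @property
    def times(self) -> np.ndarray:
        """Stacked time axis (per-batch times concatenated)."""
        return np.concatenate([b.times for b in self.batches])

    def segments(self) -> list[slice]:
        """Row slices of the stacked matrix, one per batch."""
        edges = self.boundaries + [self.boundaries[-1] + self.batches[-1].n_times]
        return [slice(edges[i], edges[i + 1]) for i in range(len(self.batches))]


def write_batch(batch: SpectralBatch, path: str | Path) -> None:
    """Write a batch as delimited text, with a JSON metadata sidecar.

    Layout: first row is the wavenumber axis (leading cell "time_min"),
    first column the acquisition times, remaining cells the absorbance.
    Values keep >= 12 significant digits so that read(write(b)) round-trips
    to full practical precision.
    """
    path = Path(path)
    with path.open("w") as fh:
        header = ",".join(["time_min"] + [f"{w:.17g}" for w in batch.wavenumbers])
        fh.write(header + "\n")
        for t, row in zip(batch.times, batch.absorbance):
            cells = ",".join([f"{t:.17g}"] + [f"{v:.17g}" for v in row])
            fh.write(cells + "\n")
    if batch.meta:
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(batch.meta, indent=2, default=_jsonable))


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dict__"):
        return vars(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def read_batch(path: str | Path) -> SpectralBatch:
    """Read a batch written by :func:`write_batch`.

    Rejects ragged rows, non-numeric cells and duplicate wavenumbers with a
    message naming the offending row or column.
    """
    path = Path(path)
    lines = path.read_text().strip().splitlines()
    if len(lines) < 2:
        raise ValueError(f"{path}: need a header row and at least one spectrum")
    header = lines[0].split(",")
    try:
        wavenumbers = np.array([float(c) for c in header[1:]])
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric wavenumber in header: {exc}") from exc
    if np.unique(wavenumbers).size != wavenumbers.size:
        dup = wavenumbers[np.where(np.diff(np.sort(wavenumbers)) == 0)[0][0]]
        raise ValueError(f"{path}: duplicate wavenumber {dup:g}")
    n = wavenumbers.size
    times = []
    rows = []
    for i, line in enumerate(lines[1:], start=2):
        cells = line.split(",")
        if len(cells) != n + 1:
            raise ValueError(
                f"{path}: row {i} has {len(cells) - 1} cells, expected {n}"
            )
        for j, c in enumerate(cells):
            if c.strip() == "":
                raise ValueError(f"{path}: empty cell at row {i}, column {j + 1}")
        try:
            values = [float(c) for c in cells]
        except ValueError:
            bad = next(j for j, c in enumerate(cells) if not _is_number(c))
            raise ValueError(
                f"{path}: non-numeric cell at row {i}, column {bad + 1}: "
                f"{cells[bad]!r}"
            ) from None
        times.append(values[0])
        rows.append(values[1:])
    meta: dict[str, Any] = {}
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return SpectralBatch(
        times=np.array(times),
        wavenumbers=wavenumbers,
        absorbance=np.array(rows),
        meta=meta,
    )


def _is_number(cell: str) -> bool:
    try:
        float(cell)
        return True
    except ValueError:
        return False


def reduce_range(
    batch: SpectralBatch, low: float = 5824.0, high: float = 12500.0
) -> SpectralBatch:
    """Keep only columns with ``low <= wavenumber <= high`` (closed interval).

    Defaults drop the noisy, saturation-prone region below 5824 cm^-1.
    Column order is preserved.
    """
    if low > high:
        raise ValueError(f"low ({low}) must not exceed high ({high})")
    keep = (batch.wavenumbers >= low) & (batch.wavenumbers <= high)
    if not np.any(keep):
        raise ValueError(
            f"no wavenumbers in [{low}, {high}] "
            f"(grid spans {batch.wavenumbers.min():g}-{batch.wavenumbers.max():g})"
        )
    return SpectralBatch(
        times=batch.times.copy(),
        wavenumbers=batch.wavenumbers[keep],
        absorbance=batch.absorbance[:, keep],
        meta=dict(batch.meta),
    )


def snv(X: np.ndarray) -> np.ndarray:
    """Standard Normal Variate: standardize each row to mean 0, sample SD 1.

    SNV suppresses the multiplicative scatter effects that dominate NIR
    spectra of turbid samples such as coagulating milk. The sample (n-1)
    standard deviation is used. Rows are transformed independently, so the
    result does not depend on which batch a spectrum sits in.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("snv needs a 2-D matrix with >= 2 columns")
    sd = X.std(axis=1, ddof=1)
    if np.any(sd == 0):
        bad = int(np.where(sd == 0)[0][0])
        raise ValueError(f"row {bad} is constant; SNV would divide by zero")
    return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]


def snv_batch(batch: SpectralBatch) -> SpectralBatch:
    """SNV applied to a batch's absorbance matrix (axes unchanged)."""
    return SpectralBatch(
        times=batch.times.copy(),
        wavenumbers=batch.wavenumbers.copy(),
        absorbance=snv(batch.absorbance),
        meta=dict(batch.meta),
    )


def mean_center(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Subtract column means; returns (centered matrix, column means)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("mean_center needs a 2-D matrix with >= 2 rows")
    mu = X.mean(axis=0)
    return X - mu, mu


def augment(batches: Sequence[SpectralBatch]) -> BatchSet:
    """Stack batches row-wise into one multi-set matrix.

    All batches must share an identical wavenumber grid; the returned
    layout boundaries give the start row of each sub-matrix so that any
    batch's segment can be recovered exactly.
    """
    if not batches:
        raise ValueError("augment needs at least one batch")
    ref = batches[0].wavenumbers
    for k, b in enumerate(batches[1:], start=1):
        if b.wavenumbers.shape != ref.shape or not np.array_equal(b.wavenumbers, ref):
            if b.wavenumbers.shape != ref.shape:
                raise ValueError(
                    f"batch {k}: grid has {b.wavenumbers.size} points, "
                    f"batch 0 has {ref.size}"
                )
            i = int(np.where(b.wavenumbers != ref)[0][0])
            raise ValueError(
                f"batch {k}: wavenumber grid differs first at index {i} "
                f"({b.wavenumbers[i]:g} vs {ref[i]:g})"
            )
    boundaries = [
        int(x) for x in np.cumsum([0] + [b.n_times for b in batches[:-1]])
    ]
    return BatchSet(batches=list(batches), boundaries=boundaries)
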