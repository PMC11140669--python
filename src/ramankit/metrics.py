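"""Spectral comparison metrics: MSE, spectral angle distance (SAD), and
spectral information divergence (SID)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["mse", "sad", "sid", "MetricReport", "metric_report", "METRICS"]

_SID_EPS = 1e-12


def mse(x: np.ndarray, y: np.ndarray) -> float:
    """Mean squared difference between two equal-length spectra."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    return float(np.mean((x - y) ** 2))


def sad(x: np.ndarray, y: np.ndarray) -> float:
    """Spectral angle distance in radians: the angle between the two
    spectra viewed as vectors.  Scale-invariant and symmetric; 0 for
    proportional spectra, pi/2 for orthogonal ones."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        raise ValueError("spectral angle undefined for a zero vector")
    cosang = np.clip(np.dot(x, y) / (nx * ny), -1.0, 1.0)
    return float(np.arccos(cosang))


def sid(x: np.ndarray, y: np.ndarray) -> float:
    """Spectral information divergence in nats.

    Both spectra are normalized to probability vectors and compared with the
    symmetrized Kullback-Leibler divergence
    ``sum p log(p/q) + sum q log(q/p)`` (natural log).  Because
    baseline-corrected spectra can dip below zero, a vector with negative
    entries is shifted up by its minimum (with a warning) before
    normalization, and an epsilon floor of 1e-12 guards the logarithms.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")

    def _prob(v: np.ndarray, label: str) -> np.ndarray:
        if v.min() < 0:
            warnings.warn(
                f"{label} has negative entries; shifting by its minimum "
                "before normalization",
                stacklevel=3,
            )
            v = v - v.min()
        total = v.sum()
        if total <= 0:
            raise ValueError(f"{label} has nonpositive total intensity")
        return v / total + _SID_EPS

    p = _prob(x, "first spectrum")
    q = _prob(y, "second spectrum")
    return float(np.sum(p * np.log(p / q)) + np.sum(q * np.log(q / p)))


METRICS: dict[str, Callable[[np.ndarray, np.ndarray], float]] = {
    "mse": mse,
    "sad": sad,
    "sid": sid,
}


@dataclass(frozen=True)
class MetricReport:
    """Per-spectrum metric values with their mean and the standard error of
    the mean (sample std / sqrt(N)), mirroring error-bar conventions."""

    metric: str
    values: np.ndarray
    mean: float
    sem: float

    @property
    def n(self) -> int:
        return int(self.values.size)


def metric_report(metric: str, X: np.ndarray, Y: np.ndarray) -> MetricReport:
    """Row-wise metric between two N x B matrices.

    Returns the N per-spectrum values, their mean, and the standard
    deviation of the sample mean (0 for N = 1).
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {sorted(METRICS)}, got {metric!r}")
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    if X.shape != Y.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {Y.shape}")
    fn = METRICS[metric]
    values = np.array([fn(xr, yr) for xr, yr in zip(X, Y)])
    n = values.size
    sem = float(values.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return MetricReport(metric=metric, values=values, mean=float(values.mean()), sem=sem)
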