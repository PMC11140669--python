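"""Spectral preprocessing: cropping, despiking, denoising, baseline
correction, normalization, background subtraction.

Every operation maps a :class:`~ramankit.core.SpectralContainer` to a new
container (inputs are never mutated) and, apart from cropping, preserves the
container shape.  All per-spectrum operations act independently along the
spectral axis, so applying them to an image is identical to applying them to
each row of the flattened spectra matrix.

Default parameters
------------------
The despiking defaults (``z_threshold=6.5``, ``window=5``) are conservative:
cosmic-ray spikes are typically tens of standard deviations above the
first-difference noise floor, so a high threshold keeps the false-positive
rate on clean spectra negligible.  The ASLS defaults (``lam=1e5``,
``p=0.01``) fit broad autofluorescence backgrounds under narrow Raman peaks;
``lam`` controls baseline stiffness (larger = smoother) and ``p`` the
asymmetry (small = baseline hugs the lower envelope).
"""

from __future__ import annotations

import warnings
from typing import Tuple

import numpy as np
import scipy.ndimage as ndi
import scipy.signal as sig
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve
from scipy.special import expit

from .core import RangeError, SpectralContainer, SpectrumKind, StructuralError

__all__ = [
    "crop",
    "despike_whitaker_hayes",
    "denoise_savgol",
    "denoise_gaussian",
    "baseline_asls",
    "baseline_aspls",
    "normalize",
    "subtract_background",
    "ParameterError",
    "DegenerateRangeError",
    "AlignmentError",
    "DEFAULT_DESPIKE_THRESHOLD",
    "DEFAULT_DESPIKE_WINDOW",
    "DEFAULT_ASLS_LAM",
    "DEFAULT_ASPLS_LAM",
    "DEFAULT_ASLS_P",
    "DEFAULT_GAUSSIAN_SIGMA",
]

DEFAULT_DESPIKE_THRESHOLD = 6.5
DEFAULT_DESPIKE_WINDOW = 5
DEFAULT_ASLS_LAM = 1e5
DEFAULT_ASPLS_LAM = 1e4
DEFAULT_ASLS_P = 0.01
DEFAULT_ASLS_MAX_ITER = 30
DEFAULT_ASLS_TOL = 1e-3
DEFAULT_GAUSSIAN_SIGMA = 1.0


class ParameterError(ValueError):
    """A step parameter violates its contract."""


class DegenerateRangeError(ValueError):
    """Normalization undefined (constant spectrum or nonpositive area)."""


class AlignmentError(ValueError):
    """Two containers do not share the same spectral axis."""


def _flat_view(c: SpectralContainer) -> np.ndarray:
    return c.intensities.reshape(-1, c.n_bands)


# ----------------------------------------------------------------------
# Cropping


def crop(c: SpectralContainer, min_wn: float, max_wn: float) -> SpectralContainer:
    """Retain the bands with ``min_wn <= wavenumber <= max_wn`` (inclusive).

    The standard use is restricting to the biological fingerprint region
    (700-1800 cm^-1), where most biomolecular Raman information lives.
    """
    if not min_wn < max_wn:
        raise ParameterError(f"min_wn ({min_wn}) must be < max_wn ({max_wn})")
    mask = (c.axis.values >= min_wn) & (c.axis.values <= max_wn)
    if not mask.any():
        raise RangeError(
            f"no bands in [{min_wn}, {max_wn}]; axis spans "
            f"[{c.axis.values[0]}, {c.axis.values[-1]}]"
        )
    from .core import SpectralAxis

    return SpectralContainer(
        intensities=c.intensities[..., mask], axis=SpectralAxis(c.axis.values[mask])
    )


# ----------------------------------------------------------------------
# Cosmic-ray despiking (Whitaker & Hayes modified z-score method)


def _despike_one(
    y: np.ndarray, z_threshold: float, half: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Despike one spectrum; returns (cleaned, flagged_mask)."""
    d = np.diff(y)
    flagged = np.zeros(y.shape, dtype=bool)
    if np.all(d == d[0]) and d[0] == 0.0:
        return y.copy(), flagged  # constant spectrum
    med = np.median(d)
    mad = np.median(np.abs(d - med))
    if mad == 0.0:
        # MAD degenerates when most differences are identical; fall back to
        # the mean absolute deviation, which is positive for non-constant d
        mad = np.mean(np.abs(d - med))
        if mad == 0.0:
            return y.copy(), flagged
    z = 0.6745 * (d - med) / mad
    # d[j] = y[j+1] - y[j]: an outlying difference implicates point j+1
    flagged[1:] = np.abs(z) > z_threshold
    if not flagged.any():
        return y.copy(), flagged

    out = y.copy()
    n = y.size
    flagged_idx = np.flatnonzero(flagged)
    good = ~flagged
    for i in flagged_idx:
        lo, hi = max(0, i - half), min(n, i + half + 1)
        neighbors = np.flatnonzero(good[lo:hi]) + lo
        if neighbors.size:
            out[i] = y[neighbors].mean()
        else:
            # window all-flagged: linearly interpolate between the nearest
            # unflagged points on either side
            left = np.flatnonzero(good[:i])
            right = np.flatnonzero(good[i + 1 :])
            if left.size and right.size:
                l, r = left[-1], right[0] + i + 1
                t = (i - l) / (r - l)
                out[i] = (1 - t) * y[l] + t * y[r]
            elif left.size:
                out[i] = y[left[-1]]
            elif right.size:
                out[i] = y[right[0] + i + 1]
            # else: nothing unflagged at all; leave as-is
    return out, flagged


def despike_whitaker_hayes(
    c: SpectralContainer,
    z_threshold: float = DEFAULT_DESPIKE_THRESHOLD,
    window: int = DEFAULT_DESPIKE_WINDOW,
    return_mask: bool = False,
):
    """Remove cosmic-ray spikes via modified z-scores of first differences.

    Per spectrum: differences ``d_i = y_i - y_{i-1}`` are scored as
    ``Z_i = 0.6745 * (d_i - median(d)) / MAD(d)``; points whose score exceeds
    ``z_threshold`` in magnitude are replaced by the mean of the unflagged
    neighbors within ``+-(window-1)/2`` bands (linear interpolation between
    the nearest unflagged points if the window holds none).  Unflagged values
    pass through unchanged.

    With ``return_mask=True``, also returns the boolean array of flagged
    positions.
    """
    if z_threshold <= 0:
        raise ParameterError("z_threshold must be positive")
    if window < 3 or window % 2 == 0:
        raise ParameterError("window must be odd and >= 3")
    if c.n_bands < 3:
        raise ParameterError("despiking needs at least 3 bands")
    half = (window - 1) // 2
    flat = _flat_view(c)
    out = np.empty_like(flat)
    mask = np.zeros(flat.shape, dtype=bool)
    for r in range(flat.shape[0]):
        out[r], mask[r] = _despike_one(flat[r], z_threshold, half)
    result = c.with_intensities(out.reshape(c.intensities.shape))
    if return_mask:
        return result, mask.reshape(c.intensities.shape)
    return result


# ----------------------------------------------------------------------
# Denoising


def denoise_savgol(
    c: SpectralContainer, polyorder: int = 3, window: int = 7
) -> SpectralContainer:
    """Savitzky-Golay smoothing along the spectral axis.

    Each point is replaced by the center value of the least-squares
    polynomial of degree ``polyorder`` fitted over the ``window`` surrounding
    bands; edges use polynomial extrapolation of the one-sided edge fit.
    Polynomials of degree <= ``polyorder`` are reproduced exactly.
    """
    if window % 2 == 0 or window < 3:
        raise ParameterError("window must be odd and >= 3")
    if polyorder >= window:
        raise ParameterError("polyorder must be < window")
    if window > c.n_bands:
        raise ParameterError(
            f"window ({window}) exceeds number of bands ({c.n_bands})"
        )
    out = sig.savgol_filter(
        c.intensities, window_length=window, polyorder=polyorder, axis=-1, mode="interp"
    )
    return c.with_intensities(out)


def denoise_gaussian(
    c: SpectralContainer, sigma_bands: float = DEFAULT_GAUSSIAN_SIGMA
) -> SpectralContainer:
    """Gaussian smoothing: unit-sum kernel truncated at 4 sigma, reflect
    padding at the edges."""
    if sigma_bands <= 0:
        raise ParameterError("sigma_bands must be positive")
    out = ndi.gaussian_filter1d(
        c.intensities, sigma=sigma_bands, axis=-1, mode="reflect", truncate=4.0
    )
    return c.with_intensities(out)


# ----------------------------------------------------------------------
# Baseline correction (penalized least squares / Whittaker smoothers)


def _second_difference(n: int) -> sp.csc_matrix:
    return sp.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n)).tocsc()


def _asls_one(
    y: np.ndarray, lam: float, p: float, max_iter: int, tol: float
) -> np.ndarray:
    """ASLS baseline of one spectrum (Eilers-style Whittaker smoother)."""
    n = y.size
    D = _second_difference(n)
    DtD = (lam * (D.T @ D)).tocsc()
    w = np.ones(n)
    z = y
    for _ in range(max_iter):
        W = sp.diags(w, format="csc")
        z = spsolve(W + DtD, w * y)
        w_new = np.where(y > z, p, 1.0 - p)
        changed = np.mean(w_new != w)
        w = w_new
        if changed < tol:
            return z
    warnings.warn(
        f"ASLS weights not stable after {max_iter} iterations; "
        "returning best iterate",
        stacklevel=3,
    )
    return z


def baseline_asls(
    c: SpectralContainer,
    lam: float = DEFAULT_ASLS_LAM,
    p: float = DEFAULT_ASLS_P,
    max_iter: int = DEFAULT_ASLS_MAX_ITER,
    tol: float = DEFAULT_ASLS_TOL,
    return_baseline: bool = False,
):
    """Asymmetric-least-squares baseline correction.

    Per spectrum, estimates the baseline ``z`` minimizing
    ``sum w_i (y_i - z_i)^2 + lam * sum (D2 z)^2`` (``D2`` = second
    difference), iterating the asymmetric weights ``w_i = p`` where
    ``y_i > z_i`` else ``1 - p``, starting from uniform weights, until fewer
    than ``tol`` of the weights change or ``max_iter`` is reached.  Returns
    the corrected container ``y - z``; with ``return_baseline=True`` also
    returns the baseline container.
    """
    if lam <= 0:
        raise ParameterError("lam must be positive")
    if not 0 < p < 1:
        raise ParameterError("p must lie strictly between 0 and 1")
    flat = _flat_view(c)
    base = np.empty_like(flat)
    for r in range(flat.shape[0]):
        base[r] = _asls_one(flat[r], lam, p, max_iter, tol)
    base = base.reshape(c.intensities.shape)
    corrected = c.with_intensities(c.intensities - base)
    if return_baseline:
        return corrected, c.with_intensities(base)
    return corrected


def _aspls_one(
    y: np.ndarray, lam: float, max_iter: int, tol: float
) -> np.ndarray:
    """Adaptive smoothness-penalized least-squares baseline of one spectrum.

    Weights follow a logistic function of the residual scaled by the spread
    of the negative residuals; the smoothness penalty is additionally scaled
    per point by the normalized residual magnitude, loosening the baseline
    where peaks dominate and stiffening it where the fit is tight.
    """
    n = y.size
    D = _second_difference(n)
    w = np.ones(n)
    alpha = np.ones(n)
    z = y
    for _ in range(max_iter):
        A = sp.diags(alpha[1:-1], format="csc")  # penalty scaling on interior
        W = sp.diags(w, format="csc")
        z = spsolve(W + lam * (D.T @ A @ D), w * y)
        r = y - z
        neg = r[r < 0]
        sigma_neg = neg.std() if neg.size else 0.0
        if sigma_neg == 0.0:
            return z  # perfect (or one-sided) fit
        w_new = expit(-2.0 * (r - sigma_neg) / sigma_neg)
        rmax = np.abs(r).max()
        alpha = np.abs(r) / rmax if rmax > 0 else np.ones(n)
        changed = np.mean(np.abs(w_new - w) > tol)
        w = w_new
        if changed < tol:
            return z
    warnings.warn(
        f"asPLS weights not stable after {max_iter} iterations; "
        "returning best iterate",
        stacklevel=3,
    )
    return z


def baseline_aspls(
    c: SpectralContainer,
    lam: float = DEFAULT_ASPLS_LAM,
    max_iter: int = 50,
    tol: float = DEFAULT_ASLS_TOL,
    return_baseline: bool = False,
):
    """Adaptive smoothness-penalized least-squares baseline correction.

    Like :func:`baseline_asls` but with residual-driven adaptive weights
    ``w_i = 1 / (1 + exp(2 (r_i - sigma_neg) / sigma_neg))`` where
    ``r = y - z`` and ``sigma_neg`` is the standard deviation of the negative
    residuals, plus a per-point penalty scaling ``alpha_i = |r_i| / max|r|``
    applied to ``lam``.  No asymmetry parameter is required.
    """
    if lam <= 0:
        raise ParameterError("lam must be positive")
    flat = _flat_view(c)
    base = np.empty_like(flat)
    for r in range(flat.shape[0]):
        base[r] = _aspls_one(flat[r], lam, max_iter, tol)
    base = base.reshape(c.intensities.shape)
    corrected = c.with_intensities(c.intensities - base)
    if return_baseline:
        return corrected, c.with_intensities(base)
    return corrected


# ----------------------------------------------------------------------
# Normalization & background subtraction

_NORMALIZE_MODES = ("minmax_global", "minmax_pixel", "auc_pixel")


def normalize(c: SpectralContainer, mode: str = "minmax_global") -> SpectralContainer:
    """Normalize intensities.

    ``minmax_global`` rescales the whole container to [0, 1];
    ``minmax_pixel`` rescales each spectrum to [0, 1] independently;
    ``auc_pixel`` divides each spectrum by its trapezoidal integral over the
    wavenumber axis so every spectrum has unit area.
    """
    if mode not in _NORMALIZE_MODES:
        raise ParameterError(f"mode must be one of {_NORMALIZE_MODES}, got {mode!r}")
    x = c.intensities
    if mode == "minmax_global":
        lo, hi = x.min(), x.max()
        if hi == lo:
            raise DegenerateRangeError("global max equals global min")
        return c.with_intensities((x - lo) / (hi - lo))
    flat = _flat_view(c)
    if mode == "minmax_pixel":
        lo = flat.min(axis=1, keepdims=True)
        hi = flat.max(axis=1, keepdims=True)
        bad = np.flatnonzero((hi == lo).ravel())
        if bad.size:
            raise DegenerateRangeError(
                f"constant spectrum at flattened pixel {int(bad[0])}"
            )
        out = (flat - lo) / (hi - lo)
    else:  # auc_pixel
        areas = np.trapezoid(flat, x=c.axis.values, axis=1)
        bad = np.flatnonzero(areas <= 0)
        if bad.size:
            raise DegenerateRangeError(
                f"nonpositive area under spectrum at flattened pixel {int(bad[0])}"
            )
        out = flat / areas[:, None]
    return c.with_intensities(out.reshape(c.intensities.shape))


def subtract_background(
    c: SpectralContainer, background: SpectralContainer
) -> SpectralContainer:
    """Subtract a single background spectrum from every spectrum.

    The background must share the container's axis exactly; no implicit
    resampling is performed.
    """
    if background.kind is not SpectrumKind.SPECTRUM:
        raise StructuralError("background must be a single spectrum")
    if background.axis != c.axis:
        raise AlignmentError("background axis does not match container axis")
    return c.with_intensities(c.intensities - background.intensities)
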