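"""Array-based spectral data model.

The central object is :class:`SpectralContainer`: an N-dimensional intensity
array whose *last* axis is the spectral axis, paired with a strictly
increasing wavenumber vector (cm^-1).  A container with no leading (spatial)
dimension is a single spectrum; one, two, or three leading dimensions give a
stack of spectra, an image scan, and a volumetric scan respectively.  Every
operation in the package consumes and produces this one type, so spectra,
maps and volumes flow through identical code paths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence, Tuple

import numpy as np

__all__ = [
    "SpectrumKind",
    "SpectralAxis",
    "SpectralContainer",
    "GroundTruthBundle",
    "make_container",
    "flatten",
    "unflatten",
    "band_slice",
    "SpectralError",
    "StructuralError",
    "ValidationError",
    "UnsupportedShapeError",
    "RangeError",
]

MAX_SPATIAL_DIMS = 3


class SpectralError(ValueError):
    """Base class for spectral data errors."""


class StructuralError(SpectralError):
    """Shape or layout of the data does not match the declared structure."""


class ValidationError(SpectralError):
    """Values violate an invariant (non-finite, non-monotone, ...)."""


class UnsupportedShapeError(SpectralError):
    """More spatial dimensions than the data model supports."""


class RangeError(SpectralError):
    """A requested coordinate lies outside the spectral axis."""


class SpectrumKind(str, Enum):
    """Modality of a container, determined by its spatial dimensionality."""

    SPECTRUM = "spectrum"
    SPECTRA_STACK = "spectra_stack"
    IMAGE = "image"
    VOLUME = "volume"


_KIND_BY_NDIM = {
    0: SpectrumKind.SPECTRUM,
    1: SpectrumKind.SPECTRA_STACK,
    2: SpectrumKind.IMAGE,
    3: SpectrumKind.VOLUME,
}


@dataclass(frozen=True)
class SpectralAxis:
    """Strictly increasing wavenumber axis in cm^-1.

    Inputs given in decreasing order must be reversed by the caller together
    with the intensities; :func:`make_container` does this automatically.
    User-facing constructors require at least 2 bands; a single-band axis can
    arise only from narrow cropping.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 1 or values.size < 1:
            raise ValidationError("axis must be a non-empty 1-D vector")
        if not np.all(np.isfinite(values)):
            raise ValidationError("axis contains non-finite values")
        if not np.all(np.diff(values) > 0):
            raise ValidationError("axis must be strictly increasing")
        values.flags.writeable = False
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralAxis):
            return NotImplemented
        return np.array_equal(self.values, other.values)


@dataclass(frozen=True)
class SpectralContainer:
    """Intensities of shape ``(s1, ..., sd, B)`` plus a wavenumber axis."""

    intensities: np.ndarray
    axis: SpectralAxis
    kind: SpectrumKind = field(init=False)

    def __post_init__(self) -> None:
        intensities = np.asarray(self.intensities, dtype=np.float64)
        if intensities.ndim == 0:
            raise StructuralError("intensities must have at least one axis")
        if intensities.shape[-1] != len(self.axis):
            raise StructuralError(
                f"last intensity axis ({intensities.shape[-1]}) does not match "
                f"axis length ({len(self.axis)})"
            )
        n_spatial = intensities.ndim - 1
        if n_spatial > MAX_SPATIAL_DIMS:
            raise UnsupportedShapeError(
                f"{n_spatial} spatial dimensions exceed the supported maximum "
                f"of {MAX_SPATIAL_DIMS}"
            )
        if not np.all(np.isfinite(intensities)):
            raise ValidationError(
                "intensities contain non-finite values "
                "(use make_container(..., nan_policy='zero') to zero-fill NaNs)"
            )
        intensities = intensities.copy()
        intensities.flags.writeable = False
        object.__setattr__(self, "intensities", intensities)
        object.__setattr__(self, "kind", _KIND_BY_NDIM[n_spatial])

    # ------------------------------------------------------------------
    @property
    def n_bands(self) -> int:
        return len(self.axis)

    @property
    def spatial_shape(self) -> Tuple[int, ...]:
        return self.intensities.shape[:-1]

    @property
    def n_spectra(self) -> int:
        return int(np.prod(self.spatial_shape, dtype=np.int64)) if self.spatial_shape else 1

    def with_intensities(self, intensities: np.ndarray) -> "SpectralContainer":
        """New container sharing this axis (shape may differ spatially)."""
        return SpectralContainer(intensities=np.asarray(intensities), axis=self.axis)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralContainer):
            return NotImplemented
        return (
            self.kind == other.kind
            and self.axis == other.axis
            and np.array_equal(self.intensities, other.intensities)
        )


@dataclass(frozen=True)
class GroundTruthBundle:
    """Full ground truth of a synthetic scene, for validating recovery.

    ``endmembers`` is K x B; ``abundances`` has shape spatial + (K,) and is a
    point on the probability simplex at every pixel; ``baseline`` and
    ``spike_mask`` match the intensity array; ``noise_sigma`` is the standard
    deviation of the additive Gaussian noise.
    """

    endmembers: np.ndarray
    abundances: np.ndarray
    baseline: np.ndarray
    spike_mask: np.ndarray
    noise_sigma: float

    def __post_init__(self) -> None:
        abund = np.asarray(self.abundances, dtype=np.float64)
        if np.any(abund < -1e-12):
            raise ValidationError("abundances must be nonnegative")
        sums = abund.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValidationError("abundances must sum to 1 along the last axis")


# ----------------------------------------------------------------------
# Operations


def make_container(
    intensities: np.ndarray,
    axis_values: Sequence[float],
    nan_policy: str = "raise",
) -> SpectralContainer:
    """Build a container, normalizing a decreasing axis to increasing order.

    Parameters
    ----------
    intensities
        Real array whose last axis is spectral.
    axis_values
        Wavenumbers, strictly monotone in either direction; decreasing input
        is reversed together with the spectral axis of ``intensities``.
    nan_policy
        ``"raise"`` (default) rejects NaN intensities; ``"zero"`` replaces
        them with 0 and emits a warning (vendor exports occasionally contain
        masked pixels).
    """
    axis_arr = np.asarray(axis_values, dtype=np.float64)
    if axis_arr.ndim != 1 or axis_arr.size < 2:
        raise ValidationError("axis must be a 1-D vector with at least 2 bands")
    if not np.all(np.isfinite(axis_arr)):
        raise ValidationError("axis contains non-finite values")
    intens = np.asarray(intensities, dtype=np.float64)
    if intens.ndim == 0:
        raise StructuralError("intensities must have at least one axis")
    if intens.shape[-1] != axis_arr.size:
        raise StructuralError(
            f"last intensity axis ({intens.shape[-1]}) does not match axis "
            f"length ({axis_arr.size})"
        )

    diffs = np.diff(axis_arr)
    if np.all(diffs > 0):
        pass
    elif np.all(diffs < 0):
        axis_arr = axis_arr[::-1]
        intens = intens[..., ::-1]
    else:
        raise ValidationError("axis must be strictly monotone")

    if nan_policy not in ("raise", "zero"):
        raise ValueError(f"unknown nan_policy {nan_policy!r}")
    if nan_policy == "zero":
        nan_mask = np.isnan(intens)
        if nan_mask.any():
            warnings.warn(
                f"replaced {int(nan_mask.sum())} NaN intensities with 0",
                stacklevel=2,
            )
            intens = np.where(nan_mask, 0.0, intens)

    return SpectralContainer(intensities=intens, axis=SpectralAxis(axis_arr))


def flatten(c: SpectralContainer) -> Tuple[np.ndarray, Tuple[int, ...]]:
    """Row-major (N, B) view of a container plus its spatial shape.

    N is the product of the spatial dimensions (1 for a single spectrum).
    Round-trips exactly through :func:`unflatten`.
    """
    matrix = c.intensities.reshape(-1, c.n_bands)
    return matrix, c.spatial_shape


def unflatten(
    matrix: np.ndarray, spatial_shape: Tuple[int, ...], axis: SpectralAxis
) -> SpectralContainer:
    """Inverse of :func:`flatten`."""
    matrix = np.asarray(matrix, dtype=np.float64)
    n_expected = int(np.prod(spatial_shape, dtype=np.int64)) if spatial_shape else 1
    if matrix.shape != (n_expected, len(axis)):
        raise StructuralError(
            f"matrix shape {matrix.shape} incompatible with spatial shape "
            f"{spatial_shape} and {len(axis)} bands"
        )
    return SpectralContainer(
        intensities=matrix.reshape(spatial_shape + (len(axis),)), axis=axis
    )


def band_slice(
    c: SpectralContainer, target: float, tol: float = 0.0
) -> Tuple[np.ndarray, float]:
    """Intensities at the band nearest ``target`` (cm^-1).

    Returns ``(spatial_array, selected_wavenumber)``.  Ties between two
    equidistant bands resolve toward the lower index.  ``target`` must lie
    within ``[axis_min - tol, axis_max + tol]``.
    """
    values = c.axis.values
    if target < values[0] - tol or target > values[-1] + tol:
        raise RangeError(
            f"target {target} cm^-1 outside axis range "
            f"[{values[0]}, {values[-1]}] (tol {tol})"
        )
    # argmin returns the first minimizer -> lower-index tie break for free
    idx = int(np.argmin(np.abs(values - target)))
    return c.intensities[..., idx].copy(), float(values[idx])
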