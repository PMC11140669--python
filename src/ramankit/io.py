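"""Readers and writers for spectral data.

Supported formats:

* delimited text — either a two-column ``wavenumber, intensity`` file for a
  single spectrum, or a matrix whose header row holds the wavenumbers and
  each subsequent row one spectrum;
* MATLAB MAT-files (v5), the export format of common vendor software; the
  caller names the intensity and axis variables explicitly rather than the
  loader guessing a vendor schema;
* the package's native HDF5 layout (group ``/ramanspec`` with float64
  datasets ``axis`` and ``intensities``, attributes ``kind`` and
  ``format_version``), a lossless bit-exact round trip.

All readers return :class:`~ramankit.core.SpectralContainer` objects that
satisfy the core invariants, or raise; there is no silent coercion.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import h5py
import numpy as np
import scipy.io as sio

from .core import (
    SpectralContainer,
    SpectrumKind,
    StructuralError,
    ValidationError,
    make_container,
)

__all__ = [
    "TextMode",
    "TextLayout",
    "ParseError",
    "FormatError",
    "IncompatibilityError",
    "load_text",
    "write_text",
    "load_matfile",
    "save_container",
    "load_container",
]

FORMAT_VERSION = "1"
_HDF5_GROUP = "ramanspec"

# repr-level precision so text round trips are reliable
_TEXT_FMT = "%.17g"


class ParseError(ValueError):
    """A text file does not parse under the declared layout."""


class FormatError(ValueError):
    """A native container file is missing required datasets/attributes."""


class IncompatibilityError(ValueError):
    """A file declares a format version this reader does not understand."""


class TextMode(str, Enum):
    TWO_COLUMN = "two_column"
    MATRIX_WITH_HEADER = "matrix_with_header"


_DELIMITERS = {
    "comma": ",",
    "tab": "\t",
    "semicolon": ";",
    "whitespace": None,  # any-run-of-whitespace split
}


@dataclass(frozen=True)
class TextLayout:
    """Declared structure of a delimited text file."""

    mode: TextMode = TextMode.TWO_COLUMN
    delimiter: str = "comma"

    def __post_init__(self) -> None:
        if self.delimiter not in _DELIMITERS:
            raise ValueError(
                f"delimiter must be one of {sorted(_DELIMITERS)}, "
                f"got {self.delimiter!r}"
            )

    @property
    def sep(self) -> Optional[str]:
        return _DELIMITERS[self.delimiter]


def _parse_rows(path: Path, sep: Optional[str]) -> list:
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            cells = line.split(sep) if sep is None else line.split(sep)
            try:
                rows.append(([float(cell) for cell in cells], lineno))
            except ValueError as exc:
                raise ParseError(f"non-numeric cell at line {lineno}: {exc}") from None
    return rows


def load_text(path: Union[str, Path], layout: TextLayout = TextLayout()) -> SpectralContainer:
    """Load a delimited text file into a container.

    ``two_column`` mode yields a single spectrum (column 1 = wavenumbers,
    column 2 = intensities); ``matrix_with_header`` yields a spectra stack
    (header row = wavenumbers, one spectrum per subsequent row).
    """
    path = Path(path)
    rows = _parse_rows(path, layout.sep)
    if not rows:
        raise ParseError(f"{path}: empty file")
    widths = {len(cells) for cells, _ in rows}
    if len(widths) != 1:
        bad = next(lineno for cells, lineno in rows if len(cells) != len(rows[0][0]))
        raise ParseError(f"{path}: ragged row at line {bad}")

    if layout.mode is TextMode.TWO_COLUMN:
        if widths != {2}:
            raise ParseError(f"{path}: two_column layout requires exactly 2 columns")
        data = np.array([cells for cells, _ in rows], dtype=np.float64)
        if data.shape[0] < 2:
            raise ValidationError(f"{path}: fewer than 2 bands")
        return make_container(data[:, 1], data[:, 0])

    header = np.array(rows[0][0], dtype=np.float64)
    if header.size < 2:
        raise ValidationError(f"{path}: fewer than 2 bands in header")
    body = np.array([cells for cells, _ in rows[1:]], dtype=np.float64)
    if body.size == 0:
        raise ParseError(f"{path}: matrix layout has a header but no spectra")
    return make_container(body, header)


def write_text(
    c: SpectralContainer, path: Union[str, Path], layout: TextLayout = TextLayout()
) -> None:
    """Write a container as delimited text (17 significant digits)."""
    path = Path(path)
    sep = layout.sep if layout.sep is not None else " "
    if layout.mode is TextMode.TWO_COLUMN:
        if c.kind is not SpectrumKind.SPECTRUM:
            raise StructuralError("two_column layout holds a single spectrum only")
        rows = np.column_stack([c.axis.values, c.intensities])
        lines = (sep.join(_TEXT_FMT % v for v in row) for row in rows)
    else:
        matrix = c.intensities.reshape(-1, c.n_bands)
        header = sep.join(_TEXT_FMT % v for v in c.axis.values)
        body = (sep.join(_TEXT_FMT % v for v in row) for row in matrix)
        lines = (line for line in (header, *body))
    with open(path, "w", encoding="utf-8") as fh:
        for line in lines:
            fh.write(line + "\n")


def load_matfile(
    path: Union[str, Path],
    intensity_var: str,
    axis_var: str,
    spatial_shape: Optional[Sequence[int]] = None,
) -> SpectralContainer:
    """Load a hyperspectral MAT-file (v5) export.

    The intensity variable is either already shaped ``spatial + (B,)`` or a
    flattened ``(N, B)`` matrix that is reshaped row-major to
    ``spatial_shape + (B,)`` when ``spatial_shape`` is given.
    """
    path = Path(path)
    mat = sio.loadmat(path)
    available = sorted(k for k in mat if not k.startswith("__"))
    for name in (intensity_var, axis_var):
        if name not in mat:
            raise KeyError(
                f"{path}: variable {name!r} not found; available: {available}"
            )
    axis = np.asarray(mat[axis_var], dtype=np.float64).squeeze()
    intens = np.asarray(mat[intensity_var], dtype=np.float64)
    # MAT stores vectors as 1xB / Bx1; squeeze singleton dims
    intens = np.squeeze(intens)
    if intens.ndim == 0:
        raise StructuralError(f"{path}: intensity variable is a scalar")
    if spatial_shape is not None:
        spatial_shape = tuple(int(s) for s in spatial_shape)
        target = spatial_shape + (axis.size,)
        if int(np.prod(target)) != intens.size:
            raise StructuralError(
                f"{path}: cannot reshape {intens.shape} to {target}"
            )
        intens = intens.reshape(target)
    return make_container(intens, axis)


def save_matfile(
    c: SpectralContainer,
    path: Union[str, Path],
    intensity_var: str = "intensities",
    axis_var: str = "axis",
) -> None:
    """Write a container as a MAT-file v5 (test fixtures, interchange)."""
    sio.savemat(Path(path), {intensity_var: c.intensities, axis_var: c.axis.values})


def save_container(c: SpectralContainer, path: Union[str, Path]) -> None:
    """Persist a container in the native HDF5 layout (lossless)."""
    with h5py.File(Path(path), "w") as fh:
        grp = fh.create_group(_HDF5_GROUP)
        grp.create_dataset("axis", data=c.axis.values, dtype=np.float64)
        grp.create_dataset("intensities", data=c.intensities, dtype=np.float64)
        grp.attrs["kind"] = c.kind.value
        grp.attrs["format_version"] = FORMAT_VERSION


def load_container(path: Union[str, Path]) -> SpectralContainer:
    """Load a container saved by :func:`save_container` (bit-exact)."""
    path = Path(path)
    with h5py.File(path, "r") as fh:
        if _HDF5_GROUP not in fh:
            raise FormatError(f"{path}: missing group /{_HDF5_GROUP}")
        grp = fh[_HDF5_GROUP]
        version = grp.attrs.get("format_version")
        if version != FORMAT_VERSION:
            raise IncompatibilityError(
                f"{path}: format_version {version!r} not supported "
                f"(expected {FORMAT_VERSION!r})"
            )
        for ds in ("axis", "intensities"):
            if ds not in grp:
                raise FormatError(f"{path}: missing dataset {ds!r}")
        axis = grp["axis"][()]
        intens = grp["intensities"][()]
        kind = grp.attrs.get("kind")
    c = make_container(intens, axis)
    if kind is not None and c.kind.value != kind:
        raise FormatError(
            f"{path}: stored kind {kind!r} inconsistent with shape {intens.shape}"
        )
    return c
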