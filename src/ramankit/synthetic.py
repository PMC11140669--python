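"""Ground-truth-bearing synthetic Raman data.

The generator emulates the structure of measured Raman scenes under the
linear mixing model: K peak-structured pure-component spectra (Gaussian and
Lorentzian bands on a wavenumber axis), per-pixel abundances drawn from a
symmetric Dirichlet, a smooth additive autofluorescence-like baseline,
sparse high-amplitude cosmic spikes, and additive Gaussian detector noise.
Every component is returned alongside the scene in a
:class:`~ramankit.core.GroundTruthBundle`, so preprocessing and unmixing can
be validated against exact truth.

Noise protocols
---------------
Two contamination orders are supported.  Generic additive noise perturbs the
raw mixed intensities.  The *paper-noise* protocol instead min-max scales
each spectrum to [0, 1] first and then adds Gaussian noise of the stated
standard deviation, emulating the preparation of low-signal-to-noise
spectra at a controlled noise level (sigma = 0.15 in the emulated protocol).

The defaults describe a plausible biological imaging scene: a 20 x 20 scan,
5 components, 500 bands over 400-1800 cm^-1, band widths of 5-30 cm^-1,
baseline comparable to half the peak signal, and a cosmic-spike rate of
5e-4 per (pixel, band) cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import GroundTruthBundle, SpectralContainer, make_container
from .metrics import sad

__all__ = [
    "PeakShape",
    "PeakSpec",
    "SceneConfig",
    "GenerationError",
    "gen_endmembers",
    "gen_abundances",
    "gen_scene",
    "gen_uniform_spectra",
]


class GenerationError(RuntimeError):
    """The generator could not satisfy its constraints in the retry budget."""


class PeakShape(str, Enum):
    GAUSSIAN = "gaussian"
    LORENTZIAN = "lorentzian"


@dataclass(frozen=True)
class PeakSpec:
    """One spectral band: center (cm^-1), width (cm^-1), amplitude, shape."""

    center: float
    width: float
    amplitude: float
    shape: PeakShape = PeakShape.GAUSSIAN

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("peak width must be positive")
        if self.amplitude <= 0:
            raise ValueError("peak amplitude must be positive")

    def evaluate(self, wn: np.ndarray) -> np.ndarray:
        if self.shape is PeakShape.GAUSSIAN:
            return self.amplitude * np.exp(
                -((wn - self.center) ** 2) / (2.0 * self.width**2)
            )
        return self.amplitude * self.width**2 / ((wn - self.center) ** 2 + self.width**2)


@dataclass(frozen=True)
class SceneConfig:
    """Everything that determines a synthetic scene, seed included."""

    spatial_shape: Tuple[int, ...] = (20, 20)
    k: int = 5
    wn_min: float = 400.0
    wn_max: float = 1800.0
    n_bands: int = 500
    peaks_per_endmember: int = 6
    peak_width_range: Tuple[float, float] = (5.0, 30.0)
    peak_amplitude_range: Tuple[float, float] = (0.2, 1.0)
    lorentzian_fraction: float = 0.3
    min_endmember_sad: float = 0.25   # radians; resampled until satisfied
    max_retries: int = 50
    dirichlet_concentration: float = 1.0
    plant_pure_pixels: bool = True
    baseline_degree: int = 3
    baseline_amplitude: float = 0.5
    baseline_pixel_jitter: float = 0.05
    spike_rate: float = 5e-4
    spike_amplitude_range: Tuple[float, float] = (3.0, 8.0)
    noise_sigma: float = 0.15
    paper_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.n_bands < 2:
            raise ValueError("n_bands must be >= 2")
        if not 0 <= self.spike_rate < 1:
            raise ValueError("spike_rate must lie in [0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.peaks_per_endmember < 1:
            raise ValueError("peaks_per_endmember must be >= 1")

    @property
    def axis(self) -> np.ndarray:
        return np.linspace(self.wn_min, self.wn_max, self.n_bands)

    @property
    def n_pixels(self) -> int:
        return int(np.prod(self.spatial_shape, dtype=np.int64)) if self.spatial_shape else 1


# ----------------------------------------------------------------------


def _sample_endmember(
    config: SceneConfig, rng: np.random.Generator
) -> Tuple[np.ndarray, List[PeakSpec]]:
    wn = config.axis
    peaks: List[PeakSpec] = []
    for _ in range(config.peaks_per_endmember):
        shape = (
            PeakShape.LORENTZIAN
            if rng.random() < config.lorentzian_fraction
            else PeakShape.GAUSSIAN
        )
        peaks.append(
            PeakSpec(
                center=float(rng.uniform(config.wn_min, config.wn_max)),
                width=float(rng.uniform(*config.peak_width_range)),
                amplitude=float(rng.uniform(*config.peak_amplitude_range)),
                shape=shape,
            )
        )
    spectrum = np.sum([p.evaluate(wn) for p in peaks], axis=0)
    # unit peak height: intensities are in arbitrary units anyway, and a
    # common scale keeps noise levels comparable across endmembers
    top = spectrum.max()
    spectrum = spectrum / top
    peaks = [replace(p, amplitude=p.amplitude / top) for p in peaks]
    return spectrum, peaks


def gen_endmembers(
    config: SceneConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[np.ndarray, List[List[PeakSpec]]]:
    """Draw K peak-structured endmember spectra on the configured axis.

    Endmembers are resampled (within ``max_retries``) until every pair is at
    least ``min_endmember_sad`` radians apart, so that the components of a
    scene are spectrally distinguishable.  Deterministic given the config
    seed.  Returns the K x B matrix and the peak list of each endmember.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    spectra: List[np.ndarray] = []
    peak_lists: List[List[PeakSpec]] = []
    for _ in range(config.k):
        for _attempt in range(config.max_retries):
            s, peaks = _sample_endmember(config, rng)
            if all(sad(s, other) >= config.min_endmember_sad for other in spectra):
                spectra.append(s)
                peak_lists.append(peaks)
                break
        else:
            raise GenerationError(
                f"could not draw {config.k} endmembers with pairwise spectral "
                f"angle >= {config.min_endmember_sad} rad in "
                f"{config.max_retries} retries; reduce k or min_endmember_sad, "
                "or allow more peaks"
            )
    return np.array(spectra), peak_lists


def gen_abundances(
    spatial_shape: Sequence[int],
    k: int,
    concentration: float = 1.0,
    seed: Optional[int] = None,
    plant_pure_pixels: bool = True,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Per-pixel abundances from a symmetric Dirichlet distribution.

    With ``plant_pure_pixels`` (default), one randomly chosen pixel per
    component is overwritten with the corresponding unit vector, so the
    pure-pixel assumption required by N-FINDR holds by construction.
    Returns an array of shape ``spatial_shape + (k,)`` summing to 1 along
    the last axis.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    spatial_shape = tuple(int(s) for s in spatial_shape)
    n = int(np.prod(spatial_shape, dtype=np.int64)) if spatial_shape else 1
    if plant_pure_pixels and n < k:
        raise ValueError(f"cannot plant {k} pure pixels in {n} pixels")
    flat = rng.dirichlet(np.full(k, concentration), size=n)
    if plant_pure_pixels:
        pure_idx = rng.choice(n, size=k, replace=False)
        flat[pure_idx] = np.eye(k)
    return flat.reshape(spatial_shape + (k,))


def _gen_baseline(
    config: SceneConfig, rng: np.random.Generator, n: int
) -> np.ndarray:
    """Shared smooth polynomial baseline with small per-pixel scale jitter,
    shifted to be nonnegative and scaled to the configured amplitude."""
    t = np.linspace(0.0, 1.0, config.n_bands)
    coeffs = rng.uniform(-1.0, 1.0, size=config.baseline_degree + 1)
    curve = np.polynomial.polynomial.polyval(t, coeffs)
    curve = curve - curve.min()
    span = curve.max()
    if span > 0:
        curve = curve / span * config.baseline_amplitude
    else:  # degenerate draw: fall back to a flat offset
        curve = np.full(config.n_bands, config.baseline_amplitude)
    scales = 1.0 + config.baseline_pixel_jitter * rng.standard_normal(n)
    return np.abs(scales)[:, None] * curve[None, :]


def gen_scene(config: SceneConfig) -> Tuple[SpectralContainer, GroundTruthBundle]:
    """Generate a full synthetic scene and its ground truth.

    Intensities are ``abundances @ endmembers + baseline + spikes``, then
    contaminated with Gaussian noise: directly additive, or — under the
    paper-noise protocol — added after per-spectrum min-max scaling to
    [0, 1].  All randomness flows from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    endmembers, _peaks = gen_endmembers(config, rng=rng)
    abundances = gen_abundances(
        config.spatial_shape,
        config.k,
        concentration=config.dirichlet_concentration,
        plant_pure_pixels=config.plant_pure_pixels,
        rng=rng,
    )
    n, b = config.n_pixels, config.n_bands
    flat_ab = abundances.reshape(n, config.k)
    clean = flat_ab @ endmembers

    if config.baseline_amplitude > 0:
        baseline = _gen_baseline(config, rng, n)
    else:
        baseline = np.zeros((n, b))

    spike_mask = rng.random((n, b)) < config.spike_rate
    spikes = np.zeros((n, b))
    if spike_mask.any():
        spikes[spike_mask] = rng.uniform(
            *config.spike_amplitude_range, size=int(spike_mask.sum())
        )

    signal = clean + baseline + spikes
    if config.noise_sigma > 0:
        if config.paper_noise:
            lo = signal.min(axis=1, keepdims=True)
            hi = signal.max(axis=1, keepdims=True)
            span = np.where(hi > lo, hi - lo, 1.0)
            signal = (signal - lo) / span
        signal = signal + config.noise_sigma * rng.standard_normal((n, b))

    shape = tuple(config.spatial_shape) + (b,)
    container = make_container(signal.reshape(shape), config.axis)
    bundle = GroundTruthBundle(
        endmembers=endmembers,
        abundances=abundances,
        baseline=baseline.reshape(shape),
        spike_mask=spike_mask.reshape(shape),
        noise_sigma=config.noise_sigma,
    )
    return container, bundle


def gen_uniform_spectra(
    n: int, b: int = 1500, seed: Optional[int] = None
) -> SpectralContainer:
    """Uniform-[0, 1) spectra for throughput profiling.

    Returns a stack of ``n`` spectra of ``b`` i.i.d. uniform values each on
    a unit-spaced axis; the default ``b = 1500`` matches the standard
    profiling input size.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if b < 2:
        raise ValueError("b must be >= 2")
    rng = np.random.default_rng(seed)
    values = rng.random((n, b))
    return make_container(values, np.arange(b, dtype=np.float64))
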