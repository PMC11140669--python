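"""Shared fixtures: wavenumber axes and synthetic spectra builders."""

import numpy as np
import pytest

from ramankit import make_container


@pytest.fixture
def fingerprint_axis():
    """800 bands across 700-1800 cm^-1."""
    return np.linspace(700.0, 1800.0, 800)


@pytest.fixture
def wide_axis():
    """Axis spanning 400-3000 cm^-1 in steps of 2."""
    return np.arange(400.0, 3000.0 + 1, 2.0)


def make_smooth_spectra(rng, n, axis, n_peaks=6, noise_sigma=0.0):
    """Multi-peak Gaussian-band spectra with an optional noise floor."""
    b = axis.size
    lo, hi = axis[0], axis[-1]
    out = np.zeros((n, b))
    for i in range(n):
        for _ in range(n_peaks):
            c = rng.uniform(lo + 50, hi - 50)
            w = rng.uniform(8.0, 30.0)
            a = rng.uniform(0.2, 1.0)
            out[i] += a * np.exp(-((axis - c) ** 2) / (2 * w**2))
    if noise_sigma > 0:
        out += noise_sigma * rng.standard_normal((n, b))
    return out


@pytest.fixture
def smooth_stack(fingerprint_axis):
    """A stack of 8 smooth spectra with a mild (2% of peak) noise floor."""
    rng = np.random.default_rng(1234)
    data = make_smooth_spectra(rng, 8, fingerprint_axis, noise_sigma=0.02)
    return make_container(data, fingerprint_axis)


@pytest.fixture
def random_image(fingerprint_axis):
    rng = np.random.default_rng(99)
    return make_container(rng.random((5, 4, fingerprint_axis.size)), fingerprint_axis)
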