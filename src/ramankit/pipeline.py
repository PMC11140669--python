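"""Composable, serializable preprocessing pipelines.

A :class:`Pipeline` is an ordered list of named steps with concrete
parameters.  Steps are resolved through a registry of canonical names, so a
pipeline serializes to plain JSON — step names and parameters only, never
code — and can be saved, shared, and re-applied bit-identically elsewhere.

Built-in protocols
------------------
``cell_phenotyping``
    crop(700, 1800) -> Whitaker-Hayes despiking -> Savitzky-Golay(order 3,
    window 7) -> ASLS baseline correction -> global min-max normalization to
    [0, 1].  The protocol used ahead of N-FINDR/FCLS unmixing of cell scans.
``pipeline_I``
    crop(700, 1800) -> Whitaker-Hayes despiking -> Gaussian denoising ->
    ASLS baseline correction -> per-spectrum area-under-curve normalization
    to 1.  A representative protocol for throughput profiling.

Where a protocol's literature description names a method without its
parameters, the package defaults are embedded explicitly at construction, so
saved protocols are fully concrete.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Dict, List, Tuple, Union

import numpy as np

from . import preprocessing as pp
from .core import SpectralContainer, make_container

__all__ = [
    "PipelineStep",
    "Pipeline",
    "RegistryError",
    "StepExecutionError",
    "register_step",
    "registered_steps",
    "pipeline_apply",
    "pipeline_save",
    "pipeline_load",
    "pipeline_to_json",
    "pipeline_from_json",
    "get_protocol",
    "PROTOCOL_NAMES",
]

PIPELINE_FORMAT_VERSION = "1"

logger = logging.getLogger("ramankit.pipeline")


class RegistryError(KeyError):
    """Unknown or conflicting step name."""

    def __str__(self) -> str:  # KeyError quotes its message otherwise
        return self.args[0] if self.args else ""


class StepExecutionError(RuntimeError):
    """A pipeline step failed; carries the step index and name."""

    def __init__(self, index: int, step_name: str, cause: Exception):
        super().__init__(f"step {index} ({step_name!r}) failed: {cause}")
        self.index = index
        self.step_name = step_name
        self.cause = cause


StepFunc = Callable[..., SpectralContainer]

_REGISTRY: Dict[str, StepFunc] = {}


def register_step(name: str, func: StepFunc) -> None:
    """Register a container -> container step under a canonical name.

    The function receives the container as first argument and the step's
    JSON-serializable params as keyword arguments.
    """
    if name in _REGISTRY:
        raise RegistryError(f"step {name!r} already registered")
    _REGISTRY[name] = func


def registered_steps() -> List[str]:
    return sorted(_REGISTRY)


def _resolve(name: str) -> StepFunc:
    if name not in _REGISTRY:
        raise RegistryError(
            f"unknown step {name!r}; registered steps: {registered_steps()}"
        )
    return _REGISTRY[name]


# ----------------------------------------------------------------------
# Built-in steps.  subtract_bg carries its background spectrum inside the
# params (axis + intensities lists) so that it serializes like any other.


def _step_subtract_bg(c: SpectralContainer, background: dict) -> SpectralContainer:
    bg = make_container(
        np.asarray(background["intensities"], dtype=np.float64),
        np.asarray(background["axis"], dtype=np.float64),
    )
    return pp.subtract_background(c, bg)


_BUILTIN_STEPS: Dict[str, StepFunc] = {
    "crop": pp.crop,
    "despike_wh": pp.despike_whitaker_hayes,
    "savgol": pp.denoise_savgol,
    "gaussian": pp.denoise_gaussian,
    "asls": pp.baseline_asls,
    "aspls": pp.baseline_aspls,
    "normalize": pp.normalize,
    "subtract_bg": _step_subtract_bg,
}

for _name, _func in _BUILTIN_STEPS.items():
    register_step(_name, _func)


# ----------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineStep:
    """One named step with fully concrete parameters."""

    step_name: str
    params: Dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _resolve(self.step_name)  # must be registered

    def apply(self, c: SpectralContainer) -> SpectralContainer:
        return _resolve(self.step_name)(c, **self.params)


@dataclass(frozen=True)
class Pipeline:
    """Ordered, serializable preprocessing protocol."""

    name: str
    steps: Tuple[PipelineStep, ...]
    format_version: str = PIPELINE_FORMAT_VERSION

    def __post_init__(self) -> None:
        steps = tuple(self.steps)
        if not steps:
            raise ValueError("a pipeline needs at least one step")
        object.__setattr__(self, "steps", steps)

    def apply(self, c: SpectralContainer) -> SpectralContainer:
        return pipeline_apply(self, c)


def pipeline_apply(p: Pipeline, c: SpectralContainer) -> SpectralContainer:
    """Apply the steps strictly left to right.

    Equivalent to manually chaining the step operations; each step emits a
    log record with its name, parameters, input/output shapes and wall time.
    A failing step aborts with its index and name attached.
    """
    out = c
    for i, step in enumerate(p.steps):
        t0 = time.perf_counter()
        shape_in = out.intensities.shape
        try:
            out = step.apply(out)
        except Exception as exc:  # noqa: BLE001 - re-raised with context
            raise StepExecutionError(i, step.step_name, exc) from exc
        logger.info(
            "pipeline=%s step=%d name=%s params=%s shape_in=%s shape_out=%s "
            "wall_s=%.6f",
            p.name, i, step.step_name, step.params, shape_in,
            out.intensities.shape, time.perf_counter() - t0,
        )
    return out


# ----------------------------------------------------------------------
# JSON serialization


def pipeline_to_json(p: Pipeline) -> str:
    """Canonical JSON form (sorted keys, reproducible diffs)."""
    doc = {
        "format_version": p.format_version,
        "name": p.name,
        "steps": [
            {"step": s.step_name, "params": s.params} for s in p.steps
        ],
    }
    return json.dumps(doc, sort_keys=True, indent=2)


def pipeline_from_json(text: str) -> Pipeline:
    doc = json.loads(text)
    version = doc.get("format_version")
    if version != PIPELINE_FORMAT_VERSION:
        raise ValueError(
            f"pipeline format_version {version!r} not supported "
            f"(expected {PIPELINE_FORMAT_VERSION!r})"
        )
    steps = tuple(
        PipelineStep(step_name=s["step"], params=dict(s.get("params", {})))
        for s in doc["steps"]
    )
    return Pipeline(name=doc.get("name", "unnamed"), steps=steps)


def pipeline_save(p: Pipeline, path: Union[str, Path]) -> None:
    Path(path).write_text(pipeline_to_json(p), encoding="utf-8")


def pipeline_load(path: Union[str, Path]) -> Pipeline:
    return pipeline_from_json(Path(path).read_text(encoding="utf-8"))


# ----------------------------------------------------------------------
# Built-in protocols (defaults embedded so saved protocols are concrete)


def _despike_defaults() -> Dict[str, Any]:
    return {
        "z_threshold": pp.DEFAULT_DESPIKE_THRESHOLD,
        "window": pp.DEFAULT_DESPIKE_WINDOW,
    }


def _asls_defaults() -> Dict[str, Any]:
    return {
        "lam": pp.DEFAULT_ASLS_LAM,
        "p": pp.DEFAULT_ASLS_P,
        "max_iter": pp.DEFAULT_ASLS_MAX_ITER,
        "tol": pp.DEFAULT_ASLS_TOL,
    }


def _build_cell_phenotyping() -> Pipeline:
    return Pipeline(
        name="cell_phenotyping",
        steps=(
            PipelineStep("crop", {"min_wn": 700.0, "max_wn": 1800.0}),
            PipelineStep("despike_wh", _despike_defaults()),
            PipelineStep("savgol", {"polyorder": 3, "window": 7}),
            PipelineStep("asls", _asls_defaults()),
            PipelineStep("normalize", {"mode": "minmax_global"}),
        ),
    )


def _build_pipeline_i() -> Pipeline:
    return Pipeline(
        name="pipeline_I",
        steps=(
            PipelineStep("crop", {"min_wn": 700.0, "max_wn": 1800.0}),
            PipelineStep("despike_wh", _despike_defaults()),
            PipelineStep("gaussian", {"sigma_bands": pp.DEFAULT_GAUSSIAN_SIGMA}),
            PipelineStep("asls", _asls_defaults()),
            PipelineStep("normalize", {"mode": "auc_pixel"}),
        ),
    )


_PROTOCOLS: Dict[str, Callable[[], Pipeline]] = {
    "cell_phenotyping": _build_cell_phenotyping,
    "pipeline_I": _build_pipeline_i,
}

PROTOCOL_NAMES = tuple(sorted(_PROTOCOLS))


def get_protocol(name: str) -> Pipeline:
    """Return a built-in named protocol (``cell_phenotyping``,
    ``pipeline_I``)."""
    if name not in _PROTOCOLS:
        raise RegistryError(
            f"unknown protocol {name!r}; available: {list(PROTOCOL_NAMES)}"
        )
    return _PROTOCOLS[name]()
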