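"""Hyperspectral unmixing: N-FINDR endmember extraction and fully
constrained least-squares (FCLS) abundance estimation.

Model
-----
Under the linear mixing model each observed spectrum is a convex combination
of K pure-component spectra (endmembers): ``y = E^T a`` with ``a >= 0`` and
``sum(a) = 1``.  N-FINDR finds the K observed pixels whose simplex, in a
(K-1)-dimensional PCA projection of the data, has maximum volume — under the
pure-pixel assumption these are the endmembers.  FCLS then solves the
constrained least-squares problem per pixel to produce fractional abundance
maps.

The simplex volume for projected endmembers ``e_1..e_K`` (each in R^{K-1})
is ``V = |det(M)| / (K-1)!`` where ``M`` stacks the vectors augmented with a
leading 1.  The N-FINDR search sweeps endmember slots, replacing a slot by
any pixel that strictly increases the volume, until a full pass makes no
replacement; multiple seeded random restarts guard against local optima.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import factorial
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import nnls

from .core import SpectralContainer, flatten
from .metrics import sad

__all__ = [
    "EndmemberSet",
    "AbundanceMap",
    "PCAProjection",
    "pca_project",
    "nfindr",
    "fcls",
    "unmix_scene",
    "match_endmembers",
    "DegenerateGeometryError",
    "RankError",
]

ABUNDANCE_NONNEG_TOL = 1e-9
ABUNDANCE_SUM_TOL = 1e-6
CONDITION_CAP = 1e10


class DegenerateGeometryError(ValueError):
    """All candidate pixels are affinely dependent (zero simplex volume)."""


class RankError(ValueError):
    """Data rank is below the requested projection dimension."""


@dataclass(frozen=True)
class PCAProjection:
    """Mean-centered orthogonal projection onto top principal directions."""

    mean: np.ndarray          # (B,)
    components: np.ndarray    # (dims, B), orthonormal rows

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.mean) @ self.components.T


@dataclass(frozen=True)
class EndmemberSet:
    """K extracted pure-component spectra.

    ``spectra`` are rows of the *original* data matrix (N-FINDR selects
    observed pixels); ``indices`` are their flattened-pixel indices and
    ``volume`` the achieved simplex volume in the projected space.
    """

    spectra: np.ndarray   # (K, B)
    indices: np.ndarray   # (K,)
    volume: float

    @property
    def k(self) -> int:
        return self.spectra.shape[0]


@dataclass(frozen=True)
class AbundanceMap:
    """Per-pixel convex mixing fractions, shape spatial + (K,)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if np.any(v < -ABUNDANCE_NONNEG_TOL):
            raise ValueError(
                f"abundances dip below -{ABUNDANCE_NONNEG_TOL}: min {v.min()}"
            )
        sums = v.sum(axis=-1)
        if np.any(np.abs(sums - 1.0) > ABUNDANCE_SUM_TOL):
            raise ValueError("abundances do not sum to 1 within tolerance")
        object.__setattr__(self, "values", v)

    @property
    def k(self) -> int:
        return self.values.shape[-1]


# ----------------------------------------------------------------------


def pca_project(X: np.ndarray, dims: int) -> Tuple[np.ndarray, PCAProjection]:
    """Project the rows of ``X`` onto the top ``dims`` principal directions.

    Returns the N x dims score matrix and a :class:`PCAProjection` record
    that maps any spectrum into the same space.  Raises :class:`RankError`
    when the centered data has rank below ``dims``.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("X must be an N x B matrix")
    n, b = X.shape
    if dims < 1:
        raise ValueError("dims must be >= 1")
    if dims > min(n, b):
        raise RankError(f"dims ({dims}) exceeds min(N, B) = {min(n, b)}")
    mean = X.mean(axis=0)
    Xc = X - mean
    # full_matrices=False: Vt rows are the principal directions
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = s[0] * max(n, b) * np.finfo(np.float64).eps if s.size else 0.0
    rank = int(np.sum(s > tol))
    if rank < dims:
        raise RankError(
            f"centered data has rank {rank}, below requested dims {dims}"
        )
    proj = PCAProjection(mean=mean, components=Vt[:dims])
    return Xc @ Vt[:dims].T, proj


def _simplex_volumes_for_slot(
    aug: np.ndarray, endmember_rows: np.ndarray, slot: int
) -> np.ndarray:
    """|det| of the augmented endmember matrix with ``slot`` replaced by
    every pixel, exploiting linearity of det in one row via cofactors."""
    K = endmember_rows.shape[0]
    M = endmember_rows.copy()
    # cofactor row: det(M with row `slot` = x) = x . c
    c = np.empty(K)
    for col in range(K):
        minor = np.delete(np.delete(M, slot, axis=0), col, axis=1)
        c[col] = (-1.0) ** (slot + col) * np.linalg.det(minor)
    return np.abs(aug @ c)


def nfindr(
    X: np.ndarray,
    k: int,
    n_restarts: int = 10,
    seed: Optional[int] = None,
) -> EndmemberSet:
    """N-FINDR endmember extraction.

    Projects the data to ``k - 1`` dimensions with PCA, then iteratively
    swaps endmember slots with pixels whenever the simplex volume strictly
    increases (ties keep the incumbent), cycling until a full pass makes no
    replacement.  The best of ``n_restarts`` seeded random initializations
    is returned, with endmember spectra taken from the original data rows.
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k ({k}) exceeds number of pixels ({n})")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")

    scores, _ = pca_project(X, k - 1)
    # augmented coordinates: leading 1 then the k-1 projected coordinates
    aug = np.column_stack([np.ones(n), scores])
    rng = np.random.default_rng(seed)
    norm = factorial(k - 1)

    best_vol = -1.0
    best_idx: Optional[np.ndarray] = None
    for _ in range(n_restarts):
        idx = rng.choice(n, size=k, replace=False)
        vol = abs(np.linalg.det(aug[idx]))
        improved = True
        while improved:
            improved = False
            for slot in range(k):
                vols = _simplex_volumes_for_slot(aug, aug[idx], slot)
                cand = int(np.argmax(vols))
                if vols[cand] > vol:   # strict: ties keep the incumbent
                    idx[slot] = cand
                    vol = vols[cand]
                    improved = True
        if vol > best_vol:
            best_vol = vol
            best_idx = idx.copy()

    assert best_idx is not None
    if best_vol <= 0.0:
        raise DegenerateGeometryError(
            "all candidate simplices have zero volume; data are affinely "
            "dependent"
        )
    order = np.sort(best_idx)
    return EndmemberSet(
        spectra=X[order].copy(), indices=order, volume=best_vol / norm
    )


def fcls(
    X: np.ndarray,
    endmembers: EndmemberSet,
    spatial_shape: Optional[Tuple[int, ...]] = None,
) -> AbundanceMap:
    """Fully constrained least-squares abundance estimation.

    Per pixel ``y`` solves ``min ||E^T a - y||^2`` subject to ``a >= 0`` and
    ``sum(a) = 1``, via nonnegative least squares on the system augmented
    with a heavily weighted sum-to-one row (weight gamma = 1e3 times the
    largest endmember norm), followed by exact renormalization to unit sum.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    E = endmembers.spectra            # (K, B)
    k, b = E.shape
    if X.shape[1] != b:
        raise ValueError("pixel spectra and endmembers disagree on band count")
    if k > b:
        raise ValueError("more endmembers than bands")
    cond = np.linalg.cond(E @ E.T)
    if cond > CONDITION_CAP:
        import warnings

        warnings.warn(
            f"endmember matrix is ill-conditioned (cond {cond:.3g}); "
            "abundances may be unstable",
            stacklevel=2,
        )

    gamma = 1e3 * float(np.max(np.linalg.norm(E, axis=1)))
    A = np.vstack([E.T, gamma * np.ones((1, k))])   # (B+1, K)
    out = np.empty((X.shape[0], k))
    for i, y in enumerate(X):
        rhs = np.concatenate([y, [gamma]])
        try:
            a, _ = nnls(A, rhs)
        except RuntimeError as exc:
            raise RuntimeError(f"FCLS failed at pixel {i}: {exc}") from exc
        total = a.sum()
        if total <= 0:
            raise RuntimeError(f"FCLS produced an all-zero abundance at pixel {i}")
        out[i] = a / total
    if spatial_shape is not None:
        out = out.reshape(tuple(spatial_shape) + (k,))
    return AbundanceMap(values=out)


def unmix_scene(
    c: SpectralContainer,
    k: int,
    n_restarts: int = 10,
    seed: Optional[int] = None,
) -> Tuple[EndmemberSet, AbundanceMap]:
    """Flatten a scene, extract K endmembers with N-FINDR, estimate per-pixel
    abundances with FCLS, and reshape them to the scene's spatial grid.
    Deterministic given ``seed``."""
    X, spatial = flatten(c)
    em = nfindr(X, k, n_restarts=n_restarts, seed=seed)
    ab = fcls(X, em, spatial_shape=spatial)
    return em, ab


def match_endmembers(
    estimated: np.ndarray, truth: np.ndarray
) -> Tuple[np.ndarray, float]:
    """Best permutation matching of estimated to true endmembers by minimum
    total spectral angle; returns (permutation, mean SAD).

    ``permutation[j]`` is the estimated row assigned to true row ``j``.
    Exhaustive over permutations — intended for the small K of validation
    studies.
    """
    k = truth.shape[0]
    if estimated.shape[0] != k:
        raise ValueError("endmember counts differ")
    best_perm, best_cost = None, np.inf
    for perm in permutations(range(k)):
        cost = sum(sad(estimated[perm[j]], truth[j]) for j in range(k))
        if cost < best_cost:
            best_cost, best_perm = cost, perm
    return np.array(best_perm), best_cost / k
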