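"""Anisotropic covariance functions for scanline interpolation.

Two stationary families are provided — the squared exponential (SE) and the
Matérn class — sharing one anisotropic distance metric

    r(x_i, x_j) = sqrt( Σ_n (x_{i,n} − x_{j,n})² / l_n² ),

with a separate characteristic length scale per axis: ``l_r`` along the
beam and ``l_α`` across beams.  Separate scales matter because scanline
sampling is strongly anisotropic (dense along the beam, sparse across
beams), and for diverging beams the physical across-beam spacing grows
linearly with depth, which is handled by shrinking the angular ``l_α``
proportionally to 1/r (:func:`depth_scaled_spec`).

The Matérn kernel is evaluated through its half-integer closed forms
(ν ∈ {1/2, 3/2, 5/2}), which are exact, fast, and well-behaved at r = 0
where the general Γ/Bessel expression degenerates to 0·∞.  ν = 1/2 is the
exponential kernel; as ν → ∞ the family approaches the SE kernel.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import DIVERGING, PointSet, ScanGrid

__all__ = [
    "KernelSpec",
    "scaled_distance",
    "se_kernel",
    "matern_kernel",
    "kernel_matrix",
    "depth_scaled_spec",
]

SQUARED_EXPONENTIAL = "squared_exponential"
MATERN = "matern"
SUPPORTED_NU = (0.5, 1.5, 2.5)

#: relative diagonal jitter added before factorizing k(a, a)
JITTER_RELATIVE = 1e-10


@dataclass(frozen=True)
class KernelSpec:
    """Covariance family and hyperparameters.

    ``signal_variance`` (σ²) and ``noise_variance`` (σn²) are expressed in
    standardized-intensity units (the GP standardizes intensities to unit
    variance, so σ² = 1 is the natural default).  Length scales are in the
    raw beam-native coordinate units of the grid they are used with; the
    regression rescales them together with the coordinates, which leaves
    every kernel value unchanged.
    """

    family: str = MATERN
    nu: float = 1.5
    signal_variance: float = 1.0
    length_scale_r: float = 1.0
    length_scale_alpha: float = 1.0
    noise_variance: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in (SQUARED_EXPONENTIAL, MATERN):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.family == MATERN and self.nu not in SUPPORTED_NU:
            raise ValueError(f"nu must be one of {SUPPORTED_NU}, got {self.nu}")
        if self.signal_variance <= 0:
            raise ValueError("signal_variance must be > 0")
        if self.length_scale_r <= 0 or self.length_scale_alpha <= 0:
            raise ValueError("length scales must be > 0")
        if self.noise_variance < 0:
            raise ValueError("noise_variance must be >= 0")

    @property
    def length_scales(self) -> np.ndarray:
        return np.array([self.length_scale_r, self.length_scale_alpha])

    def replace(self, **kw) -> "KernelSpec":
        return dataclasses.replace(self, **kw)

    # serialization ---------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "nu": self.nu,
            "signal_variance": self.signal_variance,
            "length_scale_r": self.length_scale_r,
            "length_scale_alpha": self.length_scale_alpha,
            "noise_variance": self.noise_variance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "KernelSpec":
        return cls(**d)

    @classmethod
    def from_json(cls, s: str) -> "KernelSpec":
        return cls.from_dict(json.loads(s))

    def fingerprint(self) -> str:
        import hashlib

        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _coords(points) -> np.ndarray:
    if isinstance(points, PointSet):
        return points.coords
    arr = np.atleast_2d(np.asarray(points, dtype=float))
    return arr


def scaled_distance(a, b, spec: KernelSpec) -> np.ndarray:
    """Length-scale-standardized Euclidean distance matrix.

    Entry (i, j) is ``sqrt(Σ_n (a_{i,n} − b_{j,n})² / l_n²)``.
    """
    xa, xb = _coords(a), _coords(b)
    if xa.shape[1] != xb.shape[1]:
        raise ValueError(
            f"coordinate dimensionality mismatch: {xa.shape[1]} vs {xb.shape[1]}"
        )
    ls = spec.length_scales[: xa.shape[1]]
    return cdist(xa / ls, xb / ls)


def se_kernel(a, b, spec: KernelSpec) -> np.ndarray:
    """Squared-exponential covariance σ²·exp(−r²/2) with anisotropic r."""
    if spec.family != SQUARED_EXPONENTIAL:
        raise ValueError("spec.family must be squared_exponential")
    r = scaled_distance(a, b, spec)
    # evaluate in place: r is a fresh array and these matrices can be large
    np.multiply(r, r, out=r)
    r *= -0.5
    np.exp(r, out=r)
    r *= spec.signal_variance
    return r


def _matern_of_r(r: np.ndarray, nu: float, sigma2: float, clobber: bool = False) -> np.ndarray:
    """Half-integer Matérn forms; with ``clobber`` the input is reused as
    scratch to cap peak memory on large matrices."""
    if not clobber:
        r = np.array(r, dtype=float, copy=True)
    if nu == 0.5:
        np.negative(r, out=r)
        np.exp(r, out=r)
        r *= sigma2
        return r
    if nu == 1.5:
        r *= math.sqrt(3.0)
        poly = 1.0 + r
        np.negative(r, out=r)
        np.exp(r, out=r)
        r *= poly
        r *= sigma2
        return r
    if nu == 2.5:
        r *= math.sqrt(5.0)
        poly = r * r
        poly /= 3.0
        poly += r
        poly += 1.0
        np.negative(r, out=r)
        np.exp(r, out=r)
        r *= poly
        r *= sigma2
        return r
    raise ValueError(f"nu must be one of {SUPPORTED_NU}, got {nu}")


def matern_kernel(a, b, spec: KernelSpec) -> np.ndarray:
    """Matérn covariance via half-integer closed forms.

    ν = 1/2: σ²·e^{−r};  ν = 3/2: σ²(1 + √3 r)e^{−√3 r};
    ν = 5/2: σ²(1 + √5 r + 5r²/3)e^{−√5 r}.  The r → 0 limit is σ² exactly.
    """
    if spec.family != MATERN:
        raise ValueError("spec.family must be matern")
    r = scaled_distance(a, b, spec)
    return _matern_of_r(r, spec.nu, spec.signal_variance, clobber=True)


def kernel_matrix(a, b, spec: KernelSpec) -> np.ndarray:
    """Covariance matrix k(a, b) for either family."""
    if spec.family == SQUARED_EXPONENTIAL:
        return se_kernel(a, b, spec)
    return matern_kernel(a, b, spec)


def matern_from_distance(r: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Matérn covariance evaluated on precomputed scaled distances."""
    return _matern_of_r(np.asarray(r, dtype=float), spec.nu, spec.signal_variance)


def depth_scaled_spec(
    spec: KernelSpec,
    grid: ScanGrid,
    depth: float,
    base_alpha: float | None = None,
    reading: str = "ratio",
) -> KernelSpec:
    """Depth-dependent across-beam length scale for diverging beams.

    The physical distance between adjacent diverging beams at depth r is
    r·Δα, so a constant *cartesian* correlation length corresponds to an
    angular length scale shrinking like 1/r.  Anchored so that at mid-depth
    (r = |r̄|/2 past the apex) the value equals the parallel-grid rule
    l_α = Δα/3:

        l_α(r̄_i) = (1/3) · (|r̄| / (2 r̄_i)) · Δα          (default reading)

    ``base_alpha`` overrides the mid-depth anchor Δα/3 (used when l_α was
    fitted rather than taken from the grid heuristic).  ``reading="squared"``
    selects the alternative grouping (1/3)·(|r̄|²/r̄_i)·Δα of the same rule;
    it is retained only for comparison and is not the default because it
    fails to reduce to the parallel-grid value at mid-depth.
    """
    if grid.geometry != DIVERGING:
        raise ValueError("depth scaling applies to diverging grids only")
    if depth <= 0:
        raise ValueError("depth must be > 0")
    anchor = grid.beam_pitch / 3.0 if base_alpha is None else float(base_alpha)
    if reading == "ratio":
        l_alpha = anchor * (grid.scan_length / 2.0) / depth
    elif reading == "squared":
        l_alpha = anchor * grid.scan_length**2 / depth
    else:
        raise ValueError("reading must be 'ratio' or 'squared'")
    return spec.replace(length_scale_alpha=l_alpha)
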