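"""Synthetic scanline phantoms.

Clinical scanline data is rarely shareable, so every part of the pipeline
is exercised on synthetic frames with the statistical structure the
regression assumes:

* ``gp_draw`` — a draw from a zero-mean stationary GP with a known kernel
  on the observation lattice, plus i.i.d. observation noise.  This is the
  matched-model ground truth: the generating hyperparameters are known
  exactly, which is what parameter-recovery and method-ordering studies
  need.
* ``layered_tissue`` — depth-wise bands of contrasting echogenicity with
  smooth transitions and optional multiplicative speckle; a cartoon of
  cardiac-style anatomy (uniform dark blood pools against bright muscle).
* ``speckle`` — a smooth low-frequency background field modulated by
  multiplicative speckle noise; a cartoon of high-frequency soft-tissue
  texture.

Defaults mirror the two probe setups the package targets: a dense parallel
grid (256 scanlines × 793 samples, linear probe) and a sparse diverging
grid (64 scanlines × 412 samples, phased-array probe), with per-probe
noise variances 2×10⁻³ and 8×10⁻³ respectively.

GP draws are exact (dense Cholesky) up to 10⁴ lattice points; larger
lattices use a circulant-embedding spectral sampler (FFT), which is the
standard exact method for stationary fields on regular grids up to
clipping of any slightly negative embedding eigenvalues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import fft2, ifft2, next_fast_len

from .geometry import DIVERGING, PARALLEL, ScanFrame, ScanGrid, observation_coords
from .kernels import KernelSpec, kernel_matrix, scaled_distance, _matern_of_r

__all__ = [
    "PhantomSpec",
    "default_grid",
    "default_kernel",
    "generate_phantom",
    "paired_study_fixture",
]

logger = logging.getLogger(__name__)

EXACT_LIMIT = 10_000
HARD_LIMIT = 100_000

#: default per-probe observation-noise std deviations (variance 2e-3 / 8e-3)
NOISE_STD = {PARALLEL: np.sqrt(2e-3), DIVERGING: np.sqrt(8e-3)}

INTENSITY_LO, INTENSITY_HI = 0.05, 0.95


def default_grid(geometry: str = DIVERGING) -> ScanGrid:
    """Reference grids: 256×793 parallel (leg-like) or 64×412 diverging
    (cardiac-like)."""
    if geometry == PARALLEL:
        return ScanGrid(PARALLEL, n_scanlines=256, n_samples=793, sample_pitch=1.0, beam_pitch=1.0)
    return ScanGrid(
        DIVERGING,
        n_scanlines=64,
        n_samples=412,
        sample_pitch=1.0,
        beam_pitch=np.deg2rad(1.2),
    )


def default_kernel(grid: ScanGrid) -> KernelSpec:
    """Default texture kernel: Matérn 3/2 with l_r = 3Δr and l_α = 1.5Δα —
    smooth along the beam over a few samples, correlated across one to two
    beams."""
    return KernelSpec(
        family="matern",
        nu=1.5,
        signal_variance=1.0,
        length_scale_r=3.0 * grid.sample_pitch,
        length_scale_alpha=1.5 * grid.beam_pitch,
        noise_variance=0.0,
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one synthetic frame; identical (spec, seed) pairs yield
    identical frames."""

    grid: ScanGrid
    texture: str = "gp_draw"
    kernel: KernelSpec | None = None
    noise_std: float | None = None
    layer_depths: tuple[float, ...] = (0.35, 0.65)  # fractional band edges
    layer_intensities: tuple[float, ...] = (0.75, 0.2, 0.6)
    edge_width: float = 0.02  # fraction of scan depth
    speckle_scale: float = 0.15
    seed: int = 0
    method: str = "auto"  # gp_draw sampler: auto | exact | spectral

    def __post_init__(self) -> None:
        if self.texture not in ("gp_draw", "layered_tissue", "speckle"):
            raise ValueError(f"unknown texture {self.texture!r}")
        if self.texture == "layered_tissue" and len(self.layer_intensities) != len(self.layer_depths) + 1:
            raise ValueError("need one intensity per band (len(depths) + 1)")
        if self.method not in ("auto", "exact", "spectral"):
            raise ValueError("method must be auto, exact or spectral")


def _rescale(field: np.ndarray) -> np.ndarray:
    """Affine map of a field onto [INTENSITY_LO, INTENSITY_HI]."""
    lo, hi = field.min(), field.max()
    if hi - lo <= 0:
        return np.full_like(field, 0.5 * (INTENSITY_LO + INTENSITY_HI))
    return INTENSITY_LO + (INTENSITY_HI - INTENSITY_LO) * (field - lo) / (hi - lo)


def _gp_draw_exact(grid: ScanGrid, kernel: KernelSpec, rng: np.random.Generator) -> np.ndarray:
    pts = observation_coords(grid)
    K = kernel_matrix(pts, pts, kernel)
    n = K.shape[0]
    K[np.arange(n), np.arange(n)] += 1e-10 * kernel.signal_variance
    L = np.linalg.cholesky(K)
    z = L @ rng.standard_normal(n)
    return z.reshape((grid.n_samples, grid.n_scanlines), order="F")


def _gp_draw_spectral(grid: ScanGrid, kernel: KernelSpec, rng: np.random.Generator) -> np.ndarray:
    """Circulant-embedding draw of a stationary field on the lattice.

    The lattice covariance depends only on the index lag, so the field is
    drawn by filtering complex white noise with the square root of the
    embedded covariance spectrum.  Slightly negative eigenvalues of the
    embedding (the covariance is not exactly periodic) are clipped to
    zero; the clipped mass is logged when non-negligible.
    """
    ns, nb = grid.n_samples, grid.n_scanlines
    m1 = next_fast_len(2 * ns)
    m2 = next_fast_len(2 * nb)
    # wrap-around lags on the embedding torus, in physical units
    lag_r = np.minimum(np.arange(m1), m1 - np.arange(m1)) * grid.sample_pitch
    lag_a = np.minimum(np.arange(m2), m2 - np.arange(m2)) * grid.beam_pitch
    d = scaled_distance(
        np.column_stack([lag_r.repeat(m2), np.tile(lag_a, m1)]),
        np.zeros((1, 2)),
        kernel,
    ).reshape(m1, m2)
    if kernel.family == "matern":
        cov = _matern_of_r(d, kernel.nu, kernel.signal_variance, clobber=True)
    else:
        cov = kernel.signal_variance * np.exp(-0.5 * d * d)
    spectrum = fft2(cov).real
    neg = spectrum < 0
    if neg.any():
        frac = -spectrum[neg].sum() / np.abs(spectrum).sum()
        if frac > 1e-6:
            logger.debug("clipped %.2e of embedding spectrum mass", frac)
        spectrum[neg] = 0.0
    eps = rng.standard_normal((m1, m2)) + 1j * rng.standard_normal((m1, m2))
    f = fft2(eps * np.sqrt(spectrum / (m1 * m2)))
    return f.real[:ns, :nb].copy()


def _smoothstep(x: np.ndarray) -> np.ndarray:
    t = np.clip(x, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _layered(grid: ScanGrid, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    depth = np.linspace(0.0, 1.0, grid.n_samples)
    profile = np.full(grid.n_samples, spec.layer_intensities[0], dtype=float)
    w = max(spec.edge_width, 1e-6)
    for edge, nxt in zip(spec.layer_depths, spec.layer_intensities[1:]):
        s = _smoothstep((depth - edge) / w + 0.5)
        profile = profile * (1.0 - s) + nxt * s
    field = np.tile(profile[:, None], (1, grid.n_scanlines))
    if spec.speckle_scale > 0:
        field = field * rng.lognormal(0.0, spec.speckle_scale, size=field.shape)
    return field


def _speckle(grid: ScanGrid, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    # smooth background: a few random low-frequency cosine modes
    r = np.linspace(0, 1, grid.n_samples)[:, None]
    a = np.linspace(0, 1, grid.n_scanlines)[None, :]
    background = np.full((grid.n_samples, grid.n_scanlines), 0.5)
    for _ in range(4):
        fr, fa = rng.uniform(0.5, 3.0, size=2)
        ph_r, ph_a = rng.uniform(0, 2 * np.pi, size=2)
        background = background + 0.15 * np.cos(2 * np.pi * fr * r + ph_r) * np.cos(
            2 * np.pi * fa * a + ph_a
        )
    return background * rng.lognormal(0.0, spec.speckle_scale, size=background.shape)


def generate_phantom(spec: PhantomSpec) -> ScanFrame:
    """Generate one frame; deterministic per (spec, seed)."""
    grid = spec.grid
    rng = np.random.default_rng(spec.seed)
    if spec.texture == "gp_draw":
        kernel = spec.kernel or default_kernel(grid)
        n = grid.n_samples * grid.n_scanlines
        method = spec.method
        if method == "auto":
            method = "exact" if n <= EXACT_LIMIT else "spectral"
        if method == "exact" and n > HARD_LIMIT:
            raise ValueError(
                f"exact gp_draw on {n} points exceeds {HARD_LIMIT}; use method='spectral'"
            )
        if method == "exact":
            field = _gp_draw_exact(grid, kernel, rng)
        else:
            field = _gp_draw_spectral(grid, kernel, rng)
        noise = spec.noise_std if spec.noise_std is not None else NOISE_STD[grid.geometry]
        if noise > 0:
            field = field + noise * rng.standard_normal(field.shape)
    elif spec.texture == "layered_tissue":
        field = _layered(grid, spec, rng)
    else:
        field = _speckle(grid, spec, rng)
    return ScanFrame(
        grid=grid,
        intensities=_rescale(field),
        provenance=f"phantom:{spec.texture} seed={spec.seed}",
    )


def paired_study_fixture(spec: PhantomSpec, keep_counts) -> tuple[ScanFrame, list]:
    """One phantom generation shared across several decimation levels.

    Returns the full frame and, per keep count, the (decimated frame,
    held-out beam indices) pair from :func:`scangp.evaluation.decimate`.
    """
    from .evaluation import decimate

    frame = generate_phantom(spec)
    return frame, [decimate(frame, int(k)) for k in keep_counts]
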