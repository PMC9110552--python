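"""Exact Gaussian-process posterior mean and variance.

Scanline interpolation is cast as GP regression: observed intensities y at
beam-native locations x are modelled as a zero-mean GP (after
standardization) with an anisotropic stationary kernel, and the intensity
at interpolation locations x* is the posterior mean

    ȳ* = K*ᵀ (K + σn² I)⁻¹ y,

with pointwise uncertainty

    V[y*] = diag(K**) − diag(K*ᵀ (K + σn² I)⁻¹ K*).

The linear algebra goes through a Cholesky factorization of (K + σn² I)
with a small escalating diagonal jitter — never an explicit inverse.  Both
intensities and coordinates are standardized (zero mean, unit variance);
the kernel length scales are rescaled by the same per-axis factors, so
standardization changes conditioning but not the model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .geometry import PointSet
from .kernels import JITTER_RELATIVE, KernelSpec, kernel_matrix

__all__ = [
    "StandardizationParams",
    "GPPosterior",
    "standardize",
    "gp_predict",
    "log_marginal_likelihood",
    "cholesky_call_count",
    "reset_cholesky_counter",
]

logger = logging.getLogger(__name__)

#: number of ×10 jitter escalations attempted before giving up
MAX_JITTER_ESCALATIONS = 6

_CHOLESKY_CALLS = 0


def cholesky_call_count() -> int:
    """Total Cholesky factorizations performed since the last reset.

    Exists so callers can verify that precomputed regression operators are
    reused without refactorizing (the O(NM) apply path).
    """
    return _CHOLESKY_CALLS


def reset_cholesky_counter() -> None:
    global _CHOLESKY_CALLS
    _CHOLESKY_CALLS = 0


@dataclass(frozen=True)
class StandardizationParams:
    """Affine standardization of intensities and coordinates.

    ``degenerate`` flags a constant intensity vector, in which case the
    value scale is left at 1 (not an error: the inverse map still holds).
    """

    value_shift: float
    value_scale: float
    coord_shift: np.ndarray
    coord_scale: np.ndarray
    degenerate: bool = False

    def transform_values(self, v: np.ndarray) -> np.ndarray:
        return (np.asarray(v, dtype=float) - self.value_shift) / self.value_scale

    def inverse_values(self, v: np.ndarray) -> np.ndarray:
        return np.asarray(v, dtype=float) * self.value_scale + self.value_shift

    def transform_coords(self, c: np.ndarray) -> np.ndarray:
        return (np.asarray(c, dtype=float) - self.coord_shift) / self.coord_scale

    def inverse_coords(self, c: np.ndarray) -> np.ndarray:
        return np.asarray(c, dtype=float) * self.coord_scale + self.coord_shift


@dataclass(frozen=True)
class GPPosterior:
    """Posterior mean and variance at the target points, de-standardized,
    plus conditioning diagnostics (jitter applied, smallest Cholesky pivot)."""

    mean: np.ndarray
    variance: np.ndarray | None
    diagnostics: dict = field(default_factory=dict)


def standardize(values, coords) -> tuple[np.ndarray, np.ndarray, StandardizationParams]:
    """Map intensities and coordinates to zero mean / unit variance.

    Returns the standardized values, standardized coordinates and the
    parameters needed for exact inversion.  A constant value vector (or a
    degenerate coordinate axis) gets scale 1 and raises the ``degenerate``
    flag instead of an error.
    """
    v = np.asarray(values, dtype=float).ravel()
    c = np.atleast_2d(np.asarray(coords, dtype=float))
    if v.size < 1:
        raise ValueError("need at least one observation")
    v_shift = float(v.mean())
    v_scale = float(v.std())
    degenerate = not v_scale > 0
    if degenerate:
        v_scale = 1.0
    c_shift = c.mean(axis=0)
    c_scale = c.std(axis=0)
    c_scale = np.where(c_scale > 0, c_scale, 1.0)
    params = StandardizationParams(v_shift, v_scale, c_shift, c_scale, degenerate)
    return params.transform_values(v), params.transform_coords(c), params


#: above this size the factorization overwrites K to halve peak memory
_OVERWRITE_THRESHOLD = 2000


def _chol_with_jitter(K: np.ndarray, sigma2: float, rebuild=None):
    """Cholesky of K with escalating diagonal jitter.

    Starts at ``JITTER_RELATIVE * σ²`` and escalates ×10 at most
    ``MAX_JITTER_ESCALATIONS`` times; raises with a conditioning report if
    every attempt fails.  Large matrices are factorized in place (K is
    rebuilt through ``rebuild`` if an escalation is needed).
    """
    global _CHOLESKY_CALLS
    jitter = JITTER_RELATIVE * sigma2
    n = K.shape[0]
    diag_idx = np.arange(n)
    overwrite = rebuild is not None and n > _OVERWRITE_THRESHOLD
    base_diag = K[diag_idx, diag_idx].copy()
    last_err: Exception | None = None
    for attempt in range(MAX_JITTER_ESCALATIONS + 1):
        K[diag_idx, diag_idx] = base_diag + jitter
        try:
            _CHOLESKY_CALLS += 1
            c, low = cho_factor(K, lower=True, check_finite=False, overwrite_a=overwrite)
            min_pivot = float(np.min(np.diag(c)))
            if attempt:
                logger.debug("cholesky needed jitter %.3e after %d escalations", jitter, attempt)
            return (c, low), jitter, min_pivot
        except np.linalg.LinAlgError as err:  # pragma: no cover - rare path
            last_err = err
            jitter *= 10.0
            if overwrite:
                K = rebuild()
                base_diag = K[diag_idx, diag_idx].copy()
    raise np.linalg.LinAlgError(
        f"Cholesky failed after {MAX_JITTER_ESCALATIONS} jitter escalations "
        f"(final jitter {jitter:.3e}, n={n}): {last_err}"
    )


def _standardized_system(obs_coords, obs_values, spec: KernelSpec):
    """Shared setup: standardize, rescale length scales, factorize."""
    x = obs_coords.coords if isinstance(obs_coords, PointSet) else np.atleast_2d(obs_coords)
    y_std, x_std, params = standardize(obs_values, x)
    spec_std = spec.replace(
        length_scale_r=spec.length_scale_r / params.coord_scale[0],
        length_scale_alpha=spec.length_scale_alpha / params.coord_scale[1],
    )

    def build() -> np.ndarray:
        K = kernel_matrix(x_std, x_std, spec_std)
        idx = np.arange(K.shape[0])
        K[idx, idx] += spec_std.noise_variance
        return K

    factor, jitter, min_pivot = _chol_with_jitter(build(), spec_std.signal_variance, rebuild=build)
    return y_std, x_std, params, spec_std, factor, jitter, min_pivot


def gp_predict(
    obs_coords,
    obs_values,
    target_coords,
    spec: KernelSpec,
    compute_variance: bool = True,
) -> GPPosterior:
    """Exact GP posterior at the target points.

    Observations and targets must be in the same coordinate frame.  Only
    the diagonal of K** enters the variance, which is therefore O(NM)
    after the factorization.  Variance entries that fall slightly negative
    through cancellation are clamped to zero after a tolerance check.
    """
    xt = target_coords.coords if isinstance(target_coords, PointSet) else np.atleast_2d(target_coords)
    if (
        isinstance(obs_coords, PointSet)
        and isinstance(target_coords, PointSet)
        and obs_coords.frame != target_coords.frame
    ):
        raise ValueError("observations and targets must share a coordinate frame")
    y_std, x_std, params, spec_std, factor, jitter, min_pivot = _standardized_system(
        obs_coords, obs_values, spec
    )
    t_std = params.transform_coords(xt)
    alpha = cho_solve(factor, y_std, check_finite=False)
    K_star = kernel_matrix(x_std, t_std, spec_std)  # (N, M)
    mean_std = K_star.T @ alpha
    mean = params.inverse_values(mean_std)
    if not np.all(np.isfinite(mean)):
        raise FloatingPointError("non-finite GP mean; conditioning failure")

    variance = None
    if compute_variance:
        c, low = factor
        v = solve_triangular(c, K_star, lower=low, check_finite=False)
        explained = np.einsum("ij,ij->j", v, v)
        var_std = spec_std.signal_variance - explained
        tol = -1e-8 * spec_std.signal_variance
        if np.any(var_std < tol):
            logger.debug(
                "variance fell below tolerance (min %.3e); clamping", float(var_std.min())
            )
        var_std = np.clip(var_std, 0.0, None)
        variance = var_std * params.value_scale**2

    diagnostics = {
        "jitter": jitter,
        "min_cholesky_pivot": min_pivot,
        "degenerate_values": params.degenerate,
    }
    return GPPosterior(mean=mean, variance=variance, diagnostics=diagnostics)


def log_marginal_likelihood(obs_coords, obs_values, spec: KernelSpec) -> float:
    """Log marginal likelihood of the standardized observations,

        log p(y|X) = −½ yᵀ(K+σn²I)⁻¹y − ½ log|K+σn²I| − (N/2) log 2π,

    with the log-determinant taken from the Cholesky factor.  Implemented
    as a diagnostic; length-scale fitting goes through held-out MSE
    (see :mod:`scangp.selection`) instead.
    """
    y_std, x_std, params, spec_std, factor, jitter, _ = _standardized_system(
        obs_coords, obs_values, spec
    )
    alpha = cho_solve(factor, y_std, check_finite=False)
    c, _low = factor
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    n = y_std.size
    lml = -0.5 * float(y_std @ alpha) - 0.5 * logdet - 0.5 * n * math.log(2.0 * math.pi)
    if not np.isfinite(lml):
        raise FloatingPointError("non-finite log marginal likelihood")
    return lml
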