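"""Reference interpolators: nearest neighbor, bilinear, cubic spline.

All three operate on the beam-native lattice — for diverging beams that is
the polar grid, matching the standard scan-conversion practice of
interpolating in polar coordinates and merely remapping the result for
cartesian display.  They are the comparison points for the GP interpolator
in leave-N-out studies.

Interpolator output is kept unclipped (cubic splines overshoot near edges,
and masking that would bias error metrics); clipping to [0, 1] is applied
only on the display path via :meth:`InterpolationResult.clipped`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .geometry import PointSet, ScanFrame

__all__ = [
    "InterpolationResult",
    "interp_nearest",
    "interp_bilinear",
    "interp_cubic_spline",
]


@dataclass(frozen=True)
class InterpolationResult:
    """Interpolated values at a set of target points.

    ``values`` follows the target-point order (use :meth:`as_image` to
    reshape lattice-ordered targets into an image).  ``variance`` is only
    populated by the GP paths.  ``outside`` flags targets that fell outside
    the observation hull and were clamped to the edge.
    """

    values: np.ndarray
    method: str
    variance: np.ndarray | None = None
    outside: np.ndarray | None = None
    grid_fingerprint: str = ""
    diagnostics: dict = field(default_factory=dict)

    @property
    def overshoot(self) -> bool:
        """True when any raw value escapes [0, 1] (e.g. spline ringing)."""
        return bool(self.values.min() < 0.0 or self.values.max() > 1.0)

    def clipped(self) -> np.ndarray:
        """Display copy of the values, clipped to [0, 1]."""
        return np.clip(self.values, 0.0, 1.0)

    def as_image(self, n_samples: int, n_scanlines: int) -> np.ndarray:
        """Reshape lattice-ordered values (beams outer, samples inner) into
        an (n_samples, n_scanlines) image."""
        return self.values.reshape((n_samples, n_scanlines), order="F")

    def variance_image(self, n_samples: int, n_scanlines: int) -> np.ndarray:
        if self.variance is None:
            raise ValueError(f"method {self.method!r} produces no variance map")
        return self.variance.reshape((n_samples, n_scanlines), order="F")


def _target_coords(targets) -> np.ndarray:
    return targets.coords if isinstance(targets, PointSet) else np.atleast_2d(targets)


def _clamped(coords: np.ndarray, r: np.ndarray, a: np.ndarray):
    """Clamp target coordinates to the observation hull; return the clamped
    coordinates and the outside flag."""
    lo = np.array([r[0], a[0]])
    hi = np.array([r[-1], a[-1]])
    outside = np.any((coords < lo) | (coords > hi), axis=1)
    return np.clip(coords, lo, hi), outside


def _nearest_indices(knots: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Nearest knot index per query, ties resolved to the lower index."""
    j = np.searchsorted(knots, q)
    j = np.clip(j, 1, knots.size - 1)
    left = j - 1
    # strict '<' keeps the lower index on exact ties
    take_right = (knots[j] - q) < (q - knots[left])
    return np.where(take_right, j, left)


def interp_nearest(frame: ScanFrame, targets) -> InterpolationResult:
    """Nearest-neighbor interpolation on the beam-native lattice.

    The nearest observation is resolved per axis; an exact tie goes to the
    lower sample index, then the lower beam index.
    """
    grid = frame.grid
    r, a = grid.radial_coords(), grid.across_coords()
    coords = _target_coords(targets)
    _, outside = _clamped(coords, r, a)
    i = _nearest_indices(r, coords[:, 0])
    j = _nearest_indices(a, coords[:, 1])
    values = frame.intensities[i, j]
    return InterpolationResult(
        values=values,
        method="nearest",
        outside=outside,
        grid_fingerprint=grid.fingerprint(),
    )


def interp_bilinear(frame: ScanFrame, targets) -> InterpolationResult:
    """Separable linear interpolation; out-of-hull targets are clamped to
    the edge and flagged."""
    grid = frame.grid
    r, a = grid.radial_coords(), grid.across_coords()
    coords = _target_coords(targets)
    clamped, outside = _clamped(coords, r, a)
    itp = RegularGridInterpolator((r, a), frame.intensities, method="linear")
    values = itp(clamped)
    return InterpolationResult(
        values=values,
        method="bilinear",
        outside=outside,
        grid_fingerprint=grid.fingerprint(),
    )


def interp_cubic_spline(frame: ScanFrame, targets) -> InterpolationResult:
    """Tensor-product cubic-spline interpolation (not-a-knot boundaries).

    Requires at least 4 samples and 4 beams.  Raw values may overshoot
    [0, 1]; the overshoot is reported, not silently clipped.
    """
    grid = frame.grid
    if grid.n_samples < 4 or grid.n_scanlines < 4:
        raise ValueError("cubic spline needs >= 4 samples and >= 4 beams")
    r, a = grid.radial_coords(), grid.across_coords()
    coords = _target_coords(targets)
    clamped, outside = _clamped(coords, r, a)
    try:
        # the true tensor-product interpolating spline; newer scipy's
        # "cubic" is a faster local approximant that is not node-exact
        itp = RegularGridInterpolator((r, a), frame.intensities, method="cubic_legacy")
    except ValueError:  # older scipy: "cubic" is the tensor spline
        itp = RegularGridInterpolator((r, a), frame.intensities, method="cubic")
    values = itp(clamped)
    return InterpolationResult(
        values=values,
        method="spline",
        outside=outside,
        grid_fingerprint=grid.fingerprint(),
    )
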