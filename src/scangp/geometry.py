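"""Scanline lattice geometry.

Ultrasound probes emit beams that are either parallel (linear arrays) or
diverging from an apex (phased/curvilinear arrays).  In both cases the raw
echo samples live on a regular *beam-native* lattice: axis 0 runs along the
beam (radial/depth direction, spacing ``sample_pitch``), axis 1 runs across
beams (lateral offset for parallel probes, angle in radians for diverging
probes, spacing ``beam_pitch``).  Scan conversion interpolates from this
lattice onto a display raster; for diverging probes the raster pixels map to
non-uniformly spaced points in the beam-native (polar) frame.

Conventions (fixed so every downstream formula is testable):

* coordinate order is ``(along_beam, across_beam)``;
* sample and beam indices are 0-based; sample ``i`` sits at depth
  ``r0 + i * sample_pitch`` (``r0 = 0`` for parallel grids);
* the middle beam is centered: at ``sector_center`` (diverging) or at zero
  lateral offset (parallel);
* point sets are ordered beams-outer / samples-inner, i.e. point
  ``j * n_samples + i`` is sample ``i`` of beam ``j`` — the Fortran-order
  ravel of an ``(n_samples, n_scanlines)`` intensity matrix.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScanGrid",
    "ScanFrame",
    "PointSet",
    "observation_coords",
    "interpolation_coords",
    "polar_to_cartesian",
    "cartesian_to_polar",
]

PARALLEL = "parallel"
DIVERGING = "diverging"


@dataclass(frozen=True)
class ScanGrid:
    """Geometry of a scanline lattice.

    Parameters
    ----------
    geometry:
        ``"parallel"`` or ``"diverging"``.
    n_scanlines, n_samples:
        Beam count and samples per beam (each >= 2).
    sample_pitch:
        Distance between consecutive samples along a beam (> 0).
    beam_pitch:
        Lateral distance between beams (parallel) or angular step in
        radians (diverging), > 0.  For grids with explicit ``beam_coords``
        this is the *nominal* (mean) spacing.
    depth_offset:
        Apex-to-first-sample distance (diverging only).  Defaults to one
        ``sample_pitch`` so the first sample never sits at r = 0, where the
        1/r length-scale rule would be singular.
    sector_center:
        Angle of the middle beam (diverging only), radians.
    beam_coords:
        Optional explicit across-beam positions (ascending tuple, length
        ``n_scanlines``).  Used by decimated grids whose kept beams are not
        uniformly spaced.
    """

    geometry: str
    n_scanlines: int
    n_samples: int
    sample_pitch: float
    beam_pitch: float
    depth_offset: float | None = None
    sector_center: float = 0.0
    beam_coords: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.geometry not in (PARALLEL, DIVERGING):
            raise ValueError(
                f"geometry must be {PARALLEL!r} or {DIVERGING!r}, got {self.geometry!r}"
            )
        if self.n_scanlines < 2 or self.n_samples < 2:
            raise ValueError("need n_scanlines >= 2 and n_samples >= 2")
        if not (self.sample_pitch > 0 and self.beam_pitch > 0):
            raise ValueError("sample_pitch and beam_pitch must be > 0")
        if self.depth_offset is None:
            r0 = self.sample_pitch if self.geometry == DIVERGING else 0.0
            object.__setattr__(self, "depth_offset", float(r0))
        if self.depth_offset < 0:
            raise ValueError("depth_offset must be >= 0")
        if self.beam_coords is not None:
            bc = np.asarray(self.beam_coords, dtype=float)
            if bc.ndim != 1 or bc.size != self.n_scanlines:
                raise ValueError("beam_coords length must equal n_scanlines")
            if not np.all(np.diff(bc) > 0):
                raise ValueError("beam_coords must be strictly increasing")
            object.__setattr__(self, "beam_coords", tuple(float(v) for v in bc))
            span = bc[-1] - bc[0]
        else:
            span = (self.n_scanlines - 1) * self.beam_pitch
        if self.geometry == DIVERGING and not span < math.pi:
            raise ValueError("total sector angle must be < pi radians")

    # -- derived quantities -------------------------------------------------

    @property
    def scan_length(self) -> float:
        """Along-beam extent |r̄| = (n_samples − 1)·Δr (strictly positive)."""
        return (self.n_samples - 1) * self.sample_pitch

    @property
    def mid_depth(self) -> float:
        """Depth of the middle of the scanline, r0 + |r̄|/2."""
        return self.depth_offset + 0.5 * self.scan_length

    def radial_coords(self) -> np.ndarray:
        return self.depth_offset + np.arange(self.n_samples) * self.sample_pitch

    def across_coords(self) -> np.ndarray:
        if self.beam_coords is not None:
            return np.asarray(self.beam_coords, dtype=float)
        offsets = (np.arange(self.n_scanlines) - (self.n_scanlines - 1) / 2.0) * self.beam_pitch
        if self.geometry == DIVERGING:
            return self.sector_center + offsets
        return offsets

    def fingerprint(self) -> str:
        import hashlib

        return hashlib.sha256(repr(dataclasses.astuple(self)).encode()).hexdigest()[:16]


@dataclass(frozen=True)
class PointSet:
    """A set of 2-D points with a coordinate-frame tag.

    ``coords`` is ``(M, 2)`` with columns ``(along_beam, across_beam)`` in
    the ``beam_native`` frame or ``(x_lateral, z_depth)`` in the
    ``cartesian`` frame.  ``outside`` optionally flags points that fall
    outside the probe footprint (they are kept, never dropped).
    """

    coords: np.ndarray
    frame: str = "beam_native"
    outside: np.ndarray | None = None

    def __post_init__(self) -> None:
        coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError(f"coords must be (M, 2), got shape {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coords must be finite")
        if self.frame not in ("beam_native", "cartesian"):
            raise ValueError(f"unknown frame {self.frame!r}")
        object.__setattr__(self, "coords", coords)
        if self.outside is not None:
            out = np.asarray(self.outside, dtype=bool)
            if out.shape != (coords.shape[0],):
                raise ValueError("outside mask must be (M,)")
            object.__setattr__(self, "outside", out)

    def __len__(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class ScanFrame:
    """A scanline intensity frame: ``intensities[i, j]`` is sample ``i`` of
    beam ``j``, normalized to [0, 1]."""

    grid: ScanGrid
    intensities: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        z = np.asarray(self.intensities, dtype=float)
        expected = (self.grid.n_samples, self.grid.n_scanlines)
        if z.shape != expected:
            raise ValueError(f"intensity shape {z.shape} does not match grid {expected}")
        if not np.all(np.isfinite(z)):
            raise ValueError("intensities must be finite")
        if z.min() < 0.0 or z.max() > 1.0:
            raise ValueError("intensities must lie in [0, 1]")
        object.__setattr__(self, "intensities", z)

    def values_flat(self) -> np.ndarray:
        """Intensities in point-set order (beams outer, samples inner)."""
        return self.intensities.ravel(order="F")


# -- coordinate generation --------------------------------------------------


def observation_coords(grid: ScanGrid) -> PointSet:
    """Beam-native coordinates of every observation on the lattice.

    Returns ``n_samples * n_scanlines`` points ordered beams-outer /
    samples-inner (matching ``ScanFrame.values_flat``).
    """
    r = grid.radial_coords()
    a = grid.across_coords()
    coords = np.column_stack(
        [np.tile(r, grid.n_scanlines), np.repeat(a, grid.n_samples)]
    )
    return PointSet(coords, frame="beam_native")


def interpolation_coords(
    grid: ScanGrid,
    target: str = "native_dense",
    density: int = 1,
    pixel_spacing: float | None = None,
) -> PointSet:
    """Coordinates of the desired interpolation points.

    ``native_dense`` refines the beam-native lattice by an integer factor
    per axis (``density=1`` reproduces :func:`observation_coords`); this is
    the frame the leave-N-out protocol scores in.  ``cartesian_raster``
    places pixel centers of a square display raster inside the probe
    footprint and maps them into beam-native coordinates; for diverging
    grids these are non-uniformly spaced and raster points outside the
    sector are flagged via ``PointSet.outside``.
    """
    if target == "native_dense":
        if density < 1 or int(density) != density:
            raise ValueError("density must be a positive integer")
        if grid.beam_coords is not None and density != 1:
            raise ValueError("native_dense refinement requires uniformly spaced beams")
        d = int(density)
        r0 = grid.depth_offset
        r = r0 + np.arange((grid.n_samples - 1) * d + 1) * (grid.sample_pitch / d)
        a_obs = grid.across_coords()
        if d == 1:
            a = a_obs
        else:
            a = a_obs[0] + np.arange((grid.n_scanlines - 1) * d + 1) * (grid.beam_pitch / d)
        coords = np.column_stack([np.tile(r, a.size), np.repeat(a, r.size)])
        return PointSet(coords, frame="beam_native")

    if target == "cartesian_raster":
        spacing = grid.sample_pitch if pixel_spacing is None else float(pixel_spacing)
        if spacing <= 0:
            raise ValueError("pixel_spacing must be > 0")
        r_lo, r_hi = grid.depth_offset, grid.depth_offset + grid.scan_length
        a = grid.across_coords()
        if grid.geometry == PARALLEL:
            xs = np.arange(a[0], a[-1] + 0.5 * spacing, spacing)
            zs = np.arange(r_lo, r_hi + 0.5 * spacing, spacing)
            if xs.size == 0 or zs.size == 0:
                raise ValueError("raster does not intersect the probe footprint")
            coords = np.column_stack([np.tile(zs, xs.size), np.repeat(xs, zs.size)])
            outside = np.zeros(len(coords), dtype=bool)
            return PointSet(coords, frame="beam_native", outside=outside)
        # diverging: bounding box of the sector in cartesian (x, z)
        edge_angles = np.array([a[0], a[-1]]) - grid.sector_center
        arc = np.linspace(a[0], a[-1], 257) - grid.sector_center
        xs_all = np.concatenate([r_hi * np.sin(arc), r_lo * np.sin(edge_angles)])
        zs_all = np.concatenate([r_hi * np.cos(arc), r_lo * np.cos(edge_angles)])
        x_lo, x_hi = xs_all.min(), xs_all.max()
        z_lo, z_hi = zs_all.min(), zs_all.max()
        xs = np.arange(x_lo, x_hi + 0.5 * spacing, spacing)
        zs = np.arange(z_lo, z_hi + 0.5 * spacing, spacing)
        if xs.size == 0 or zs.size == 0:
            raise ValueError("raster does not intersect the probe footprint")
        xx = np.repeat(xs, zs.size)
        zz = np.tile(zs, xs.size)
        cart = PointSet(np.column_stack([xx, zz]), frame="cartesian")
        native = cartesian_to_polar(cart, grid)
        r, alpha = native.coords[:, 0], native.coords[:, 1]
        eps = 1e-12
        outside = (
            (r < r_lo - eps)
            | (r > r_hi + eps)
            | (alpha < a[0] - eps)
            | (alpha > a[-1] + eps)
        )
        if np.all(outside):
            raise ValueError("raster does not intersect the probe footprint")
        return PointSet(native.coords, frame="beam_native", outside=outside)

    raise ValueError(f"unknown target {target!r}")


# -- frame conversion -------------------------------------------------------


def polar_to_cartesian(points: PointSet, grid: ScanGrid) -> PointSet:
    """Map beam-native (r, α) points to cartesian (x, z).

    Axis convention: ``x = r·sin(α − sector_center)`` (lateral),
    ``z = r·cos(α − sector_center)`` (depth away from the apex).  For
    parallel grids the beam-native frame already is cartesian, so the map
    is the identity (only the frame tag changes).
    """
    if points.frame != "beam_native":
        raise ValueError("expected points in the beam_native frame")
    if grid.geometry == PARALLEL:
        # (r, lateral) -> (x=lateral, z=r)
        r, x = points.coords[:, 0], points.coords[:, 1]
        return PointSet(np.column_stack([x, r]), frame="cartesian", outside=points.outside)
    r = points.coords[:, 0]
    ang = points.coords[:, 1] - grid.sector_center
    coords = np.column_stack([r * np.sin(ang), r * np.cos(ang)])
    return PointSet(coords, frame="cartesian", outside=points.outside)


def cartesian_to_polar(points: PointSet, grid: ScanGrid) -> PointSet:
    """Inverse of :func:`polar_to_cartesian`."""
    if points.frame != "cartesian":
        raise ValueError("expected points in the cartesian frame")
    if grid.geometry == PARALLEL:
        x, z = points.coords[:, 0], points.coords[:, 1]
        return PointSet(np.column_stack([z, x]), frame="beam_native", outside=points.outside)
    x, z = points.coords[:, 0], points.coords[:, 1]
    r = np.hypot(x, z)
    alpha = grid.sector_center + np.arctan2(x, z)
    return PointSet(np.column_stack([r, alpha]), frame="beam_native", outside=points.outside)
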