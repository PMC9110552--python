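"""Frame and configuration I/O.

A :class:`~scangp.geometry.ScanFrame` on disk is an intensity matrix (16-bit
PGM or PNG, or a lossless CSV of floats in [0, 1]) plus a JSON *sidecar*
carrying the grid geometry: ``{geometry, n_scanlines, n_samples,
sample_pitch, beam_pitch, depth_offset, sector_center}`` (and
``beam_coords`` for decimated grids).  Readers cross-check the matrix shape
against the sidecar and reject out-of-range intensities with distinct
errors.  Integer containers are rescaled by their bit depth, so a 16-bit
PGM round-trips to within 1/65535.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .geometry import ScanFrame, ScanGrid

__all__ = [
    "read_frame",
    "write_frame",
    "sidecar_path",
    "RunConfig",
]

_GRID_KEYS = (
    "geometry",
    "n_scanlines",
    "n_samples",
    "sample_pitch",
    "beam_pitch",
    "depth_offset",
    "sector_center",
)


def sidecar_path(path) -> Path:
    return Path(path).with_suffix(".json")


def grid_to_dict(grid: ScanGrid) -> dict:
    d = {k: getattr(grid, k) for k in _GRID_KEYS}
    if grid.beam_coords is not None:
        d["beam_coords"] = list(grid.beam_coords)
    return d


def grid_from_dict(d: dict) -> ScanGrid:
    kwargs = {k: d[k] for k in _GRID_KEYS if k in d}
    missing = set(("geometry", "n_scanlines", "n_samples", "sample_pitch", "beam_pitch")) - set(kwargs)
    if missing:
        raise ValueError(f"sidecar missing required keys: {sorted(missing)}")
    if "beam_coords" in d and d["beam_coords"] is not None:
        kwargs["beam_coords"] = tuple(d["beam_coords"])
    return ScanGrid(**kwargs)


def write_frame(path, frame: ScanFrame, sidecar: str | Path | None = None) -> Path:
    """Write the intensity matrix and its JSON geometry sidecar.

    Format by suffix: ``.csv`` stores floats losslessly; ``.pgm`` / ``.png``
    store 16-bit integers scaled to [0, 65535].
    """
    path = Path(path)
    side = Path(sidecar) if sidecar is not None else sidecar_path(path)
    suffix = path.suffix.lower()
    if suffix == ".csv":
        np.savetxt(path, frame.intensities, delimiter=",", fmt="%.17g")
    elif suffix in (".pgm", ".png"):
        scaled = np.round(frame.intensities * 65535.0).astype(np.uint16)
        iio.imwrite(path, scaled)
    else:
        raise ValueError(f"unsupported frame format {suffix!r} (use .csv, .pgm or .png)")
    meta = grid_to_dict(frame.grid)
    meta["provenance"] = frame.provenance
    with open(side, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    return side


def _pgm_maxval(path) -> int:
    """Full-scale (maxval) token from a P2/P5 header."""
    with open(path, "rb") as fh:
        head = fh.read(256)
    tokens = []
    for word in head.split():
        if word.startswith(b"#"):
            continue
        tokens.append(word)
        if len(tokens) == 4:  # magic, width, height, maxval
            return int(tokens[3])
    raise ValueError(f"{path}: malformed PGM header")


def read_frame(path, sidecar: str | Path | None = None) -> ScanFrame:
    """Read a frame and validate it against its sidecar.

    Raises distinct errors for a shape mismatch, an unknown geometry tag
    and out-of-range intensity values.
    """
    path = Path(path)
    side = Path(sidecar) if sidecar is not None else sidecar_path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not side.exists():
        raise FileNotFoundError(f"missing geometry sidecar {side}")
    with open(side) as fh:
        meta = json.load(fh)
    try:
        grid = grid_from_dict(meta)
    except ValueError as err:
        raise ValueError(f"invalid sidecar {side}: {err}") from err

    suffix = path.suffix.lower()
    if suffix == ".csv":
        z = np.atleast_2d(np.loadtxt(path, delimiter=","))
    elif suffix in (".pgm", ".png"):
        raw = np.asarray(iio.imread(path))
        if raw.ndim != 2:
            raise ValueError(f"{path}: expected a single-channel intensity image")
        if suffix == ".pgm":
            # the decoded dtype can be wider than the container (int32 for
            # 16-bit P5), so take the full-scale value from the header
            scale = _pgm_maxval(path)
        elif np.issubdtype(raw.dtype, np.integer):
            scale = np.iinfo(raw.dtype).max
        else:
            scale = 1.0
        z = raw.astype(float) / scale
    else:
        raise ValueError(f"unsupported frame format {suffix!r} (use .csv, .pgm or .png)")

    expected = (grid.n_samples, grid.n_scanlines)
    if z.shape != expected:
        raise ValueError(
            f"shape mismatch: matrix is {z.shape} but sidecar declares {expected}"
        )
    if z.min() < 0.0 or z.max() > 1.0:
        raise ValueError(f"intensities outside [0, 1] in {path}")
    return ScanFrame(grid=grid, intensities=z, provenance=str(meta.get("provenance", "")))


@dataclass(frozen=True)
class RunConfig:
    """One CLI run, serializable to JSON and back losslessly."""

    command: str = ""
    frame_path: str = ""
    output_dir: str = "."
    method: str = "gp"
    methods: tuple[str, ...] = ("nearest", "bilinear", "spline", "gp")
    keep_counts: tuple[int, ...] = (32, 16, 8)
    window_size: int = 15
    kernel: dict | None = None
    n_keep: int = 0
    seed: int = 0
    verbosity: int = 0
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["methods"] = list(self.methods)
        d["keep_counts"] = [int(k) for k in self.keep_counts]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "methods" in d:
            d["methods"] = tuple(d["methods"])
        if "keep_counts" in d:
            d["keep_counts"] = tuple(int(k) for k in d["keep_counts"])
        return cls(**d)

    def fingerprint(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]
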