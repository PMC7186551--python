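"""File formats: TIFF z-stacks, outline text files, detection-settings text
files and cell-cycle scoring CSVs, plus maximal projection.

Conventions
-----------
* A stack is stored z-major: TIFF page ``k`` is focal plane ``k``.
* Coordinates are 0-based pixel indices; voxel ``i`` along an axis of pitch
  ``d`` spans ``[i*d, (i+1)*d)`` nm with center ``(i+0.5)*d``.
* Outline polygons are in lateral pixel units and are implicitly closed
  (last vertex connects back to the first).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Point, Polygon

__all__ = [
    "ImageStack",
    "CellOutline",
    "DetectionSettings",
    "read_stack",
    "write_stack",
    "max_project",
    "read_outlines",
    "write_outlines",
    "count_cells",
    "read_scoring_csv",
    "write_scoring_csv",
    "match_scoring_to_outlines",
    "read_settings",
    "write_settings",
]

CHANNELS = ("FISH", "IF", "DAPI", "DIC")
PHASES = ("G1", "S", "G2", "M")
GROUP_LABELS = PHASES + ("unscored",)


# ---------------------------------------------------------------------------
# ImageStack


@dataclass
class ImageStack:
    """A 3D intensity array (z, y, x) with voxel geometry and channel label."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (200.0, 64.5, 64.5)  # (dz, dy, dx) nm
    channel: str = "FISH"
    position_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError(f"stack must be 3D (z,y,x); got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack contains non-finite values")
        if any(d <= 0 for d in self.voxel_size):
            raise ValueError("voxel_size components must be positive")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}; got {self.channel!r}")
        if self.channel == "DIC" and self.data.shape[0] != 1:
            raise ValueError("DIC stacks must have a single z-plane")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def read_stack(
    path,
    voxel_size: tuple[float, float, float] = (200.0, 64.5, 64.5),
    channel: str = "FISH",
    position_id: str = "",
) -> ImageStack:
    """Read a multi-page grayscale TIFF as an :class:`ImageStack` (z = page order)."""
    arr = tifffile.imread(str(path))
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(
            f"{path}: expected multi-page grayscale TIFF, got array of shape {arr.shape}"
        )
    return ImageStack(arr, voxel_size=voxel_size, channel=channel, position_id=position_id)


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as a multi-page grayscale TIFF, one page per plane."""
    tifffile.imwrite(str(path), stack.data, photometric="minisblack")


def max_project(stack: ImageStack, z_range: tuple[int, int] | None = None) -> np.ndarray:
    """Per-pixel maximum over planes ``z_range=(lo, hi)`` inclusive.

    Mirrors the common practice of projecting only the planes where the cells
    actually sit, so out-of-focus planes (and slide-bottom debris) do not
    contribute.
    """
    nz = stack.data.shape[0]
    if z_range is None:
        z_range = (0, nz - 1)
    lo, hi = int(z_range[0]), int(z_range[1])
    if lo < 0 or hi >= nz or lo > hi:
        raise ValueError(f"z_range {z_range} invalid for stack with {nz} planes")
    return stack.data[lo : hi + 1].max(axis=0)


# ---------------------------------------------------------------------------
# Cell outlines


@dataclass
class CellOutline:
    """A cell outline polygon (pixels), optionally with nucleus and phase label."""

    cell_id: str
    cell_polygon: list[tuple[float, float]]
    nucleus_polygon: list[tuple[float, float]] | None = None
    group: str | None = None
    position_id: str = ""
    nucleus_outside_cell: bool = False  # set by the reader when invariant fails

    def __post_init__(self) -> None:
        if len(self.cell_polygon) < 3:
            raise ValueError(f"cell {self.cell_id}: polygon needs >= 3 vertices")
        if self.nucleus_polygon is not None and len(self.nucleus_polygon) < 3:
            raise ValueError(f"cell {self.cell_id}: nucleus polygon needs >= 3 vertices")
        if self.group is not None and self.group not in GROUP_LABELS:
            raise ValueError(
                f"cell {self.cell_id}: group {self.group!r} not in {GROUP_LABELS}"
            )

    @property
    def cell_shape(self) -> Polygon:
        return Polygon(self.cell_polygon)

    @property
    def nucleus_shape(self) -> Polygon | None:
        return Polygon(self.nucleus_polygon) if self.nucleus_polygon else None


def _fmt_coords(vals: Iterable[float]) -> str:
    return "\t".join(repr(float(v)) for v in vals)


def write_outlines(outlines: Sequence[CellOutline], path) -> None:
    """Write outlines in the block text dialect (see :func:`read_outlines`)."""
    lines: list[str] = ["SMFISHQ-OUTLINES", "VERSION\t1"]
    for o in outlines:
        lines.append(f"CELL\t{o.cell_id}")
        if o.group is not None:
            lines.append(f"GROUP\t{o.group}")
        xs, ys = zip(*o.cell_polygon)
        lines.append("X_POS\t" + _fmt_coords(xs))
        lines.append("Y_POS\t" + _fmt_coords(ys))
        if o.nucleus_polygon is not None:
            lines.append("Nucleus")
            nxs, nys = zip(*o.nucleus_polygon)
            lines.append("X_POS\t" + _fmt_coords(nxs))
            lines.append("Y_POS\t" + _fmt_coords(nys))
        lines.append("END_CELL")
    Path(path).write_text("\n".join(lines) + "\n")


def read_outlines(path, position_id: str | None = None) -> list[CellOutline]:
    """Read a block-structured outline text file.

    Dialect: a ``CELL <id>`` line opens a block; ``X_POS`` / ``Y_POS`` lines
    carry tab-separated coordinates; an optional ``Nucleus`` sub-block has its
    own ``X_POS`` / ``Y_POS``; an optional ``GROUP <label>`` carries the phase.
    Unknown header/key lines are skipped (tolerant reader), so files with
    extra metadata lines parse cleanly.  A nucleus that is not fully inside
    its cell raises a warning and flags the outline rather than failing.
    """
    if position_id is None:
        position_id = Path(path).stem
    text = Path(path).read_text()
    outlines: list[CellOutline] = []

    cur_id: str | None = None
    cur_group: str | None = None
    cell_xy: dict[str, list[float]] = {}
    nuc_xy: dict[str, list[float]] = {}
    in_nucleus = False

    def _parse_coords(line: str, lineno: int) -> list[float]:
        parts = line.split("\t")[1:]
        try:
            return [float(p) for p in parts if p.strip() != ""]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: unparseable coordinate line") from exc

    def _flush(lineno: int) -> None:
        nonlocal cur_id, cur_group, cell_xy, nuc_xy, in_nucleus
        if cur_id is None:
            return
        if "x" not in cell_xy or "y" not in cell_xy:
            raise ValueError(f"{path}:{lineno}: cell {cur_id} missing X_POS/Y_POS")
        if len(cell_xy["x"]) != len(cell_xy["y"]):
            raise ValueError(f"{path}:{lineno}: cell {cur_id} X/Y length mismatch")
        poly = list(zip(cell_xy["x"], cell_xy["y"]))
        nucleus = None
        if nuc_xy:
            if len(nuc_xy.get("x", [])) != len(nuc_xy.get("y", [])):
                raise ValueError(f"{path}:{lineno}: cell {cur_id} nucleus X/Y mismatch")
            nucleus = list(zip(nuc_xy["x"], nuc_xy["y"]))
        o = CellOutline(
            cell_id=cur_id,
            cell_polygon=poly,
            nucleus_polygon=nucleus,
            group=cur_group,
            position_id=position_id,
        )
        if nucleus is not None and not o.cell_shape.buffer(1e-6).covers(o.nucleus_shape):
            warnings.warn(
                f"{path}: cell {cur_id}: nucleus outline not inside cell outline",
                stacklevel=3,
            )
            o.nucleus_outside_cell = True
        outlines.append(o)
        cur_id, cur_group, cell_xy, nuc_xy, in_nucleus = None, None, {}, {}, False

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip()
        if not line.strip():
            continue
        key = line.split("\t")[0].strip()
        if key == "CELL":
            _flush(lineno)
            parts = line.split("\t")
            if len(parts) < 2 or not parts[1].strip():
                raise ValueError(f"{path}:{lineno}: CELL line without an id")
            cur_id = parts[1].strip()
        elif key == "GROUP" and cur_id is not None:
            cur_group = line.split("\t")[1].strip()
        elif key == "Nucleus" and cur_id is not None:
            in_nucleus = True
        elif key == "END_CELL":
            _flush(lineno)
        elif key in ("X_POS", "Y_POS") and cur_id is not None:
            axis = "x" if key == "X_POS" else "y"
            target = nuc_xy if in_nucleus else cell_xy
            target[axis] = _parse_coords(line, lineno)
        else:
            continue  # tolerant: skip unknown header/key lines
    _flush(len(text.splitlines()) + 1)
    return outlines


def count_cells(paths: Iterable) -> int:
    """Total number of outlined cells across several outline files."""
    return sum(len(read_outlines(p)) for p in paths)


# ---------------------------------------------------------------------------
# Cell-cycle scoring CSV


def read_scoring_csv(path) -> pd.DataFrame:
    """Read a manual cell-cycle scoring table (position_id, x, y, group)."""
    df = pd.read_csv(path)
    required = {"position_id", "x", "y", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: scoring CSV missing column(s) {sorted(missing)}")
    bad = sorted(set(df["group"].astype(str)) - set(GROUP_LABELS))
    if bad:
        raise ValueError(
            f"{path}: unknown group label(s) {bad}; allowed: {list(GROUP_LABELS)}"
        )
    return df


def write_scoring_csv(records: pd.DataFrame | list[dict], path) -> None:
    df = pd.DataFrame(records)
    df.to_csv(path, index=False)


def match_scoring_to_outlines(
    scoring: pd.DataFrame, outlines: Sequence[CellOutline]
) -> tuple[dict[str, str], list[dict]]:
    """Join scoring points to outlines by point-in-polygon.

    Returns ``(cell_id -> group, unmatched_rows)``.  A point inside several
    polygons goes to the smallest one; a point in none is reported unmatched.
    """
    shapes = [(o, o.cell_shape) for o in outlines]
    assigned: dict[str, str] = {}
    unmatched: list[dict] = []
    for row in scoring.itertuples(index=False):
        pt = Point(float(row.x), float(row.y))
        hits = [(o, s) for o, s in shapes if s.covers(pt)]
        if not hits:
            unmatched.append(row._asdict())
            continue
        best = min(hits, key=lambda t: t[1].area)[0]
        assigned[best.cell_id] = str(row.group)
    return assigned, unmatched


# ---------------------------------------------------------------------------
# Detection settings


@dataclass
class DetectionSettings:
    """Detection parameters: bandpass kernel widths, pre-detection threshold,
    fit window, acceptance bounds and the transcription-site threshold factor.

    ``predetect_threshold=None`` means "derive from the filtered image"
    (robust median + k*MAD); a settings *file* must always state a value, as
    the threshold is normally tuned interactively on a reference cell.
    """

    sigma_small_xy: float = 1.0  # px
    sigma_large_xy: float = 5.0  # px
    sigma_small_z: float = 0.5  # planes
    sigma_large_z: float = 2.5  # planes
    predetect_threshold: float | None = None  # ADU on the filtered image
    min_separation: int = 3  # px
    fit_window: tuple[int, int, int] = (11, 15, 15)  # (wz, wy, wx) voxels, odd
    sigma_xy_bounds: tuple[float, float] = (50.0, 400.0)  # nm, fit bounds
    sigma_z_bounds: tuple[float, float] = (150.0, 1000.0)  # nm
    accept_sigma_xy: tuple[float, float] = (50.0, 400.0)  # nm
    accept_sigma_z: tuple[float, float] = (150.0, 1000.0)  # nm
    accept_amplitude: tuple[float, float] = (0.0, float("inf"))  # ADU
    accept_Q: tuple[float, float] = (0.0, float("inf"))  # ADU*voxel
    ts_factor: float = 1.5
    max_ts_per_cell: int = 1
    voxel_size: tuple[float, float, float] = (200.0, 64.5, 64.5)  # (dz,dy,dx) nm
    extra: dict = field(default_factory=dict)  # unknown keys, preserved verbatim

    def __post_init__(self) -> None:
        for w in self.fit_window:
            if w % 2 != 1:
                raise ValueError(f"fit_window must be odd-sized; got {self.fit_window}")
        if not self.sigma_small_xy < self.sigma_large_xy:
            raise ValueError("sigma_small_xy must be < sigma_large_xy")
        if not self.sigma_small_z < self.sigma_large_z:
            raise ValueError("sigma_small_z must be < sigma_large_z")
        for name in (
            "sigma_xy_bounds",
            "sigma_z_bounds",
            "accept_sigma_xy",
            "accept_sigma_z",
            "accept_amplitude",
            "accept_Q",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: min {lo} > max {hi}")


_MANDATORY_KEYS = (
    "sigma_small_xy",
    "sigma_large_xy",
    "sigma_small_z",
    "sigma_large_z",
    "predetect_threshold",
    "min_separation",
    "fit_window",
    "ts_factor",
    "voxel_size",
)

_TUPLE_KEYS = {
    "fit_window": int,
    "voxel_size": float,
    "sigma_xy_bounds": float,
    "sigma_z_bounds": float,
    "accept_sigma_xy": float,
    "accept_sigma_z": float,
    "accept_amplitude": float,
    "accept_Q": float,
}
_INT_KEYS = {"min_separation", "max_ts_per_cell"}
_FLOAT_KEYS = {
    "sigma_small_xy",
    "sigma_large_xy",
    "sigma_small_z",
    "sigma_large_z",
    "predetect_threshold",
    "ts_factor",
}


def write_settings(settings: DetectionSettings, path) -> None:
    """Write settings as key=value text (tuples comma-joined)."""
    lines = []
    for key in (*_FLOAT_KEYS, *_INT_KEYS, *_TUPLE_KEYS):
        val = getattr(settings, key)
        if val is None:
            continue
        if isinstance(val, tuple):
            lines.append(f"{key}=" + ",".join(repr(float(v)) if _TUPLE_KEYS[key] is float else str(int(v)) for v in val))
        elif key in _INT_KEYS:
            lines.append(f"{key}={int(val)}")
        else:
            lines.append(f"{key}={val!r}")
    for key, val in settings.extra.items():
        lines.append(f"{key}={val}")
    Path(path).write_text("\n".join(sorted(lines)) + "\n")


def read_settings(path) -> DetectionSettings:
    """Read key=value settings text; unknown keys are preserved in ``extra``."""
    kv: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
        key, _, val = line.partition("=")
        kv[key.strip()] = val.strip()
    for key in _MANDATORY_KEYS:
        if key not in kv:
            raise ValueError(f"{path}: missing mandatory key {key!r}")
    kwargs: dict = {}
    extra: dict = {}
    for key, val in kv.items():
        if key in _TUPLE_KEYS:
            conv = _TUPLE_KEYS[key]
            kwargs[key] = tuple(conv(float(v)) for v in val.split(","))
        elif key in _INT_KEYS:
            kwargs[key] = int(val)
        elif key in _FLOAT_KEYS:
            kwargs[key] = float(val)
        else:
            extra[key] = val
    return DetectionSettings(**kwargs, extra=extra)
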