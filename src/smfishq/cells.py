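"""Per-cell quantification: spot-to-cell assignment, immunofluorescence (IF)
integrated intensity, morphology features and cell-cycle scoring.

Cell-cycle logic for budding yeast probed with anti-tubulin IF: through the
cycle the tubulin signal rises (spindle pole body duplication in S, spindle
assembly and elongation in G2/M), buds appear at S and grow through G2, and
anaphase stretches the spindle across mother and daughter.  The scorer
encodes those cues as an ordered decision list over measured features:

    M   if spindle_span > span_M
    G2  elif bud_ratio > r_G2
    S   elif bud_ratio > r_S
    G1  elif if_integrated < tau_G1  (a cohort percentile)
    unscored otherwise
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from shapely.geometry import Point
from skimage.draw import polygon2mask

from .io import ImageStack, CellOutline, max_project
from .detect import SpotFit, SpotTable
from .ts import TSRecord

__all__ = [
    "CellRecord",
    "ScoringThresholds",
    "assign_spots",
    "if_integrated_intensity",
    "measure_bud_ratio",
    "measure_spindle",
    "score_cell_cycle",
    "score_cohort",
    "build_cell_records",
]


@dataclass
class CellRecord:
    cell_id: str
    phase: str = "unscored"
    n_mature: int = 0
    n_nascent: int = 0
    if_integrated: float = 0.0
    bud_ratio: float = 0.0
    spindle_span: float = 0.0  # nm
    position_id: str = ""

    @property
    def expressing(self) -> bool:
        return self.n_mature + self.n_nascent >= 1


@dataclass(frozen=True)
class ScoringThresholds:
    r_S: float = 0.05  # bud/mother area ratio above which a bud "exists"
    r_G2: float = 0.35  # large-bud boundary
    span_M: float = 2000.0  # nm; anaphase spindles exceed this
    tau_G1_percentile: float = 40.0  # cohort IF percentile for the G1 cut


# ---------------------------------------------------------------------------
# Spot assignment


def assign_spots(
    table: SpotTable, outlines: Sequence[CellOutline]
) -> tuple[dict[str, list[SpotFit]], list[SpotFit]]:
    """Assign accepted spots to cells by lateral point-in-polygon.

    On-edge points count as inside; a spot inside several (overlapping)
    polygons goes to the smallest; spots in no polygon land in the
    ``unassigned`` bucket.  Returns ``(cell_id -> spots, unassigned)``.
    """
    dz, dyv, dxv = table.settings.voxel_size
    shapes = [(o.cell_id, o.cell_shape) for o in outlines]
    assigned: dict[str, list[SpotFit]] = {o.cell_id: [] for o in outlines}
    unassigned: list[SpotFit] = []
    for s in table.accepted:
        pt = Point(s.x / dxv - 0.5, s.y / dyv - 0.5)
        hits = [(cid, shp) for cid, shp in shapes if shp.covers(pt)]
        if not hits:
            unassigned.append(s)
            continue
        cid = min(hits, key=lambda t: t[1].area)[0]
        assigned[cid].append(s)
    return assigned, unassigned


# ---------------------------------------------------------------------------
# IF quantification


def _polygon_mask(outline: CellOutline, shape) -> np.ndarray:
    # polygon2mask expects (row, col) = (y, x) vertex order
    verts = np.array([(y, x) for x, y in outline.cell_polygon])
    return polygon2mask(shape, verts)


def if_integrated_intensity(
    if_stack: ImageStack,
    outline: CellOutline,
    z_range: tuple[int, int] | None = None,
    exclude_bottom: int = 3,
) -> float:
    """Integrated IF signal inside the cell outline.

    The stack is maximum-projected over ``z_range`` (default: everything
    above the lowest ``exclude_bottom`` planes, so slide-bottom debris never
    enters the projection), the whole-image median is subtracted as
    background, and the result is summed over pixels inside the cell
    polygon.
    """
    nz = if_stack.data.shape[0]
    if z_range is None:
        z_range = (exclude_bottom, nz - 1)
    if z_range[0] > z_range[1]:
        raise ValueError("empty z_range after bottom exclusion")
    proj = max_project(if_stack, z_range)
    bg = float(np.median(proj))
    mask = _polygon_mask(outline, proj.shape)
    return float((proj[mask] - bg).sum())


# ---------------------------------------------------------------------------
# Morphology features


def measure_bud_ratio(outline: CellOutline) -> float:
    """Bud-to-mother area ratio from the cell polygon alone.

    The polygon is rasterized and eroded with growing discs until it splits
    into two components (the neck pinches off first); every original pixel is
    then assigned to the nearest fragment and the ratio of the smaller to the
    larger area is returned.  A round, unbudded cell never splits: ratio 0.
    """
    xs = [v[0] for v in outline.cell_polygon]
    ys = [v[1] for v in outline.cell_polygon]
    x0, y0 = int(np.floor(min(xs))) - 2, int(np.floor(min(ys))) - 2
    w = int(np.ceil(max(xs))) - x0 + 3
    h = int(np.ceil(max(ys))) - y0 + 3
    verts = np.array([(y - y0, x - x0) for x, y in outline.cell_polygon])
    mask = polygon2mask((h, w), verts)
    if mask.sum() < 9:
        return 0.0

    dist = ndimage.distance_transform_edt(mask)
    max_r = int(dist.max())
    for r in range(2, max_r):
        eroded = dist > r
        lab, n = ndimage.label(eroded)
        if n >= 2:
            sizes = ndimage.sum(eroded, lab, index=range(1, n + 1))
            order = np.argsort(sizes)[::-1][:2]
            seeds = np.zeros_like(lab)
            seeds[lab == order[0] + 1] = 1
            seeds[lab == order[1] + 1] = 2
            # nearest-seed assignment of the full mask
            _, (iy, ix) = ndimage.distance_transform_edt(
                seeds == 0, return_indices=True
            )
            full = seeds[iy, ix]
            full[~mask] = 0
            a1 = float((full == 1).sum())
            a2 = float((full == 2).sum())
            if min(a1, a2) < 9:  # spurious sliver, keep eroding
                continue
            return min(a1, a2) / max(a1, a2)
    return 0.0


def measure_spindle(
    if_stack: ImageStack,
    outline: CellOutline,
    z_range: tuple[int, int] | None = None,
    exclude_bottom: int = 3,
    rel_threshold: float = 0.3,
) -> dict:
    """Spindle geometry from the IF projection inside one cell.

    Pixels brighter than ``background + rel_threshold * (peak - background)``
    within the cell mask are "spindle"; the maximal pairwise distance among
    them (in nm) is the spindle span, and the number of connected components
    the focus count.
    """
    nz = if_stack.data.shape[0]
    if z_range is None:
        z_range = (exclude_bottom, nz - 1)
    proj = max_project(if_stack, z_range)
    bg = float(np.median(proj))
    mask = _polygon_mask(outline, proj.shape)
    vals = proj[mask]
    if vals.size == 0:
        return {"spindle_span": 0.0, "n_foci": 0}
    peak = float(vals.max())
    thr = bg + rel_threshold * (peak - bg)
    bright = mask & (proj > thr)
    if not bright.any():
        return {"spindle_span": 0.0, "n_foci": 0}
    _, n_foci = ndimage.label(bright)
    yy, xx = np.nonzero(bright)
    dyv, dxv = if_stack.voxel_size[1], if_stack.voxel_size[2]
    pts = np.column_stack([xx * dxv, yy * dyv])
    # convex-hull-free max pairwise distance; bright sets are small
    if len(pts) > 400:
        sel = np.linspace(0, len(pts) - 1, 400).astype(int)
        pts = pts[sel]
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return {"spindle_span": float(np.sqrt(d2.max())), "n_foci": int(n_foci)}


# ---------------------------------------------------------------------------
# Scoring


def score_cell_cycle(
    features: dict, tau_G1: float, thresholds: ScoringThresholds = ScoringThresholds()
) -> str:
    """Ordered decision list over one cell's features (see module docstring).
    Missing features yield ``unscored``."""
    try:
        span = features["spindle_span"]
        bud = features["bud_ratio"]
        if_int = features["if_integrated"]
    except KeyError:
        return "unscored"
    if span is None or bud is None or if_int is None:
        return "unscored"
    if span > thresholds.span_M:
        return "M"
    if bud > thresholds.r_G2:
        return "G2"
    if bud > thresholds.r_S:
        return "S"
    if if_int < tau_G1:
        return "G1"
    return "unscored"


def score_cohort(
    features_per_cell: dict[str, dict], thresholds: ScoringThresholds = ScoringThresholds()
) -> dict[str, str]:
    """Score every cell; the G1 intensity cut tau_G1 is the cohort
    ``tau_G1_percentile`` of IF integrated intensity."""
    if_vals = [f["if_integrated"] for f in features_per_cell.values()
               if f.get("if_integrated") is not None]
    tau = float(np.percentile(if_vals, thresholds.tau_G1_percentile)) if if_vals else 0.0
    return {cid: score_cell_cycle(f, tau, thresholds) for cid, f in features_per_cell.items()}


# ---------------------------------------------------------------------------
# Mature-count estimation


def _count_mature(
    table: SpotTable,
    ts_records: Sequence[TSRecord],
    outlines: Sequence[CellOutline],
    Q_ref: float | None,
) -> dict[str, int]:
    """Per-cell mature-mRNA counts from converged cytoplasmic fits.

    Accepted single-molecule spots count one each.  Without ``Q_ref`` that is
    the whole story.  With ``Q_ref``, converged spots are grouped into
    proximity clusters (within twice ``min_separation``); a cluster that
    contains an over-bright fit — optically merged molecules that a
    single-spot model cannot split — is counted as ``round(total Q / Q_ref)``
    so that a split pair is not double-counted as a multiplet plus its
    leftover fragment.
    """
    dzv, dyv, dxv = table.settings.voxel_size
    ts_centers = {t.center for t in ts_records}
    shapes = [(o.cell_id, o.cell_shape) for o in outlines]

    def _cell_of(s: SpotFit) -> str | None:
        pt = Point(s.x / dxv - 0.5, s.y / dyv - 0.5)
        hits = [(cid, shp) for cid, shp in shapes if shp.covers(pt)]
        return min(hits, key=lambda t: t[1].area)[0] if hits else None

    counts: dict[str, int] = {o.cell_id: 0 for o in outlines}
    by_cell: dict[str, list[SpotFit]] = {o.cell_id: [] for o in outlines}
    for s in table.spots:
        if not s.converged or s.center in ts_centers:
            continue
        if s.reject_reason not in (None, "Q_high", "Q_low", "amplitude_high"):
            continue
        cid = _cell_of(s)
        if cid is not None:
            by_cell[cid].append(s)

    if Q_ref is None or Q_ref <= 0:
        return {cid: sum(1 for s in sp if s.accepted) for cid, sp in by_cell.items()}

    link_r = 2.0 * float(table.settings.min_separation)
    for cid, spots in by_cell.items():
        if not spots:
            continue
        pts = np.array([[s.z / dzv, s.y / dyv, s.x / dxv] for s in spots])
        parent = list(range(len(spots)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        tree = cKDTree(pts)
        for i, j in tree.query_pairs(link_r):
            parent[find(i)] = find(j)
        comps: dict[int, list[SpotFit]] = {}
        for i, s in enumerate(spots):
            comps.setdefault(find(i), []).append(s)
        n = 0
        for comp in comps.values():
            if any(s.reject_reason in ("Q_high", "amplitude_high") for s in comp):
                n += max(1, round(sum(s.Q for s in comp) / Q_ref))
            else:
                n += sum(1 for s in comp if s.accepted)
        counts[cid] = n
    return counts


# ---------------------------------------------------------------------------
# Record assembly


def build_cell_records(
    table: SpotTable,
    ts_records: Sequence[TSRecord],
    outlines: Sequence[CellOutline],
    if_stack: ImageStack | None = None,
    thresholds: ScoringThresholds = ScoringThresholds(),
    manual_groups: dict[str, str] | None = None,
    exclude_bottom: int = 3,
    Q_ref: float | None = None,
) -> tuple[list[CellRecord], list[SpotFit]]:
    """Assemble per-cell records: assign spots, subtract TS spots from the
    mature count, quantify IF and morphology, and score the phase (manual
    scoring overrides the automated decision list when provided).

    When ``Q_ref`` is given, cytoplasmic spots rejected only for being too
    bright (optically merged molecules that single-spot fitting cannot
    split) contribute ``round(Q / Q_ref)`` to the mature count — the same
    intensity-ratio logic used for transcription sites.
    Returns ``(records, unassigned_spots)``."""
    assigned, unassigned = assign_spots(table, outlines)
    mature_by_cell = _count_mature(table, ts_records, outlines, Q_ref)
    ts_by_cell: dict[str, list[TSRecord]] = {}
    for t in ts_records:
        ts_by_cell.setdefault(t.cell_id, []).append(t)

    features: dict[str, dict] = {}
    for o in outlines:
        f: dict = {"bud_ratio": measure_bud_ratio(o)}
        if if_stack is not None:
            f["if_integrated"] = if_integrated_intensity(
                if_stack, o, exclude_bottom=exclude_bottom
            )
            f.update(measure_spindle(if_stack, o, exclude_bottom=exclude_bottom))
        else:
            f["if_integrated"] = None
            f["spindle_span"] = None
        features[o.cell_id] = f

    phases = score_cohort(features, thresholds) if if_stack is not None else {}
    records: list[CellRecord] = []
    for o in outlines:
        cell_ts = ts_by_cell.get(o.cell_id, [])
        f = features[o.cell_id]
        phase = phases.get(o.cell_id, "unscored")
        if manual_groups and o.cell_id in manual_groups:
            phase = manual_groups[o.cell_id]
        elif o.group is not None and manual_groups is None and if_stack is None:
            phase = o.group
        records.append(
            CellRecord(
                cell_id=o.cell_id,
                phase=phase,
                n_mature=mature_by_cell.get(o.cell_id, 0),
                n_nascent=sum(t.nascent_n for t in cell_ts),
                if_integrated=f.get("if_integrated") or 0.0,
                bud_ratio=f.get("bud_ratio") or 0.0,
                spindle_span=f.get("spindle_span") or 0.0,
                position_id=o.position_id,
            )
        )
    return records, unassigned
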