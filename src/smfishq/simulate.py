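"""Synthetic smFISH-IF scenes for budding yeast.

The generator builds a ground-truth *scene* — cell and nucleus polygons, a
cell-cycle phase per cell, cytoplasmic mRNA positions with per-molecule
brightness, an optional intra-nuclear transcription site (TS) carrying
several nascent transcripts, and a phase-dependent tubulin/spindle structure
— and renders it into noisy multichannel 3D stacks with the acquisition
geometry of a widefield yeast experiment (41 planes, 200 nm z-pitch,
64.5 nm lateral pixels).

Brightness model: each mRNA is tiled by ``n_probes`` singly-labelled oligos,
each bound independently with probability ``p_bind`` and contributing
``q_probe`` ADU of integrated signal, so the integrated spot intensity is
``q_probe * Binomial(n_probes, p_bind)``.  With 48 probes at p=0.8 this
reproduces the narrow single-molecule intensity histogram characteristic of
good smFISH data.  A TS with ``n`` nascent transcripts is rendered as ``n``
co-located molecule equivalents.

The point-spread function is a tri-axial Gaussian integrated over each voxel
(error-function integral per axis), so total rendered mass equals the
ground-truth integrated intensity exactly up to window truncation — the
bookkeeping the photon-conservation tests rely on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import erf
from shapely.geometry import Point, Polygon
from shapely.ops import unary_union
import shapely

from .io import ImageStack, CellOutline, PHASES
from .probes import ProbeSet, make_probe_set, CLN2_QUASAR570_PROBES

__all__ = [
    "ScenarioParams",
    "CellTruth",
    "Scene",
    "sample_scene",
    "make_sparse_scene",
    "render_stack",
    "inject_z_drift",
    "add_bottom_debris",
    "scene_outlines",
    "scene_truth_table",
    "zero_truncated_poisson_rate",
    "zero_truncated_poisson_mean",
]


# ---------------------------------------------------------------------------
# Parameters


@dataclass(frozen=True)
class ScenarioParams:
    """Study-condition parameters for a synthetic field of cells.

    Defaults emulate a non-synchronized exponentially growing haploid
    culture probed for a G1-restricted cyclin transcript: an unbudded (G1)
    fraction of ~35%, expression confined to G1, a mean of 10.1 mature
    mRNAs per expressing cell and 3.6 nascent RNAs per active TS.
    """

    n_cells: int = 12
    field_shape: tuple[int, int, int] = (41, 416, 416)  # (nz, ny, nx) voxels
    voxel_size: tuple[float, float, float] = (200.0, 64.5, 64.5)  # (dz,dy,dx) nm
    phase_fractions: dict = field(
        default_factory=lambda: {"G1": 0.35, "S": 0.25, "G2": 0.25, "M": 0.15}
    )
    expressing_fraction_G1: float = 0.8
    ts_fraction: float = 0.22  # active-TS fraction among expressing cells
    mature_mean: float = 10.1  # negative-binomial mean, mRNAs/expressing cell
    mature_dispersion: float = 3.0  # NB size parameter r (var = mu + mu^2/r)
    nascent_mean: float = 3.6  # zero-truncated-Poisson mean, RNAs/TS
    n_probes: int = 48
    p_bind: float = 0.8  # per-probe hybridization probability
    q_probe: float = 180.0  # integrated ADU per bound probe
    psf_sigma: tuple[float, float] = (130.0, 350.0)  # (sigma_xy, sigma_z) nm
    noise: dict = field(
        default_factory=lambda: {
            "gain": 2.0,  # ADU per photon
            "offset": 100.0,  # camera baseline, ADU
            "read_sd": 2.0,  # read noise, ADU
            "bg_fluor": 20.0,  # cellular autofluorescence, ADU/voxel
        }
    )
    cell_radius_nm: float = 2000.0  # mother-lobe radius
    if_photons: dict = field(
        default_factory=lambda: {"G1": 6.0e4, "S": 1.3e5, "G2": 1.7e5, "M": 2.2e5}
    )
    dapi_photons: float = 30000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.phase_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("phase_fractions must sum to 1")
        if set(self.phase_fractions) != set(PHASES):
            raise ValueError(f"phase_fractions must cover {PHASES}")
        if any(s <= 0 for s in self.field_shape):
            raise ValueError("field_shape must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        for name in ("mature_mean", "mature_dispersion", "nascent_mean", "q_probe"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 <= self.p_bind <= 1.0):
            raise ValueError("p_bind must be a probability")

    @property
    def mean_single_Q(self) -> float:
        """Expected integrated intensity of one fully-sampled mRNA (ADU*voxel)."""
        return self.q_probe * self.n_probes * self.p_bind


# ---------------------------------------------------------------------------
# Scene containers


@dataclass
class CellTruth:
    cell_id: str
    phase: str
    center_nm: tuple[float, float]
    cell_polygon: list[tuple[float, float]]  # (x, y) nm
    nucleus_polygon: list[tuple[float, float]]
    mrnas: np.ndarray  # (n, 4): x, y, z [nm], Q_true [ADU*voxel]
    ts: dict | None = None  # {x, y, z, nascent_n, Q_true}
    spindle: list = field(default_factory=list)  # IF primitives
    bud_ratio_true: float = 0.0
    spindle_span_true: float = 0.0

    @property
    def expressing(self) -> bool:
        return len(self.mrnas) > 0 or self.ts is not None


@dataclass
class Scene:
    cells: list[CellTruth]
    params: ScenarioParams
    position_id: str = "pos_00"

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def all_mrnas(self) -> np.ndarray:
        """All cytoplasmic molecules, (n, 4) array of x, y, z, Q_true."""
        parts = [c.mrnas for c in self.cells if len(c.mrnas)]
        return np.vstack(parts) if parts else np.empty((0, 4))


# ---------------------------------------------------------------------------
# Count laws


def zero_truncated_poisson_rate(mean: float) -> float:
    """Poisson rate lambda such that the zero-truncated mean lam/(1-e^-lam)
    equals ``mean`` (mean must be > 1)."""
    if mean <= 1.0:
        raise ValueError("zero-truncated Poisson mean must exceed 1")
    f = lambda lam: lam / (1.0 - math.exp(-lam)) - mean
    return brentq(f, 1e-9, mean)


def zero_truncated_poisson_mean(lam: float) -> float:
    return lam / (1.0 - math.exp(-lam))


def _sample_ztp(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Zero-truncated Poisson draws by resampling zeros."""
    out = rng.poisson(lam, size=size)
    while True:
        zero = out == 0
        if not zero.any():
            return out
        out[zero] = rng.poisson(lam, size=int(zero.sum()))


def _sample_nb(rng: np.random.Generator, mean: float, dispersion: float, size: int):
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


# ---------------------------------------------------------------------------
# Geometry helpers


def _round_polygon(rng, cx, cy, radius, n_pts=48, wobble=0.06):
    """Slightly irregular convex-ish blob standing in for an unbudded cell."""
    theta = np.linspace(0, 2 * np.pi, n_pts, endpoint=False)
    k1, k2 = rng.integers(2, 5, size=2)
    ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
    r = radius * (1 + wobble * np.sin(k1 * theta + ph1) + 0.5 * wobble * np.sin(k2 * theta + ph2))
    return list(zip(cx + r * np.cos(theta), cy + r * np.sin(theta)))


def _budded_polygon(rng, cx, cy, r_mother, area_ratio):
    """Two-lobe (mother + bud) outline as the union of two discs."""
    r_bud = r_mother * math.sqrt(area_ratio)
    theta = rng.uniform(0, 2 * np.pi)
    d = 0.97 * (r_mother + r_bud)
    bx, by = cx + d * math.cos(theta), cy + d * math.sin(theta)
    mother = Point(cx, cy).buffer(r_mother, quad_segs=24)
    bud = Point(bx, by).buffer(r_bud, quad_segs=24)
    poly = unary_union([mother, bud])
    coords = list(poly.exterior.coords)[:-1]
    return coords, (bx, by), r_bud


_BUD_RATIO = {"S": (0.10, 0.25), "G2": (0.42, 0.60), "M": (0.60, 0.80)}


def _spindle_primitives(rng, phase, cx, cy, z_mid, nuc_r, bud_xy, photons):
    """Tubulin/spindle IF structure per phase: G1 one focus (single spindle
    pole body); S two close foci; G2 a short bar into the bud; M an extended
    anaphase spindle."""
    prims = []
    if phase == "G1":
        prims.append({"kind": "focus", "x": cx, "y": cy, "z": z_mid, "photons": photons})
        span = 0.0
    elif phase == "S":
        sep = rng.uniform(250.0, 400.0)
        ang = rng.uniform(0, 2 * np.pi)
        dx, dy = 0.5 * sep * math.cos(ang), 0.5 * sep * math.sin(ang)
        for s in (-1, 1):
            prims.append(
                {"kind": "focus", "x": cx + s * dx, "y": cy + s * dy, "z": z_mid,
                 "photons": photons / 2}
            )
        span = sep
    else:
        span = rng.uniform(900.0, 1500.0) if phase == "G2" else rng.uniform(2600.0, 3800.0)
        if bud_xy is not None:
            ang = math.atan2(bud_xy[1] - cy, bud_xy[0] - cx)
        else:
            ang = rng.uniform(0, 2 * np.pi)
        x2, y2 = cx + span * math.cos(ang), cy + span * math.sin(ang)
        prims.append(
            {"kind": "bar", "x": cx, "y": cy, "x2": x2, "y2": y2, "z": z_mid,
             "photons": photons}
        )
    return prims, span


def _uniform_in_polygon(rng, poly: Polygon, n: int, max_tries: int = 200) -> np.ndarray:
    """Uniform points inside a polygon by rejection from its bounding box."""
    if n == 0:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = poly.bounds
    out = np.empty((n, 2))
    got = 0
    for _ in range(max_tries):
        m = max(4 * (n - got), 16)
        xs = rng.uniform(minx, maxx, size=m)
        ys = rng.uniform(miny, maxy, size=m)
        inside = shapely.contains_xy(poly, xs, ys)
        take = min(n - got, int(inside.sum()))
        out[got : got + take] = np.column_stack([xs[inside], ys[inside]])[:take]
        got += take
        if got == n:
            return out
    raise RuntimeError("failed to sample points inside polygon")


# ---------------------------------------------------------------------------
# Scene sampling


def sample_scene(params: ScenarioParams, position_id: str = "pos_00") -> Scene:
    """Draw a ground-truth scene: cells on a jittered grid, phases from
    ``phase_fractions``, expression confined to G1, counts from the
    negative-binomial / zero-truncated-Poisson laws.  Deterministic given
    ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    nz, ny, nx = params.field_shape
    dz, dy, dx = params.voxel_size
    r_m = params.cell_radius_nm

    # grid packing: one cell per node; collision-checked placement with
    # bounded retries (budded shapes can reach well beyond the mother radius)
    step = 3.2 * r_m
    margin = 1.4 * r_m
    xs = np.arange(margin, nx * dx - margin + 1e-9, step)
    ys = np.arange(margin, ny * dy - margin + 1e-9, step)
    capacity = len(xs) * len(ys)
    if params.n_cells > capacity:
        raise ValueError(
            f"cannot pack {params.n_cells} cells into field "
            f"({capacity} grid sites); enlarge field_shape"
        )
    nodes = [(x, y) for y in ys for x in xs]
    order = rng.permutation(len(nodes))[: params.n_cells]

    phases = list(params.phase_fractions)
    probs = np.array([params.phase_fractions[p] for p in phases])
    lam_ts = zero_truncated_poisson_rate(params.nascent_mean) if params.nascent_mean > 1 else None
    z_mid_field = 0.5 * nz * dz
    field_box = Polygon(
        [(0.0, 0.0), (nx * dx, 0.0), (nx * dx, ny * dy), (0.0, ny * dy)]
    )

    cells: list[CellTruth] = []
    placed: list[Polygon] = []
    for i, node in enumerate(order):
        cx0, cy0 = nodes[node]
        phase = phases[rng.choice(len(phases), p=probs)]
        radius = r_m * rng.uniform(0.9, 1.1)
        for attempt in range(80):
            cx = cx0 + rng.uniform(-0.15, 0.15) * r_m
            cy = cy0 + rng.uniform(-0.15, 0.15) * r_m
            bud_xy = None
            bud_ratio = 0.0
            if phase == "G1":
                poly_xy = _round_polygon(rng, cx, cy, radius)
            else:
                lo, hi = _BUD_RATIO[phase]
                bud_ratio = rng.uniform(lo, hi)
                poly_xy, bud_xy, _ = _budded_polygon(rng, cx, cy, radius, bud_ratio)
            cell_poly = Polygon(poly_xy)
            if field_box.covers(cell_poly) and not any(
                cell_poly.intersects(p) for p in placed
            ):
                break
            radius *= 0.98  # shrink a little and retry
        else:
            raise RuntimeError(
                f"could not place cell {i} without overlap after bounded retries"
            )
        placed.append(cell_poly)

        nuc_r = 0.45 * radius
        off = rng.uniform(-0.12, 0.12, size=2) * radius
        nucleus_xy = _round_polygon(rng, cx + off[0], cy + off[1], nuc_r, wobble=0.04)
        nucleus = Polygon(nucleus_xy)
        if not cell_poly.covers(nucleus):
            nucleus_xy = _round_polygon(rng, cx, cy, nuc_r, wobble=0.04)
            nucleus = Polygon(nucleus_xy)

        z_mid = z_mid_field + rng.uniform(-300.0, 300.0)
        z_half = 0.75 * radius  # cells span ~3 um of the stack

        expressing = phase == "G1" and rng.uniform() < params.expressing_fraction_G1
        n_mature = int(_sample_nb(rng, params.mature_mean, params.mature_dispersion, 1)[0]) if expressing else 0
        cytoplasm = cell_poly.difference(nucleus)
        pts = _uniform_in_polygon(rng, cytoplasm, n_mature)
        zs = rng.uniform(z_mid - z_half, z_mid + z_half, size=n_mature)
        qs = params.q_probe * rng.binomial(params.n_probes, params.p_bind, size=n_mature)
        mrnas = np.column_stack([pts[:, 0], pts[:, 1], zs, qs.astype(float)]) if n_mature else np.empty((0, 4))

        ts = None
        if expressing and lam_ts is not None and rng.uniform() < params.ts_fraction:
            n_nascent = int(_sample_ztp(rng, lam_ts, 1)[0])
            txy = _uniform_in_polygon(rng, nucleus, 1)[0]
            tz = z_mid + rng.uniform(-400.0, 400.0)
            q_ts = float(params.q_probe * rng.binomial(params.n_probes, params.p_bind, size=n_nascent).sum())
            ts = {"x": float(txy[0]), "y": float(txy[1]), "z": float(tz),
                  "nascent_n": n_nascent, "Q_true": q_ts}

        photons = params.if_photons[phase] * rng.uniform(0.85, 1.15)
        prims, span = _spindle_primitives(rng, phase, cx, cy, z_mid, nuc_r, bud_xy, photons)

        cells.append(
            CellTruth(
                cell_id=f"cell_{i:04d}",
                phase=phase,
                center_nm=(cx, cy),
                cell_polygon=poly_xy,
                nucleus_polygon=nucleus_xy,
                mrnas=mrnas,
                ts=ts,
                spindle=prims,
                bud_ratio_true=bud_ratio,
                spindle_span_true=span,
            )
        )
    return Scene(cells=cells, params=params, position_id=position_id)


def make_ts_ladder_scene(
    nascent_ns: list[int], params: ScenarioParams, n_singles: int = 8,
    position_id: str = "ladder",
) -> Scene:
    """A controlled scene for nascent-count validation: one G1 cell per
    requested transcription site, each TS carrying exactly ``nascent_ns[i]``
    transcripts, plus ``n_singles`` cytoplasmic molecules per cell to anchor
    the single-mRNA reference intensity."""
    base = replace(
        params,
        n_cells=len(nascent_ns),
        phase_fractions={"G1": 1.0, "S": 0.0, "G2": 0.0, "M": 0.0},
        expressing_fraction_G1=1.0,
        ts_fraction=1.0,
        mature_mean=float(n_singles),
        mature_dispersion=1e6,  # essentially Poisson-tight around n_singles
    )
    scene = sample_scene(base, position_id=position_id)
    rng = np.random.default_rng((params.seed, 0x7ADDE5))
    lamless = None
    for cell, n in zip(scene.cells, nascent_ns):
        nucleus = Polygon(cell.nucleus_polygon)
        txy = _uniform_in_polygon(rng, nucleus, 1)[0]
        z_mid = float(np.mean(cell.mrnas[:, 2])) if len(cell.mrnas) else 0.5 * base.field_shape[0] * base.voxel_size[0]
        q_ts = float(params.q_probe * rng.binomial(params.n_probes, params.p_bind, size=n).sum())
        cell.ts = {"x": float(txy[0]), "y": float(txy[1]), "z": z_mid + rng.uniform(-300, 300),
                   "nascent_n": int(n), "Q_true": q_ts}
    return scene


def make_sparse_scene(
    n_spots: int, params: ScenarioParams, min_separation_px: float = 6.0,
    position_id: str = "sparse",
) -> Scene:
    """A field of well-separated single molecules (no cells): the standard
    scenario for localization and detection benchmarks."""
    rng = np.random.default_rng(params.seed)
    nz, ny, nx = params.field_shape
    dz, dy, dx = params.voxel_size
    pts: list[tuple[float, float]] = []
    guard = 0
    while len(pts) < n_spots:
        x = rng.uniform(8 * dx, (nx - 8) * dx)
        y = rng.uniform(8 * dy, (ny - 8) * dy)
        if all((x - px) ** 2 + (y - py) ** 2 > (min_separation_px * dx) ** 2 for px, py in pts):
            pts.append((x, y))
        guard += 1
        if guard > 200 * n_spots:
            raise RuntimeError("field too small for requested spot count")
    zs = rng.uniform(8 * dz, (nz - 8) * dz, size=n_spots)
    qs = params.q_probe * rng.binomial(params.n_probes, params.p_bind, size=n_spots)
    arr = np.column_stack([np.array(pts), zs, qs.astype(float)])
    big = [(0.0, 0.0), (nx * dx, 0.0), (nx * dx, ny * dy), (0.0, ny * dy)]
    tiny = [(-3.0, -3.0), (-2.0, -3.0), (-2.0, -2.0)]  # degenerate off-field nucleus
    cell = CellTruth(
        cell_id="cell_0000", phase="G1", center_nm=(nx * dx / 2, ny * dy / 2),
        cell_polygon=big, nucleus_polygon=tiny, mrnas=arr,
    )
    return Scene(cells=[cell], params=params, position_id=position_id)


# ---------------------------------------------------------------------------
# Rendering


def _axis_profile(n: int, d: float, center: float, sigma: float, lo: int, hi: int):
    """Voxel-integrated 1D Gaussian mass on voxels lo..hi-1 (axis pitch d)."""
    edges = np.arange(lo, hi + 1) * d
    c = erf((edges - center) / (sigma * math.sqrt(2.0)))
    return 0.5 * (c[1:] - c[:-1])


def _add_gaussian(photon: np.ndarray, voxel, x, y, z, Q, sigma_xy, sigma_z, n_sigma=5.0):
    """Accumulate a voxel-integrated tri-axial Gaussian of total mass Q."""
    nz, ny, nx = photon.shape
    dz, dy, dx = voxel
    z0 = max(0, int((z - n_sigma * sigma_z) / dz))
    z1 = min(nz, int((z + n_sigma * sigma_z) / dz) + 2)
    y0 = max(0, int((y - n_sigma * sigma_xy) / dy))
    y1 = min(ny, int((y + n_sigma * sigma_xy) / dy) + 2)
    x0 = max(0, int((x - n_sigma * sigma_xy) / dx))
    x1 = min(nx, int((x + n_sigma * sigma_xy) / dx) + 2)
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return
    pz = _axis_profile(nz, dz, z, sigma_z, z0, z1)
    py = _axis_profile(ny, dy, y, sigma_xy, y0, y1)
    px = _axis_profile(nx, dx, x, sigma_xy, x0, x1)
    photon[z0:z1, y0:y1, x0:x1] += Q * pz[:, None, None] * py[None, :, None] * px[None, None, :]


def _render_if(photon, scene, voxel):
    sigma_xy, sigma_z = 200.0, 320.0
    for cell in scene.cells:
        for p in cell.spindle:
            if p["kind"] == "focus":
                _add_gaussian(photon, voxel, p["x"], p["y"], p["z"], p["photons"], sigma_xy, sigma_z)
            else:  # bar: line of overlapping foci
                n_seg = 12
                for t in np.linspace(0.0, 1.0, n_seg):
                    _add_gaussian(
                        photon, voxel,
                        p["x"] + t * (p["x2"] - p["x"]),
                        p["y"] + t * (p["y2"] - p["y"]),
                        p["z"], p["photons"] / n_seg, sigma_xy, sigma_z,
                    )


def _render_dapi(photon, scene, voxel):
    for cell in scene.cells:
        nuc = Polygon(cell.nucleus_polygon)
        c = nuc.centroid
        r = math.sqrt(max(nuc.area, 1.0) / math.pi)
        z_mid = np.mean([p["z"] for p in cell.spindle]) if cell.spindle else 0.5 * photon.shape[0] * voxel[0]
        _add_gaussian(photon, voxel, c.x, c.y, z_mid, scene.params.dapi_photons, 0.6 * r, 700.0)


def _render_dic(scene, params) -> np.ndarray:
    """Flat edge-map proxy for the single-plane DIC image."""
    from skimage.draw import polygon_perimeter
    from scipy.ndimage import gaussian_filter

    nz, ny, nx = params.field_shape
    _, dyv, dxv = params.voxel_size
    img = np.zeros((ny, nx))
    for cell in scene.cells:
        xs = np.array([v[0] for v in cell.cell_polygon]) / dxv - 0.5
        ys = np.array([v[1] for v in cell.cell_polygon]) / dyv - 0.5
        rr, cc = polygon_perimeter(np.clip(ys, 0, ny - 1), np.clip(xs, 0, nx - 1), shape=(ny, nx))
        img[rr, cc] = 1.0
    return gaussian_filter(img, 1.0)


def render_stack(
    scene: Scene,
    channel: str,
    params: ScenarioParams | None = None,
    noise: bool = True,
) -> ImageStack:
    """Render one channel of a scene into an :class:`~smfishq.io.ImageStack`.

    With ``noise=True`` the photon image E (ADU) is passed through the camera
    model ``offset + gain * Poisson(E / gain) + Normal(0, read_sd)``, clipped
    at zero; cellular autofluorescence ``bg_fluor`` is part of E for the
    fluorescent channels.  Deterministic given the scene seed and channel.
    """
    params = params or scene.params
    nz, ny, nx = params.field_shape
    voxel = params.voxel_size
    chan_seed = {"FISH": 1, "IF": 2, "DAPI": 3, "DIC": 4}[channel]
    rng = np.random.default_rng((params.seed, 0x5CE11E, chan_seed))

    if channel == "DIC":
        base = 500.0 * _render_dic(scene, params)[None]
        data = base + params.noise["offset"]
        if noise:
            data = data + rng.normal(0.0, params.noise["read_sd"], size=data.shape)
        return ImageStack(np.clip(data, 0, None), voxel_size=voxel, channel="DIC",
                          position_id=scene.position_id)

    photon = np.zeros((nz, ny, nx))
    if channel == "FISH":
        sxy, sz = params.psf_sigma
        for cell in scene.cells:
            for x, y, z, q in cell.mrnas:
                _add_gaussian(photon, voxel, x, y, z, q, sxy, sz)
            if cell.ts is not None:
                t = cell.ts
                _add_gaussian(photon, voxel, t["x"], t["y"], t["z"], t["Q_true"], sxy, sz)
    elif channel == "IF":
        _render_if(photon, scene, voxel)
    elif channel == "DAPI":
        _render_dapi(photon, scene, voxel)
    else:
        raise ValueError(f"unknown channel {channel!r}")

    nz_p = params.noise
    if noise:
        photon = photon + nz_p["bg_fluor"]
        gain = nz_p["gain"]
        data = (
            nz_p["offset"]
            + gain * rng.poisson(photon / gain)
            + rng.normal(0.0, nz_p["read_sd"], size=photon.shape)
        )
        data = np.clip(data, 0, None)
    else:
        data = photon + nz_p["offset"]
    return ImageStack(data, voxel_size=voxel, channel=channel, position_id=scene.position_id)


# ---------------------------------------------------------------------------
# Artifact injection


def inject_z_drift(stack: ImageStack, drift_per_plane: tuple[float, float]) -> ImageStack:
    """Translate plane k by k*(dy, dx) pixels (subpixel, linear interpolation):
    the bubble-in-the-oil acquisition artifact where the field slides as the
    stage steps through z."""
    from scipy.ndimage import shift as nd_shift

    dy, dx = drift_per_plane
    if not (np.isfinite(dy) and np.isfinite(dx)):
        raise ValueError("drift must be finite")
    if dy == 0 and dx == 0:
        return ImageStack(stack.data.copy(), stack.voxel_size, stack.channel, stack.position_id)
    out = np.empty_like(stack.data, dtype=float)
    for k in range(stack.data.shape[0]):
        out[k] = nd_shift(stack.data[k].astype(float), (k * dy, k * dx), order=1, mode="nearest")
    return ImageStack(out, stack.voxel_size, stack.channel, stack.position_id)


def add_bottom_debris(
    stack: ImageStack, n_blobs: int = 12, planes: int = 3, amplitude: float = 400.0,
    seed: int = 0,
) -> ImageStack:
    """Bright antibody-aggregate debris confined to the lowest z-planes of an
    IF stack (incomplete-wash artifact)."""
    rng = np.random.default_rng((seed, 0xDEB815))
    nz, ny, nx = stack.data.shape
    data = stack.data.astype(float).copy()
    dz, dyv, dxv = stack.voxel_size
    for _ in range(n_blobs):
        x = rng.uniform(0, nx * dxv)
        y = rng.uniform(0, ny * dyv)
        # keep the blob's axial mass inside the bottom planes
        z = rng.uniform(0.3 * dz, (planes - 0.9) * dz)
        q = amplitude * rng.uniform(0.5, 2.0) * 50.0
        _add_gaussian(data, stack.voxel_size, x, y, z, q, 300.0, 0.2 * dz)
    return ImageStack(data, stack.voxel_size, stack.channel, stack.position_id)


# ---------------------------------------------------------------------------
# Exports


def _nm_poly_to_px(poly, voxel):
    _, dyv, dxv = voxel
    return [(x / dxv - 0.5, y / dyv - 0.5) for x, y in poly]


def scene_outlines(scene: Scene) -> list[CellOutline]:
    """Ground-truth outlines in pixel units, with the phase as group label."""
    out = []
    for cell in scene.cells:
        out.append(
            CellOutline(
                cell_id=cell.cell_id,
                cell_polygon=_nm_poly_to_px(cell.cell_polygon, scene.params.voxel_size),
                nucleus_polygon=_nm_poly_to_px(cell.nucleus_polygon, scene.params.voxel_size),
                group=cell.phase,
                position_id=scene.position_id,
            )
        )
    return out


def scene_truth_table(scene: Scene) -> pd.DataFrame:
    """Long-form truth table: one row per molecule / TS, plus cell metadata."""
    rows = []
    for cell in scene.cells:
        for x, y, z, q in cell.mrnas:
            rows.append(dict(position_id=scene.position_id, cell_id=cell.cell_id,
                             phase=cell.phase, kind="mature", x=x, y=y, z=z,
                             Q_true=q, nascent_n=0))
        if cell.ts is not None:
            t = cell.ts
            rows.append(dict(position_id=scene.position_id, cell_id=cell.cell_id,
                             phase=cell.phase, kind="ts", x=t["x"], y=t["y"], z=t["z"],
                             Q_true=t["Q_true"], nascent_n=t["nascent_n"]))
        if not cell.expressing:
            rows.append(dict(position_id=scene.position_id, cell_id=cell.cell_id,
                             phase=cell.phase, kind="none", x=np.nan, y=np.nan,
                             z=np.nan, Q_true=0.0, nascent_n=0))
    return pd.DataFrame(rows)
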