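"""Preprocessing and quality control: background statistics, difference-of-
Gaussian bandpass filtering for SNR enhancement, per-stack z-drift detection
and DIC-to-fluorescence registration.

Z-drift: a bubble in the immersion oil (or a dirty objective) makes the
field slide laterally as the stage steps through z, at up to ~1 px/plane.
Such stacks remain countable but are useless for precision localization, so
the QC flags them.  DIC registration: transmitted-light and fluorescence
paths often have a systematic lateral offset that must be corrected by a
rigid translation before outlines drawn on DIC are used on fluorescence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import ImageStack, DetectionSettings

__all__ = [
    "DriftReport",
    "estimate_background",
    "bandpass_filter",
    "estimate_z_drift",
    "register_dic",
]


def estimate_background(stack: ImageStack) -> dict:
    """Robust background over all voxels: ``{"median": ..., "mad": ...}``
    (MAD is the raw median absolute deviation, unscaled)."""
    flat = np.asarray(stack.data, dtype=float).ravel()
    if flat.size == 0:
        raise ValueError("empty stack")
    med = float(np.median(flat))
    mad = float(np.median(np.abs(flat - med)))
    return {"median": med, "mad": mad}


def bandpass_filter(
    stack: ImageStack, settings: DetectionSettings | None = None, clip: bool = True
) -> ImageStack:
    """Difference-of-Gaussians bandpass: ``G(sigma_small)*I - G(sigma_large)*I``.

    The small kernel suppresses shot noise at the scale of single voxels; the
    large kernel removes background and out-of-focus haze; what survives is
    structure at the diffraction-limited spot scale.  Negative values are
    clipped to zero by default (the filtered image feeds a positive
    threshold).
    """
    settings = settings or DetectionSettings()
    data = np.asarray(stack.data, dtype=float)
    small = ndimage.gaussian_filter(
        data, (settings.sigma_small_z, settings.sigma_small_xy, settings.sigma_small_xy)
    )
    large = ndimage.gaussian_filter(
        data, (settings.sigma_large_z, settings.sigma_large_xy, settings.sigma_large_xy)
    )
    out = small - large
    if clip:
        out = np.clip(out, 0, None)
    return ImageStack(out, stack.voxel_size, stack.channel, stack.position_id)


@dataclass
class DriftReport:
    per_plane_shift: list[tuple[float, float] | None]  # (dy, dx) px vs plane 0
    slope: tuple[float, float]  # px/plane by least squares
    flagged: bool
    threshold: float
    estimable: bool = True


def estimate_z_drift(stack: ImageStack, threshold: float = 0.5) -> DriftReport:
    """Estimate lateral drift through the z-stack by spot tracklets.

    Bright diffraction-limited spots are detected on the bandpassed stack,
    the lateral centroid of each is followed across its two neighbouring
    planes on either side, and the median per-spot centroid slope is the
    drift in px/plane (three passes, re-centering the tracking windows on
    the running estimate so large drifts are not attenuated).  Per-plane
    shifts for the report come from a joint solve of
    ``centroid[i, k] = base[i] + shift[k]``.  Flagged when either slope
    component exceeds ``threshold`` (default 0.5 px/plane).  Featureless or
    spotless stacks are reported as not estimable and never flagged.
    """
    data = np.asarray(stack.data, dtype=float)
    nz, ny, nx = data.shape
    if nz < 3:
        raise ValueError("z-drift estimation needs at least 3 planes")
    if data.std() < 1e-12:
        return DriftReport([None] * nz, (0.0, 0.0), False, threshold, estimable=False)

    # Spot tracklets: drift turns every diffraction-limited spot into a
    # slanted streak, so the per-plane lateral centroid of each bright spot
    # moves linearly with plane index at exactly the drift slope.  Tracking
    # dozens of spots and taking the median slope is far better conditioned
    # than correlating whole planes, which at smFISH spot densities is
    # dominated by chance alignments between different molecules.
    dog = np.empty_like(data)
    for k in range(nz):
        dog[k] = ndimage.gaussian_filter(data[k], 1.0) - ndimage.gaussian_filter(data[k], 5.0)
    med = float(np.median(dog))
    sd = 1.4826 * float(np.median(np.abs(dog - med)))
    if sd <= 0:
        return DriftReport([None] * nz, (0.0, 0.0), False, threshold, estimable=False)
    thr = med + 8.0 * sd
    floor = med + 3.0 * sd  # centroid noise floor

    mx = ndimage.maximum_filter(dog, size=3)
    coords = np.argwhere((dog >= mx) & (dog > thr))
    if len(coords) == 0:
        return DriftReport([None] * nz, (0.0, 0.0), False, threshold, estimable=False)
    vals = dog[tuple(coords.T)]
    coords = coords[np.argsort(-vals)][:120]
    kept: list[np.ndarray] = []
    for c in coords:
        if all(np.sum((c[1:] - p[1:]) ** 2) > 36 or abs(c[0] - p[0]) > 6 for p in kept):
            kept.append(c)

    R = 6
    yy, xx = np.mgrid[0 : 2 * R + 1, 0 : 2 * R + 1]

    def _tracklet(k0, y0, x0, slope):
        pts = []
        for k in range(max(0, k0 - 2), min(nz, k0 + 3)):
            yi = int(round(y0 + slope[0] * (k - k0)))
            xi = int(round(x0 + slope[1] * (k - k0)))
            if yi - R < 0 or xi - R < 0 or yi + R + 1 > ny or xi + R + 1 > nx:
                continue
            w = np.clip(dog[k, yi - R : yi + R + 1, xi - R : xi + R + 1] - floor, 0, None)
            s = w.sum()
            if s < 20:
                continue
            pts.append((k, (w * yy).sum() / s + yi - R, (w * xx).sum() / s + xi - R))
        return np.array(pts) if len(pts) >= 3 else None

    def _median_slope(slope0):
        slopes, tracks = [], []
        for k0, y0, x0 in kept:
            t = _tracklet(int(k0), int(y0), int(x0), slope0)
            if t is None:
                continue
            A = np.column_stack([t[:, 0], np.ones(len(t))])
            sy = float(np.linalg.lstsq(A, t[:, 1], rcond=None)[0][0])
            sx = float(np.linalg.lstsq(A, t[:, 2], rcond=None)[0][0])
            slopes.append((sy, sx))
            tracks.append(t)
        return (np.array(slopes) if slopes else None), tracks

    slope = (0.0, 0.0)
    tracks: list[np.ndarray] = []
    for _ in range(3):  # re-center the tracking windows on the running estimate
        slopes, tracks = _median_slope(slope)
        if slopes is None or len(slopes) < 5:
            return DriftReport([None] * nz, (0.0, 0.0), False, threshold, estimable=False)
        slope = tuple(np.median(slopes, axis=0))

    # joint per-plane shifts: centroid_{i,k} = base_i + shift_k, solved by
    # alternating means; anchored at the first measurable plane
    shift_y = np.zeros(nz)
    shift_x = np.zeros(nz)
    covered = np.zeros(nz, dtype=bool)
    for t in tracks:
        covered[t[:, 0].astype(int)] = True
    for _ in range(8):
        num_y = np.zeros(nz)
        num_x = np.zeros(nz)
        cnt = np.zeros(nz)
        for t in tracks:
            ks = t[:, 0].astype(int)
            base_y = float(np.mean(t[:, 1] - shift_y[ks]))
            base_x = float(np.mean(t[:, 2] - shift_x[ks]))
            num_y[ks] += t[:, 1] - base_y
            num_x[ks] += t[:, 2] - base_x
            cnt[ks] += 1
        sel = cnt > 0
        shift_y[sel] = num_y[sel] / cnt[sel]
        shift_x[sel] = num_x[sel] / cnt[sel]
    first = int(np.argmax(covered))
    shift_y -= shift_y[first]
    shift_x -= shift_x[first]
    shifts: list[tuple[float, float] | None] = [
        (float(shift_y[k]), float(shift_x[k])) if covered[k] else None for k in range(nz)
    ]

    ks = np.array([k for k in range(nz) if covered[k]], dtype=float)
    A = np.column_stack([ks, np.ones_like(ks)])
    ls_y = float(np.linalg.lstsq(A, shift_y[covered.nonzero()[0]], rcond=None)[0][0])
    ls_x = float(np.linalg.lstsq(A, shift_x[covered.nonzero()[0]], rcond=None)[0][0])
    # the tracklet median is the robust headline number; the joint solve
    # provides the per-plane curve (they agree on clean linear drifts)
    slope_y, slope_x = float(slope[0]), float(slope[1])
    flagged = max(abs(slope_y), abs(slope_x)) > threshold
    return DriftReport(shifts, (slope_y, slope_x), flagged, threshold)


def register_dic(
    dic: np.ndarray,
    reference: np.ndarray,
    shift: tuple[int, int] | None = None,
    max_shift: int = 10,
    confidence_floor: float = 0.1,
) -> tuple[np.ndarray, tuple[int, int]]:
    """Rigid integer translation of a DIC image onto a fluorescence reference.

    If ``shift`` (dy, dx) is given it is applied directly (zero fill).
    Otherwise the shift maximizing the normalized cross-correlation over a
    ``+-max_shift`` px window is estimated; if the best correlation falls
    below ``confidence_floor`` the image is returned unshifted with a
    warning.  Returns ``(shifted_image, shift_used)``.
    """
    dic = np.asarray(dic, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if dic.shape != reference.shape:
        raise ValueError("DIC and reference must have the same shape")
    if 2 * max_shift + 1 > min(dic.shape):
        raise ValueError("search window larger than image")

    def _apply(img, dydx):
        out = np.zeros_like(img)
        dy, dx = int(dydx[0]), int(dydx[1])
        ys = slice(max(dy, 0), img.shape[0] + min(dy, 0))
        xs = slice(max(dx, 0), img.shape[1] + min(dx, 0))
        ys_src = slice(max(-dy, 0), img.shape[0] + min(-dy, 0))
        xs_src = slice(max(-dx, 0), img.shape[1] + min(-dx, 0))
        out[ys, xs] = img[ys_src, xs_src]
        return out

    if shift is not None:
        return _apply(dic, shift), (int(shift[0]), int(shift[1]))

    m = max_shift
    ref_c = reference[m:-m, m:-m]
    ref_c = ref_c - ref_c.mean()
    ref_norm = np.sqrt((ref_c**2).sum())
    best, best_val = (0, 0), -np.inf
    for dy in range(-m, m + 1):
        for dx in range(-m, m + 1):
            sub = dic[m - dy : dic.shape[0] - m - dy, m - dx : dic.shape[1] - m - dx]
            sub = sub - sub.mean()
            denom = ref_norm * np.sqrt((sub**2).sum())
            val = float((ref_c * sub).sum() / denom) if denom > 0 else 0.0
            if val > best_val:
                best_val, best = val, (dy, dx)
    if best_val < confidence_floor:
        warnings.warn(
            f"DIC registration correlation {best_val:.3f} below confidence "
            f"floor {confidence_floor}; leaving image unshifted",
            stacklevel=2,
        )
        return dic.copy(), (0, 0)
    return _apply(dic, best), best
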