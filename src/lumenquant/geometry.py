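"""Per-cross-section shape metrics for segmented duct masks.

Two effective diameters are computed per duct and slice:

* Feret diameter ``D_F = (D_v + D_h) / 2`` — the mean of the maximal
  vertical and horizontal extents of the mask.  (This axis-aligned mean is
  the definition used throughout; it is *not* the rotating-calipers
  maximal Feret diameter.)
* Hydraulic diameter ``D_Hy = 4 * area / perimeter`` — the fluid-mechanics
  effective diameter of the flow cross-section, with the duct's full mask
  boundary (including the flap-facing side) as the wetted perimeter.

Extents use the inclusive pixel span (+1 convention: a single pixel has
extent one spacing).  The perimeter is measured on the sub-pixel 0.5
iso-contour of the mask (marching squares); pixel-edge counting would
overestimate smooth boundaries by up to ~27% and bias D_Hy low.  The raw
marching-squares polygon itself is still biased (up to +8% on oblique
straight edges, about +6% averaged over a circle) and clips corners, so
the contour is post-processed: a short moving average removes the
staircase bias on smooth arcs, zones of concentrated turning are detected
as corners and restored by intersecting line fits to the raw vertices on
either side, and near-180-degree turning zones (cusps, thin slivers) keep
the raw contour, which tracks them best.  The result is exact on
axis-aligned rectangles and accurate to a few tenths of a percent on
disks of radius >= 10 pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import measure as skmeasure


@dataclass(frozen=True)
class CrossSectionMetrics:
    """Shape and brightness metrics of one duct on one slice.

    Lengths in mm, area in mm^2, B_AV in raw pixel value.  An *empty*
    record (duct expected but no pixels segmented) carries NaN metrics.
    """

    slice_index: int
    duct: str
    D_v: float
    D_h: float
    D_F: float
    area: float
    perimeter: float
    D_Hy: float
    B_AV: float

    @property
    def is_empty(self) -> bool:
        return math.isnan(self.D_F)

    @classmethod
    def empty(cls, slice_index: int, duct: str) -> "CrossSectionMetrics":
        nan = float("nan")
        return cls(slice_index, duct, nan, nan, nan, nan, nan, nan, nan)


def _require_nonempty(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not mask.any():
        raise ValueError("mask is empty")
    return mask


def extent_diameters(
    mask: np.ndarray, spacing_mm: tuple[float, float]
) -> tuple[float, float]:
    """Maximal vertical (row) and horizontal (col) extents of the mask, mm.

    Inclusive pixel span: (max index − min index + 1) × spacing.
    """
    mask = _require_nonempty(mask)
    rows, cols = np.nonzero(mask)
    d_v = (rows.max() - rows.min() + 1) * spacing_mm[0]
    d_h = (cols.max() - cols.min() + 1) * spacing_mm[1]
    return float(d_v), float(d_h)


def feret_diameter(d_v: float, d_h: float) -> float:
    """Mean of the vertical and horizontal extents, mm."""
    if d_v <= 0 or d_h <= 0:
        raise ValueError(f"extents must be positive, got ({d_v}, {d_h})")
    return (d_v + d_h) / 2


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % (2 * np.pi) - np.pi


def _fit_direction(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal direction (unit vector) and centroid of a small point set."""
    center = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - center)
    return vt[0], center


def _polygon_perimeter(
    pts: np.ndarray,
    px: float,
    smooth_window: int = 5,
    turn_window: int = 2,
    corner_turn: float = np.pi / 3,
    cusp_turn: float = np.radians(100),
    fit_window: int = 5,
    max_extend_px: float = 15.0,
) -> float:
    """Length of one closed boundary polygon (physical coordinates).

    ``pts`` are marching-squares vertices without the repeated endpoint.
    Smooth stretches use the moving-average polygon; corner zones
    (windowed turning above ``corner_turn``) are rebuilt by intersecting
    line fits to the raw vertices flanking the zone; cusp zones (turning
    above ``cusp_turn``) keep the raw polyline.
    """
    n = len(pts)
    if n < 3 * smooth_window:
        d = np.diff(np.vstack([pts, pts[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    k = smooth_window
    kern = np.ones(k) / k
    sm = np.stack(
        [
            np.convolve(np.r_[pts[-(k // 2):, i], pts[:, i], pts[: k // 2, i]],
                        kern, mode="valid")
            for i in (0, 1)
        ],
        axis=1,
    )
    seg = np.roll(sm, -1, axis=0) - sm
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    phi = np.arctan2(seg[:, 0], seg[:, 1])
    dphi = _wrap_angle(np.roll(phi, -1) - phi)

    ext = np.r_[dphi, dphi, dphi]
    turning = np.array(
        [ext[n + i - turn_window: n + i + turn_window].sum() for i in range(n)]
    )
    corner = np.abs(turning) > corner_turn
    if not corner.any():
        return float(seglen.sum())
    if corner.sum() > 0.7 * n:  # tiny or wildly irregular blob: raw contour
        d = np.diff(np.vstack([pts, pts[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())
    corner = corner | np.roll(corner, 1) | np.roll(corner, -1)

    idx = np.where(corner)[0]
    breaks = np.where(np.diff(idx) > 1)[0]
    runs = np.split(idx, breaks + 1) if len(breaks) else [idx]
    if len(runs) > 1 and idx[0] == 0 and idx[-1] == n - 1:
        runs[0] = np.r_[runs[-1], runs[0]]
        runs.pop()

    length = 0.0
    for i in range(n):  # smooth stretches between zones
        if not (corner[i] or corner[(i + 1) % n]):
            length += seglen[i]

    for run in runs:
        a_i = (run[0] - 1) % n
        b_i = (run[-1] + 1) % n
        zone_turn = abs(sum(dphi[i % n] for i in range(run[0] - 1, run[-1] + 1)))

        def _raw_zone_length() -> float:
            zone = [a_i, *run, b_i]
            return sum(
                float(np.hypot(*(pts[zone[j + 1] % n] - pts[zone[j] % n])))
                for j in range(len(zone) - 1)
            )

        if zone_turn > cusp_turn:
            length += _raw_zone_length()
            continue
        ia = [(a_i - j) % n for j in range(fit_window)]
        ib = [(b_i + j) % n for j in range(fit_window)]
        da, ca = _fit_direction(pts[ia])
        db, cb = _fit_direction(pts[ib])
        a = ca + da * float(np.dot(pts[a_i] - ca, da))
        b = cb + db * float(np.dot(pts[b_i] - cb, db))
        # orient both directions to point into the zone
        if np.dot(da, a - pts[ia[-1]]) < 0:
            da = -da
        if np.dot(db, b - pts[ib[-1]]) < 0:
            db = -db
        A = np.array([[da[0], -db[0]], [da[1], -db[1]]])
        det = float(np.linalg.det(A))
        good = abs(det) > 1e-6
        if good:
            s, u = np.linalg.solve(A, b - a)
            good = (
                s > -0.5 * px and u > -0.5 * px
                and s < max_extend_px * px and u < max_extend_px * px
            )
        if good:
            x = a + s * da
            length += float(np.hypot(*(x - a)) + np.hypot(*(b - x)))
        else:
            length += _raw_zone_length()
    return float(length)


def area_perimeter(
    mask: np.ndarray, spacing_mm: tuple[float, float]
) -> tuple[float, float]:
    """Mask area (pixel count × pixel area, mm^2) and sub-pixel perimeter (mm).

    The perimeter sums the corner-restored, smoothed marching-squares
    contours of the (zero-padded) mask; inner boundaries of holes are
    included.  See the module docstring for the estimator's construction.
    """
    mask = _require_nonempty(mask)
    area = float(mask.sum()) * spacing_mm[0] * spacing_mm[1]

    scale = np.asarray(spacing_mm, dtype=float)
    px = float(np.sqrt(scale[0] * scale[1]))
    padded = np.pad(mask.astype(float), 1)
    perimeter = 0.0
    for contour in skmeasure.find_contours(padded, 0.5):
        closed = bool(np.allclose(contour[0], contour[-1]))
        pts = (contour[:-1] if closed else contour) * scale
        perimeter += _polygon_perimeter(pts, px)
    if perimeter <= 0:
        raise ValueError("degenerate mask: no boundary contour found")
    return area, perimeter


def hydraulic_diameter(area: float, perimeter: float) -> float:
    """4 × cross-section area / wetted perimeter, mm."""
    if area <= 0 or perimeter <= 0:
        raise ValueError(
            f"area and perimeter must be positive, got ({area}, {perimeter})"
        )
    return 4 * area / perimeter


def measure_mask(
    mask: np.ndarray,
    slice_image: np.ndarray,
    spacing_mm: tuple[float, float],
    slice_index: int,
    duct: str,
) -> CrossSectionMetrics:
    """All cross-section metrics of one duct mask on one slice."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return CrossSectionMetrics.empty(slice_index, duct)
    d_v, d_h = extent_diameters(mask, spacing_mm)
    area, perimeter = area_perimeter(mask, spacing_mm)
    b_av = float(np.asarray(slice_image, dtype=float)[mask].mean())
    return CrossSectionMetrics(
        slice_index=slice_index,
        duct=duct,
        D_v=d_v,
        D_h=d_h,
        D_F=feret_diameter(d_v, d_h),
        area=area,
        perimeter=perimeter,
        D_Hy=hydraulic_diameter(area, perimeter),
        B_AV=b_av,
    )


def measure_series(volume, labeling) -> dict[str, list[CrossSectionMetrics]]:
    """Measure every (slice, duct) the labeling reports, ordered by slice.

    ``volume`` is an :class:`~lumenquant.io.ImageVolume`; ``labeling`` a
    :class:`~lumenquant.segmentation.DuctLabeling`.  Returns duct ->
    ordered list of metrics; a duct expected on a slice but segmented
    empty yields an empty record (NaN metrics, flagged).
    """
    if labeling.labels.shape != volume.voxels.shape:
        raise ValueError(
            f"labeling shape {labeling.labels.shape} does not match volume "
            f"shape {volume.voxels.shape}"
        )
    spacing = volume.spacing_mm[:2]
    series: dict[str, list[CrossSectionMetrics]] = {}
    for k in range(volume.n_slices):
        for duct in labeling.ducts_on_slice(k):
            metrics = measure_mask(
                labeling.mask(k, duct), volume.voxels[k], spacing, k, duct
            )
            series.setdefault(duct, []).append(metrics)
    return series
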