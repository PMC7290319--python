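"""Enhancement (brightness) metrics and image-quality ratios.

The average brightness of a duct, ``B_AV = sum(B_i) / N_pixels``, is the
mean raw pixel value over the duct mask and serves as a surrogate for
contrast-agent concentration, hence flow.  Image quality is summarized by

* ``BI  = aorta_mean / noise_sd`` (brightness-to-noise), and
* ``CNR = (aorta_mean - background_mean) / noise_sd`` (contrast-to-noise),

with the noise SD pooled from two background regions of interest placed
outside the body (left and right of the patient).  Standard ROI sizes are
80 mm^2 in the lumen and 100 mm^2 for the background regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: conventional ROI target areas, mm^2
LUMEN_ROI_AREA_MM2 = 80.0
BACKGROUND_ROI_AREA_MM2 = 100.0


@dataclass(frozen=True)
class ROISpec:
    """A disk region of interest on one slice.

    ``center`` is (row, col) in pixel indices; ``target_area_mm2`` sets the
    disk radius (realized pixel area matches the target to within one
    boundary pixel ring).
    """

    slice_index: int
    center: tuple[float, float]
    target_area_mm2: float = LUMEN_ROI_AREA_MM2
    shape: str = "disk"

    def radius_mm(self) -> float:
        return math.sqrt(self.target_area_mm2 / math.pi)


@dataclass(frozen=True)
class ROIMeasurement:
    mean: float
    n_pixels: int
    area_mm2: float
    sd: float


@dataclass(frozen=True)
class QualityMetrics:
    """Brightness-to-noise and contrast-to-noise summary for one duct."""

    BI: float
    CNR: float
    noise_sd: float
    aorta_mean: float
    background_mean: float


def average_brightness(slice_image: np.ndarray, mask: np.ndarray) -> float:
    """Mean pixel value over the mask (B_AV), in raw pixel units."""
    image = np.asarray(slice_image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask shape does not match image")
    if not mask.any():
        raise ValueError("mask is empty")
    return float(image[mask].mean())


def _roi_mask(slice_image: np.ndarray, roi: ROISpec,
              spacing_mm: tuple[float, float]) -> np.ndarray:
    if roi.shape != "disk":
        raise ValueError(f"unsupported ROI shape {roi.shape!r}")
    rows, cols = slice_image.shape
    r_mm = roi.radius_mm()
    r0, c0 = roi.center
    if (
        r0 * spacing_mm[0] - r_mm < -spacing_mm[0] / 2
        or c0 * spacing_mm[1] - r_mm < -spacing_mm[1] / 2
        or r0 * spacing_mm[0] + r_mm > (rows - 0.5) * spacing_mm[0]
        or c0 * spacing_mm[1] + r_mm > (cols - 0.5) * spacing_mm[1]
    ):
        raise ValueError(f"ROI at {roi.center} (radius {r_mm:.2f} mm) exits the image")
    rr = (np.arange(rows)[:, None] - r0) * spacing_mm[0]
    cc = (np.arange(cols)[None, :] - c0) * spacing_mm[1]
    return rr**2 + cc**2 <= r_mm**2


def roi_mean(slice_image: np.ndarray, roi: ROISpec,
             spacing_mm: tuple[float, float]) -> ROIMeasurement:
    """Mean intensity over a disk ROI; the realized area is reported."""
    image = np.asarray(slice_image, dtype=float)
    mask = _roi_mask(image, roi, spacing_mm)
    vals = image[mask]
    return ROIMeasurement(
        mean=float(vals.mean()),
        n_pixels=int(mask.sum()),
        area_mm2=float(mask.sum()) * spacing_mm[0] * spacing_mm[1],
        sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
    )


def estimate_noise(slice_image: np.ndarray, background_rois,
                   spacing_mm: tuple[float, float],
                   body_mask: np.ndarray | None = None) -> float:
    """Pooled noise SD from (typically two) background ROIs.

    Each ROI contributes its *within-ROI* sample SD; the pooled value is
    the root mean square of the per-ROI SDs, so a constant offset between
    the left and right background regions does not inflate the estimate.
    ROIs overlapping the body mask (when given) are rejected.
    """
    image = np.asarray(slice_image, dtype=float)
    variances = []
    for roi in background_rois:
        mask = _roi_mask(image, roi, spacing_mm)
        if body_mask is not None and (mask & np.asarray(body_mask, dtype=bool)).any():
            raise ValueError(
                f"background ROI at {roi.center} overlaps the body mask"
            )
        variances.append(float(image[mask].var(ddof=1)))
    if not variances:
        raise ValueError("no background ROIs given")
    return math.sqrt(sum(variances) / len(variances))


def quality_metrics(aorta_roi_means, background_mean: float,
                    noise_sd: float) -> QualityMetrics:
    """BI and CNR from per-slice lumen ROI means and a noise estimate.

    ``aorta_roi_means`` are the per-slice ROI means for one duct; their
    mean over slices is the duct's brightness intensity.
    """
    means = np.asarray(list(aorta_roi_means), dtype=float)
    if means.size == 0:
        raise ValueError("need at least one aorta ROI mean")
    if noise_sd <= 0:
        raise ValueError(
            "noise SD must be positive: BI/CNR are undefined on noiseless images"
        )
    aorta_mean = float(means.mean())
    return QualityMetrics(
        BI=aorta_mean / noise_sd,
        CNR=(aorta_mean - background_mean) / noise_sd,
        noise_sd=noise_sd,
        aorta_mean=aorta_mean,
        background_mean=background_mean,
    )


def centered_lumen_roi(mask: np.ndarray, slice_index: int,
                       target_area_mm2: float = LUMEN_ROI_AREA_MM2,
                       spacing_mm: tuple[float, float] = (1.0, 1.0)) -> ROISpec:
    """ROI at the duct centroid (the reproducible default placement).

    When the centroid falls outside the mask (possible for a crescent),
    the ROI recenters on the interior pixel farthest from the boundary.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    r0, c0 = (float(v) for v in np.argwhere(mask).mean(axis=0))
    if not mask[int(round(r0)), int(round(c0))]:
        from scipy import ndimage

        dist = ndimage.distance_transform_edt(mask, sampling=spacing_mm)
        r0, c0 = (float(v) for v in np.unravel_index(np.argmax(dist), mask.shape))
    return ROISpec(slice_index, (r0, c0), target_area_mm2)
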