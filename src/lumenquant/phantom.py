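"""Synthetic dissected-aorta CTA phantom with ground truth.

The phantom emulates an axial contrast-enhanced CT stack of a Stanford
type B (DeBakey IIIb) dissection of the descending aorta: a single bright
lumen (the *common duct*) that, over a configurable axial range, is split
by a dark intimal flap into a smaller *true lumen* and a crescent-shaped
*false lumen* wrapping it.  Each region has a configurable mean
enhancement; independent additive Gaussian noise is superimposed.  The
default enhancement ordering (false > common > true) mirrors the clinical
observation that the false lumen is the more strongly enhanced channel and
the true lumen the least.

Intensities are plain non-negative pixel values, not Hounsfield units.

Every voxel carries exactly one ground-truth label, so the phantom doubles
as a segmentation oracle.  For the analytically shaped regions (disks) the
module also provides closed-form cross-section metrics, used to validate
the raster-based geometry estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.special import ellipe

from .geometry import CrossSectionMetrics
from .io import ImageVolume

# ground-truth label codes
BACKGROUND = 0
COMMON = 1
TRUE = 2
FALSE = 3
FLAP = 4

LABEL_NAMES: dict[int, str] = {
    BACKGROUND: "background",
    COMMON: "common",
    TRUE: "true",
    FALSE: "false",
    FLAP: "flap",
}
LABEL_CODES: dict[str, int] = {v: k for k, v in LABEL_NAMES.items()}

#: Regions that represent blood-filled channels (as opposed to flap/background).
LUMEN_LABELS = ("common", "true", "false")

DEFAULT_ENHANCEMENT: dict[str, float] = {
    "background": 30.0,
    "flap": 60.0,
    "true": 150.0,
    "common": 180.0,
    "false": 200.0,
}


class InvalidConfigError(ValueError):
    """A phantom configuration violates one of its invariants."""


class UnsupportedShapeError(ValueError):
    """Raised when no closed-form metrics exist for a shape kind."""


@dataclass(frozen=True)
class ShapeSpec:
    """A 2-D cross-section shape in physical (mm) coordinates.

    ``center`` is (row_mm, col_mm); physical position of pixel (i, j) is
    (i * row_spacing, j * col_spacing).

    Parameters by kind
    ------------------
    disk:       ``radius``
    ellipse:    ``semi_axis_row``, ``semi_axis_col`` (axis-aligned)
    rectangle:  ``height`` (row extent), ``width`` (col extent)
    crescent:   ``outer_radius``, ``inner_radius``, ``inner_center``
                (row, col offset of the excluded inner disk, mm)
    """

    kind: str
    parameters: Mapping[str, object]
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.kind not in ("disk", "ellipse", "rectangle", "crescent"):
            raise InvalidConfigError(f"unknown shape kind {self.kind!r}")
        for name, value in self.parameters.items():
            if name == "inner_center":
                continue
            if not np.isfinite(value) or value <= 0:
                raise InvalidConfigError(
                    f"shape dimension {name!r} must be > 0, got {value}"
                )


@dataclass(frozen=True)
class PhantomConfig:
    """Full description of a synthetic dissection stack.

    ``grid_size`` is (rows, cols, slices); ``spacing_mm`` is
    (row, col, slice) spacing.  Slices ``[split_slice, merge_slice)`` are
    dissected (two lumens), all others contain the single common duct.
    ``enhancement`` maps region name -> mean intensity (pixel value).
    """

    grid_size: tuple[int, int, int] = (128, 128, 140)
    spacing_mm: tuple[float, float, float] = (0.78, 0.78, 0.8)
    lumen_radius_mm: float = 15.0
    split_slice: int = 40
    merge_slice: int = 100
    flap_thickness_mm: float = 2.0
    true_radius_fraction: float = 0.45
    enhancement: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ENHANCEMENT)
    )
    noise_sd: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        rows, cols, slices = self.grid_size
        if min(rows, cols, slices) < 1:
            raise InvalidConfigError("grid_size components must be >= 1")
        if any(s <= 0 for s in self.spacing_mm):
            raise InvalidConfigError("spacing_mm components must be > 0")
        if not 0 <= self.split_slice < self.merge_slice < slices:
            raise InvalidConfigError(
                "require 0 <= split_slice < merge_slice < axial grid size, "
                f"got split={self.split_slice}, merge={self.merge_slice}, "
                f"slices={slices}"
            )
        missing = set(LABEL_NAMES.values()) - set(self.enhancement)
        if missing:
            raise InvalidConfigError(f"enhancement missing regions {sorted(missing)}")
        if any(v < 0 for v in self.enhancement.values()):
            raise InvalidConfigError("all enhancement means must be >= 0")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")
        if self.flap_thickness_mm <= 0:
            raise InvalidConfigError("flap_thickness_mm must be > 0")
        if not 0 < self.true_radius_fraction < 1:
            raise InvalidConfigError("true_radius_fraction must be in (0, 1)")
        fov = (rows * self.spacing_mm[0], cols * self.spacing_mm[1])
        if 2 * self.lumen_radius_mm >= min(fov):
            raise InvalidConfigError(
                f"lumen (diameter {2 * self.lumen_radius_mm} mm) does not fit "
                f"the in-plane field of view {fov} mm"
            )

    # geometry derived from the primary parameters -------------------------

    @property
    def center_mm(self) -> tuple[float, float]:
        rows, cols, _ = self.grid_size
        return ((rows - 1) / 2 * self.spacing_mm[0], (cols - 1) / 2 * self.spacing_mm[1])

    @property
    def true_radius_mm(self) -> float:
        return self.true_radius_fraction * self.lumen_radius_mm

    @property
    def true_offset_mm(self) -> float:
        """Column offset of the true-lumen center from the common center.

        The true lumen sits tangent to the outer wall (the compressed
        channel hugs the wall), so the flap ring pierces the wall by the
        full flap thickness.  The false lumen is then a genuine crescent
        with blunt, raster-representable tips, and the flap is never an
        enclosed hole.
        """
        return self.lumen_radius_mm - self.true_radius_mm

    def common_shape(self) -> ShapeSpec:
        return ShapeSpec("disk", {"radius": self.lumen_radius_mm}, self.center_mm)

    def true_shape(self) -> ShapeSpec:
        r0, c0 = self.center_mm
        return ShapeSpec(
            "disk", {"radius": self.true_radius_mm}, (r0, c0 + self.true_offset_mm)
        )

    def false_shape(self) -> ShapeSpec:
        return ShapeSpec(
            "crescent",
            {
                "outer_radius": self.lumen_radius_mm,
                "inner_radius": self.true_radius_mm + self.flap_thickness_mm,
                "inner_center": (0.0, self.true_offset_mm),
            },
            self.center_mm,
        )


@dataclass
class GroundTruth:
    """Voxel-exact reference labeling and generation parameters.

    ``labels`` has shape (slices, rows, cols) and values from
    :data:`LABEL_NAMES`.  ``analytic_metrics`` holds closed-form
    cross-section metrics for the regions that are analytic shapes
    (common and true lumens: disks); the crescent false lumen has no
    closed form and must be measured on the raster.
    """

    labels: np.ndarray
    per_region_mean: dict[str, float]
    config: PhantomConfig
    analytic_metrics: dict[str, CrossSectionMetrics]

    def mask(self, slice_index: int, region: str) -> np.ndarray:
        return self.labels[slice_index] == LABEL_CODES[region]

    def lumen_mask(self, slice_index: int) -> np.ndarray:
        sl = self.labels[slice_index]
        return (sl == COMMON) | (sl == TRUE) | (sl == FALSE)

    def ducts_on_slice(self, slice_index: int) -> list[str]:
        present = np.unique(self.labels[slice_index])
        return [LABEL_NAMES[c] for c in present if LABEL_NAMES[c] in LUMEN_LABELS]

    def validate(self) -> None:
        cfg = self.config
        n = self.labels.shape[0]
        for k in range(n):
            ducts = set(self.ducts_on_slice(k))
            if cfg.split_slice <= k < cfg.merge_slice:
                if ducts != {"true", "false"}:
                    raise AssertionError(
                        f"dissected slice {k} must hold exactly the true and "
                        f"false lumens, found {sorted(ducts)}"
                    )
            elif ducts != {"common"}:
                raise AssertionError(
                    f"undissected slice {k} must hold exactly the common "
                    f"duct, found {sorted(ducts)}"
                )


# ---------------------------------------------------------------------------
# rasterization


def _pixel_grids(spacing_mm, grid_size):
    rows, cols = grid_size
    r = np.arange(rows)[:, None] * spacing_mm[0]
    c = np.arange(cols)[None, :] * spacing_mm[1]
    return r, c


def rasterize_shape(
    shape: ShapeSpec,
    spacing_mm: tuple[float, float],
    grid_size: tuple[int, int],
) -> np.ndarray:
    """Rasterize ``shape`` onto a pixel grid (center-inside rule).

    Returns a boolean mask of shape ``grid_size``.  A pixel belongs to the
    mask when its center lies inside the shape.  Raises ``ValueError`` when
    the shape's bounding box exceeds the grid.
    """
    r, c = _pixel_grids(spacing_mm, grid_size)
    r0, c0 = shape.center
    p = shape.parameters
    if shape.kind == "disk":
        radius = float(p["radius"])
        half = (radius, radius)
        mask = (r - r0) ** 2 + (c - c0) ** 2 <= radius**2
    elif shape.kind == "ellipse":
        a, b = float(p["semi_axis_row"]), float(p["semi_axis_col"])
        half = (a, b)
        mask = ((r - r0) / a) ** 2 + ((c - c0) / b) ** 2 <= 1.0
    elif shape.kind == "rectangle":
        h, w = float(p["height"]), float(p["width"])
        half = (h / 2, w / 2)
        # half-open intervals: a rectangle of integer-multiple side length
        # covers exactly side/spacing pixels regardless of grid alignment
        mask = (
            (r >= r0 - h / 2) & (r < r0 + h / 2)
            & (c >= c0 - w / 2) & (c < c0 + w / 2)
        )
    elif shape.kind == "crescent":
        outer = float(p["outer_radius"])
        inner = float(p["inner_radius"])
        dr, dc = p.get("inner_center", (0.0, 0.0))
        half = (outer, outer)
        mask = ((r - r0) ** 2 + (c - c0) ** 2 <= outer**2) & (
            (r - r0 - dr) ** 2 + (c - c0 - dc) ** 2 > inner**2
        )
    else:  # pragma: no cover - guarded by ShapeSpec
        raise UnsupportedShapeError(shape.kind)

    extent = ((grid_size[0] - 1) * spacing_mm[0], (grid_size[1] - 1) * spacing_mm[1])
    for axis in (0, 1):
        if shape.center[axis] - half[axis] < -spacing_mm[axis] / 2 or (
            shape.center[axis] + half[axis] > extent[axis] + spacing_mm[axis] / 2
        ):
            raise ValueError(
                f"shape of half-extent {half} mm at {shape.center} mm exceeds "
                f"the grid ({extent} mm)"
            )
    return mask


# ---------------------------------------------------------------------------
# analytic oracles


def ellipse_perimeter(semi_major: float, semi_minor: float) -> float:
    """Exact ellipse perimeter via the complete elliptic integral E."""
    a, b = max(semi_major, semi_minor), min(semi_major, semi_minor)
    m = 1.0 - (b / a) ** 2  # eccentricity squared, scipy's m convention
    return float(4.0 * a * ellipe(m))


def analytic_metrics(shape: ShapeSpec) -> CrossSectionMetrics:
    """Closed-form cross-section metrics for disk / ellipse / rectangle.

    Feret diameter here is the mean of the vertical and horizontal extents;
    hydraulic diameter is 4 * area / perimeter.  The crescent has no closed
    form and raises :class:`UnsupportedShapeError` — measure its raster.
    """
    p = shape.parameters
    if shape.kind == "disk":
        d = 2 * float(p["radius"])
        dv = dh = d
        area = np.pi * float(p["radius"]) ** 2
        perimeter = np.pi * d
    elif shape.kind == "ellipse":
        a, b = float(p["semi_axis_row"]), float(p["semi_axis_col"])
        dv, dh = 2 * a, 2 * b
        area = np.pi * a * b
        perimeter = ellipse_perimeter(a, b)
    elif shape.kind == "rectangle":
        dv, dh = float(p["height"]), float(p["width"])
        area = dv * dh
        perimeter = 2 * (dv + dh)
    else:
        raise UnsupportedShapeError(
            f"no closed-form metrics for shape kind {shape.kind!r}; "
            "rasterize and measure instead"
        )
    return CrossSectionMetrics(
        slice_index=-1,
        duct="analytic",
        D_v=dv,
        D_h=dh,
        D_F=(dv + dh) / 2,
        area=area,
        perimeter=perimeter,
        D_Hy=4 * area / perimeter,
        B_AV=float("nan"),
    )


# ---------------------------------------------------------------------------
# volume generation


def _label_slice_templates(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Label images for the two slice archetypes (undissected, dissected)."""
    rows, cols, _ = config.grid_size
    spacing = config.spacing_mm[:2]
    grid = (rows, cols)

    common = rasterize_shape(config.common_shape(), spacing, grid)
    undissected = np.zeros(grid, dtype=np.uint8)
    undissected[common] = COMMON

    true_m = rasterize_shape(config.true_shape(), spacing, grid) & common
    false_m = rasterize_shape(config.false_shape(), spacing, grid) & common
    # stray sub-pixel fragments at the crescent tips belong to the flap:
    # each lumen must be one 4-connected component
    true_m = _largest_component(true_m)
    false_m = _largest_component(false_m)
    dissected = np.zeros(grid, dtype=np.uint8)
    dissected[common] = FLAP  # whatever is neither lumen is flap
    dissected[false_m] = FALSE
    dissected[true_m] = TRUE
    return undissected, dissected


def _largest_component(mask: np.ndarray) -> np.ndarray:
    from scipy import ndimage

    labeled, n = ndimage.label(mask, structure=ndimage.generate_binary_structure(2, 1))
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(mask, labeled, index=range(1, n + 1))
    return labeled == (1 + int(np.argmax(sizes)))


def generate_phantom(config: PhantomConfig) -> tuple[ImageVolume, GroundTruth]:
    """Generate the synthetic dissection stack and its ground truth.

    Deterministic: the same config (including ``seed``) yields a
    bit-identical volume.  Noise is i.i.d. Gaussian added on top of the
    per-region mean enhancement.
    """
    config.validate()
    rows, cols, slices = config.grid_size

    undissected, dissected = _label_slice_templates(config)
    labels = np.empty((slices, rows, cols), dtype=np.uint8)
    for k in range(slices):
        inside = config.split_slice <= k < config.merge_slice
        labels[k] = dissected if inside else undissected

    means = np.array(
        [config.enhancement[LABEL_NAMES[code]] for code in range(5)], dtype=np.float64
    )
    voxels = means[labels]
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        voxels = voxels + rng.normal(0.0, config.noise_sd, size=voxels.shape)

    volume = ImageVolume(
        voxels=voxels,
        spacing_mm=config.spacing_mm,
        intensity_units="pixel",
    )
    oracle = {
        "common": replace_duct(analytic_metrics(config.common_shape()), "common"),
        "true": replace_duct(analytic_metrics(config.true_shape()), "true"),
    }
    truth = GroundTruth(
        labels=labels,
        per_region_mean=dict(config.enhancement),
        config=config,
        analytic_metrics=oracle,
    )
    truth.validate()
    return volume, truth


def replace_duct(metrics: CrossSectionMetrics, duct: str) -> CrossSectionMetrics:
    return replace(metrics, duct=duct)
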