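"""Per-slice lumen segmentation and true/false/common duct labeling.

The segmentation follows the classic contrast-CT workflow: (1) optional
intensity windowing for contrast, (2) seeded region growing against the
running mean of the grown region, (3) morphological hole filling, and
(4) per-slice connected-component labeling of the ducts.

4-connectivity is used for both growing and component labeling so the
thin intimal flap cannot be leaked through diagonally.  Seeds are given
for the first analyzed slice and propagate slice-to-slice through the
previous slice's mask; a slice where the single lumen splits into two is
handled naturally because both daughter lumens inherit seed pixels from
the parent mask's footprint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-connectivity

#: numeric codes used in DuctLabeling.labels
DUCT_CODES: dict[str, int] = {"common": 1, "true": 2, "false": 3}
DUCT_NAMES: dict[int, str] = {v: k for k, v in DUCT_CODES.items()}


@dataclass(frozen=True)
class Seed:
    """One seed point: (slice, row, col), optionally tagged with a duct."""

    slice_index: int
    row: int
    col: int
    duct: str | None = None


@dataclass
class SeedSet:
    """Seed points for segmentation; at least one on the first analyzed slice."""

    seeds: list[Seed]

    def validate(self, volume_shape: tuple[int, int, int]) -> None:
        if not self.seeds:
            raise ValueError("seed set is empty")
        n, rows, cols = volume_shape
        for s in self.seeds:
            if not (0 <= s.slice_index < n and 0 <= s.row < rows and 0 <= s.col < cols):
                raise ValueError(f"seed {s} lies outside the volume {volume_shape}")

    def on_slice(self, k: int) -> list[Seed]:
        return [s for s in self.seeds if s.slice_index == k]

    @property
    def first_slice(self) -> int:
        return min(s.slice_index for s in self.seeds)


@dataclass(frozen=True)
class Transition:
    """A component-count change between consecutive slices."""

    slice_index: int  # first slice with the new count
    kind: str  # "split" (1 -> 2) or "merge" (2 -> 1)


@dataclass
class DuctLabeling:
    """Per-slice duct labels: 0 = none, 1 = common, 2 = true, 3 = false."""

    labels: np.ndarray  # (slices, rows, cols) uint8
    component_count: list[int]
    transitions: list[Transition] = field(default_factory=list)

    def mask(self, slice_index: int, duct: str) -> np.ndarray:
        return self.labels[slice_index] == DUCT_CODES[duct]

    def ducts_on_slice(self, slice_index: int) -> list[str]:
        codes = np.unique(self.labels[slice_index])
        return [DUCT_NAMES[c] for c in sorted(codes) if c in DUCT_NAMES]

    def lumen_mask(self, slice_index: int) -> np.ndarray:
        return self.labels[slice_index] > 0


# ---------------------------------------------------------------------------
# intensity windowing


def window_intensity(image: np.ndarray, low: float, high: float,
                     max_range: float | None = None) -> np.ndarray:
    """Clip intensities to [low, high], then rescale linearly to [0, max_range].

    Monotone: the ordering of in-window intensities is preserved.  The
    default output range equals the window width, so in-window values are
    merely shifted and tolerances keep their meaning.
    """
    if low >= high:
        raise ValueError(f"window requires low < high, got ({low}, {high})")
    if max_range is None:
        max_range = high - low
    clipped = np.clip(np.asarray(image, dtype=float), low, high)
    return (clipped - low) * (max_range / (high - low))


# ---------------------------------------------------------------------------
# region growing


def _grow_from_mask(image: np.ndarray, seed_mask: np.ndarray,
                    tolerance: float) -> np.ndarray:
    """Expand the seed region to all 4-connected pixels within ``tolerance``
    of the running region mean (mean recomputed after each accepted shell)."""
    region = seed_mask.copy()
    if not region.any():
        return region
    mean = float(image[region].mean())
    total = float(image[region].sum())
    count = int(region.sum())
    while True:
        frontier = ndimage.binary_dilation(region, structure=_CROSS) & ~region
        accept = frontier & (np.abs(image - mean) <= tolerance)
        n_new = int(accept.sum())
        if n_new == 0:
            return region
        region |= accept
        total += float(image[accept].sum())
        count += n_new
        mean = total / count


def region_grow(slice_image: np.ndarray, seeds, tolerance: float) -> np.ndarray:
    """Grow a region from seed points on one slice.

    ``seeds`` is an iterable of (row, col).  The result contains all seeds
    and every pixel 4-connected to a seed through pixels whose intensity
    stays within ``tolerance`` of the running mean of the grown region.
    """
    image = np.asarray(slice_image, dtype=float)
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    seed_mask = np.zeros(image.shape, dtype=bool)
    for row, col in seeds:
        if not (0 <= row < image.shape[0] and 0 <= col < image.shape[1]):
            raise ValueError(f"seed ({row}, {col}) outside image {image.shape}")
        seed_mask[row, col] = True
    if not seed_mask.any():
        raise ValueError("no seeds given")
    return _grow_from_mask(image, seed_mask, tolerance)


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background components not connected to the image border.

    Idempotent; the foreground is never removed.
    """
    mask = np.asarray(mask, dtype=bool)
    return ndimage.binary_fill_holes(mask)


# ---------------------------------------------------------------------------
# slice-to-slice propagation


def _propagated_seed_mask(image: np.ndarray, prev_mask: np.ndarray,
                          tolerance: float) -> np.ndarray:
    """Seed pixels for the next slice: the eroded previous mask, restricted
    to pixels whose intensity is near the median over that footprint.

    The median filter matters at a split: the footprint of the parent
    lumen covers the new flap, whose dark pixels must not pollute the
    running mean.
    """
    seeds = ndimage.binary_erosion(prev_mask, structure=_CROSS)
    if not seeds.any():
        seeds = prev_mask
    ref = float(np.median(image[seeds]))
    filtered = seeds & (np.abs(image - ref) <= tolerance)
    return filtered if filtered.any() else seeds


def segment_volume(volume, seed_set: SeedSet, tolerance: float,
                   window: tuple[float, float] | None = None) -> list[np.ndarray]:
    """Segment the whole stack; returns one filled binary lumen mask per slice.

    Seeds are required on (at least) one slice; masks propagate forward
    and backward from there.  Explicit seeds on other slices are merged
    into the propagated seed mask for their slice.
    """
    voxels = volume.voxels
    seed_set.validate(voxels.shape)
    if window is not None:
        voxels = window_intensity(voxels, *window)

    n = voxels.shape[0]
    masks: list[np.ndarray | None] = [None] * n
    start = seed_set.first_slice

    def _segment_slice(k: int, seed_mask: np.ndarray) -> np.ndarray:
        for s in seed_set.on_slice(k):
            seed_mask = seed_mask.copy()
            seed_mask[s.row, s.col] = True
        grown = _grow_from_mask(voxels[k], seed_mask, tolerance)
        return fill_holes(grown)

    first_seeds = np.zeros(voxels.shape[1:], dtype=bool)
    for s in seed_set.on_slice(start):
        first_seeds[s.row, s.col] = True
    masks[start] = _segment_slice(start, first_seeds)

    for k in range(start + 1, n):
        seed_mask = _propagated_seed_mask(voxels[k], masks[k - 1], tolerance)
        masks[k] = _segment_slice(k, seed_mask)
    for k in range(start - 1, -1, -1):
        seed_mask = _propagated_seed_mask(voxels[k], masks[k + 1], tolerance)
        masks[k] = _segment_slice(k, seed_mask)
    return masks  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# duct labeling


def label_ducts(volume, masks_per_slice, rule: str = "brightness") -> DuctLabeling:
    """Assign common/true/false labels to the per-slice lumen components.

    A slice with one connected component is the common duct.  With two,
    the default rule tags the component with the higher mean brightness
    as the false lumen (the more strongly enhanced channel); ``rule="area"``
    tags the larger one instead.  Once both ducts exist, labels propagate
    to the next slice by maximal pixel overlap, so a transient brightness
    fluctuation cannot swap them mid-stack.  Component-count changes are
    recorded as split/merge transitions.
    """
    if rule not in ("brightness", "area"):
        raise ValueError(f"unknown duct labeling rule {rule!r}")
    voxels = volume.voxels
    if len(masks_per_slice) != voxels.shape[0]:
        raise ValueError(
            f"expected {voxels.shape[0]} slice masks, got {len(masks_per_slice)}"
        )

    n = voxels.shape[0]
    labels = np.zeros(voxels.shape, dtype=np.uint8)
    counts: list[int] = []
    transitions: list[Transition] = []
    prev_two: dict[str, np.ndarray] | None = None  # last slice with 2 comps
    prev_count: int | None = None

    for k in range(n):
        mask = np.asarray(masks_per_slice[k], dtype=bool)
        comp, n_comp = ndimage.label(mask, structure=_CROSS)
        counts.append(n_comp)
        if n_comp > 2:
            raise ValueError(
                f"slice {k}: {n_comp} lumen components (at most 2 supported); "
                "adjust the segmentation tolerance or windowing"
            )
        if n_comp == 1:
            labels[k][comp == 1] = DUCT_CODES["common"]
            prev_two = None
        elif n_comp == 2:
            comps = {i: comp == i for i in (1, 2)}
            assignment = _assign_two(voxels[k], comps, prev_two, rule)
            for duct, m in assignment.items():
                labels[k][m] = DUCT_CODES[duct]
            prev_two = assignment

        if prev_count is not None and n_comp != prev_count:
            if prev_count == 1 and n_comp == 2:
                transitions.append(Transition(k, "split"))
            elif prev_count == 2 and n_comp == 1:
                transitions.append(Transition(k, "merge"))
        if n_comp > 0:
            prev_count = n_comp
    return DuctLabeling(labels=labels, component_count=counts, transitions=transitions)


def _assign_two(slice_image, comps, prev_two, rule):
    """Map the two components of a slice onto {true, false}."""
    if prev_two is not None:
        overlap = {
            i: {d: int((m & pm).sum()) for d, pm in prev_two.items()}
            for i, m in comps.items()
        }
        # inherit by maximal overlap when it is unambiguous
        best = {i: max(ov, key=ov.get) for i, ov in overlap.items()}
        if set(best.values()) == {"true", "false"} and all(
            max(ov.values()) > 0 for ov in overlap.values()
        ):
            return {best[i]: comps[i] for i in comps}
    if rule == "brightness":
        score = {i: float(slice_image[m].mean()) for i, m in comps.items()}
    else:
        score = {i: float(m.sum()) for i, m in comps.items()}
    false_i = max(score, key=score.get)
    true_i = min(score, key=score.get)
    if false_i == true_i:  # identical scores: fall back to component order
        false_i, true_i = 2, 1
    return {"false": comps[false_i], "true": comps[true_i]}


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two binary masks (1.0 when both empty)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float((a & b).sum()) / float(denom)
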