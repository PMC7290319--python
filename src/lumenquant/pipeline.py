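"""End-to-end pipeline: volume -> segmentation -> morphometry -> report.

The pipeline ties the modules together in the order a reader of a
dissection CTA study would apply them: obtain an axial stack (DICOM
series or synthetic phantom), window, segment by seeded region growing,
fill holes, label the ducts, measure every cross-section, and summarize
— per-duct mean ± SD tables, normalized inter-duct difference series,
Bland–Altman agreement of the Feret vs hydraulic diameter, split/merge
transitions with adjacent-slice brightness, and ROI-based BI/CNR image
quality.  Every tunable (window bounds, tolerance, labeling rule, seed)
is recorded in the report so a re-run with the same config reproduces the
outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np

from . import brightness as br
from . import comparison as cmp
from . import stats as st
from .geometry import extent_diameters, measure_series
from .io import ImageVolume, measurements_frame, read_dicom_series, write_measurements
from .phantom import PhantomConfig, generate_phantom
from .segmentation import (
    DuctLabeling,
    Seed,
    SeedSet,
    dice_coefficient,
    label_ducts,
    segment_volume,
)

SUMMARY_FIELDS = ("D_F", "D_Hy", "area", "B_AV")
DIFF_QUANTITIES = ("B_AV", "D_F", "D_Hy")


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage (and slice when known)."""


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run.

    Exactly one of ``dicom_dir`` / ``phantom`` must be set.  ``seeds``
    defaults, for phantoms, to an interior point of the ground-truth
    lumen on the first analyzed slice.  ``slice_range`` restricts the
    analysis to a sub-stack (the anatomical window of interest, e.g.
    descending aorta to diaphragm, is not recoverable from pixels alone).
    """

    dicom_dir: str | None = None
    phantom: PhantomConfig | None = None
    seeds: SeedSet | None = None
    window: tuple[float, float] | None = None
    tolerance: float = 60.0
    labeling_rule: str = "brightness"
    slice_range: tuple[int, int] | None = None
    seed: int | None = None  # overrides the phantom's own seed when set

    def validate(self) -> None:
        if (self.dicom_dir is None) == (self.phantom is None):
            raise ValueError("exactly one of dicom_dir / phantom must be given")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")


@dataclass
class ReportBundle:
    """All pipeline outputs plus the parameters that produced them."""

    measurements: Any  # pandas frame, one row per (slice, duct)
    summaries: dict  # duct -> field -> mean/sd/n  (brightness table analogue)
    diffs: dict  # "true_vs_false" -> quantity -> summary + series
    bland_altman: dict  # duct -> Feret-vs-hydraulic agreement
    transitions: list  # split/merge events with adjacent B_AV
    quality: dict  # duct -> BI / CNR / noise
    gt_eval: dict | None  # Dice + relative errors vs ground truth
    params: dict

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {"measurements": out / "measurements.csv"}
        write_measurements(self.measurements, paths["measurements"])
        blobs = {
            "summary": self.summaries,
            "diffs": self.diffs,
            "bland_altman": self.bland_altman,
            "transitions": self.transitions,
            "quality": self.quality,
            "params": self.params,
        }
        if self.gt_eval is not None:
            blobs["ground_truth_eval"] = self.gt_eval
        for name, blob in blobs.items():
            paths[name] = out / f"{name}.json"
            paths[name].write_text(
                json.dumps(_jsonable(blob), indent=2, sort_keys=True) + "\n"
            )
        return paths


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.generic,)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # annotate with the failing stage
                raise PipelineError(f"stage {name!r}: {exc}") from exc

        return wrapped

    return deco


@_stage("input")
def _obtain_volume(config: PipelineConfig):
    if config.dicom_dir is not None:
        return read_dicom_series(config.dicom_dir), None
    pconf = config.phantom
    if config.seed is not None:
        pconf = dataclasses.replace(pconf, seed=config.seed)
    return generate_phantom(pconf)


def _crop(volume: ImageVolume, truth, slice_range):
    if slice_range is None:
        return volume, truth, (0, volume.n_slices)
    start, stop = slice_range
    if not (0 <= start < stop <= volume.n_slices):
        raise PipelineError(
            f"stage 'input': slice_range {slice_range} outside stack "
            f"of {volume.n_slices} slices"
        )
    volume = ImageVolume(
        voxels=volume.voxels[start:stop],
        spacing_mm=volume.spacing_mm,
        origin=volume.origin,
        intensity_units=volume.intensity_units,
        rescale_applied=volume.rescale_applied,
    )
    if truth is not None:
        truth = dataclasses.replace(
            truth,
            labels=truth.labels[start:stop],
            config=dataclasses.replace(
                truth.config,
                grid_size=(*truth.config.grid_size[:2], stop - start),
                split_slice=int(np.clip(truth.config.split_slice - start, 0, stop - start - 1)),
                merge_slice=int(np.clip(truth.config.merge_slice - start, 1, stop - start)),
            ),
        )
    return volume, truth, (start, stop)


def _default_seeds(volume: ImageVolume, truth) -> SeedSet:
    if truth is None:
        raise PipelineError(
            "stage 'seeds': no seeds given and no ground truth to derive them from"
        )
    from scipy import ndimage

    mask = truth.lumen_mask(0)
    dist = ndimage.distance_transform_edt(mask)
    row, col = np.unravel_index(int(np.argmax(dist)), mask.shape)
    return SeedSet([Seed(0, int(row), int(col))])


@_stage("quality")
def _quality_report(volume: ImageVolume, labeling: DuctLabeling, series) -> dict:
    spacing = volume.spacing_mm[:2]
    rows, cols = volume.voxels.shape[1:]
    mid = volume.n_slices // 2
    bg_radius_px = int(np.ceil(np.sqrt(br.BACKGROUND_ROI_AREA_MM2 / np.pi) / min(spacing))) + 1
    bg_rois = [
        br.ROISpec(mid, (rows / 2, bg_radius_px + 1), br.BACKGROUND_ROI_AREA_MM2),
        br.ROISpec(mid, (rows / 2, cols - bg_radius_px - 2), br.BACKGROUND_ROI_AREA_MM2),
    ]
    body = labeling.lumen_mask(mid)
    noise_sd = br.estimate_noise(volume.voxels[mid], bg_rois, spacing, body_mask=body)
    background_mean = float(
        np.mean([br.roi_mean(volume.voxels[mid], r, spacing).mean for r in bg_rois])
    )
    report: dict[str, Any] = {
        "noise_sd": noise_sd,
        "background_mean": background_mean,
        "roi_areas_mm2": {
            "lumen": br.LUMEN_ROI_AREA_MM2,
            "background": br.BACKGROUND_ROI_AREA_MM2,
        },
    }
    for duct in series:
        means = []
        for m in series[duct]:
            if m.is_empty:
                continue
            mask = labeling.mask(m.slice_index, duct)
            try:
                roi = br.centered_lumen_roi(
                    mask, m.slice_index, br.LUMEN_ROI_AREA_MM2, spacing
                )
                means.append(br.roi_mean(volume.voxels[m.slice_index], roi, spacing).mean)
            except ValueError:
                continue  # duct too close to the border for the standard ROI
        if means and noise_sd > 0:
            report[duct] = dataclasses.asdict(
                br.quality_metrics(means, background_mean, noise_sd)
            )
    return report


@_stage("ground-truth-eval")
def _ground_truth_eval(volume: ImageVolume, truth, labeling: DuctLabeling) -> dict:
    """Per-slice Dice and relative errors of area / Feret diameter vs truth."""
    spacing = volume.spacing_mm[:2]
    per_duct: dict[str, dict[str, list]] = {}
    worst = 0.0
    worst_dice = 1.0
    for k in range(volume.n_slices):
        for duct in truth.ducts_on_slice(k):
            gt = truth.mask(k, duct)
            seg = labeling.mask(k, duct)
            d = dice_coefficient(gt, seg)
            if seg.any():
                area_err = abs(float(seg.sum()) - float(gt.sum())) / float(gt.sum())
                dv_g, dh_g = extent_diameters(gt, spacing)
                dv_s, dh_s = extent_diameters(seg, spacing)
                feret_err = abs((dv_s + dh_s) - (dv_g + dh_g)) / (dv_g + dh_g)
            else:
                area_err = feret_err = 1.0
            rec = per_duct.setdefault(
                duct, {"slice": [], "dice": [], "rel_area_err": [], "rel_feret_err": []}
            )
            rec["slice"].append(k)
            rec["dice"].append(d)
            rec["rel_area_err"].append(area_err)
            rec["rel_feret_err"].append(feret_err)
            worst = max(worst, area_err, feret_err)
            worst_dice = min(worst_dice, d)
    mean_dice = float(
        np.mean([v for rec in per_duct.values() for v in rec["dice"]])
    )
    return {
        "per_duct": per_duct,
        "max_relative_error": worst,
        "min_dice": worst_dice,
        "mean_dice": mean_dice,
    }


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run the full analysis and return the report bundle (nothing written)."""
    config.validate()
    volume, truth = _obtain_volume(config)
    volume, truth, analyzed = _crop(volume, truth, config.slice_range)

    seeds = config.seeds or _default_seeds(volume, truth)

    try:
        masks = segment_volume(volume, seeds, config.tolerance, window=config.window)
        labeling = label_ducts(volume, masks, rule=config.labeling_rule)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'segmentation': {exc}") from exc

    try:
        series = measure_series(volume, labeling)
    except Exception as exc:
        raise PipelineError(f"stage 'geometry': {exc}") from exc

    flat = [m for duct in sorted(series) for m in series[duct]]
    frame = measurements_frame(flat)

    summaries = {
        duct: {
            f: dataclasses.asdict(cmp.duct_summary(series[duct], f))
            for f in SUMMARY_FIELDS
        }
        for duct in series
    }

    diffs: dict[str, Any] = {}
    if "true" in series and "false" in series:
        entry = {}
        for q in DIFF_QUANTITIES:
            ds = cmp.diff_series(series["true"], series["false"], q)
            entry[q] = {
                "summary": dataclasses.asdict(cmp.diff_summary(ds)),
                "slice_indices": ds.slice_indices,
                "values": ds.values,
                "raw": ds.raw,
            }
        diffs["true_vs_false"] = entry

    bland = {}
    for duct, s in series.items():
        df = [m.D_F for m in s if not m.is_empty]
        dhy = [m.D_Hy for m in s if not m.is_empty]
        if len(df) >= 3:
            bland[duct] = dataclasses.asdict(st.bland_altman(df, dhy))

    transitions = cmp.detect_transitions(labeling, series)
    quality = _quality_report(volume, labeling, series)
    gt_eval = _ground_truth_eval(volume, truth, labeling) if truth is not None else None

    params = {
        "analyzed_slice_range": list(analyzed),
        "window": list(config.window) if config.window else None,
        "tolerance": config.tolerance,
        "labeling_rule": config.labeling_rule,
        "seeds": [dataclasses.asdict(s) for s in seeds.seeds],
        "spacing_mm": list(volume.spacing_mm),
        "source": "dicom" if config.dicom_dir else "phantom",
        "phantom_config": _jsonable(dataclasses.asdict(config.phantom))
        if config.phantom
        else None,
        "seed_override": config.seed,
    }
    return ReportBundle(
        measurements=frame,
        summaries=summaries,
        diffs=diffs,
        bland_altman=bland,
        transitions=[dataclasses.asdict(t) for t in transitions],
        quality=quality,
        gt_eval=gt_eval,
        params=params,
    )
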