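"""Volume I/O: DICOM series reading/writing, measurement tables, containers.

Conventions (fixed for reproducibility of the extent-based diameters):
slice index, row and column indices are 0-based; the physical position of
a voxel is index * spacing along each axis; in-plane order is (row, col).
Measurement tables are RFC-4180 CSV with "." as the decimal separator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

#: column order of the per-(slice, duct) measurement table
MEASUREMENT_COLUMNS = [
    "slice_index",
    "duct",
    "D_v",
    "D_h",
    "D_F",
    "D_Hy",
    "area",
    "perimeter",
    "B_AV",
    "empty",
]


@dataclass
class ImageVolume:
    """A 3-D intensity grid with physical voxel spacing.

    ``voxels`` has shape (slices, rows, cols); ``spacing_mm`` is
    (row, col, slice) spacing in mm.  Intensities are raw pixel values
    ("Pixels"), not Hounsfield units; ``rescale_applied`` records whether a
    DICOM rescale slope/intercept was folded in at read time.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    intensity_units: str = "pixel"
    rescale_applied: bool = False

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise ValueError("voxels must be a 3-D (slices, rows, cols) array")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite intensities")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def pixel_area_mm2(self) -> float:
        return self.spacing_mm[0] * self.spacing_mm[1]


# ---------------------------------------------------------------------------
# DICOM


def read_dicom_series(path: str | Path) -> ImageVolume:
    """Read a single-series axial DICOM directory into an ImageVolume.

    Slices are ordered by physical position along the slice axis
    (ImagePositionPatient z, falling back to InstanceNumber).  Rescale
    slope/intercept are applied when present.  Mixed series UIDs or
    missing spacing tags raise ``ValueError``.
    """
    path = Path(path)
    files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        raise ValueError(f"no .dcm files found in {path}")
    datasets = [pydicom.dcmread(f) for f in files]

    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(uids) != 1:
        raise ValueError(f"directory mixes {len(uids)} series UIDs; expected one")

    def _z(ds: Dataset) -> float:
        if "ImagePositionPatient" in ds:
            return float(ds.ImagePositionPatient[2])
        return float(ds.InstanceNumber)

    datasets.sort(key=_z)

    first = datasets[0]
    if "PixelSpacing" not in first:
        raise ValueError("series lacks the PixelSpacing tag")
    row_sp, col_sp = (float(v) for v in first.PixelSpacing)

    if len(datasets) > 1 and all("ImagePositionPatient" in ds for ds in datasets):
        zs = np.array([_z(ds) for ds in datasets])
        slice_sp = float(np.mean(np.diff(zs)))
    elif "SliceThickness" in first:
        slice_sp = float(first.SliceThickness)
    else:
        raise ValueError("series lacks both SliceThickness and slice positions")

    slope = float(getattr(first, "RescaleSlope", 1.0))
    intercept = float(getattr(first, "RescaleIntercept", 0.0))
    rescale = (slope, intercept) != (1.0, 0.0)

    stack = np.stack([ds.pixel_array.astype(np.float64) for ds in datasets])
    if rescale:
        stack = stack * slope + intercept

    origin = (0.0, 0.0, 0.0)
    if "ImagePositionPatient" in first:
        x, y, z = (float(v) for v in first.ImagePositionPatient)
        origin = (y, x, z)  # (row, col, slice) physical origin
    return ImageVolume(
        voxels=stack,
        spacing_mm=(row_sp, col_sp, slice_sp),
        origin=origin,
        rescale_applied=rescale,
    )


def write_dicom_series(
    volume: ImageVolume,
    path: str | Path,
    series_description: str = "lumenquant phantom",
    uid_entropy: Sequence[str] = (),
) -> list[Path]:
    """Write the volume as one CT DICOM file per slice.

    Intensities are rounded and clipped to the uint16 range (exact for
    integer-valued, non-negative volumes).  UIDs are derived
    deterministically from ``uid_entropy`` so identical inputs produce
    byte-identical series.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    entropy = [series_description, str(volume.voxels.shape), *map(str, uid_entropy)]
    series_uid = generate_uid(entropy_srcs=entropy + ["series"])
    study_uid = generate_uid(entropy_srcs=entropy + ["study"])
    frame_uid = generate_uid(entropy_srcs=entropy + ["frame"])

    pixels = np.clip(np.round(volume.voxels), 0, np.iinfo(np.uint16).max)
    pixels = pixels.astype(np.uint16)
    row_sp, col_sp, slice_sp = volume.spacing_mm

    written = []
    for k in range(volume.n_slices):
        ds = Dataset()
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = generate_uid(entropy_srcs=entropy + [f"slice{k}"])
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.SeriesDescription = series_description
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [0.0, 0.0, k * slice_sp]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [row_sp, col_sp]
        ds.SliceThickness = slice_sp
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = 0.0
        ds.ContentDate = "20200101"
        ds.ContentTime = "000000"
        ds.Rows, ds.Columns = pixels.shape[1:]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = pixels[k].tobytes()

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta

        out = path / f"slice_{k:04d}.dcm"
        ds.save_as(out, enforce_file_format=True)
        written.append(out)
    return written


# ---------------------------------------------------------------------------
# portable phantom container (lossless)


def write_phantom_bundle(volume: ImageVolume, truth, path: str | Path) -> None:
    """Save volume + ground truth as a compressed array container + JSON sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        path / "phantom.npz", voxels=volume.voxels, labels=truth.labels
    )
    from dataclasses import asdict

    sidecar = {
        "spacing_mm": list(volume.spacing_mm),
        "intensity_units": volume.intensity_units,
        "per_region_mean": truth.per_region_mean,
        "config": _jsonable(asdict(truth.config)),
    }
    (path / "ground_truth.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_phantom_bundle(path: str | Path):
    """Load a phantom bundle; returns (ImageVolume, labels array, sidecar dict)."""
    path = Path(path)
    arrays = np.load(path / "phantom.npz")
    sidecar = json.loads((path / "ground_truth.json").read_text())
    volume = ImageVolume(
        voxels=arrays["voxels"],
        spacing_mm=tuple(sidecar["spacing_mm"]),
        intensity_units=sidecar["intensity_units"],
    )
    return volume, arrays["labels"], sidecar


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# measurement tables


def measurements_frame(measurements: Iterable) -> pd.DataFrame:
    """Assemble CrossSectionMetrics rows into the canonical table."""
    rows = []
    for m in measurements:
        rows.append(
            {
                "slice_index": m.slice_index,
                "duct": m.duct,
                "D_v": m.D_v,
                "D_h": m.D_h,
                "D_F": m.D_F,
                "D_Hy": m.D_Hy,
                "area": m.area,
                "perimeter": m.perimeter,
                "B_AV": m.B_AV,
                "empty": m.is_empty,
            }
        )
    if not rows:
        raise ValueError("no measurements to write")
    frame = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    return frame.sort_values(["slice_index", "duct"], kind="stable").reset_index(
        drop=True
    )


def write_measurements(measurements, path: str | Path) -> pd.DataFrame:
    """Write one CSV row per (slice, duct); empty ducts flagged, fields blank.

    Numbers are mm / mm^2 / pixels, written with 6-decimal precision.
    Returns the frame that was written.
    """
    frame = (
        measurements
        if isinstance(measurements, pd.DataFrame)
        else measurements_frame(measurements)
    )
    frame.to_csv(path, index=False, float_format="%.6f", lineterminator="\n")
    return frame


def read_measurements(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
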