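"""Readers and writers for the formats the pipeline touches.

The canonical on-disk format for image stacks is a "raw container": a
directory holding ``voxels.npy`` plus a JSON sidecar ``meta.json`` with the
geometry (pixel spacing, slice thickness) and free-form labels.  DICOM
series are supported read-mostly (HU values after rescale slope/intercept,
slices ordered by position); a minimal DICOM writer is provided for
round-trip testing and interoperability.

Ratings travel as CSV with header
``case_id,reader_id,question_id,condition,rating,scale_size``; PS curves and
dose records as CSV; summaries as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dose import DoseRecord
from .ps import PSCurve1D
from .ratings import RATING_COLUMNS, RatingSet
from .stack import ImageStack

__all__ = [
    "write_stack", "read_stack", "write_dicom_series",
    "write_ratings", "read_ratings",
    "write_curve", "read_curve",
    "write_dose_records", "read_dose_records",
]

_META_NAME = "meta.json"
_VOXEL_NAME = "voxels.npy"


# ---------------------------------------------------------------- stacks

def write_stack(stack: ImageStack, path) -> Path:
    """Write a stack as a raw container directory (voxels.npy + meta.json)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / _VOXEL_NAME, stack.voxels)
    meta = {
        "pixel_spacing_mm": stack.pixel_spacing,
        "slice_thickness_mm": stack.slice_thickness,
        "shape": list(stack.voxels.shape),
        "labels": stack.labels,
    }
    (path / _META_NAME).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def _read_raw_container(path: Path) -> ImageStack:
    meta = json.loads((path / _META_NAME).read_text())
    voxels = np.load(path / _VOXEL_NAME)
    return ImageStack(voxels=voxels, pixel_spacing=meta["pixel_spacing_mm"],
                      slice_thickness=meta["slice_thickness_mm"],
                      labels=meta.get("labels", {}))


def _read_dicom_series(path: Path) -> ImageStack:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".dcm", ".ima"))
    if not files:
        files = sorted(p for p in path.iterdir() if p.is_file() and p.name != _META_NAME)
    datasets = [pydicom.dcmread(str(f)) for f in files]
    if not datasets:
        raise ValueError(f"no DICOM files found in {path}")

    def z_pos(ds):
        if "ImagePositionPatient" in ds:
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=z_pos)
    spacings = {tuple(round(float(v), 6) for v in ds.PixelSpacing) for ds in datasets}
    if len(spacings) != 1:
        raise ValueError(f"inconsistent pixel spacing within series: {sorted(spacings)}")
    sp_row, sp_col = spacings.pop()
    if not np.isclose(sp_row, sp_col):
        raise ValueError("anisotropic in-plane pixel spacing is not supported")
    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    thickness = float(getattr(datasets[0], "SliceThickness", 1.0))
    return ImageStack(voxels=np.stack(slices), pixel_spacing=float(sp_row),
                      slice_thickness=thickness,
                      labels={"source": "dicom", "path": str(path)})


def read_stack(path) -> ImageStack:
    """Read a stack from a raw container directory or a DICOM series directory."""
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"{path} is not a directory")
    if (path / _META_NAME).exists() and (path / _VOXEL_NAME).exists():
        return _read_raw_container(path)
    return _read_dicom_series(path)


def write_dicom_series(stack: ImageStack, path) -> Path:
    """Write a minimal CT DICOM series (16-bit, slope 1 / intercept -1024)."""
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    intercept = -1024.0
    for i, slice_img in enumerate(stack.voxels):
        stored = np.round(slice_img - intercept).astype(np.uint16)
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
        ds.SOPClassUID = pydicom.uid.CTImageStorage
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = [0.0, 0.0, i * stack.slice_thickness]
        ds.PixelSpacing = [stack.pixel_spacing, stack.pixel_spacing]
        ds.SliceThickness = stack.slice_thickness
        ds.Rows, ds.Columns = stored.shape
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = intercept
        ds.PixelData = stored.tobytes()
        ds.save_as(str(path / f"slice{i + 1:04d}.dcm"), enforce_file_format=True)
    return path


# ---------------------------------------------------------------- ratings

def write_ratings(ratings: RatingSet, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ratings.data.to_csv(path, index=False, columns=RATING_COLUMNS)
    return path


def read_ratings(path, conditions=None) -> RatingSet:
    """Read and validate a ratings CSV.

    ``conditions`` is the ordered (reference, test) pair; if omitted, the two
    condition labels are taken in sorted order (first = reference).
    """
    df = pd.read_csv(path, dtype={"case_id": str, "reader_id": str,
                                  "question_id": str, "condition": str})
    missing = [c for c in RATING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("rating", "scale_size"):
        if not np.issubdtype(df[col].dtype, np.integer):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
            if len(bad):
                raise ValueError(f"{path}: non-integer {col} at row {bad.index[0] + 2}")
            df[col] = df[col].astype(int)
    out_of_range = df[(df["rating"] < 1) | (df["rating"] > df["scale_size"])]
    if len(out_of_range):
        raise ValueError(f"{path}: rating out of 1..scale_size range at row "
                         f"{out_of_range.index[0] + 2}")  # +2: header + 0-base
    dup = df.duplicated(subset=["case_id", "reader_id", "question_id", "condition"])
    if dup.any():
        raise ValueError(f"{path}: duplicate (case, reader, question, condition) "
                         f"at row {df.index[dup][0] + 2}")
    if conditions is None:
        found = sorted(df["condition"].unique())
        if len(found) != 2:
            raise ValueError(f"{path}: expected exactly 2 conditions, found {found}")
        conditions = tuple(found)
    return RatingSet(data=df, conditions=tuple(conditions))


# ---------------------------------------------------------------- curves

def write_curve(curve: PSCurve1D, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"freq_mm^-1": curve.bin_freq, "ps_hu2mm2": curve.ps})
    if curve.relative_se is not None:
        df["relative_se_pct"] = curve.relative_se
    df.to_csv(path, index=False)
    return path


def read_curve(path) -> PSCurve1D:
    df = pd.read_csv(path)
    rse = df["relative_se_pct"].to_numpy() if "relative_se_pct" in df.columns else None
    return PSCurve1D(bin_freq=df["freq_mm^-1"].to_numpy(),
                     ps=df["ps_hu2mm2"].to_numpy(), relative_se=rse)


# ---------------------------------------------------------------- dose

def write_dose_records(records: Sequence[DoseRecord], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([{
        "patient_id": r.patient_id, "protocol": r.protocol,
        "ctdi_vol_mgy": r.ctdi_vol, "dlp_mgycm": r.dlp,
    } for r in records]).to_csv(path, index=False)
    return path


def read_dose_records(path, k_factor: float = None) -> list:
    from .dose import CHEST_K_FACTOR
    k = CHEST_K_FACTOR if k_factor is None else k_factor
    df = pd.read_csv(path, dtype={"patient_id": str, "protocol": str})
    return [DoseRecord(patient_id=row.patient_id, protocol=row.protocol,
                       ctdi_vol=float(row.ctdi_vol_mgy), dlp=float(row.dlp_mgycm),
                       k_factor=k)
            for row in df.itertuples()]
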