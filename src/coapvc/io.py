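"""File formats: TAC CSV, 4-D NIfTI + JSON sidecar, DICOM read.

Conventions, stated in every file written:

* frame times are seconds, start-of-frame plus duration, half-open
  intervals ``[start, start + duration)``;
* activities are kBq/cc, volumes cc;
* the canonical image interchange is one 4-D NIfTI (4th dim = frames)
  with a JSON sidecar carrying the frame schedule and units.  DICOM
  directories are read-only convenience.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParseError
from .phantom import DynamicImage
from .tac import TimeActivityCurve

__all__ = [
    "read_tac_csv",
    "write_tac_csv",
    "read_dynamic_image",
    "write_dynamic_image",
    "read_label_mask",
]

_VALUE_COLUMNS = ("value_kBq_per_cc", "value_HU", "value")


def write_tac_csv(tac: TimeActivityCurve, path) -> None:
    """Write a TAC as CSV with columns frame_start_s, frame_duration_s, value."""
    value_col = "value_HU" if tac.unit == "HU" else "value_kBq_per_cc"
    df = pd.DataFrame({
        "frame_start_s": tac.frame_start,
        "frame_duration_s": tac.frame_duration,
        value_col: tac.values,
    })
    df.to_csv(path, index=False)


def read_tac_csv(path) -> TimeActivityCurve:
    """Read a TAC CSV; raises :class:`ParseError` naming the offending row."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"could not read TAC CSV {path}: {exc}") from exc
    for col in ("frame_start_s", "frame_duration_s"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    value_col = next((c for c in _VALUE_COLUMNS if c in df.columns), None)
    if value_col is None:
        raise ParseError(
            f"{path}: no value column (expected one of {_VALUE_COLUMNS})"
        )
    unit = "HU" if value_col == "value_HU" else "kBq/cc"
    return TimeActivityCurve(df["frame_start_s"].to_numpy(float),
                             df["frame_duration_s"].to_numpy(float),
                             df[value_col].to_numpy(float), unit=unit)


# ----------------------------------------------------------------------
# NIfTI + sidecar
# ----------------------------------------------------------------------
def _sidecar_path(image_path: Path) -> Path:
    name = image_path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return image_path.with_name(name[: -len(suffix)] + ".json")
    return image_path.with_suffix(".json")


def write_dynamic_image(image: DynamicImage, path) -> None:
    """Write a 4-D NIfTI plus its JSON frame-schedule sidecar."""
    import nibabel as nib

    path = Path(path)
    affine = np.diag([*image.voxel_size, 1.0])
    nib.save(nib.Nifti1Image(image.data.astype(np.float32), affine), path)
    sidecar = {
        "frame_start_s": list(map(float, image.frame_start)),
        "frame_duration_s": list(map(float, image.frame_duration)),
        "unit": image.unit,
        "convention": "frames are half-open [start, start+duration) in seconds",
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))


def read_dynamic_image(path, unit: str | None = None) -> DynamicImage:
    """Read a 4-D dynamic image.

    ``path`` may be a 4-D NIfTI (requiring its JSON sidecar next to it) or
    a directory of per-frame DICOM series.  A missing sidecar or a frame
    count mismatch is an explicit error — no silent defaults.
    """
    path = Path(path)
    if path.is_dir():
        return _read_dicom_dir(path, unit=unit)
    import nibabel as nib

    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ParseError(f"{path}: expected a 4-D image, got shape {data.shape}")
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise ParseError(
            f"{path}: missing frame-schedule sidecar {sidecar_path.name}"
        )
    sidecar = json.loads(sidecar_path.read_text())
    starts = np.asarray(sidecar["frame_start_s"], float)
    durs = np.asarray(sidecar["frame_duration_s"], float)
    if starts.size != data.shape[3]:
        raise ParseError(
            f"{path}: image has {data.shape[3]} frames but sidecar lists {starts.size}"
        )
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DynamicImage(data, voxel_size, starts, durs,
                        unit=unit or sidecar.get("unit", "kBq/cc"))


def read_label_mask(path, label: int) -> tuple[np.ndarray, float]:
    """Read a NIfTI integer label mask into a binary occupancy map.

    For patient-like images with no analytic geometry the region volume is
    taken from the supplied contour: returns ``(occupancy, volume_cc)``
    with occupancy 1.0 where the mask equals ``label``.  The occupancy
    plugs straight into :func:`coapvc.rois.extract_tac`.
    """
    import nibabel as nib

    img = nib.load(path)
    mask = np.asarray(img.dataobj)
    if mask.ndim != 3:
        raise ParseError(f"{path}: expected a 3-D label mask, got shape {mask.shape}")
    occ = (np.rint(mask) == label).astype(np.float32)
    if occ.sum() == 0:
        raise ParseError(f"{path}: label {label} not present in the mask")
    voxel_cc = float(np.prod(img.header.get_zooms()[:3])) / 1000.0
    return occ, float(occ.sum() * voxel_cc)


def _read_dicom_dir(path: Path, unit: str | None = None) -> DynamicImage:
    """Assemble a dynamic image from a directory of DICOM slices.

    Slices are grouped into frames by AcquisitionNumber, ordered within a
    frame by slice position; the schedule comes from FrameReferenceTime
    (ms) and ActualFrameDuration (ms).  RescaleSlope/Intercept are applied.
    """
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix != ".json")
    if not files:
        raise ParseError(f"{path}: no DICOM files found")
    frames: dict[int, list] = {}
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception as exc:
            raise ParseError(f"{f}: not a readable DICOM file: {exc}") from exc
        acq = int(getattr(ds, "AcquisitionNumber", 1) or 1)
        frames.setdefault(acq, []).append(ds)

    starts, durs, volumes = [], [], []
    spacing = None
    for acq in sorted(frames):
        slices = sorted(frames[acq],
                        key=lambda d: float(d.ImagePositionPatient[2]))
        arrs = []
        for ds in slices:
            slope = float(getattr(ds, "RescaleSlope", 1.0))
            inter = float(getattr(ds, "RescaleIntercept", 0.0))
            arrs.append(ds.pixel_array.astype(np.float64) * slope + inter)
        # DICOM pixel_array is (row=y, col=x); transpose to (x, y)
        vol = np.stack([a.T for a in arrs], axis=-1)
        volumes.append(vol)
        ds0 = slices[0]
        try:
            starts.append(float(ds0.FrameReferenceTime) / 1000.0)
            durs.append(float(ds0.ActualFrameDuration) / 1000.0)
        except AttributeError as exc:
            raise ParseError(
                f"{path}: DICOM frame {acq} lacks FrameReferenceTime/"
                f"ActualFrameDuration needed for the schedule"
            ) from exc
        px = [float(v) for v in ds0.PixelSpacing]
        dz = float(getattr(ds0, "SpacingBetweenSlices",
                           getattr(ds0, "SliceThickness", 1.0)))
        spacing = (px[1], px[0], dz)  # PixelSpacing is (row, col)
    shapes = {v.shape for v in volumes}
    if len(shapes) != 1:
        raise ParseError(f"{path}: inconsistent frame volume shapes {shapes}")
    data = np.stack(volumes, axis=-1)
    return DynamicImage(data, spacing, np.asarray(starts), np.asarray(durs),
                        unit=unit or "kBq/cc")
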