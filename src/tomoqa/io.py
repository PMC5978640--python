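"""Volume and report I/O.

Volumes are exchanged as DICOM (multi-frame secondary capture or a
single-frame series) or as a stacked TIFF with a JSON sidecar.  Reading
never alters intensities beyond applying the declared DICOM rescale
slope/intercept, which is recorded in the volume metadata.

Because no cross-vendor pixel-value scale exists for tomosynthesis, all
contrast metrics downstream are ratios or percent differences; the reader
therefore makes no attempt to normalise intensities.

Reports are emitted as machine-readable JSON plus a human-readable CSV
with a fixed column order; identical inputs produce byte-identical files.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
import tifffile

from .volume import ReconVolume

__all__ = ["read_volume", "write_volume", "ReportRecord", "write_report",
           "read_report"]

REPORT_SCHEMA_VERSION = 1

_MULTIFRAME_SC = "1.2.840.10008.5.1.4.1.1.7.2"  # multi-frame grayscale word SC
_SC = "1.2.840.10008.5.1.4.1.1.7"

# deterministic UID root for simulator output (research use only)
_UID_PREFIX = "2.25."


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def dump_json(obj, path: str | Path) -> None:
    """Canonical JSON dump: sorted keys, fixed separators, trailing newline."""
    text = json.dumps(obj, indent=1, sort_keys=True, default=_json_default)
    Path(path).write_text(text + "\n")


# ---------------------------------------------------------------------------
# volume writing
# ---------------------------------------------------------------------------

def _quantize(arr: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Map float intensities to uint16 with rescale slope/intercept.

    Integer-valued volumes within uint16 range are stored losslessly with
    slope 1, intercept 0 (voxel-identical round trip); anything else is
    scaled across the full 16-bit range.
    """
    a = np.asarray(arr)
    if np.allclose(a, np.round(a), atol=0.0) and a.min() >= 0 and a.max() <= 65535:
        return a.astype(np.uint16), 1.0, 0.0
    lo = float(a.min())
    hi = float(a.max())
    slope = (hi - lo) / 65535.0 if hi > lo else 1.0
    stored = np.round((a - lo) / slope).astype(np.uint16)
    return stored, slope, lo


def _base_dataset(vol: ReconVolume, sop_class: str, uid_seed: str) -> Dataset:
    ds = Dataset()
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = generate_uid(entropy_srcs=[uid_seed])
    ds.SeriesInstanceUID = generate_uid(entropy_srcs=[uid_seed, "series"])
    ds.StudyInstanceUID = generate_uid(entropy_srcs=[uid_seed, "study"])
    ds.Modality = "OT"
    ds.PatientName = "QA^Phantom"
    ds.PatientID = "TOMOQA"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    dz, dy, dx = vol.spacing
    ds.PixelSpacing = [f"{dy:.6g}", f"{dx:.6g}"]
    ds.SpacingBetweenSlices = f"{dz:.6g}"
    ds.SliceThickness = f"{vol.metadata.get('nominal_slice_width_mm', dz):.6g}"
    x0, y0, z0 = vol.origin
    ds.ImagePositionPatient = [f"{x0:.6g}", f"{y0:.6g}", f"{z0:.6g}"]
    ds.ImageOrientationPatient = ["1", "0", "0", "0", "1", "0"]
    ds.Rows, ds.Columns = vol.shape[1], vol.shape[2]
    return ds


def _save(ds: Dataset, path: Path) -> None:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = ds.SOPClassUID
    meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds.file_meta = meta
    ds.save_as(path, enforce_file_format=True)


def write_volume(vol: ReconVolume, path: str | Path,
                 fmt: str = "dicom-multiframe") -> list[Path]:
    """Write a volume; returns the list of files written.

    ``fmt``: ``dicom-multiframe`` (single file), ``dicom-series`` (one file
    per slice in a directory) or ``tiff`` (float32 stack + JSON sidecar,
    always lossless).
    """
    path = Path(path)
    uid_seed = f"tomoqa:{vol.shape}:{vol.metadata.get('seed', 0)}"
    if fmt == "tiff":
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, vol.intensities.astype(np.float32))
        sidecar = path.with_suffix(".json")
        dump_json({"spacing_zyx_mm": list(vol.spacing),
                   "origin_xyz_mm": list(vol.origin),
                   "metadata": vol.metadata}, sidecar)
        return [path, sidecar]

    stored, slope, intercept = _quantize(vol.intensities)
    if fmt == "dicom-multiframe":
        ds = _base_dataset(vol, _MULTIFRAME_SC, uid_seed)
        ds.NumberOfFrames = vol.shape[0]
        ds.RescaleSlope = f"{slope:.10g}"
        ds.RescaleIntercept = f"{intercept:.10g}"
        ds.PixelData = stored.tobytes()
        path.parent.mkdir(parents=True, exist_ok=True)
        _save(ds, path)
        return [path]
    if fmt == "dicom-series":
        path.mkdir(parents=True, exist_ok=True)
        files = []
        dz = vol.spacing[0]
        series_uid = generate_uid(entropy_srcs=[uid_seed, "series"])
        study_uid = generate_uid(entropy_srcs=[uid_seed, "study"])
        for k in range(vol.shape[0]):
            ds = _base_dataset(vol, _SC, f"{uid_seed}:{k}")
            ds.SeriesInstanceUID = series_uid
            ds.StudyInstanceUID = study_uid
            ds.InstanceNumber = k + 1
            x0, y0, z0 = vol.origin
            ds.ImagePositionPatient = [f"{x0:.6g}", f"{y0:.6g}",
                                       f"{z0 + k * dz:.6g}"]
            ds.RescaleSlope = f"{slope:.10g}"
            ds.RescaleIntercept = f"{intercept:.10g}"
            ds.PixelData = stored[k].tobytes()
            f = path / f"slice_{k:04d}.dcm"
            _save(ds, f)
            files.append(f)
        return files
    raise ValueError(f"unknown volume format {fmt!r}")


# ---------------------------------------------------------------------------
# volume reading
# ---------------------------------------------------------------------------

def _require(ds: Dataset, tag: str):
    if tag not in ds:
        raise ValueError(f"DICOM file is missing required tag {tag}")
    return ds.data_element(tag).value


def _check_orientation(ds: Dataset) -> None:
    """Warn when orientation tags conflict with the chest-wall-at-row-0
    convention; the configured convention wins."""
    iop = getattr(ds, "ImageOrientationPatient", None)
    if iop is not None and not np.allclose([float(v) for v in iop],
                                           [1, 0, 0, 0, 1, 0]):
        warnings.warn(
            "DICOM orientation differs from the configured chest-wall "
            "edge convention (row 0 at the wall); using the configuration",
            stacklevel=3)


def _frame_array(ds: Dataset) -> np.ndarray:
    arr = ds.pixel_array.astype(np.float32)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    if slope != 1.0 or intercept != 0.0:
        arr = arr * slope + intercept
    return arr


def _read_multiframe(path: Path) -> ReconVolume:
    ds = pydicom.dcmread(path)
    _check_orientation(ds)
    dy, dx = (float(v) for v in _require(ds, "PixelSpacing"))
    dz = float(_require(ds, "SpacingBetweenSlices"))
    pos = [float(v) for v in _require(ds, "ImagePositionPatient")]
    arr = _frame_array(ds)
    if arr.ndim == 2:
        arr = arr[None]
    meta = {"rescale_slope": float(getattr(ds, "RescaleSlope", 1.0)),
            "rescale_intercept": float(getattr(ds, "RescaleIntercept", 0.0)),
            "slice_thickness_mm": float(getattr(ds, "SliceThickness", dz))}
    return ReconVolume(arr, spacing=(dz, dy, dx),
                       origin=(pos[0], pos[1], pos[2]), metadata=meta)


def _read_series(path: Path) -> ReconVolume:
    files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        raise ValueError(f"no DICOM files found in {path}")
    frames = []
    for f in files:
        ds = pydicom.dcmread(f)
        dy, dx = (float(v) for v in _require(ds, "PixelSpacing"))
        pos = [float(v) for v in _require(ds, "ImagePositionPatient")]
        frames.append((pos[2], pos, (dy, dx), _frame_array(ds)))
    frames.sort(key=lambda t: t[0])  # slices ordered by increasing z
    zs = np.array([f[0] for f in frames])
    dz_all = np.diff(zs)
    if len(dz_all) == 0:
        raise ValueError("series must contain at least two slices")
    dz = float(np.mean(dz_all))
    if dz <= 0:
        raise ValueError("series slice positions are not strictly increasing")
    if np.any(np.abs(dz_all - dz) > 0.01 * dz):
        raise ValueError("inconsistent inter-slice spacing (beyond 1%)")
    dy, dx = frames[0][2]
    arr = np.stack([f[3] for f in frames])
    pos0 = frames[0][1]
    return ReconVolume(arr, spacing=(dz, dy, dx),
                       origin=(pos0[0], pos0[1], zs[0]),
                       metadata={"n_files": len(files)})


def _read_tiff(path: Path) -> ReconVolume:
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise ValueError(f"TIFF volume requires a JSON sidecar at {sidecar}")
    info = json.loads(sidecar.read_text())
    for key in ("spacing_zyx_mm", "origin_xyz_mm"):
        if key not in info:
            raise ValueError(f"sidecar is missing required field {key!r}")
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return ReconVolume(arr.astype(np.float32),
                       spacing=tuple(info["spacing_zyx_mm"]),
                       origin=tuple(info["origin_xyz_mm"]),
                       metadata=info.get("metadata", {}))


def read_volume(path: str | Path, fmt: str | None = None) -> ReconVolume:
    """Read a reconstructed volume.

    ``fmt`` is one of ``dicom-series``, ``dicom-multiframe``,
    ``tiff+json`` or None (sniffed from the path).  Slices are ordered by
    increasing z and spacings are populated from metadata; missing spacing
    tags are a hard error naming the tag.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        if path.is_dir():
            fmt = "dicom-series"
        elif path.suffix.lower() in (".tif", ".tiff"):
            fmt = "tiff+json"
        else:
            fmt = "dicom-multiframe"
    if fmt == "dicom-series":
        return _read_series(path)
    if fmt == "dicom-multiframe":
        return _read_multiframe(path)
    if fmt in ("tiff", "tiff+json"):
        return _read_tiff(path)
    raise ValueError(f"unknown volume format {fmt!r}")


# ---------------------------------------------------------------------------
# report records
# ---------------------------------------------------------------------------

@dataclass
class ReportRecord:
    """One computed QA metric with units and ROI/curve provenance."""

    name: str
    value: float | list | dict
    units: str
    provenance: dict = field(default_factory=dict)
    status: str = "ok"  # ok | flagged | failed

    def __post_init__(self) -> None:
        if not self.units:
            raise ValueError("every numeric value must carry units "
                             "(use 'ratio', 'percent' or '1' if unitless)")
        if not self.provenance:
            raise ValueError("provenance must be non-empty")

    def to_dict(self) -> dict:
        return {"name": self.name, "value": self.value, "units": self.units,
                "provenance": self.provenance, "status": self.status}


_CSV_COLUMNS = ("name", "value", "units", "status")


def write_report(records: list[ReportRecord], out_dir: str | Path,
                 header: dict | None = None,
                 stem: str = "qa_report") -> tuple[Path, Path]:
    """Write the QA report as JSON + CSV; returns both paths.

    Re-running on identical input is byte-identical: nothing derived from
    the wall clock is written (timestamps, when present, come from the
    acquisition metadata in ``header``).
    """
    if not records:
        raise ValueError("records must be non-empty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    doc = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "header": header or {},
        "records": [r.to_dict() for r in records],
    }
    json_path = out_dir / f"{stem}.json"
    dump_json(doc, json_path)
    csv_path = out_dir / f"{stem}.csv"
    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_CSV_COLUMNS)
        for r in records:
            val = r.value
            if isinstance(val, (list, dict, np.ndarray)):
                val = json.dumps(val, default=_json_default)
            w.writerow([r.name, val, r.units, r.status])
    return json_path, csv_path


def read_report(json_path: str | Path) -> dict:
    doc = json.loads(Path(json_path).read_text())
    if doc.get("schema_version") != REPORT_SCHEMA_VERSION:
        raise ValueError("unsupported report schema version")
    return doc
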