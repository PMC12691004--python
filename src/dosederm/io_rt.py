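"""Reading and writing of the cohort exchange layout.

A cohort is a directory tree with one sub-directory per patient holding a
DICOM CT series (``ct_*.dcm``), an RT-STRUCT (``rs.dcm``) and an RT-DOSE
(``rd.dcm``), plus a cohort-level ``clinical.csv`` and ``manifest.json``.

Geometry conventions follow :mod:`dosederm.core`: grids are axis-aligned
(identity orientation; oblique series are rejected), arrays are indexed
``[z, y, x]`` and world coordinates are voxel centers in mm.  Contours are
rasterized with the even-odd rule: a voxel belongs to a structure iff its
center lies inside an odd number of that structure's polygons on the slice.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from dosederm.core import ClinicalRecord, ImageGrid, StructureMask
from dosederm.dicom import (
    SOP_CLASS_CT,
    SOP_CLASS_RTDOSE,
    SOP_CLASS_RTSTRUCT,
    TAG,
    make_uid,
    read_file,
    write_file,
)

_AXIAL_ORIENTATION = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0)


def _require_axial(orientation) -> None:
    if orientation is None:
        return
    if not np.allclose(orientation, _AXIAL_ORIENTATION, atol=1e-6):
        raise ValueError("oblique acquisition: only axis-aligned axial grids supported")


# ---------------------------------------------------------------------------
# readers

def read_ct_series(directory) -> ImageGrid:
    """Load a single-series axial CT stack into HU.

    Slices are sorted by their z position; pixel values are converted to HU
    with the per-file rescale slope/intercept.
    """
    directory = Path(directory)
    files = sorted(directory.glob("ct_*.dcm"))
    if len(files) < 2:
        raise ValueError("inconsistent series: need >= 2 CT slices")
    slices = []
    series_uids = set()
    frame_id = ""
    for f in files:
        ds = read_file(f)
        if ds.get(TAG["Modality"]) != "CT":
            continue
        series_uids.add(ds.get(TAG["SeriesInstanceUID"]))
        _require_axial(ds.get(TAG["ImageOrientationPatient"]))
        frame_id = ds.get(TAG["FrameOfReferenceUID"], "")
        pos = ds[TAG["ImagePositionPatient"]]
        rows, cols = ds[TAG["Rows"]], ds[TAG["Columns"]]
        raw = np.frombuffer(ds[TAG["PixelData"]], dtype="<u2", count=rows * cols)
        stored = raw.reshape(rows, cols).astype(np.float64)
        slope = float(ds.get(TAG["RescaleSlope"], 1.0))
        intercept = float(ds.get(TAG["RescaleIntercept"], 0.0))
        hu = stored * slope + intercept
        spacing_yx = ds[TAG["PixelSpacing"]]
        slices.append((float(pos[2]), float(pos[1]), float(pos[0]),
                       float(spacing_yx[0]), float(spacing_yx[1]), hu))
    if len(series_uids) > 1:
        raise ValueError("multiple series in directory")
    if len(slices) < 2:
        raise ValueError("inconsistent series: need >= 2 CT slices")
    slices.sort(key=lambda s: s[0])
    zs = np.array([s[0] for s in slices])
    dz = np.diff(zs)
    if np.any(dz <= 0):
        raise ValueError("inconsistent series: missing/duplicate slice positions")
    if not np.allclose(dz, dz[0], atol=1e-4):
        raise ValueError("inconsistent series: non-uniform slice spacing")
    z0, y0, x0, sy, sx, _ = slices[0]
    values = np.stack([s[5] for s in slices])
    return ImageGrid(values, spacing=(float(dz[0]), sy, sx),
                     origin=(z0, y0, x0), frame_id=frame_id)


def points_in_polygon(poly_xy: np.ndarray, px: np.ndarray, py: np.ndarray) -> np.ndarray:
    """Even-odd (ray-casting) point-in-polygon test, vectorized over points."""
    poly_xy = np.asarray(poly_xy, dtype=float)
    px = np.asarray(px, dtype=float)
    py = np.asarray(py, dtype=float)
    inside = np.zeros(px.shape, dtype=bool)
    n = len(poly_xy)
    for i in range(n):
        x1, y1 = poly_xy[i]
        x2, y2 = poly_xy[(i + 1) % n]
        crosses = (y1 > py) != (y2 > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at = (x2 - x1) * (py - y1) / (y2 - y1) + x1
        inside ^= crosses & (px < x_at)
    return inside


def rasterize_contours(contours, ref: ImageGrid, name: str) -> StructureMask:
    """Rasterize planar polygons onto the reference grid.

    ``contours`` is a list of ``(z_mm, (N,2) array of (x,y) mm)`` closed
    polygons.  Polygons on the same slice combine by even-odd parity, so a
    hole contour carves out its interior.
    """
    mask = np.zeros(ref.shape, dtype=bool)
    zc, yc, xc = ref.axis_centers()
    gx, gy = np.meshgrid(xc, yc)  # (ny, nx)
    for z_mm, poly in contours:
        k = int(np.argmin(np.abs(zc - z_mm)))
        if abs(zc[k] - z_mm) > ref.spacing[0] / 2 + 1e-6:
            raise ValueError(f"unaligned contour at z={z_mm}")
        mask[k] ^= points_in_polygon(poly, gx, gy)
    return StructureMask(name, mask)


def read_rtstruct(file, ref: ImageGrid) -> list[StructureMask]:
    """Read an RT-STRUCT and rasterize each ROI onto the reference grid."""
    ds = read_file(file)
    names = {}
    for item in ds.get(TAG["StructureSetROISequence"], []):
        names[int(item[TAG["ROINumber"]])] = item[TAG["ROIName"]]
    masks = []
    for roi in ds.get(TAG["ROIContourSequence"], []):
        number = int(roi[TAG["ReferencedROINumber"]])
        contours = []
        for c in roi.get(TAG["ContourSequence"], []):
            data = np.asarray(c[TAG["ContourData"]], dtype=float).reshape(-1, 3)
            contours.append((float(data[0, 2]), data[:, :2]))
        masks.append(rasterize_contours(contours, ref, names.get(number, str(number))))
    return masks


def read_rtdose(file) -> ImageGrid:
    """Read an RT-DOSE grid into Gy (stored integers x dose-grid scaling)."""
    ds = read_file(file)
    if TAG["DoseGridScaling"] not in ds:
        raise ValueError("unscaled dose: DoseGridScaling missing")
    scaling = float(ds[TAG["DoseGridScaling"]])
    _require_axial(ds.get(TAG["ImageOrientationPatient"]))
    rows, cols = ds[TAG["Rows"]], ds[TAG["Columns"]]
    n_frames = int(ds[TAG["NumberOfFrames"]])
    raw = np.frombuffer(ds[TAG["PixelData"]], dtype="<u4",
                        count=n_frames * rows * cols)
    values = raw.reshape(n_frames, rows, cols).astype(np.float64) * scaling
    pos = ds[TAG["ImagePositionPatient"]]
    spacing_yx = ds[TAG["PixelSpacing"]]
    offsets = np.atleast_1d(np.asarray(ds[TAG["GridFrameOffsetVector"]], dtype=float))
    dz = np.diff(offsets)
    if len(offsets) > 1 and not np.allclose(dz, dz[0], atol=1e-6):
        raise ValueError("non-uniform dose frame offsets")
    dz0 = float(dz[0]) if len(offsets) > 1 else 1.0
    return ImageGrid(values,
                     spacing=(dz0, float(spacing_yx[0]), float(spacing_yx[1])),
                     origin=(float(pos[2]) + float(offsets[0]),
                             float(pos[1]), float(pos[0])),
                     frame_id=ds.get(TAG["FrameOfReferenceUID"], ""))


# ---------------------------------------------------------------------------
# writers (synthetic cohorts and fixtures only)

def write_ct_series(grid: ImageGrid, directory, patient_id: str = "anon",
                    intercept: float = -1024.0) -> None:
    """Write a CT grid as one Part-10 file per slice (slope 1)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = make_uid("series")
    study_uid = make_uid("study")
    frame_uid = grid.frame_id or make_uid("frame")
    nz, ny, nx = grid.shape
    stored = np.round(grid.values - intercept)
    if stored.min() < 0 or stored.max() > 0xFFFF:
        raise ValueError("HU values out of storable range")
    stored = stored.astype("<u2")
    for k in range(nz):
        z, y, x = grid.world_coords((k, 0, 0))
        ds = {
            TAG["SOPClassUID"]: SOP_CLASS_CT,
            TAG["SOPInstanceUID"]: make_uid("ct"),
            TAG["Modality"]: "CT",
            TAG["PatientID"]: patient_id,
            TAG["StudyInstanceUID"]: study_uid,
            TAG["SeriesInstanceUID"]: series_uid,
            TAG["FrameOfReferenceUID"]: frame_uid,
            TAG["ImagePositionPatient"]: [x, y, z],
            TAG["ImageOrientationPatient"]: list(_AXIAL_ORIENTATION),
            TAG["PixelSpacing"]: [grid.spacing[1], grid.spacing[2]],
            TAG["SliceThickness"]: grid.spacing[0],
            TAG["SamplesPerPixel"]: 1,
            TAG["Rows"]: ny,
            TAG["Columns"]: nx,
            TAG["BitsAllocated"]: 16,
            TAG["BitsStored"]: 16,
            TAG["HighBit"]: 15,
            TAG["PixelRepresentation"]: 0,
            TAG["RescaleSlope"]: 1.0,
            TAG["RescaleIntercept"]: intercept,
            TAG["PixelData"]: stored[k].tobytes(),
        }
        write_file(directory / f"ct_{k:03d}.dcm", ds)


def write_rtdose(grid: ImageGrid, path, scaling: float = 1e-3) -> None:
    """Write a dose grid as a multi-frame RT-DOSE (32-bit stored values)."""
    stored = np.round(grid.values / scaling)
    if stored.min() < 0:
        raise ValueError("dose must be non-negative")
    stored = stored.astype("<u4")
    nz, ny, nx = grid.shape
    z0, y0, x0 = grid.origin
    ds = {
        TAG["SOPClassUID"]: SOP_CLASS_RTDOSE,
        TAG["SOPInstanceUID"]: make_uid("rd"),
        TAG["Modality"]: "RTDOSE",
        TAG["FrameOfReferenceUID"]: grid.frame_id or make_uid("frame"),
        TAG["ImagePositionPatient"]: [x0, y0, z0],
        TAG["ImageOrientationPatient"]: list(_AXIAL_ORIENTATION),
        TAG["PixelSpacing"]: [grid.spacing[1], grid.spacing[2]],
        TAG["SamplesPerPixel"]: 1,
        TAG["NumberOfFrames"]: nz,
        TAG["Rows"]: ny,
        TAG["Columns"]: nx,
        TAG["BitsAllocated"]: 32,
        TAG["BitsStored"]: 32,
        TAG["HighBit"]: 31,
        TAG["PixelRepresentation"]: 0,
        TAG["DoseUnits"]: "GY",
        TAG["GridFrameOffsetVector"]: [k * grid.spacing[0] for k in range(nz)],
        TAG["DoseGridScaling"]: scaling,
        TAG["PixelData"]: stored.tobytes(),
    }
    write_file(path, ds)


def write_rtstruct(structures: dict, path, frame_id: str = "") -> None:
    """Write named contour sets: ``{name: [(z_mm, (N,2) xy polygon), ...]}``."""
    roi_seq = []
    contour_seq = []
    frame_uid = frame_id or make_uid("frame")
    for number, (name, contours) in enumerate(structures.items(), start=1):
        roi_seq.append({
            TAG["ROINumber"]: number,
            TAG["ReferencedFrameOfReferenceUID"]: frame_uid,
            TAG["ROIName"]: name,
        })
        items = []
        for z_mm, poly in contours:
            poly = np.asarray(poly, dtype=float)
            data = np.column_stack([poly, np.full(len(poly), z_mm)]).ravel()
            items.append({
                TAG["ContourGeometricType"]: "CLOSED_PLANAR",
                TAG["NumberOfContourPoints"]: len(poly),
                TAG["ContourData"]: list(data),
            })
        contour_seq.append({
            TAG["ReferencedROINumber"]: number,
            TAG["ContourSequence"]: items,
        })
    ds = {
        TAG["SOPClassUID"]: SOP_CLASS_RTSTRUCT,
        TAG["SOPInstanceUID"]: make_uid("rs"),
        TAG["Modality"]: "RTSTRUCT",
        TAG["StructureSetLabel"]: "synthetic",
        TAG["StructureSetROISequence"]: roi_seq,
        TAG["ROIContourSequence"]: contour_seq,
    }
    write_file(path, ds)


# ---------------------------------------------------------------------------
# clinical table + manifest

_CLINICAL_FIELDS = ["patient_id", "age", "bmi", "laterality", "surgery",
                    "ajcc_stage", "scf", "imn", "chemotherapy", "rd_grade_ge2"]


def write_clinical_csv(records: list[ClinicalRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_CLINICAL_FIELDS)
        writer.writeheader()
        for rec in records:
            row = asdict(rec)
            for b in ("scf", "imn", "chemotherapy", "rd_grade_ge2"):
                row[b] = int(row[b])
            writer.writerow(row)


def read_clinical_csv(path) -> list[ClinicalRecord]:
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(ClinicalRecord(
                patient_id=row["patient_id"],
                age=float(row["age"]),
                bmi=float(row["bmi"]),
                laterality=row["laterality"],
                surgery=row["surgery"],
                ajcc_stage=int(row["ajcc_stage"]),
                scf=bool(int(row["scf"])),
                imn=bool(int(row["imn"])),
                chemotherapy=bool(int(row["chemotherapy"])),
                rd_grade_ge2=bool(int(row["rd_grade_ge2"])),
            ))
    return records


def write_manifest(path, manifest: dict) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
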