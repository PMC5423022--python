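"""Readers and writers for plan data, models and cohort scatters.

Two plan representations are supported:

* a plain-text fixture dialect — a directory holding ``grid.json`` (origin,
  spacing, shape), ``dose.csv`` and ``roi_<name>.csv`` voxel arrays and a
  ``plan.json`` with plan metadata — used throughout the test-suite and by
  the synthetic generators;
* DICOM RT files (RT-STRUCT contours, RT-DOSE grid with its scaling factor,
  RT-PLAN for the total beam meterset) via pydicom.

Voxel CSV arrays are the 3-D array reshaped to (nz*ny, nx) rows so that a
file row is one x-line of one slice; dose is stored in Gy.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .dose_geometry import ContourSet, DoseGrid, DVHCurve, ROIMask, VoxelGrid
from .sparing_model import ModelPair, SparingModel

# ---------------------------------------------------------------------------
# plain-text fixture dialect


def _array_to_csv(path: Path, arr: np.ndarray, fmt: str) -> None:
    nx, ny, nz = arr.shape
    flat = np.transpose(arr, (2, 1, 0)).reshape(nz * ny, nx)  # rows: (z, y), cols: x
    np.savetxt(path, flat, fmt=fmt, delimiter=",")


def _array_from_csv(path: Path, shape: tuple[int, int, int]) -> np.ndarray:
    nx, ny, nz = shape
    flat = np.loadtxt(path, delimiter=",", ndmin=2)
    return np.transpose(flat.reshape(nz, ny, nx), (2, 1, 0))


def write_fixture_plan(
    directory: str | Path,
    structures: dict[str, ROIMask],
    dose: DoseGrid,
    plan_meta: dict,
) -> Path:
    """Write a plan (dose + masks + metadata) as the plain-text fixture dialect."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    grid = dose.grid
    with open(directory / "grid.json", "w") as fh:
        json.dump(
            {"origin": list(grid.origin), "spacing": list(grid.spacing), "shape": list(grid.shape)},
            fh,
            indent=1,
        )
    _array_to_csv(directory / "dose.csv", dose.dose, fmt="%.4f")
    for name, mask in structures.items():
        if not mask.grid.same_lattice(grid):
            raise ValueError(f"structure {name!r} is not on the dose lattice")
        _array_to_csv(directory / f"roi_{name}.csv", mask.occupancy.astype(np.uint8), fmt="%d")
    with open(directory / "plan.json", "w") as fh:
        json.dump(plan_meta, fh, indent=1, sort_keys=True)
    return directory


def read_fixture_plan(
    directory: str | Path,
) -> tuple[dict[str, ROIMask], DoseGrid, dict]:
    """Read a plain-text fixture plan directory back into in-memory objects."""
    directory = Path(directory)
    with open(directory / "grid.json") as fh:
        g = json.load(fh)
    grid = VoxelGrid(origin=tuple(g["origin"]), spacing=tuple(g["spacing"]), shape=tuple(g["shape"]))
    dose = DoseGrid(grid=grid, dose=_array_from_csv(directory / "dose.csv", grid.shape))
    structures: dict[str, ROIMask] = {}
    for roi_path in sorted(directory.glob("roi_*.csv")):
        name = roi_path.stem[len("roi_"):]
        occ = _array_from_csv(roi_path, grid.shape).astype(bool)
        structures[name] = ROIMask(grid=grid, occupancy=occ, roi_name=name)
    with open(directory / "plan.json") as fh:
        plan_meta = json.load(fh)
    return structures, dose, plan_meta


# ---------------------------------------------------------------------------
# DVH export


def write_dvh_csv(path: str | Path, dvh: DVHCurve) -> None:
    """Two-column CSV export: dose_Gy, cum_fraction."""
    with open(path, "w") as fh:
        fh.write("dose_Gy,cum_fraction\n")
        for edge, cum in zip(dvh.bin_edges, dvh.cum_volume):
            fh.write(f"{edge:.6g},{cum:.8g}\n")


# ---------------------------------------------------------------------------
# model persistence


def save_model_pair(
    path: str | Path,
    pair: ModelPair,
    q_oard: float = 0.10,
    q_mard: float = 0.50,
    d_px: float = 74.0,
) -> None:
    payload = {
        "oard": {"A": pair.oard.A, "B": pair.oard.B, "C": pair.oard.C},
        "mard": {"A": pair.mard.A, "B": pair.mard.B, "C": pair.mard.C},
        "q_oard": q_oard,
        "q_mard": q_mard,
        "d_px_Gy": d_px,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def load_model_pair(path: str | Path) -> tuple[ModelPair, dict]:
    """Load a saved OARD/MARD pair; returns (pair, metadata dict)."""
    with open(path) as fh:
        payload = json.load(fh)
    pair = ModelPair(
        oard=SparingModel(**payload["oard"]),
        mard=SparingModel(**payload["mard"]),
    )
    meta = {k: payload[k] for k in ("q_oard", "q_mard", "d_px_Gy") if k in payload}
    return pair, meta


# ---------------------------------------------------------------------------
# DICOM RT


def read_rtdose(path: str | Path) -> DoseGrid:
    """Read a DICOM RT-DOSE file, applying the dose-grid scaling factor."""
    ds = pydicom.dcmread(path)
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    arr = ds.pixel_array.astype(float) * scaling  # (frames=z, rows=y, cols=x)
    dose = np.transpose(arr, (2, 1, 0))
    row_spacing, col_spacing = (float(v) for v in ds.PixelSpacing)
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    dz = float(offsets[1] - offsets[0]) if len(offsets) > 1 else 1.0
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    grid = VoxelGrid(origin=origin, spacing=(col_spacing, row_spacing, dz), shape=dose.shape)
    return DoseGrid(grid=grid, dose=dose)


def read_rtstruct(path: str | Path) -> dict[str, ContourSet]:
    """Read a DICOM RT-STRUCT into ContourSets keyed by ROI name."""
    ds = pydicom.dcmread(path)
    names = {int(roi.ROINumber): str(roi.ROIName) for roi in ds.StructureSetROISequence}
    out: dict[str, ContourSet] = {}
    for roi_contour in ds.ROIContourSequence:
        name = names[int(roi_contour.ReferencedROINumber)]
        slices = []
        for contour in getattr(roi_contour, "ContourSequence", []):
            pts = np.asarray(contour.ContourData, dtype=float).reshape(-1, 3)
            slices.append((float(pts[0, 2]), pts[:, :2]))
        out[name] = ContourSet(roi_name=name, slices=slices)
    return out


def read_rtplan_total_mu(path: str | Path) -> float:
    """Total plan meterset (MU) summed over all referenced beams."""
    ds = pydicom.dcmread(path)
    total = 0.0
    for fg in ds.FractionGroupSequence:
        for rb in getattr(fg, "ReferencedBeamSequence", []):
            total += float(getattr(rb, "BeamMeterset", 0.0))
    return total


def _file_dataset(sop_class_uid: str) -> FileDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class_uid
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = sop_class_uid
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    now = datetime.datetime(2000, 1, 1)
    ds.ContentDate = now.strftime("%Y%m%d")
    ds.ContentTime = now.strftime("%H%M%S")
    ds.PatientName = "SYNTHETIC^PHANTOM"
    ds.PatientID = "SYN000"
    return ds


def write_rtdose(path: str | Path, dose: DoseGrid) -> None:
    """Write a dose grid as DICOM RT-DOSE (uint32 pixels + scaling factor)."""
    ds = _file_dataset("1.2.840.10008.5.1.4.1.1.481.2")
    ds.Modality = "RTDOSE"
    grid = dose.grid
    arr = np.transpose(dose.dose, (2, 1, 0))  # (z, y, x)
    dmax = float(arr.max())
    scaling = (dmax / (2**32 - 1)) if dmax > 0 else 1.0
    pixels = np.round(arr / scaling).astype(np.uint32) if dmax > 0 else arr.astype(np.uint32)
    ds.DoseGridScaling = scaling
    ds.DoseUnits = "GY"
    ds.DoseSummationType = "PLAN"
    ds.DoseType = "PHYSICAL"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.NumberOfFrames = grid.shape[2]
    ds.Rows = grid.shape[1]
    ds.Columns = grid.shape[0]
    ds.PixelSpacing = [str(grid.spacing[1]), str(grid.spacing[0])]
    ds.GridFrameOffsetVector = [str(k * grid.spacing[2]) for k in range(grid.shape[2])]
    ds.ImagePositionPatient = [str(v) for v in grid.origin]
    ds.ImageOrientationPatient = ["1", "0", "0", "0", "1", "0"]
    ds.FrameOfReferenceUID = generate_uid()
    ds.PixelData = pixels.tobytes()
    ds.save_as(path, enforce_file_format=True)


def write_rtstruct(path: str | Path, contour_sets: list[ContourSet]) -> None:
    """Write contours as a minimal DICOM RT-STRUCT."""
    ds = _file_dataset("1.2.840.10008.5.1.4.1.1.481.3")
    ds.Modality = "RTSTRUCT"
    ds.StructureSetLabel = "SYNTHETIC"
    frame_uid = generate_uid()
    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    for number, cs in enumerate(contour_sets, start=1):
        roi = Dataset()
        roi.ROINumber = number
        roi.ROIName = cs.roi_name
        roi.ReferencedFrameOfReferenceUID = frame_uid
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        ds.StructureSetROISequence.append(roi)
        rc = Dataset()
        rc.ReferencedROINumber = number
        rc.ContourSequence = []
        for z, verts in cs.slices:
            contour = Dataset()
            contour.ContourGeometricType = "CLOSED_PLANAR"
            contour.NumberOfContourPoints = len(verts)
            data: list[str] = []
            for x, y in verts:
                data.extend([f"{x:.6g}", f"{y:.6g}", f"{z:.6g}"])
            contour.ContourData = data
            rc.ContourSequence.append(contour)
        ds.ROIContourSequence.append(rc)
    ds.save_as(path, enforce_file_format=True)


def write_rtplan(path: str | Path, total_mu: float, n_beams: int = 1) -> None:
    """Write a minimal DICOM RT-PLAN carrying the total meterset."""
    ds = _file_dataset("1.2.840.10008.5.1.4.1.1.481.5")
    ds.Modality = "RTPLAN"
    ds.RTPlanLabel = "SYNTHETIC"
    fg = Dataset()
    fg.FractionGroupNumber = 1
    fg.ReferencedBeamSequence = []
    for b in range(n_beams):
        rb = Dataset()
        rb.ReferencedBeamNumber = b + 1
        rb.BeamMeterset = total_mu / n_beams
        fg.ReferencedBeamSequence.append(rb)
    ds.FractionGroupSequence = [fg]
    ds.save_as(path, enforce_file_format=True)
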