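"""Shared fixtures: small grids, random masks, in-memory DICOM-RT files."""

from __future__ import annotations

import numpy as np
import pydicom
import pytest
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from kbplan.core import BinaryMask, VoxelGrid


@pytest.fixture
def grid8() -> VoxelGrid:
    return VoxelGrid((8, 8, 8), (1.0, 1.0, 1.0))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)


def random_mask(grid: VoxelGrid, density: float, rng: np.random.Generator,
                nonempty: bool = True) -> BinaryMask:
    values = rng.random(grid.shape) < density
    if nonempty and not values.any():
        idx = tuple(rng.integers(0, s) for s in grid.shape)
        values[idx] = True
    return BinaryMask(grid, values)


def _base_dataset(modality: str, sop_class: str) -> pydicom.FileDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = generate_uid(entropy_srcs=["kbplan-test"])
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = pydicom.FileDataset(None, Dataset(), file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = modality
    ds.PatientID = "TEST001"
    ds.PatientName = "Test^Patient"
    return ds


def make_rtstruct(path, rois: dict[str, list[tuple[float, np.ndarray]]]):
    """Write a minimal RTSTRUCT: roi name -> [(z_mm, (V,2) polygon mm)]."""
    ds = _base_dataset("RTSTRUCT", "1.2.840.10008.5.1.4.1.1.481.3")
    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    for number, (name, contours) in enumerate(rois.items(), start=1):
        roi = Dataset()
        roi.ROINumber = number
        roi.ROIName = name
        roi.ReferencedFrameOfReferenceUID = generate_uid(entropy_srcs=[name])
        ds.StructureSetROISequence.append(roi)
        rc = Dataset()
        rc.ReferencedROINumber = number
        rc.ContourSequence = []
        for z, poly in contours:
            poly = np.asarray(poly, dtype=float)
            item = Dataset()
            item.ContourGeometricType = "CLOSED_PLANAR"
            item.NumberOfContourPoints = len(poly)
            pts = np.column_stack([poly, np.full(len(poly), z)])
            item.ContourData = [float(v) for v in pts.ravel()]
            rc.ContourSequence.append(item)
        ds.ROIContourSequence.append(rc)
    ds.save_as(str(path), enforce_file_format=True)
    return path


def make_rtdose(path, dose_xyz: np.ndarray, grid: VoxelGrid, scaling: float = 0.001):
    """Write a minimal RTDOSE holding ``dose_xyz`` (Gy) on ``grid``."""
    ds = _base_dataset("RTDOSE", "1.2.840.10008.5.1.4.1.1.481.2")
    stored = np.rint(dose_xyz / scaling).astype(np.uint32)
    frames = np.transpose(stored, (2, 1, 0))  # (z, y, x)
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.NumberOfFrames = frames.shape[0]
    ds.Rows = frames.shape[1]
    ds.Columns = frames.shape[2]
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = scaling
    ds.ImagePositionPatient = [float(grid.origin[0]), float(grid.origin[1]),
                               float(grid.origin[2])]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.PixelSpacing = [float(grid.spacing[1]), float(grid.spacing[0])]
    ds.GridFrameOffsetVector = [float(grid.spacing[2] * k)
                                for k in range(frames.shape[0])]
    ds.PixelData = frames.tobytes()
    ds.save_as(str(path), enforce_file_format=True)
    return path


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-patient synthetic cohort on a reduced grid for fast pipeline tests."""
    from kbplan.core import VoxelGrid
    from kbplan.synthetic import make_database

    grid = VoxelGrid((72, 72, 48), (3.5, 3.5, 3.5), (1.75, 1.75, 1.75))
    return make_database(12, seed=7, grid=grid)
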