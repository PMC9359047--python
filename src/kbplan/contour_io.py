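"""DICOM-RT and NIfTI I/O: contour rasterization, mask caching, dose import.

RTSTRUCT planar contours are rasterized slice by slice onto a target grid
with the even-odd rule evaluated at voxel centers; multiple polygons on one
slice are XOR-combined so that inner contours punch holes.  Structure names
are mapped onto the canonical vocabulary through a case-insensitive alias
table that callers can extend.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from scipy import ndimage

from .core import CANONICAL_STRUCTURES, BinaryMask, DoseGrid, StructureSet, VoxelGrid

logger = logging.getLogger(__name__)

#: Default case-insensitive aliases mapping clinical ROI names to the
#: canonical vocabulary.  Keys are lower-cased, with spaces/hyphens collapsed
#: to underscores before lookup.
DEFAULT_ALIASES: dict[str, str] = {
    "ptv": "PTV",
    "ptv50": "PTV",
    "ctv": "PTV",
    "rectum": "rectum",
    "rect": "rectum",
    "bladder": "bladder",
    "bladder_full": "bladder",
    "vessie": "bladder",
    "femoral_head_l": "femoral_head_L",
    "femur_l": "femoral_head_L",
    "left_femoral_head": "femoral_head_L",
    "femoral_head_lt": "femoral_head_L",
    "femoral_head_r": "femoral_head_R",
    "femur_r": "femoral_head_R",
    "right_femoral_head": "femoral_head_R",
    "femoral_head_rt": "femoral_head_R",
    "small_intestine": "small_intestine",
    "small_bowel": "small_intestine",
    "bowel": "small_intestine",
    "intestine": "small_intestine",
    "spinal_cord": "spinal_cord",
    "cord": "spinal_cord",
    "spinalcord": "spinal_cord",
}


def normalize_roi_name(name: str, aliases: dict[str, str] | None = None) -> str | None:
    """Map a clinical ROI name to the canonical vocabulary, or None."""
    table = dict(DEFAULT_ALIASES)
    if aliases:
        table.update({k.lower().replace(" ", "_").replace("-", "_"): v for k, v in aliases.items()})
    key = name.strip().lower().replace(" ", "_").replace("-", "_")
    canon = table.get(key)
    if canon is not None and canon not in CANONICAL_STRUCTURES:
        raise ValueError(f"alias target {canon!r} is not canonical")
    return canon


def load_alias_table(path: str | Path) -> dict[str, str]:
    """Load a user alias table (JSON object: clinical name -> canonical)."""
    with open(path) as fh:
        return json.load(fh)


def _points_in_polygon(px: np.ndarray, py: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Even-odd (crossing number) point-in-polygon test, vectorized.

    poly is (V, 2) in mm; an implicitly closed simple or self-intersecting
    polygon.  Points exactly on an edge fall on whichever side floating-point
    arithmetic lands them.
    """
    inside = np.zeros(px.shape, dtype=bool)
    x1, y1 = poly[-1]
    for x2, y2 in poly:
        if y1 != y2:
            crosses = (y1 > py) != (y2 > py)
            with np.errstate(divide="ignore", invalid="ignore"):
                xint = (x2 - x1) * (py - y1) / (y2 - y1) + x1
            inside ^= crosses & (px < xint)
        x1, y1 = x2, y2
    return inside


def rasterize_polygon_stack(
    contours: list[tuple[float, np.ndarray]],
    grid: VoxelGrid,
) -> BinaryMask:
    """Rasterize closed planar contours into a binary mask.

    Parameters
    ----------
    contours : list of (z_mm, polygon)
        Each polygon is an (V, 2) array of in-plane (x, y) vertices in mm,
        implicitly closed (a repeated last vertex is tolerated).
    grid : VoxelGrid
        Target lattice.  A contour whose z lies within half a slice spacing
        of a grid slice is assigned to that slice; otherwise it is skipped
        with a warning.

    A voxel is set iff its center is inside its slice's polygon by the
    even-odd rule; several polygons on one slice XOR-combine (holes).
    """
    values = np.zeros(grid.shape, dtype=bool)
    xs = grid.axis_coords(0)
    ys = grid.axis_coords(1)
    px, py = np.meshgrid(xs, ys, indexing="ij")
    for z_mm, poly in contours:
        poly = np.asarray(poly, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
            raise ValueError("each contour must be an (V>=3, 2) polygon")
        if np.allclose(poly[0], poly[-1]):
            poly = poly[:-1]
        k = (z_mm - grid.origin[2]) / grid.spacing[2]
        k_idx = int(round(k))
        if not (0 <= k_idx < grid.shape[2]) or abs(k - k_idx) > 0.5 + 1e-9:
            logger.warning("contour at z=%.2f mm outside grid extent; skipped", z_mm)
            continue
        values[:, :, k_idx] ^= _points_in_polygon(px, py, poly)
    return BinaryMask(grid, values)


def resample_mask(mask: BinaryMask, target_grid: VoxelGrid) -> BinaryMask:
    """Nearest-neighbor resample of occupancy by voxel-center lookup.

    Each target voxel center is mapped to patient coordinates and takes the
    value of the nearest source voxel; centers outside the source extent are
    0.  Identical grids return an identical mask.
    """
    if target_grid == mask.grid:
        return mask.copy()
    # nearest source voxel index per target center, per axis
    idx, valid = [], []
    for a in range(3):
        frac = (target_grid.axis_coords(a) - mask.grid.origin[a]) / mask.grid.spacing[a]
        near = np.rint(frac).astype(int)
        valid.append((near >= 0) & (near < mask.grid.shape[a]))
        idx.append(np.clip(near, 0, mask.grid.shape[a] - 1))
    out = mask.values[np.ix_(*idx)]
    out &= valid[0][:, None, None] & valid[1][None, :, None] & valid[2][None, None, :]
    return BinaryMask(target_grid, out)


def _read_dicom(path: str | Path, expected_modality: str) -> pydicom.Dataset:
    try:
        ds = pydicom.dcmread(str(path))
    except Exception as exc:  # pragma: no cover - pydicom error text varies
        raise ValueError(f"cannot parse DICOM file {path}: {exc}") from exc
    modality = getattr(ds, "Modality", None)
    if modality != expected_modality:
        raise ValueError(f"{path}: expected {expected_modality}, got modality {modality!r}")
    return ds


def read_rtstruct(
    path: str | Path,
    target_grid: VoxelGrid,
    aliases: dict[str, str] | None = None,
    patient_id: str | None = None,
) -> StructureSet:
    """Read a DICOM RTSTRUCT and rasterize recognised ROIs onto a grid.

    ROIs whose names do not alias to the canonical vocabulary are ignored
    with a warning.  A missing PTV is a hard error.
    """
    ds = _read_dicom(path, "RTSTRUCT")
    roi_names = {
        int(roi.ROINumber): str(roi.ROIName) for roi in ds.StructureSetROISequence
    }
    structures: dict[str, BinaryMask] = {}
    for roi_contour in getattr(ds, "ROIContourSequence", []):
        number = int(roi_contour.ReferencedROINumber)
        name = roi_names.get(number, f"ROI_{number}")
        canon = normalize_roi_name(name, aliases)
        if canon is None:
            logger.warning("%s: ROI %r has no canonical alias; ignored", path, name)
            continue
        contours: list[tuple[float, np.ndarray]] = []
        for item in getattr(roi_contour, "ContourSequence", []):
            data = np.asarray(item.ContourData, dtype=float).reshape(-1, 3)
            contours.append((float(data[0, 2]), data[:, :2]))
        mask = rasterize_polygon_stack(contours, target_grid)
        if canon in structures:  # merge split ROIs mapping to one structure
            mask.values |= structures[canon].values
        structures[canon] = mask
    if "PTV" not in structures:
        raise ValueError(f"{path}: no ROI aliases to PTV")
    pid = patient_id or str(getattr(ds, "PatientID", Path(path).stem))
    return StructureSet(pid, structures)


def read_rtdose(path: str | Path, target_grid: VoxelGrid) -> DoseGrid:
    """Read a DICOM RTDOSE and trilinearly resample it onto a grid (Gy)."""
    ds = _read_dicom(path, "RTDOSE")
    if "DoseGridScaling" not in ds:
        raise ValueError(f"{path}: RTDOSE is missing DoseGridScaling")
    scaling = float(ds.DoseGridScaling)
    # pixel_array is (frames, rows, cols) = (z, y, x); reorder to (x, y, z)
    stored = ds.pixel_array.astype(float) * scaling
    dose_xyz = np.transpose(stored, (2, 1, 0))
    ipp = np.asarray(ds.ImagePositionPatient, dtype=float)
    row_spacing, col_spacing = (float(v) for v in ds.PixelSpacing)
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    dz = float(offsets[1] - offsets[0]) if len(offsets) > 1 else 1.0
    src = VoxelGrid(dose_xyz.shape, (col_spacing, row_spacing, dz),
                    (ipp[0], ipp[1], ipp[2] + offsets[0]))
    axes = [
        (target_grid.axis_coords(a) - src.origin[a]) / src.spacing[a]
        for a in range(3)
    ]
    ii, jj, kk = np.meshgrid(*axes, indexing="ij")
    out = ndimage.map_coordinates(
        dose_xyz, np.stack([ii, jj, kk]), order=1, mode="constant", cval=0.0
    )
    return DoseGrid(target_grid, np.clip(out, 0.0, None))


# ---------------------------------------------------------------------------
# NIfTI mask caching (one file per structure + JSON sidecar per patient)
# ---------------------------------------------------------------------------

def _grid_affine(grid: VoxelGrid) -> np.ndarray:
    """NIfTI (RAS) affine for our LPS-convention grid: flip x and y."""
    affine = np.diag([-grid.spacing[0], -grid.spacing[1], grid.spacing[2], 1.0])
    affine[:3, 3] = [-grid.origin[0], -grid.origin[1], grid.origin[2]]
    return affine


def write_mask_nifti(mask: BinaryMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.values.astype(np.uint8), _grid_affine(mask.grid))
    nib.save(img, str(path))


def read_mask_nifti(path: str | Path) -> BinaryMask:
    img = nib.load(str(path))
    affine = img.affine
    spacing = (float(-affine[0, 0]), float(-affine[1, 1]), float(affine[2, 2]))
    origin = (float(-affine[0, 3]), float(-affine[1, 3]), float(affine[2, 3]))
    data = np.asarray(img.dataobj)
    grid = VoxelGrid(data.shape, spacing, origin)
    return BinaryMask(grid, data > 0)


def write_structure_set(sset: StructureSet, out_dir: str | Path) -> Path:
    """Write one NIfTI per structure plus a JSON sidecar; returns sidecar path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = sset.grid
    for name, mask in sorted(sset.structures.items()):
        write_mask_nifti(mask, out / f"{name}.nii.gz")
    sidecar = {
        "patient_id": sset.patient_id,
        "grid": {"shape": list(grid.shape), "spacing": list(grid.spacing),
                 "origin": list(grid.origin)},
        "structures": sorted(sset.structures),
    }
    sidecar_path = out / "structures.json"
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return sidecar_path


def read_structure_set(in_dir: str | Path) -> StructureSet:
    in_dir = Path(in_dir)
    with open(in_dir / "structures.json") as fh:
        meta = json.load(fh)
    structures = {
        name: read_mask_nifti(in_dir / f"{name}.nii.gz")
        for name in meta["structures"]
    }
    return StructureSet(meta["patient_id"], structures)
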