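"""Synthetic pelvic phantom cohorts with a parametric achievable-dose model.

A phantom emulates female pelvic anatomy on the common grid: an ellipsoidal
PTV mid-pelvis, a spherical bladder anterior(-superior) to it, a tubular
rectum posterior to it, lateral spherical femoral heads, and a thin posterior
midline spinal cord.  The bladder and rectum positions are parametrized by
an ``overlap`` control in [0, 1]: at 0 the organ surface sits a small gap
away from the PTV surface (empty intersection); raising it pushes the organ
into the PTV, so the overlap fraction is controllable and recoverable by
voxel counting.

The achievable dose of a plan is modelled as a sigmoid of the signed
Euclidean distance s(x) from the PTV surface (negative inside),

    D(x) = (1 + h) * D_Rx / (1 + exp(s(x) / sigma)) + noise,

where sigma sets the dose-falloff scale in mm and h is a small hotspot
calibration so the target interior actually reaches the prescription (a
pure sigmoid saturates strictly below D_Rx, which would make every V50Gy
identically zero).  With noise = 0 the achieved V50Gy of any structure is an
exact threshold on s(x), which the DVH route must reproduce; anatomically
similar patients get similar achievable doses by construction, which is the
premise knowledge-based constraint transfer relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core import BinaryMask, DoseGrid, StructureSet, VoxelGrid
from .dvh import cumulative_dvh, v_at_dose
from .similarity import PatientRecord

#: Common cohort grid: 96 x 96 x 64 voxels at 2.5 mm, centered so the
#: lateral midline (x = 120 mm) falls exactly between voxel columns' mirror
#: pairs, making zero-jitter phantoms exactly left-right symmetric.
DEFAULT_GRID = VoxelGrid((96, 96, 64), (2.5, 2.5, 2.5), (1.25, 1.25, 1.25))


@dataclass(frozen=True)
class PhantomParams:
    """Geometry of one synthetic pelvic patient (all lengths in mm)."""

    patient_id: str = "phantom"
    ptv_center: tuple[float, float, float] = (120.0, 120.0, 80.0)
    ptv_semiaxes: tuple[float, float, float] = (45.0, 35.0, 40.0)
    bladder_radius: float = 27.0
    bladder_overlap: float = 0.4          # 0 = 3 mm gap, 1 = deep indentation
    bladder_sup_offset: float = 15.0
    rectum_radius: float = 12.0
    rectum_length: float = 100.0
    rectum_overlap: float = 0.4
    femoral_radius: float = 20.0
    femoral_offset: float = 80.0          # lateral distance from midline
    cord_radius: float = 5.0
    center_jitter: float = 0.0            # uniform +/- mm on structure centers
    size_jitter: float = 0.0              # uniform relative scale on sizes
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.ptv_semiaxes):
            raise ValueError("PTV semi-axes must be > 0")
        for name in ("bladder_radius", "rectum_radius", "rectum_length",
                     "femoral_radius", "cord_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("bladder_overlap", "rectum_overlap"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class DoseModelParams:
    """Sigmoid-of-distance achievable-dose surrogate."""

    prescription: float = 50.0     # Gy
    sigma: float = 1.5             # mm falloff scale
    hotspot: float = 0.08          # fractional over-prescription inside the PTV
    noise: float = 0.0             # Gy, std of additive Gaussian noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.prescription <= 0 or self.sigma <= 0:
            raise ValueError("prescription and sigma must be > 0")
        if self.noise < 0 or self.hotspot < 0:
            raise ValueError("noise and hotspot must be >= 0")


# --------------------------------------------------------------------------
# geometry helpers
# --------------------------------------------------------------------------

def _center_coords(grid: VoxelGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return np.meshgrid(*(grid.axis_coords(a) for a in range(3)), indexing="ij")


def _ellipsoid(grid, center, semiaxes) -> np.ndarray:
    X, Y, Z = _center_coords(grid)
    return (
        ((X - center[0]) / semiaxes[0]) ** 2
        + ((Y - center[1]) / semiaxes[1]) ** 2
        + ((Z - center[2]) / semiaxes[2]) ** 2
    ) <= 1.0


def _cylinder_z(grid, center_xy, radius, z_lo, z_hi) -> np.ndarray:
    X, Y, Z = _center_coords(grid)
    radial = (X - center_xy[0]) ** 2 + (Y - center_xy[1]) ** 2 <= radius**2
    return radial & (Z >= z_lo) & (Z <= z_hi)


def _check_inside(name: str, mask: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    if not mask.any():
        raise ValueError(f"structure {name} rasterizes to an empty mask")
    for axis in range(3):
        proj = mask.any(axis=tuple(a for a in range(3) if a != axis))
        if proj[0] or proj[-1]:
            raise ValueError(f"structure {name} exceeds the grid extent")
    return mask


_GAP_MM = 3.0  # organ-PTV surface gap at overlap control 0


def make_phantom(params: PhantomParams, grid: VoxelGrid = DEFAULT_GRID) -> StructureSet:
    """Rasterize one synthetic pelvic patient; deterministic per seed."""
    rng = np.random.default_rng(params.seed)

    def jc() -> np.ndarray:  # center jitter, one draw per structure
        return rng.uniform(-params.center_jitter, params.center_jitter, size=3)

    def js() -> float:       # relative size jitter
        return float(rng.uniform(1.0 - params.size_jitter, 1.0 + params.size_jitter))

    cx, cy, cz = np.asarray(params.ptv_center) + jc()
    semi = np.asarray(params.ptv_semiaxes) * np.array([js(), js(), js()])

    b_r = params.bladder_radius * js()
    b_off = jc()
    # overlap 0: surface gap of _GAP_MM; overlap 1: center pushed b_r inward
    b_cy = cy - (semi[1] + b_r + _GAP_MM) + params.bladder_overlap * (b_r + _GAP_MM)
    b_center = np.array([cx, b_cy, cz + params.bladder_sup_offset]) + b_off

    r_r = params.rectum_radius * js()
    r_len = params.rectum_length * js()
    r_off = jc()
    r_cy = cy + (semi[1] + r_r + _GAP_MM) - params.rectum_overlap * (r_r + _GAP_MM + 10.0)
    r_center_xy = np.array([cx, r_cy]) + r_off[:2]
    r_zlo = cz - r_len / 2 + r_off[2]
    r_zhi = cz + r_len / 2 + r_off[2]

    f_r = params.femoral_radius * js()
    f_l_center = np.array([cx - params.femoral_offset, cy, cz]) + jc()
    f_r_center = np.array([cx + params.femoral_offset, cy, cz]) + jc()

    cord_xy = np.array([cx, cy + semi[1] + 40.0]) + jc()[:2]
    z_lo, z_hi = grid.extent_mm()[2]

    masks = {
        "PTV": _ellipsoid(grid, (cx, cy, cz), semi),
        "bladder": _ellipsoid(grid, b_center, (b_r, b_r, b_r)),
        "rectum": _cylinder_z(grid, r_center_xy, r_r, r_zlo, r_zhi),
        "femoral_head_L": _ellipsoid(grid, f_l_center, (f_r, f_r, f_r)),
        "femoral_head_R": _ellipsoid(grid, f_r_center, (f_r, f_r, f_r)),
        "spinal_cord": _cylinder_z(
            grid, cord_xy, params.cord_radius, z_lo + 2.5, z_hi - 2.5
        ),
    }
    structures = {
        name: BinaryMask(grid, _check_inside(name, m, grid))
        for name, m in masks.items()
    }
    return StructureSet(params.patient_id, structures)


def signed_distance_mm(mask: BinaryMask) -> np.ndarray:
    """Signed Euclidean distance (mm) from the mask surface, negative inside.

    Computed as the distance transform of the complement minus the distance
    transform of the mask, both with physical voxel spacing.
    """
    spacing = mask.grid.spacing
    outside = ndimage.distance_transform_edt(~mask.values, sampling=spacing)
    inside = ndimage.distance_transform_edt(mask.values, sampling=spacing)
    return np.asarray(outside - inside, dtype=float)


def dose_from_distance(s, params: DoseModelParams) -> np.ndarray:
    """Noise-free sigmoid dose at signed surface distance ``s`` (mm)."""
    s = np.asarray(s, dtype=float)
    z = np.clip(s / params.sigma, -700.0, 700.0)  # avoid exp overflow; dose -> 0
    return (1.0 + params.hotspot) * params.prescription / (1.0 + np.exp(z))


def synth_dose(structures: StructureSet, params: DoseModelParams) -> DoseGrid:
    """Achievable dose surrogate for one patient; deterministic per seed."""
    if "PTV" not in structures:
        raise ValueError("synth_dose requires a PTV")
    s = signed_distance_mm(structures["PTV"])
    dose = dose_from_distance(s, params)
    if params.noise > 0:
        rng = np.random.default_rng(params.seed)
        dose = dose + rng.normal(0.0, params.noise, size=dose.shape)
    return DoseGrid(structures.grid, np.clip(dose, 0.0, None))


def achieved_v50(
    structures: StructureSet, dose: DoseGrid, prescription: float = 50.0
) -> dict[tuple[str, str], float]:
    """Read the achieved V(prescription)Gy per structure off the DVH."""
    out: dict[tuple[str, str], float] = {}
    for name, mask in structures.structures.items():
        curve = cumulative_dvh(dose, mask, structure=name)
        out[(name, "V50Gy")] = v_at_dose(curve, prescription)
    return out


def make_database(
    n: int,
    base: PhantomParams | None = None,
    dose_params: DoseModelParams | None = None,
    seed: int = 0,
    grid: VoxelGrid = DEFAULT_GRID,
) -> list[PatientRecord]:
    """Generate an n-patient synthetic cohort with achieved DVH parameters.

    Each patient draws independent anatomy jitters (center positions,
    structure sizes, bladder/rectum overlap controls) around ``base`` and has
    its achievable dose evaluated to fill the achieved rectum/bladder V50Gy
    (plus PTV V50Gy as a diagnostic).  Deterministic per seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base = base or PhantomParams(center_jitter=6.0, size_jitter=0.15)
    dose_params = dose_params or DoseModelParams()
    rng = np.random.default_rng(seed)
    records: list[PatientRecord] = []
    for i in range(n):
        p = replace(
            base,
            patient_id=f"P{i:03d}",
            bladder_overlap=float(rng.uniform(0.35, 0.95)),
            rectum_overlap=float(rng.uniform(0.35, 0.95)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        structures = make_phantom(p, grid)
        dp = replace(dose_params, seed=int(rng.integers(0, 2**31 - 1)))
        dose = synth_dose(structures, dp)
        achieved = achieved_v50(structures, dose, dp.prescription)
        keep = {
            k: v
            for k, v in achieved.items()
            if k[0] in ("rectum", "bladder", "PTV")
        }
        records.append(PatientRecord(structures, keep, provenance="synthetic"))
    return records
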