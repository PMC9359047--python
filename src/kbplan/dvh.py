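"""Cumulative dose-volume histograms and plan-quality metrics.

Conventions: a cumulative DVH reports, at each dose level d, the percent of
a structure's volume receiving at least d Gy (inclusive thresholding).
VxGy reads the curve at x Gy; Dx is the minimum dose received by the hottest
x% of the volume; Dmax is the maximum single-voxel dose; the homogeneity
index is HI = (D2 - D98) / D_Rx * 100%, zero for a perfectly uniform target
dose.  Vx and Dx are computed from the underlying voxel doses when the curve
retains them, falling back to linear interpolation between bin edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import BinaryMask, DoseGrid, StructureSet

#: Plan evaluation goals: (structure, metric) -> (comparison, limit).
EVALUATION_GOALS: dict[tuple[str, str], tuple[str, float]] = {
    ("PTV", "V50Gy"): (">", 96.0),
    ("rectum", "V50Gy"): ("<", 50.0),
    ("bladder", "V50Gy"): ("<", 50.0),
    ("femoral_head_L", "V50Gy"): ("<", 10.0),
    ("femoral_head_R", "V50Gy"): ("<", 10.0),
    ("small_intestine", "V50Gy"): ("<", 10.0),
    ("small_intestine", "Dmax"): ("<", 52.0),
    ("spinal_cord", "Dmax"): ("<", 45.0),
}


@dataclass
class DVHCurve:
    """Cumulative dose-volume curve for one structure."""

    structure: str
    dose_edges: np.ndarray          # Gy, ascending from 0
    volume_fraction: np.ndarray     # percent, non-increasing, starts at 100
    total_volume_cc: float
    voxel_doses: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.dose_edges = np.asarray(self.dose_edges, dtype=float)
        self.volume_fraction = np.asarray(self.volume_fraction, dtype=float)
        if self.dose_edges.shape != self.volume_fraction.shape:
            raise ValueError("dose_edges and volume_fraction must align")
        if self.dose_edges[0] != 0.0:
            raise ValueError("dose_edges must start at 0 Gy")
        if np.any(np.diff(self.volume_fraction) > 1e-9):
            raise ValueError("cumulative DVH must be non-increasing")

    @property
    def bin_width(self) -> float:
        return float(self.dose_edges[1] - self.dose_edges[0])

    @property
    def max_dose(self) -> float:
        if self.voxel_doses is not None:
            return float(self.voxel_doses.max())
        nonzero = np.flatnonzero(self.volume_fraction > 0)
        return float(self.dose_edges[nonzero[-1]]) if len(nonzero) else 0.0


def cumulative_dvh(
    dose: DoseGrid, mask: BinaryMask, bin_width: float = 0.05, structure: str = ""
) -> DVHCurve:
    """Cumulative DVH of ``dose`` within ``mask`` on fixed-width bins.

    The curve value at edge d is 100 x (structure voxels with dose >= d) /
    |structure|.  The voxel doses are retained on the curve so point metrics
    can be read exactly.
    """
    if dose.grid.shape != mask.grid.shape:
        raise ValueError("dose and mask must be on one grid")
    if mask.is_empty():
        raise ValueError("cannot build a DVH for an empty structure")
    doses = np.sort(dose.dose[mask.values])
    n_bins = int(math.floor(doses[-1] / bin_width)) + 2
    edges = np.arange(n_bins) * bin_width
    # voxels with dose >= edge == n - searchsorted(left)
    counts = doses.size - np.searchsorted(doses, edges, side="left")
    return DVHCurve(
        structure=structure,
        dose_edges=edges,
        volume_fraction=100.0 * counts / doses.size,
        total_volume_cc=mask.volume_cc,
        voxel_doses=doses,
    )


def v_at_dose(curve: DVHCurve, d: float) -> float:
    """VdGy: percent of the structure receiving at least ``d`` Gy."""
    if d < 0:
        raise ValueError("dose must be >= 0")
    if curve.voxel_doses is not None:
        n = curve.voxel_doses.size
        return float(100.0 * (n - np.searchsorted(curve.voxel_doses, d, side="left")) / n)
    if d >= curve.dose_edges[-1]:
        return float(curve.volume_fraction[-1]) if d == curve.dose_edges[-1] else 0.0
    return float(np.interp(d, curve.dose_edges, curve.volume_fraction))


def d_at_volume(curve: DVHCurve, v: float) -> float:
    """Dv: smallest dose at which the cumulative curve drops to ``v`` percent.

    Linearly interpolated between the bracketing bin edges.
    """
    if not (0.0 < v <= 100.0):
        raise ValueError("volume percent must be in (0, 100]")
    vf = curve.volume_fraction
    edges = curve.dose_edges
    below = np.flatnonzero(vf < v)
    if len(below) == 0:          # curve never drops below v within the binned range
        return float(edges[-1])
    i = int(below[0])
    if i == 0:
        return float(edges[0])
    v0, v1 = vf[i - 1], vf[i]
    if v0 <= v:                  # curve sits exactly at v up to this edge
        return float(edges[i - 1])
    frac = (v0 - v) / (v0 - v1)
    return float(edges[i - 1] + frac * (edges[i] - edges[i - 1]))


def dose_max(curve: DVHCurve) -> float:
    """Maximum single-voxel dose (Gy)."""
    return curve.max_dose


def homogeneity_index(curve: DVHCurve, prescription: float) -> float:
    """HI = 100 x (D2 - D98) / prescription, in percent; 0 when uniform."""
    if prescription <= 0:
        raise ValueError("prescription must be > 0")
    return 100.0 * (d_at_volume(curve, 2.0) - d_at_volume(curve, 98.0)) / prescription


#: Metric vocabulary computed per structure by :func:`evaluate_plan`.
_PLAN_METRICS: dict[str, tuple[str, ...]] = {
    "PTV": ("V50Gy", "HI", "D98", "D95", "D2"),
    "rectum": ("V50Gy",),
    "bladder": ("V50Gy",),
    "femoral_head_L": ("V50Gy",),
    "femoral_head_R": ("V50Gy",),
    "small_intestine": ("V50Gy", "Dmax"),
    "spinal_cord": ("Dmax",),
}


def evaluate_plan(
    dose: DoseGrid,
    structures: StructureSet,
    prescription: float = 50.0,
    bin_width: float = 0.05,
) -> tuple[dict[tuple[str, str], float], list[dict]]:
    """Compute the plan-quality metrics and flag each against its goal.

    Returns ``(metrics, goal_report)``: metrics maps (structure, metric) to
    its value; the goal report lists, per goal whose structure is present,
    the value, the goal and a pass flag.  Structures absent from the set are
    simply not reported (missing, not failed).  A missing PTV is an error.
    """
    if "PTV" not in structures:
        raise ValueError("evaluate_plan requires a PTV structure")
    metrics: dict[tuple[str, str], float] = {}
    for name, wanted in _PLAN_METRICS.items():
        if name not in structures:
            continue
        curve = cumulative_dvh(dose, structures[name], bin_width, structure=name)
        for metric in wanted:
            if metric == "V50Gy":
                value = v_at_dose(curve, 50.0)
            elif metric == "Dmax":
                value = dose_max(curve)
            elif metric == "HI":
                value = homogeneity_index(curve, prescription)
            elif metric.startswith("D"):
                value = d_at_volume(curve, float(metric[1:]))
            else:  # pragma: no cover
                raise AssertionError(metric)
            metrics[(name, metric)] = value
    report = []
    for (structure, metric), (op, limit) in EVALUATION_GOALS.items():
        if (structure, metric) not in metrics:
            continue
        value = metrics[(structure, metric)]
        passed = value > limit if op == ">" else value < limit
        report.append(
            {
                "structure": structure,
                "metric": metric,
                "value": value,
                "goal": f"{op}{limit:g}",
                "passed": bool(passed),
            }
        )
    return metrics, report


def compare_plan_cohorts(
    a: list[dict[tuple[str, str], float]],
    b: list[dict[tuple[str, str], float]],
) -> dict[tuple[str, str], dict[str, float]]:
    """Paired comparison of two plan cohorts, metric by metric.

    For each (structure, metric) key present in every plan of both cohorts,
    reports the mean and SD of the paired differences a - b and the paired
    t-test (two-sided, n-1 degrees of freedom).  Identical cohorts give
    p = 1; a zero-variance nonzero difference is flagged degenerate with
    p = 0.
    """
    if len(a) != len(b):
        raise ValueError("cohorts must be paired (equal length)")
    if len(a) < 2:
        raise ValueError("need at least two paired plans")
    keys = set(a[0])
    for plan in (*a, *b):
        keys &= set(plan)
    out: dict[tuple[str, str], dict[str, float]] = {}
    n = len(a)
    for key in sorted(keys):
        diff = np.array([pa[key] - pb[key] for pa, pb in zip(a, b)])
        mean = float(diff.mean())
        sd = float(diff.std(ddof=1))
        degenerate = sd == 0.0
        if degenerate:
            t = 0.0 if mean == 0.0 else math.inf * np.sign(mean)
            p = 1.0 if mean == 0.0 else 0.0
        else:
            t = mean / (sd / math.sqrt(n))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
        out[key] = {
            "mean_diff": mean,
            "sd_diff": sd,
            "t": float(t),
            "p": p,
            "n": float(n),
            "degenerate": float(degenerate),
        }
    return out
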