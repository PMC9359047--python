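"""Translation-only rigid registration of 3D binary masks.

Aligning a moving PTV mask to a fixed PTV mask by minimizing the voxelwise
squared difference is equivalent to maximizing their spatial correlation,

    S(t) = sum_x fixed(x) * moving(x - t),

the number of overlapping voxels after shifting the moving mask by the
integer translation t = (u, v, w).  The full linear correlation over every
candidate translation is computed with FFTs after zero-padding both masks to
the combined linear-correlation size (fixed_i + moving_i - 1 per axis), which
eliminates circular wrap-around; the inverse transform is rounded to the
nearest integer since the true values are overlap counts.  A direct
spatial-domain evaluation is provided as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import fft as sp_fft

from .core import BinaryMask


class Translation(NamedTuple):
    """Signed integer voxel offsets along the grid axes."""

    u: int
    v: int
    w: int


@dataclass
class ScoreVolume:
    """Overlap count S(t) for every candidate integer translation t.

    ``scores[i, j, k]`` is the overlap between the fixed mask and the moving
    mask after shifting the latter by ``min_offset + (i, j, k)`` voxels.
    """

    scores: np.ndarray
    min_offset: tuple[int, int, int]

    def translation_at(self, index: tuple[int, int, int]) -> Translation:
        return Translation(*(int(i) + o for i, o in zip(index, self.min_offset)))

    def score_at(self, t: Translation) -> int:
        idx = tuple(int(c) - o for c, o in zip(t, self.min_offset))
        if any(i < 0 or i >= s for i, s in zip(idx, self.scores.shape)):
            return 0
        return int(self.scores[idx])

    @property
    def max_score(self) -> int:
        return int(self.scores.max())


@dataclass(frozen=True)
class RegistrationResult:
    translation: Translation
    score: int


def _check_pair(fixed: BinaryMask, moving: BinaryMask) -> None:
    if fixed.grid.spacing != moving.grid.spacing:
        raise ValueError("fixed and moving masks must share one voxel spacing")
    if fixed.is_empty() or moving.is_empty():
        raise ValueError("registration of an empty mask has no meaningful optimum")


def correlation_map(fixed: BinaryMask, moving: BinaryMask) -> ScoreVolume:
    """All-translation overlap counts via zero-padded FFT correlation.

    Both masks are zero-padded to shape ``fixed + moving - 1`` per axis, the
    product of the fixed spectrum with the conjugate moving spectrum is
    inverted, and the result is rounded to integer overlap counts.  The
    translation range per axis is ``-(moving_i - 1) .. fixed_i - 1``.
    """
    _check_pair(fixed, moving)
    nf = fixed.values.shape
    nm = moving.values.shape
    full = tuple(a + b - 1 for a, b in zip(nf, nm))
    F = sp_fft.rfftn(fixed.values.astype(np.float64), s=full)
    M = sp_fft.rfftn(moving.values.astype(np.float64), s=full)
    raw = sp_fft.irfftn(F * np.conj(M), s=full)
    # raw[k] = S(t = k mod full); rotate so index 0 is the most negative shift
    raw = np.roll(raw, shift=tuple(n - 1 for n in nm), axis=(0, 1, 2))
    scores = np.rint(raw).astype(np.int64)
    np.maximum(scores, 0, out=scores)
    return ScoreVolume(scores, tuple(-(n - 1) for n in nm))


def brute_force_correlation(fixed: BinaryMask, moving: BinaryMask) -> ScoreVolume:
    """Direct spatial-domain overlap counts over the full translation range.

    Exact by construction; cost grows with the sixth power of the side
    length, so intended for masks up to roughly 24 voxels per side.  Serves
    as the independent oracle for :func:`correlation_map`.
    """
    _check_pair(fixed, moving)
    nf = fixed.values.shape
    nm = moving.values.shape
    full = tuple(a + b - 1 for a, b in zip(nf, nm))
    min_off = tuple(-(n - 1) for n in nm)
    scores = np.zeros(full, dtype=np.int64)
    f = fixed.values
    m = moving.values
    for i in range(full[0]):
        u = min_off[0] + i
        for j in range(full[1]):
            v = min_off[1] + j
            for k in range(full[2]):
                w = min_off[2] + k
                # overlap of fixed(x) with moving(x - t)
                fsl, msl = [], []
                for t, nfa, nma in zip((u, v, w), nf, nm):
                    lo = max(0, t)
                    hi = min(nfa, nma + t)
                    if hi <= lo:
                        break
                    fsl.append(slice(lo, hi))
                    msl.append(slice(lo - t, hi - t))
                else:
                    scores[i, j, k] = np.count_nonzero(
                        f[tuple(fsl)] & m[tuple(msl)]
                    )
    return ScoreVolume(scores, min_off)


def _crop_to_bbox(mask: BinaryMask) -> tuple[BinaryMask, tuple[int, int, int]]:
    bbox = mask.bounding_box()
    assert bbox is not None
    sl = tuple(slice(lo, hi) for lo, hi in bbox)
    sub = mask.values[sl]
    from .core import VoxelGrid

    grid = VoxelGrid(sub.shape, mask.grid.spacing, mask.grid.origin)
    return BinaryMask(grid, sub), tuple(lo for lo, _ in bbox)


def register_translation(fixed: BinaryMask, moving: BinaryMask) -> RegistrationResult:
    """Best integer translation of ``moving`` onto ``fixed`` by max overlap.

    Ties on the overlap count are broken by (1) the smallest Euclidean
    displacement in mm, then (2) lexicographic order on (u, v, w), so the
    result is deterministic across FFT backends.

    Both masks are cropped to their occupied bounding boxes before the FFT
    and the recovered translation is shifted back; this is exact (all-zero
    planes contribute nothing to any overlap, and for nonempty masks the
    optimum overlap is at least 1, which occurs within the cropped range).
    """
    _check_pair(fixed, moving)
    fsub, foff = _crop_to_bbox(fixed)
    msub, moff = _crop_to_bbox(moving)
    vol = correlation_map(fsub, msub)
    best = vol.max_score
    cand_idx = np.argwhere(vol.scores == best)
    offset_delta = tuple(fo - mo for fo, mo in zip(foff, moff))
    spacing = np.asarray(fixed.grid.spacing)
    best_t: Translation | None = None
    best_key = None
    for idx in cand_idx:
        t = tuple(
            c + o for c, o in zip(vol.translation_at(tuple(idx)), offset_delta)
        )
        key = (float(np.sum((np.asarray(t) * spacing) ** 2)), t)
        if best_key is None or key < best_key:
            best_key = key
            best_t = Translation(*t)
    assert best_t is not None
    return RegistrationResult(best_t, best)


def apply_translation(mask: BinaryMask, t: Translation | tuple[int, int, int]) -> BinaryMask:
    """Shift occupancy by t voxels on the same grid; clipped, no wrap-around."""
    t = tuple(int(c) for c in t)
    n = mask.values.shape
    out = np.zeros_like(mask.values)
    dst, src = [], []
    for ti, ni in zip(t, n):
        lo = max(0, ti)
        hi = min(ni, ni + ti)
        if hi <= lo:
            return BinaryMask(mask.grid, out)
        dst.append(slice(lo, hi))
        src.append(slice(lo - ti, hi - ti))
    out[tuple(dst)] = mask.values[tuple(src)]
    return BinaryMask(mask.grid, out)
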