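"""Segmentation overlap metrics and method-agreement statistics.

Volume, Dice similarity coefficient (DSC), surface extraction, average
symmetric surface distance (ASSD), and Bland-Altman / Pearson agreement
between paired measurement series.

ASSD here uses 6-connectivity surface voxels and Euclidean distances
between voxel *centres* in world millimetres; nearest-surface distances are
found with a KD-tree and averaged over both directions:

    ASSD(A, B) = ( sum_{a in S(A)} min_b ||a - b||
                 + sum_{b in S(B)} min_a ||a - b|| ) / (|S(A)| + |S(B)|)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import pearsonr

from .image_model import BinaryMask

__all__ = ["volume_ml", "dice", "surface_voxels", "assd", "bland_altman", "AgreementStats"]


def volume_ml(mask: BinaryMask) -> float:
    """Foreground volume in millilitres (voxel count x voxel volume)."""
    return mask.count * mask.grid.voxel_volume_mm3() / 1000.0


def _check_same_grid(a: BinaryMask, b: BinaryMask) -> None:
    if not a.grid.same_geometry(b.grid):
        raise ValueError("masks live on different grids")


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|).

    Two empty masks are an error rather than a trivial 1.0 — a silently
    "perfect" degenerate overlap would hide upstream segmentation failures.
    """
    _check_same_grid(a, b)
    na, nb = a.count, b.count
    if na == 0 and nb == 0:
        raise ValueError("Dice of two empty masks is undefined")
    inter = int((a.values & b.values).sum())
    return 2.0 * inter / (na + nb)


def surface_voxels(mask: BinaryMask, connectivity: int = 6) -> BinaryMask:
    """Foreground voxels with >= 1 background (or out-of-volume) neighbour.

    ``connectivity`` 6 uses face neighbours, 26 all cube neighbours.  The
    26-neighbourhood surface is always a superset of the 6-neighbourhood one.
    """
    if mask.count == 0:
        raise ValueError("surface of an empty mask is undefined")
    if connectivity not in (6, 26):
        raise ValueError("connectivity must be 6 or 26")
    structure = ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)
    # border_value=0 treats out-of-volume as background, so voxels on the
    # image border are surface voxels.
    interior = ndimage.binary_erosion(mask.values, structure=structure, border_value=0)
    return mask.with_values(mask.values & ~interior)


def assd(a: BinaryMask, b: BinaryMask, connectivity: int = 6) -> float:
    """Average symmetric surface distance in world mm (voxel centres)."""
    _check_same_grid(a, b)
    sa = surface_voxels(a, connectivity).foreground_world()
    sb = surface_voxels(b, connectivity).foreground_world()
    d_ab, _ = cKDTree(sb).query(sa)
    d_ba, _ = cKDTree(sa).query(sb)
    return float((d_ab.sum() + d_ba.sum()) / (len(sa) + len(sb)))


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman mean difference with 95% limits of agreement, plus Pearson r."""

    mean_difference: float
    loa_low: float
    loa_high: float
    pearson_r: float

    def __post_init__(self) -> None:
        if not (self.loa_low <= self.mean_difference <= self.loa_high):
            raise ValueError("limits of agreement must bracket the mean difference")
        if not -1.0 - 1e-12 <= self.pearson_r <= 1.0 + 1e-12:
            raise ValueError("Pearson r outside [-1, 1]")


def bland_altman(x, y) -> AgreementStats:
    """Agreement between two paired measurement series.

    Differences ``d = x - y``; limits of agreement are mean(d) ± 1.96 sd(d)
    with the sample (n-1) standard deviation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D series of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired measurements")
    d = x - y
    mean_d = float(d.mean())
    sd = float(d.std(ddof=1))
    if x.std() == 0 or y.std() == 0:
        raise ValueError("Pearson r undefined for a zero-variance series")
    r = float(pearsonr(x, y).statistic)
    return AgreementStats(mean_d, mean_d - 1.96 * sd, mean_d + 1.96 * sd, r)
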