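"""Functional quantification of 4D-flow velocity fields within a mask.

Two region summaries used to characterise atrial flow:

* mean velocity — the pooled mean speed over all (voxel in mask, frame)
  pairs, reported in cm/s.  Pooled space x time averaging is identical to a
  per-frame mean of means for a fixed mask, but stated once to remove
  ambiguity.
* stasis — for each voxel, the fraction of the cardiac cycle its speed
  stays strictly below a threshold (default 0.1 m/s); reported as the
  spatial mean of that fraction over the mask, in percent.  High stasis
  marks slow, thrombosis-prone flow.

Stasis is deliberately boundary-sensitive: voxels at the blood-tissue
border carry partial-volume speeds near zero, and thresholding converts
them to fully "static", whereas mean velocity merely dilutes them.
"""

from __future__ import annotations

import numpy as np

from .image_model import BinaryMask, FourDFlowSeries, ScalarVolume

__all__ = ["mean_velocity", "stasis", "stasis_map"]

STASIS_THRESHOLD_MS = 0.1  # m/s, the conventional atrial stasis cut-off


def _masked_speeds(series: FourDFlowSeries, mask: BinaryMask) -> np.ndarray:
    """Speed (m/s) of every mask voxel at every frame, shape (N, n_voxels)."""
    if not series.grid.same_geometry(mask.grid):
        raise ValueError("mask grid does not match the flow series grid")
    if mask.count == 0:
        raise ValueError("mask is empty")
    vel = series.velocity[:, mask.values, :]  # (N, n_voxels, 3)
    return np.linalg.norm(vel, axis=-1)


def mean_velocity(series: FourDFlowSeries, mask: BinaryMask) -> float:
    """Pooled mean speed over mask voxels and frames, in cm/s."""
    return float(_masked_speeds(series, mask).mean() * 100.0)


def stasis(
    series: FourDFlowSeries,
    mask: BinaryMask,
    threshold: float = STASIS_THRESHOLD_MS,
) -> float:
    """Mean time-fraction below ``threshold`` (strict) over the mask, in %."""
    speeds = _masked_speeds(series, mask)
    below = (speeds < threshold).mean(axis=0)  # per-voxel time fraction
    return float(below.mean() * 100.0)


def stasis_map(
    series: FourDFlowSeries,
    mask: BinaryMask,
    threshold: float = STASIS_THRESHOLD_MS,
) -> ScalarVolume:
    """Per-voxel stasis fraction in [0, 1]; 0 outside the mask.

    The mask-mean of this map times 100 equals :func:`stasis` exactly.
    """
    speeds = _masked_speeds(series, mask)
    below = (speeds < threshold).mean(axis=0)
    out = np.zeros(series.grid.shape)
    out[mask.values] = below
    return ScalarVolume(series.grid, out)
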