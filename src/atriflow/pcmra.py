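"""Phase-contrast MR angiogram (PC-MRA) derivation from a 4D-flow series.

The PC-MRA is the time average, over the cardiac cycle, of the magnitude
image weighted by the velocity magnitude:

    PCMRA(r) = (1/N) * sum_i  I_i^Mag(r) * sqrt(vx_i^2 + vy_i^2 + vz_i^2)

Voxels with consistent flow throughout the cycle therefore appear bright,
producing an angiogram-like volume without contrast agent.  No intensity
rescaling or clipping is applied here; normalisation for registration
happens downstream.
"""

from __future__ import annotations

import numpy as np

from .image_model import FourDFlowSeries, ScalarVolume

__all__ = ["compute_pcmra", "speed_volume"]


def compute_pcmra(series: FourDFlowSeries) -> ScalarVolume:
    """Time-averaged magnitude-weighted speed volume on the series' grid.

    Output values are non-negative whenever the magnitudes are.
    """
    speed = np.linalg.norm(series.velocity, axis=-1)  # (N, nx, ny, nz), m/s
    values = (series.magnitude * speed).mean(axis=0)
    return ScalarVolume(series.grid, values)


def speed_volume(series: FourDFlowSeries, frame: int) -> ScalarVolume:
    """Voxelwise velocity magnitude (m/s) of one cardiac phase."""
    if not 0 <= frame < series.n_frames:
        raise IndexError(f"frame {frame} out of range [0, {series.n_frames})")
    values = np.linalg.norm(series.velocity[frame], axis=-1)
    return ScalarVolume(series.grid, values)
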