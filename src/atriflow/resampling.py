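"""Rigid resampling of masks and scalar volumes onto a target grid.

Transform direction: all transforms in this package are pull-back maps from
*target/fixed* world coordinates into *source/moving* world coordinates.
For each target voxel centre ``p`` the source is sampled at ``T(p)`` — the
same convention the registration module optimises, so a recovered transform
plugs in here directly.

Masks use nearest-neighbour interpolation (half-away-from-zero rounding of
fractional indices, stated explicitly because voxel-boundary ties otherwise
differ across platforms); scalar volumes use trilinear interpolation.
Out-of-bounds samples become background / zero.
"""

from __future__ import annotations

import numpy as np

from .image_model import BinaryMask, ImageGrid, RigidTransform, ScalarVolume

__all__ = ["resample_mask", "resample_scalar"]


def _source_indices(target: ImageGrid, t: RigidTransform, source: ImageGrid) -> np.ndarray:
    """Fractional source-voxel indices of every target voxel centre under T."""
    idx = np.indices(target.shape).reshape(3, -1).T.astype(float)
    world = target.world_from_index(idx)
    mapped = t.apply(world)
    return source.index_from_world(mapped)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round halves away from zero (platform-stable, unlike banker's rounding)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def resample_mask(mask: BinaryMask, t: RigidTransform, target: ImageGrid) -> BinaryMask:
    """Nearest-neighbour resampling of a binary mask onto ``target``."""
    src_idx = _source_indices(target, t, mask.grid)
    nn = _round_half_away(src_idx).astype(int)
    shape = np.asarray(mask.grid.shape)
    inside = np.all((nn >= 0) & (nn < shape), axis=1)
    out = np.zeros(target.n_voxels, dtype=bool)
    nn_in = nn[inside]
    out[inside] = mask.values[nn_in[:, 0], nn_in[:, 1], nn_in[:, 2]]
    return BinaryMask(target, out.reshape(target.shape), mask.label)


def resample_scalar(vol: ScalarVolume, t: RigidTransform, target: ImageGrid) -> ScalarVolume:
    """Trilinear resampling of a scalar volume onto ``target``; 0 outside."""
    from .registration import _trilinear  # shared interpolation kernel

    src_idx = _source_indices(target, t, vol.grid)
    values, inside = _trilinear(vol.values, src_idx)
    values = np.where(inside, values, 0.0)
    return ScalarVolume(target, values.reshape(target.shape))
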