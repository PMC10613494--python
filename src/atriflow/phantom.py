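"""Synthetic paired angiography / 4D-flow phantom with known ground truth.

The phantom emulates the geometry of a left-heart acquisition at desk
scale: a ~1.2 mm isotropic contrast-enhanced angiography volume and a
~3 mm, 25-phase 4D-flow series of an ellipsoidal left atrium (LA) with an
appendage lobe (LAA), four pulmonary-vein tubes (PV), a torus-arc aorta and
an ellipsoidal left ventricle (LV) on a dark background.

Scene layout is defined once in the *flow* (fixed) world frame.  The
angiography scene is posed at a known rigid transform relative to it — the
transform the registration stage must recover — and the aorta can be given
an extra "decoy" displacement, reproducing the clinical failure mode where
global registration locks onto the aortic arch (whose position relative to
the chambers differs between the time-averaged PC-MRA and the single-phase
CE-MRA).

Inter-modality intensity relationship is deliberately non-affine (gamma
remap with different per-structure contrasts), so mutual information
succeeds where a correlation metric would not.  The angiography volume also
carries a smooth multiplicative bias field and additive Gaussian noise
(additive rather than Rician: at phantom SNR the distinction is
immaterial).

Flow model: inside the true LA mask (on the flow grid) the velocity is a
rigid-body-like swirl about the atrium's long axis,

    v(x, t_i) = s_i * w(x) * omega x (x - c),    s_i = |sin(2 pi t_i / T)|,

damped near the wall by ``w(x) = min(1, dist_to_wall / boundary_layer)`` so
a low-speed boundary layer exists, as in real chambers where partial-volume
voxels mix blood and stationary tissue.  The pulmonary-vein tubes carry a
plug inflow toward the atrium with the same per-frame scaling — without
it, a noise-free PC-MRA would show only the swirl ring, which is nearly
rotationally symmetric about the swirl axis, and the rigid pose would not
be identifiable.  Everywhere else, velocity is zero-mean Gaussian noise.
Because the in-mask speed is an explicit per-voxel formula, stasis and
mean velocity over the truth mask have closed forms, stored in
:class:`PhantomTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image_model import (
    BinaryMask,
    FourDFlowSeries,
    ImageGrid,
    RigidTransform,
    ScalarVolume,
)
from .resampling import resample_mask

__all__ = ["PhantomSpec", "PhantomTruth", "generate_phantom", "perturb_mask"]

_DEG = np.pi / 180.0


def _default_transform() -> RigidTransform:
    return RigidTransform(
        angles=(5.0 * _DEG, -3.0 * _DEG, 2.0 * _DEG), translation=(6.0, -4.0, 8.0)
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters; defaults follow clinical acquisition scales.

    ``ce_spacing`` ~1.2 mm isotropic matches contrast-enhanced angiography;
    ``flow_spacing`` 3 mm and 25 phases match a conventional 4D-flow scan.
    ``omega_rad_s`` is the swirl angular speed (10 rad/s puts peak LA speeds
    near 0.4 m/s, well inside a 1.5 m/s venc); ``noise_sd`` is the velocity
    noise sd in m/s (a few percent of venc).
    """

    ce_spacing: float = 1.2
    flow_spacing: float = 3.0
    n_frames: int = 25
    la_semiaxes: tuple[float, float, float] = (32.0, 28.0, 22.0)
    true_transform: RigidTransform = field(default_factory=_default_transform)
    decoy_offset_mm: float = 0.0
    noise_sd: float = 0.05
    bias_amplitude: float = 0.2
    seed: int = 0
    omega_rad_s: float = 10.0
    boundary_layer_mm: float = 4.5
    venc: float = 1.5

    def __post_init__(self) -> None:
        if self.ce_spacing <= 0 or self.flow_spacing <= 0:
            raise ValueError("spacings must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if any(a <= 0 for a in self.la_semiaxes):
            raise ValueError("la_semiaxes must be positive")


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth of a generated phantom: the acceptance oracle."""

    transform: RigidTransform
    la_mask_ce: BinaryMask
    laa_mask_ce: BinaryMask
    pv_mask_ce: BinaryMask
    aorta_mask_ce: BinaryMask
    la_mask_flow: BinaryMask
    analytic_stasis: float
    analytic_mean_velocity: float
    la_volume_ml: float


# --------------------------------------------------------------------------
# Scene geometry, defined in the flow (fixed) world frame, LA centred at the
# origin.  Distances in mm.

# Vein geometry is deliberately irregular, as in real anatomy: a symmetric
# tube cross plus the near-spherical atrium would leave the velocity-visible
# scene with approximate discrete rotational symmetries (e.g. a half-turn
# mapping the vein set onto itself) and an ambiguous registration.
_PV_DIRECTIONS = np.array(
    [
        [0.84, 0.42, 0.34],
        [0.66, 0.58, -0.48],
        [-0.72, 0.40, 0.56],
        [-0.87, 0.48, -0.12],
    ]
)
_PV_RADII = (6.5, 5.0, 7.0, 4.5)
_PV_SPEEDS = (0.32, 0.22, 0.28, 0.18)  # m/s plug inflow per vein
_PV_LENGTH = 38.0
_LAA_CENTER = np.array([-30.0, -16.0, 6.0])
_LAA_SEMIAXES = np.array([11.0, 9.0, 8.0])
_AORTA_CENTER = np.array([0.0, -45.0, 22.0])
_AORTA_MAJOR_R = 28.0
_AORTA_TUBE_R = 10.0
_LV_CENTER = np.array([0.0, 52.0, -20.0])
_LV_SEMIAXES = np.array([30.0, 26.0, 26.0])


def _ellipsoid_soft(pts: np.ndarray, center: np.ndarray, semiaxes: np.ndarray,
                    width: float) -> np.ndarray:
    """Soft (0..1) indicator of an ellipsoid, edge blurred over ~width mm."""
    f = np.sqrt((((pts - center) / semiaxes) ** 2).sum(axis=-1))
    approx_dist = (1.0 - f) * semiaxes.min()
    return np.clip(0.5 + approx_dist / (2.0 * width), 0.0, 1.0)


def _ellipsoid_hard(pts: np.ndarray, center: np.ndarray, semiaxes: np.ndarray) -> np.ndarray:
    return (((pts - center) / semiaxes) ** 2).sum(axis=-1) <= 1.0


def _capsule_distance(pts: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    """Distance from points to the segment p0-p1."""
    d = p1 - p0
    t = np.clip(((pts - p0) @ d) / (d @ d), 0.0, 1.0)
    proj = p0 + t[..., None] * d
    return np.linalg.norm(pts - proj, axis=-1)


def _pv_segments(
    semiaxes: np.ndarray,
) -> list[tuple[np.ndarray, np.ndarray, float, float]]:
    """(start, end, radius_mm, inflow_speed_m_s) of each pulmonary-vein tube."""
    segs = []
    for direction, radius, speed in zip(_PV_DIRECTIONS, _PV_RADII, _PV_SPEEDS):
        u = direction / np.linalg.norm(direction)
        # radius of the LA ellipsoid along u
        r_surf = 1.0 / np.sqrt(((u / semiaxes) ** 2).sum())
        p0 = u * (0.85 * r_surf)  # start just inside the wall so tube connects
        p1 = u * (r_surf + _PV_LENGTH)
        segs.append((p0, p1, radius, speed))
    return segs


def _aorta_distance(pts: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Distance to the upper-half torus arc (axis along y)."""
    rel = pts - center
    ring = np.sqrt(rel[..., 0] ** 2 + rel[..., 2] ** 2) - _AORTA_MAJOR_R
    dist = np.sqrt(ring**2 + rel[..., 1] ** 2)
    # restrict to the arch (upper half, z above centre); below it the tube
    # is "cut", so distance grows with depth below the cut plane
    below = np.maximum(0.0, -rel[..., 2])
    return np.sqrt(dist**2 + below**2)


def _structure_fields(
    pts: np.ndarray, spec: PhantomSpec, aorta_shift: np.ndarray, width: float
) -> dict[str, np.ndarray]:
    """Soft indicators (0..1) of every structure at world points ``pts``."""
    semi = np.asarray(spec.la_semiaxes)
    la = _ellipsoid_soft(pts, np.zeros(3), semi, width)
    laa = _ellipsoid_soft(pts, _LAA_CENTER, _LAA_SEMIAXES, width)
    pv = np.zeros(pts.shape[:-1])
    for p0, p1, radius, _speed in _pv_segments(semi):
        d = _capsule_distance(pts, p0, p1)
        pv = np.maximum(pv, np.clip(0.5 + (radius - d) / (2.0 * width), 0.0, 1.0))
    ao_d = _aorta_distance(pts - aorta_shift, _AORTA_CENTER)
    aorta = np.clip(0.5 + (_AORTA_TUBE_R - ao_d) / (2.0 * width), 0.0, 1.0)
    lv = _ellipsoid_soft(pts, _LV_CENTER, _LV_SEMIAXES, width)
    return {"LA": la, "LAA": laa, "PV": pv, "AORTA": aorta, "LV": lv}


def _structure_masks(
    pts: np.ndarray, spec: PhantomSpec, aorta_shift: np.ndarray
) -> dict[str, np.ndarray]:
    """Hard, mutually disjoint masks with precedence LA > LAA > PV > AORTA > LV."""
    semi = np.asarray(spec.la_semiaxes)
    la = _ellipsoid_hard(pts, np.zeros(3), semi)
    laa = _ellipsoid_hard(pts, _LAA_CENTER, _LAA_SEMIAXES) & ~la
    pv = np.zeros(pts.shape[:-1], dtype=bool)
    for p0, p1, radius, _speed in _pv_segments(semi):
        pv |= _capsule_distance(pts, p0, p1) <= radius
    pv &= ~(la | laa)
    aorta = (_aorta_distance(pts - aorta_shift, _AORTA_CENTER) <= _AORTA_TUBE_R) & ~(
        la | laa | pv
    )
    return {"LA": la, "LAA": laa, "PV": pv, "AORTA": aorta}


# Per-structure blood signal in each modality.  Chosen differently per
# modality (and gamma-remapped on the CE side) so the inter-modality
# intensity relationship is non-affine.
_CE_WEIGHTS = {"LA": 1.0, "LAA": 0.95, "PV": 0.9, "AORTA": 1.0, "LV": 0.55}
_MAG_WEIGHTS = {"LA": 0.55, "LAA": 0.5, "PV": 0.6, "AORTA": 1.0, "LV": 0.8}
_CE_GAMMA = 0.6
_CE_SCALE = 1000.0
_CE_TISSUE = 0.08
_MAG_TISSUE = 0.3


def _grids(spec: PhantomSpec) -> tuple[ImageGrid, ImageGrid]:
    """Flow and CE grids covering the scene with margin for misalignment."""
    lo = np.array([-81.0, -102.0, -69.0])
    hi = np.array([81.0, 84.0, 75.0])
    extent = hi - lo
    flow_shape = tuple(int(np.ceil(e / spec.flow_spacing)) for e in extent)
    ce_shape = tuple(int(np.ceil(e / spec.ce_spacing)) for e in extent)
    flow = ImageGrid.from_spacing(flow_shape, spec.flow_spacing, tuple(lo))
    ce = ImageGrid.from_spacing(ce_shape, spec.ce_spacing, tuple(lo))
    return flow, ce


def _grid_points(grid: ImageGrid) -> np.ndarray:
    idx = np.indices(grid.shape).reshape(3, -1).T.astype(float)
    return grid.world_from_index(idx)


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[ScalarVolume, FourDFlowSeries, PhantomTruth]:
    """Generate a paired CE-angiography volume and 4D-flow series.

    Deterministic given ``spec.seed``.  The returned truth carries the posing
    transform (a pull-back from flow world into angiography world, directly
    comparable with the registration result), the structure masks on both
    grids, and closed-form hemodynamics of the swirl field.
    """
    rng = np.random.default_rng(spec.seed)
    flow_grid, ce_grid = _grids(spec)
    semi = np.asarray(spec.la_semiaxes)

    # --- sanity: the LA (plus the misalignment) must stay inside the FOV
    flow_lo = flow_grid.world_from_index((0, 0, 0))
    flow_hi = flow_grid.world_from_index(tuple(np.asarray(flow_grid.shape) - 1))
    if np.any(-semi < flow_lo + spec.flow_spacing) or np.any(semi > flow_hi - spec.flow_spacing):
        raise ValueError("LA extends outside the field of view")

    edge = 1.0  # mm, partial-volume edge width of the soft indicators
    decoy_vec = spec.decoy_offset_mm * np.array([0.0, -0.8, 0.6])

    # --- CE angiography volume: anatomy posed at truth.transform.
    # transform maps fixed (flow) world -> moving (CE) world, so the scene
    # at a CE point q is the anatomy evaluated at transform^-1(q).
    t_inv = spec.true_transform.inverse()
    ce_pts_world = _grid_points(ce_grid)
    ce_pts_anat = t_inv.apply(ce_pts_world)
    fields = _structure_fields(ce_pts_anat, spec, decoy_vec, edge)
    blood = np.zeros(ce_pts_anat.shape[0])
    for name, f in fields.items():
        blood = np.maximum(blood, _CE_WEIGHTS[name] * f)
    signal = _CE_SCALE * (_CE_TISSUE + (1.0 - _CE_TISSUE) * blood) ** _CE_GAMMA
    # smooth multiplicative bias field (low-order polynomial in normalised coords)
    span = ce_pts_world.max(axis=0) - ce_pts_world.min(axis=0)
    nrm = (ce_pts_world - ce_pts_world.min(axis=0)) / span * 2.0 - 1.0
    bias = 1.0 + spec.bias_amplitude * 0.5 * (
        nrm[:, 0] + 0.6 * nrm[:, 1] ** 2 - 0.8 * nrm[:, 2]
    )
    # CE noise scales with the velocity-noise setting so a "noise-free"
    # phantom is noise-free in both modalities (0.4 * 0.05 = 2% of scale at
    # the defaults)
    ce_noise_sd = 0.4 * spec.noise_sd * _CE_SCALE
    signal = signal * bias + rng.normal(0.0, ce_noise_sd, size=signal.shape)
    ce_volume = ScalarVolume(ce_grid, np.maximum(signal, 0.0).reshape(ce_grid.shape))

    # --- truth masks on the CE grid (hard indicators, disjoint)
    ce_masks = _structure_masks(ce_pts_anat, spec, decoy_vec)
    shape = ce_grid.shape
    la_ce = BinaryMask(ce_grid, ce_masks["LA"].reshape(shape), "LA")
    laa_ce = BinaryMask(ce_grid, ce_masks["LAA"].reshape(shape), "LAA")
    pv_ce = BinaryMask(ce_grid, ce_masks["PV"].reshape(shape), "PV")
    aorta_ce = BinaryMask(ce_grid, ce_masks["AORTA"].reshape(shape), "AORTA")

    # --- flow-grid truth LA mask, constructed by the same resampling used
    # downstream so the two representations agree exactly
    la_flow = resample_mask(la_ce, spec.true_transform, flow_grid)

    # --- 4D-flow series on the flow grid (anatomy frame = flow world frame)
    flow_pts = _grid_points(flow_grid)
    mag_fields = _structure_fields(flow_pts, spec, np.zeros(3), edge)
    mag_blood = np.zeros(flow_pts.shape[0])
    for name, f in mag_fields.items():
        mag_blood = np.maximum(mag_blood, _MAG_WEIGHTS[name] * f)
    mag_base = _MAG_TISSUE + (1.4 - _MAG_TISSUE) * mag_blood

    n = spec.n_frames
    t_frac = (np.arange(n) + 0.5) / n
    s_i = np.abs(np.sin(2.0 * np.pi * t_frac))  # per-frame swirl scaling

    in_la = la_flow.values.reshape(-1)
    # wall-distance damping: low-speed boundary layer inside the LA
    dist_mm = ndimage.distance_transform_edt(
        la_flow.values, sampling=flow_grid.spacing
    ).reshape(-1)
    damping = np.minimum(1.0, dist_mm / spec.boundary_layer_mm)
    # swirl about the z axis through the LA centre (origin), in m/s
    rel_m = flow_pts / 1000.0
    swirl = spec.omega_rad_s * np.stack(
        [-rel_m[:, 1], rel_m[:, 0], np.zeros(len(rel_m))], axis=-1
    )
    swirl *= damping[:, None]
    swirl[~in_la] = 0.0

    # plug inflow (m/s, toward the LA) inside the PV tubes
    pv_flow = np.zeros_like(swirl)
    in_pv = np.zeros(len(flow_pts), dtype=bool)
    for p0, p1, radius, speed in _pv_segments(semi):
        seg = _capsule_distance(flow_pts, p0, p1) <= radius
        u = (p1 - p0) / np.linalg.norm(p1 - p0)
        pv_flow[seg] = -speed * u  # flow from vein into the atrium
        in_pv |= seg
    in_pv &= ~in_la
    swirl[in_pv] = pv_flow[in_pv]

    velocity = np.empty((n,) + flow_grid.shape + (3,))
    magnitude = np.empty((n,) + flow_grid.shape)
    noise_vel = rng.normal(0.0, spec.noise_sd, size=(n, len(flow_pts), 3))
    noise_vel[:, in_la | in_pv, :] = 0.0
    noise_mag = rng.normal(0.0, spec.noise_sd, size=(n, len(flow_pts)))
    for i in range(n):
        v = swirl * s_i[i] + noise_vel[i]
        velocity[i] = v.reshape(flow_grid.shape + (3,))
        magnitude[i] = np.maximum(mag_base + noise_mag[i], 0.0).reshape(flow_grid.shape)
    flow = FourDFlowSeries(
        flow_grid, magnitude, velocity, venc=spec.venc, frame_duration_ms=40.0
    )

    # --- closed-form hemodynamics over the truth flow mask
    speed_coeff = (
        spec.omega_rad_s
        * damping[in_la]
        * np.sqrt(rel_m[in_la, 0] ** 2 + rel_m[in_la, 1] ** 2)
    )  # per-voxel peak speed (m/s); speed at frame i = coeff * s_i
    speeds = speed_coeff[:, None] * s_i[None, :]
    analytic_stasis = float((speeds < 0.1).mean() * 100.0)
    analytic_mean_velocity = float(speeds.mean() * 100.0)
    la_volume = la_ce.count * ce_grid.voxel_volume_mm3() / 1000.0

    truth = PhantomTruth(
        transform=spec.true_transform,
        la_mask_ce=la_ce,
        laa_mask_ce=laa_ce,
        pv_mask_ce=pv_ce,
        aorta_mask_ce=aorta_ce,
        la_mask_flow=la_flow,
        analytic_stasis=analytic_stasis,
        analytic_mean_velocity=analytic_mean_velocity,
        la_volume_ml=la_volume,
    )
    return ce_volume, flow, truth


def perturb_mask(mask: BinaryMask, target_dice: float, seed: int = 0) -> BinaryMask:
    """Randomly dilate/erode a mask's boundary to a prescribed Dice overlap.

    A smooth Gaussian random field is added to the mask's signed distance
    map and the zero level set re-thresholded; the field amplitude is
    bisected until Dice(mask, out) is within ±0.02 of ``target_dice``.
    Deterministic given ``seed``.
    """
    from .metrics import dice as _dice

    if not 0.0 < target_dice < 1.0:
        raise ValueError("target_dice must be strictly inside (0, 1)")
    if mask.count == 0:
        raise ValueError("cannot perturb an empty mask")
    rng = np.random.default_rng(seed)
    spacing = mask.grid.spacing
    # signed distance (mm): negative inside, positive outside
    d_out = ndimage.distance_transform_edt(~mask.values, sampling=spacing)
    d_in = ndimage.distance_transform_edt(mask.values, sampling=spacing)
    signed = d_out - d_in
    noise = rng.normal(size=mask.grid.shape)
    noise = ndimage.gaussian_filter(noise, sigma=6.0 / spacing)  # ~6 mm correlation
    noise /= noise.std()

    def dice_at(alpha: float) -> tuple[float, np.ndarray]:
        out = signed + alpha * noise < 0.0
        if not out.any():
            return 0.0, out
        return _dice(mask, mask.with_values(out)), out

    lo, hi = 0.0, 1.0
    d_hi, out_hi = dice_at(hi)
    attempts = 0
    while d_hi > target_dice and attempts < 30:  # grow until we overshoot the target
        hi *= 2.0
        d_hi, out_hi = dice_at(hi)
        attempts += 1
    if d_hi > target_dice:
        raise ValueError(f"target Dice {target_dice} unreachable for this mask")
    best_alpha = hi
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        d_mid, out_mid = dice_at(mid)
        if abs(d_mid - target_dice) <= 0.02:
            best_alpha = mid
            break
        if d_mid > target_dice:
            lo = mid
        else:
            hi = mid
    else:
        raise ValueError(
            f"could not reach Dice {target_dice} ± 0.02 within bounded attempts"
        )
    _, out = dice_at(best_alpha)
    return mask.with_values(out)
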