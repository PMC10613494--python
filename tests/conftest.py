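import numpy as np
import pytest

import atriflow as af


def transform_error(t: af.RigidTransform, reference: af.RigidTransform,
                    point=(0.0, 0.0, 0.0)) -> tuple[float, float]:
    """(translation error at a point in mm, rotation error in degrees)."""
    p = np.asarray(point, dtype=float)
    e_t = float(np.linalg.norm(t.apply(p) - reference.apply(p)))
    r = t.matrix()[:3, :3] @ reference.matrix()[:3, :3].T
    e_r = float(np.degrees(np.arccos(np.clip((np.trace(r) - 1.0) / 2.0, -1.0, 1.0))))
    return e_t, e_r


def random_rigid(rng: np.random.Generator, max_translation_mm: float = 10.0,
                 max_rotation_deg: float = 10.0, center=(0.0, 0.0, 0.0)) -> af.RigidTransform:
    angles = np.radians(rng.uniform(-max_rotation_deg, max_rotation_deg, 3))
    translation = rng.uniform(-max_translation_mm, max_translation_mm, 3)
    translation *= rng.uniform(0.3, 1.0) * max_translation_mm / max(
        np.linalg.norm(translation), 1e-9
    )
    return af.RigidTransform(tuple(angles), tuple(translation), tuple(center))


@pytest.fixture(scope="session")
def clean_phantom():
    """Default-condition phantom shared across test modules (no decoy)."""
    return af.generate_phantom(af.PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def coarse_phantom():
    """Fast low-resolution phantom for end-to-end and determinism checks."""
    spec = af.PhantomSpec(ce_spacing=2.4, flow_spacing=6.0, n_frames=8, seed=4)
    return spec, af.generate_phantom(spec)


@pytest.fixture(scope="session")
def pcmra_corrected(clean_phantom):
    _, flow, _ = clean_phantom
    return af.bias_correct(af.compute_pcmra(flow))
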