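"""Shared fixtures: the default synthetic mouse study, built once per session."""

import numpy as np
import pytest

import voxdose as vd


@pytest.fixture(scope="session")
def mouse():
    """Default phantom: (MaterialMap, VoiSet, HU volume)."""
    return vd.build_mouse_phantom()


@pytest.fixture(scope="session")
def truth(mouse):
    _, voi, _ = mouse
    return vd.default_kinetic_truth(voi)


@pytest.fixture(scope="session")
def schedule():
    return vd.default_frame_schedule()


@pytest.fixture(scope="session")
def noise_free_study(mouse, truth, schedule):
    """Noise-free rendered frames plus the ground-truth TACs and activity."""
    _, voi, _ = mouse
    times, durs = schedule
    injected = 3.10
    tacs, unc = vd.simulate_tacs(truth, times, injected, durs)
    frames = vd.render_pet_frames(voi, unc, times, durs, noise=None)
    return {"frames": frames, "tacs": tacs, "uncorrected_mbq": unc,
            "injected_mbq": injected, "times": times, "durations": durs}


@pytest.fixture(scope="session")
def soft_cube():
    """Uniform soft-tissue cube factory for MC checks (20 mm, 1 mm voxels)."""
    from voxdose.materials import MaterialMap, default_materials
    from voxdose.volume import ImageVolume

    def build(n_decays: int, n: int = 20, voxel_mm: float = 1.0):
        soft = default_materials()[2]
        mat = MaterialMap(np.zeros((n, n, n), dtype=np.int8), [soft],
                          (voxel_mm,) * 3)
        conc = n_decays / (n**3 * voxel_mm**3 / 1000.0)
        src = ImageVolume(np.full((n, n, n), conc), (voxel_mm,) * 3, "Bq/ml")
        return src, mat

    return build
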