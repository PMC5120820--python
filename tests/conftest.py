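"""Shared phantom fixtures (session-scoped: rasterization is the slow part)."""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from pulse4d.phantom import PhantomSpec, generate_phantom_noisefree
from pulse4d.segmentation import keep_component, threshold_lumen
from pulse4d.surface import extract_mesh_sequence
from pulse4d.volume import CTVolume4D


def make_volume(spec: PhantomSpec, hu4: np.ndarray) -> CTVolume4D:
    return CTVolume4D(voxels=hu4, spacing=np.asarray(spec.spacing))


@pytest.fixture(scope="session")
def still_phantom():
    """Non-pulsating, noise-free phantom (identical analytic geometry per phase)."""
    spec = PhantomSpec(pulsation_amplitude=1.0, noise_fraction=0.0)
    hu4, truth = generate_phantom_noisefree(spec)
    return spec, hu4, truth


@pytest.fixture(scope="session")
def pulsating_phantom():
    """Noise-free phantom pulsating at amplitude 1.06 (a cohort-typical value)."""
    spec = PhantomSpec(pulsation_amplitude=1.06, noise_fraction=0.0)
    hu4, truth = generate_phantom_noisefree(spec)
    return spec, hu4, truth


@pytest.fixture(scope="session")
def pulsating_meshes(pulsating_phantom):
    """3D+t model of the pulsating phantom at the half-maximum iso-value."""
    spec, hu4, truth = pulsating_phantom
    vol = make_volume(spec, hu4)
    mask = threshold_lumen(vol)
    seed = tuple(int(round(i)) for i in vol.world_to_index(np.asarray(spec.aneurysm_center)))
    mask = keep_component(mask, seed)
    seq = extract_mesh_sequence(vol, mask, iso=220.0)
    return spec, truth, seq


@pytest.fixture(scope="session")
def still_meshes(still_phantom):
    spec, hu4, truth = still_phantom
    vol = make_volume(spec, hu4)
    mask = threshold_lumen(vol)
    seed = tuple(int(round(i)) for i in vol.world_to_index(np.asarray(spec.aneurysm_center)))
    mask = keep_component(mask, seed)
    seq = extract_mesh_sequence(vol, mask, iso=220.0)
    return spec, truth, seq
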