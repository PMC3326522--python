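"""Shared fixtures: small phantom models, maps and stacks, built once."""

import numpy as np
import pytest

import conformosort.phantom as ph


@pytest.fixture(scope="session")
def geometry():
    return ph.reference_subunit()


@pytest.fixture(scope="session")
def model_T():
    return ph.build_state_model("T", "T")


@pytest.fixture(scope="session")
def model_Rs1():
    return ph.build_state_model("Rs1", "T")


@pytest.fixture(scope="session")
def model_Rs2():
    return ph.build_state_model("Rs2", "T")


@pytest.fixture(scope="session")
def model_Rs_open():
    return ph.build_state_model("Rs_open", "T")


@pytest.fixture(scope="session")
def map_T48(model_T):
    """T-state density on the small test grid (48 voxels at 4 A)."""
    return ph.synthesize_density(model_T, 4.0, 48, 9.0)


@pytest.fixture(scope="session")
def rs_maps48(model_Rs1, model_Rs2, model_Rs_open):
    return [ph.synthesize_density(m, 4.0, 48, 9.0)
            for m in (model_Rs1, model_Rs2, model_Rs_open)]


@pytest.fixture(scope="session")
def noisefree_stack_T(model_T):
    """Small noise-free side-view stack of the T state, no shifts, no CTF."""
    return ph.simulate_stack([model_T], 24, ctf=None, snr=np.inf, seed=11,
                             voxel_A=4.0, box_vox=48, resolution_A=9.0,
                             shift_max_px=0.0, interp_order=1)
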