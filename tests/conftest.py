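import numpy as np
import pytest

from iirbssfp import ParamGrid, PhantomSpec, SequenceParams, build_dictionary, build_phantom


@pytest.fixture(scope="session")
def seq40() -> SequenceParams:
    """Default acquisition with enough cycles for long-T1 convergence."""
    return SequenceParams(n_cycles_max=40)


@pytest.fixture(scope="session")
def phantom64():
    """Noisy (SNR 50) full tumor phantom at 64^3 / 2 mm, fixed seed."""
    return build_phantom(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def phantom32_noiseless_lesion_free():
    """Noise- and bias-free WM/GM/CSF-only phantom at 32^3 / 4 mm."""
    spec = PhantomSpec(
        shape_voxels=(32,) * 3,
        voxel_size_mm=(4.0,) * 3,
        snr=np.inf,
        bias_field_order=0,
        include_lesion=False,
        seed=0,
    )
    return build_phantom(spec)


@pytest.fixture(scope="session")
def coarse_dict():
    """Runtime-scale dictionary (~10% T1/T2 steps, MF step 0.02)."""
    return build_dictionary(ParamGrid.coarse())


@pytest.fixture(scope="session")
def tiny_dict():
    """Small dictionary on a short inversion interval for fast matching tests."""
    seq = SequenceParams(tinv_ms=1000.0, n_frames=20, n_cycles_max=60)
    grid = ParamGrid(
        t1_values_ms=np.geomspace(300.0, 3000.0, 8),
        t2_values_ms=np.geomspace(20.0, 280.0, 8),
        mf_values=np.array([0.0, 0.05, 0.10, 0.20]),
    )
    return build_dictionary(grid, seq)
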