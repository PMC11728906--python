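import numpy as np
import pytest

from octcoreg.phantom import PhantomSpec, SutureSpec, generate_shaving_phantom
from octcoreg.volume_io import OCTVolume, StressStrainCurve


@pytest.fixture(scope="session")
def small_phantom():
    """A mixed-tissue phantom with a suture, shared across read-only tests."""
    spec = PhantomSpec(
        extent_um=(9000.0, 9000.0, 1200.0),
        spacing_lateral_um=30.0,
        spacing_axial_um=10.0,
        adipose_fraction=0.3,
        seed=1,
        suture=SutureSpec(centroid_um=(4500.0, 4500.0), length_um=2000.0, width_um=200.0, axis_deg=20.0, protrusion_um=60.0),
    )
    wf, truth = generate_shaving_phantom(spec)
    return spec, wf, truth


@pytest.fixture(scope="session")
def flat_qme_phantom():
    """A flat, dense-only phantom suitable for elastography forward/inverse tests."""
    spec = PhantomSpec(
        extent_um=(2000.0, 2000.0, 1500.0),
        spacing_lateral_um=40.0,
        spacing_axial_um=10.0,
        adipose_fraction=0.0,
        thermal_fraction=0.0,
        seed=3,
        suture=SutureSpec(present=False),
        surface_topography_amplitude_um=0.0,
        base_surface_depth_um=30.0,
    )
    wf, truth = generate_shaving_phantom(spec)
    truth.elasticity_map_kPa[:] = 20.0
    return wf, truth


@pytest.fixture
def linear_layer_curve():
    """A linear 20 kPa/strain layer characterization."""
    return StressStrainCurve(np.array([0.0, 0.05, 0.1, 0.2]), np.array([0.0, 1.0, 2.0, 4.0]))


@pytest.fixture
def tiny_volume():
    rng = np.random.default_rng(0)
    data = rng.integers(0, 4096, size=(8, 8, 8), dtype=np.uint16)
    return OCTVolume(data, spacing_z_um=3.4, spacing_y_um=12.7, spacing_x_um=12.7, role="in_vivo_tile", tile_id="t0")
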