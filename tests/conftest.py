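import numpy as np
import pytest

from pausim import acoustics, beamform, core, pipeline


@pytest.fixture(scope="session")
def geometry():
    """Default-scale probe: 128 elements, 20 fibers."""
    return core.build_probe_geometry()


@pytest.fixture(scope="session")
def small_geometry():
    return core.build_probe_geometry(n_elements=48, element_pitch=0.26e-3)


@pytest.fixture(scope="session")
def small_grid():
    return core.ImageGrid.centered(11e-3, 7e-3, 0.1e-3, z0=2e-3, pitch_axial=0.04e-3)


@pytest.fixture(scope="session")
def speckle_frames(small_geometry, small_grid):
    """Two B-mode frames of the same dense scatterer field, the second with
    the scatterers rigidly shifted by (0.12 mm axial, 0.06 mm lateral)."""
    rng = np.random.default_rng(42)
    n = 30000  # >= 10 scatterers per resolution cell: fully developed speckle
    pos = np.column_stack([
        rng.uniform(-5.5e-3, 5.5e-3, n), np.zeros(n), rng.uniform(1.5e-3, 9.5e-3, n),
    ])
    refl = rng.normal(0.0, 1.0, n)
    nt = acoustics.n_samples_for(small_grid, small_geometry, "us")
    shift = np.array([0.06e-3, 0.0, 0.12e-3])
    rf0 = acoustics.simulate_us_rf(pos, refl, small_geometry, n_time=nt)
    rf1 = acoustics.simulate_us_rf(pos + shift, refl, small_geometry, n_time=nt)
    b0 = beamform.das_us(rf0, small_geometry, small_grid, f_number=2.0)
    b1 = beamform.das_us(rf1, small_geometry, small_grid, f_number=2.0)
    return b0, b1, shift


@pytest.fixture(scope="session")
def demo_result():
    """One full pipeline run on the built-in demo scene (shared: read-only)."""
    return pipeline.run_pipeline(pipeline.demo_config(), seed=1)
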