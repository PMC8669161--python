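import numpy as np
import pytest

import spectune as st
from spectune.synthetic import SceneGeometry, make_population


@pytest.fixture(scope="session")
def protocol():
    return st.make_stimulus_protocol()


@pytest.fixture(scope="session")
def cones():
    return st.make_cone_tunings()


@pytest.fixture(scope="session")
def basis(protocol):
    return st.make_temporal_basis(protocol)


@pytest.fixture(scope="session")
def small_population():
    return make_population(n_per_group=4, noise_sd=0.05, n_repeats=5, seed=7)


@pytest.fixture(scope="session")
def small_records(small_population, protocol, cones, basis):
    return st.simulate_roi_traces(small_population, protocol, cones, basis)


@pytest.fixture(scope="session")
def fast_protocol():
    """Reduced protocol for image-stack tests: fewer LEDs, coarse sampling."""
    return st.make_stimulus_protocol(
        led_peaks_nm=(622.0, 550.0, 501.0, 448.0, 407.0),
        led_powers_uw=(0.44,) * 5,
        central_led_indices=(1, 2, 3),
        frame_rate_hz=4.0,
        pre_stim_s=2.0,
    )


@pytest.fixture(scope="session")
def small_geometry():
    return SceneGeometry(nx=96, ny=48, n_planes=1, min_separation_px=9.0)


@pytest.fixture(scope="session")
def scene_bundle(fast_protocol, cones):
    """A single-plane high-SNR scene with 18 well-separated terminals."""
    geometry = SceneGeometry(nx=128, ny=64, n_planes=1, min_separation_px=9.0)
    population = make_population(n_per_group=3, noise_sd=0.0, n_repeats=5, seed=11)
    scene = st.simulate_triplane_stack(
        population, fast_protocol, cones, geometry=geometry
    )
    return scene, population, fast_protocol, geometry
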