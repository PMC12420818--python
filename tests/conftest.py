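import numpy as np
import pytest

from kinetoquant import synthgen as sg


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_cell_scene():
    """A compact rendered mitotic cell (few z-slices) for unit tests."""
    spec = sg.SceneSpec(
        shape_px=(160, 160),
        n_z=3,
        chromatin_axes_px=(38.0, 52.0),
        cell_axes_px=(66.0, 76.0),
    )
    rng = np.random.default_rng(11)
    centers = sg.scatter_spots_in_ellipse(
        rng, (79.5, 79.5), spec.chromatin_axes_px, n=25, min_sep_px=12.0
    )
    amp = sg.amplitude_for_snr(10.0, spec.cytoplasm_photons, spec.read_noise_sd)
    spec.spots = [
        sg.SpotSpec(center_px=c, amplitudes={"reference_kt": amp, "measure_1": amp * 0.6})
        for c in centers
    ]
    stack, truth = sg.render_scene(spec, seed=11)
    return spec, stack, truth


@pytest.fixture(scope="session")
def noiseless_cell_scene(small_cell_scene):
    spec, _, _ = small_cell_scene
    stack, truth = sg.render_scene(spec, seed=11, noise=False)
    return spec, stack, truth
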