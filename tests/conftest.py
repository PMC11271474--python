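import numpy as np
import pytest

from rodfission.popgen import (
    ImageSpec,
    PopulationConfig,
    TrueCell,
    make_reference_measurements,
    render_population_image,
)

PX = 0.029  # µm per pixel used throughout the image fixtures


def render_single(length, width=0.5, division_fraction=None, is_sphere=False,
                  seed=3, noise_sigma=0.0):
    """Render one cell in an image sized to fit it."""
    side = max(200, int(length / PX) + 100)
    spec = ImageSpec(noise_sigma=noise_sigma, image_shape=(side, side))
    cell = TrueCell("c0", length, width, division_fraction=division_fraction,
                    is_sphere=is_sphere)
    return render_population_image([cell], spec, seed=seed), spec


@pytest.fixture(scope="session")
def reference_measurements():
    """The canonical 300-cell division dataset (200/70/30 composition)."""
    cells, records = make_reference_measurements(seed=11)
    return cells, records


@pytest.fixture(scope="session")
def noise_free_rod_scenes():
    """Noise-free single-rod renders across the tested length range."""
    return {L: render_single(L) for L in (1.0, 2.0, 5.0, 8.0, 12.0)}


@pytest.fixture(scope="session")
def constricted_scenes():
    """Noise-free renders of dividing cells with known septum positions."""
    cases = [(3.0, 0.5), (6.0, 1.0 / 3.0), (9.0, 0.25)]
    return {
        (L, f): render_single(L, division_fraction=f, seed=5) for L, f in cases
    }


@pytest.fixture(scope="session")
def multi_cell_scene():
    """A noise-free scene with several non-touching cells of mixed shape."""
    cells = [
        TrueCell("a", 3.0, 0.5),
        TrueCell("b", 6.0, 0.5, division_fraction=1.0 / 3.0),
        TrueCell("c", 2.0, 0.5),
        TrueCell("d", 0.8, 0.8, is_sphere=True),
        TrueCell("e", 4.0, 0.5, division_fraction=0.5),
    ]
    spec = ImageSpec(noise_sigma=0.0, image_shape=(600, 600))
    return render_population_image(cells, spec, seed=9), spec
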