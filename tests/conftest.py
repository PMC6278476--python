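import numpy as np
import pytest

from chrysospec import (
    SceneSpec,
    WavelengthGrid,
    correct_reflectance,
    make_variety_profiles,
    render_scene,
)


@pytest.fixture(scope="session")
def default_grid() -> WavelengthGrid:
    """The acquisition grid: 256 bands spanning 874-1734 nm."""
    return WavelengthGrid.linspace(874.0, 1734.0, 256)


@pytest.fixture(scope="session")
def small_scene():
    """One 120x120 scene: 7 varieties x 3 samples, with references."""
    profiles = make_variety_profiles(7, seed=42)
    spec = SceneSpec(height=120, width=120, samples_per_class=3, seed=5)
    return render_scene(spec, profiles), profiles


@pytest.fixture(scope="session")
def small_reflectance(small_scene):
    scene, profiles = small_scene
    refl = correct_reflectance(scene.raw_cube, scene.white_cube, scene.dark_cube)
    return refl, scene, profiles


@pytest.fixture(scope="session")
def noiseless_scene():
    """A scene with zero pixel noise and zero within-class spread."""
    profiles = make_variety_profiles(
        7, seed=3, within_class_sd=0.0, pixel_noise_sd=0.0
    )
    spec = SceneSpec(height=140, width=140, samples_per_class=3, seed=9)
    scene = render_scene(spec, profiles)
    refl = correct_reflectance(scene.raw_cube, scene.white_cube, scene.dark_cube)
    return refl, scene, profiles


def make_easy_table(n_per_class: int = 40, n_classes: int = 7, n_bands: int = 200,
                    seed: int = 0, sep: float = 0.05, noise: float = 0.005):
    """Directly drawn well-separated mean spectra (no scene rendering)."""
    from chrysospec import SpectraTable

    grid = WavelengthGrid.linspace(975.0, 1646.0, n_bands)
    profiles = make_variety_profiles(
        n_classes, seed, class_offset_step=sep, within_class_sd=noise,
        pixel_noise_sd=0.001, near_overlap_pair=False,
    )
    rng = np.random.default_rng(seed + 1)
    rows, labels = [], []
    for p in profiles:
        base = p.mean_curve(grid.centers)
        for _ in range(n_per_class):
            rows.append(base + rng.normal(0, noise) + rng.normal(0, 0.001, n_bands))
            labels.append(p.class_id)
    return SpectraTable(np.array(rows), np.array(labels), grid)
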