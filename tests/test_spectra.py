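"""Band cropping, wavelet smoothing, ROI means, table building, splitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chrysospec import (
    HyperCube,
    SpectraTable,
    WavelengthGrid,
    build_table,
    crop_bands,
    mean_spectrum,
    split_dataset,
    wavelet_smooth,
)
from chrysospec.exceptions import InvalidArgumentError
from chrysospec.segmentation import SampleMask


def _table(n_bands=256, n_rows=4, grid=None, labels=None, seed=0):
    grid = grid or WavelengthGrid.linspace(874, 1734, n_bands)
    rng = np.random.default_rng(seed)
    labels = labels if labels is not None else np.ones(n_rows, int)
    return SpectraTable(rng.uniform(0.1, 0.9, (len(labels), len(grid))), labels, grid)


class TestCropBands:
    def test_default_crop_keeps_middle_200_bands(self):
        table = _table(256)
        out = crop_bands(table)
        assert out.n_bands == 200
        lo, hi = out.grid.span
        spacing = out.grid.mean_spacing
        assert abs(lo - 975.0) <= spacing / 2
        assert abs(hi - 1646.0) <= spacing / 2
        assert out.meta["crop_index_range"] == (30, 229)

    def test_crop_applies_to_cubes_too(self, default_grid):
        cube = HyperCube(np.zeros((4, 4, 256), np.float32), default_grid)
        out = crop_bands(cube)
        assert out.n_bands == 200
        assert out.meta["crop_index_range"] == (30, 229)

    def test_identity_index_range(self):
        table = _table(200, grid=WavelengthGrid.linspace(975, 1646, 200))
        out = crop_bands(table, policy="index_range", index_range=(0, 199))
        assert np.array_equal(out.spectra, table.spectra)
        assert np.array_equal(out.grid.centers, table.grid.centers)

    def test_too_short_grid_rejected(self):
        with pytest.raises(InvalidArgumentError):
            crop_bands(_table(100, grid=WavelengthGrid.linspace(874, 1734, 100)))


class TestWaveletSmooth:
    def test_constant_spectrum_passes_unchanged(self):
        x = np.full(200, 0.42)
        assert np.max(np.abs(wavelet_smooth(x) - x)) < 1e-10

    def test_high_frequency_ripple_is_attenuated(self):
        grid = np.linspace(975, 1646, 200)
        smooth = 0.5 + 0.2 * np.sin((grid - 975) / 300)
        ripple = smooth + 0.05 * np.where(np.arange(200) % 2 == 0, 1.0, -1.0)
        out = wavelet_smooth(ripple)
        assert np.linalg.norm(out - smooth) < np.linalg.norm(ripple - smooth)

    def test_noise_variance_strictly_reduced(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            x = rng.normal(0, 1, 256)
            assert wavelet_smooth(x).var() < x.var()

    def test_idempotent_projection(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0.2, 0.8, 200)
        once = wavelet_smooth(x)
        twice = wavelet_smooth(once)
        assert np.max(np.abs(twice - once)) < 1e-8

    def test_linearity_means_smoothing_commutes_with_averaging(self):
        rng = np.random.default_rng(5)
        rows = rng.uniform(0.2, 0.8, (10, 200))
        assert np.allclose(
            wavelet_smooth(rows).mean(axis=0), wavelet_smooth(rows.mean(axis=0)),
            atol=1e-10,
        )

    def test_too_short_input_rejected(self):
        with pytest.raises(InvalidArgumentError):
            wavelet_smooth(np.ones(16))


class TestMeanSpectrum:
    def _scene(self):
        grid = WavelengthGrid.linspace(975, 1646, 200)
        rng = np.random.default_rng(1)
        cube = HyperCube(rng.uniform(0.1, 0.9, (6, 6, 200)).astype(np.float32), grid)
        labels = np.zeros((6, 6), int)
        labels[0, 0] = labels[0, 1] = 1
        labels[3:5, 3:5] = 2
        return cube, SampleMask.from_labels(labels)

    def test_identical_pixels_give_that_spectrum(self):
        grid = WavelengthGrid.linspace(975, 1646, 200)
        spectrum = np.linspace(0.2, 0.8, 200)
        data = np.tile(spectrum, (4, 4, 1)).astype(np.float64)
        cube = HyperCube(data, grid)
        mask = SampleMask.from_labels(np.ones((4, 4), int))
        out = mean_spectrum(cube, mask, 1, smooth_first=False)
        assert np.allclose(out, spectrum, atol=1e-7)

    def test_two_pixel_region_is_arithmetic_mean(self):
        cube, mask = self._scene()
        a = cube.data[0, 0].astype(np.float64)
        b = cube.data[0, 1].astype(np.float64)
        out = mean_spectrum(cube, mask, 1, smooth_first=False)
        assert np.allclose(out, (a + b) / 2)

    def test_matches_naive_accumulation_oracle(self):
        cube, mask = self._scene()
        out = mean_spectrum(cube, mask, 2, smooth_first=False)
        acc = np.zeros(200)
        count = 0
        for r in range(6):
            for c in range(6):
                if mask.labels[r, c] == 2:
                    acc += cube.data[r, c]
                    count += 1
        assert np.allclose(out, acc / count, atol=1e-7)

    def test_unknown_region_rejected(self):
        cube, mask = self._scene()
        with pytest.raises(InvalidArgumentError):
            mean_spectrum(cube, mask, 99)


class TestBuildTable:
    def _entries(self, n_scenes, regions_per_scene):
        grid = WavelengthGrid.linspace(975, 1646, 200)
        rng = np.random.default_rng(7)
        out = []
        for _ in range(n_scenes):
            labels = np.zeros((10, 10), int)
            for r in range(regions_per_scene):
                labels[r, 2 * r : 2 * r + 2] = r + 1
            cube = HyperCube(rng.uniform(0.1, 0.9, (10, 10, 200)), grid)
            out.append((cube, SampleMask.from_labels(labels),
                        {r + 1: (r % 7) + 1 for r in range(regions_per_scene)}))
        return out

    def test_row_count_is_total_region_count(self):
        table = build_table(self._entries(7, 3), smooth_first=False)
        assert len(table) == 21

    def test_empty_scene_list_gives_empty_table(self):
        assert len(build_table([])) == 0

    def test_rows_equal_per_region_mean_spectra(self):
        entries = self._entries(2, 3)
        table = build_table(entries, smooth_first=False)
        cube, mask, _ = entries[1]
        row = table.spectra[(table.scene_ids == 1) & (table.region_ids == 2)][0]
        assert np.allclose(row, mean_spectrum(cube, mask, 2, smooth_first=False))

    def test_missing_label_rejected(self):
        entries = self._entries(1, 3)
        cube, mask, labels = entries[0]
        del labels[2]
        with pytest.raises(InvalidArgumentError):
            build_table([(cube, mask, labels)])

    def test_csv_roundtrip(self, tmp_path):
        table = build_table(self._entries(2, 3), smooth_first=False)
        path = table.to_csv(tmp_path / "t.csv")
        back = SpectraTable.from_csv(path)
        assert np.allclose(back.spectra, table.spectra, atol=1e-12)
        assert np.array_equal(back.labels, table.labels)


class TestSplitDataset:
    def test_reference_per_class_counts_reproduce_totals(self):
        counts = (1600, 1500, 1643, 1600, 1500, 1590, 1605)
        labels = np.repeat(np.arange(1, 8), counts)
        grid = WavelengthGrid.linspace(975, 1646, 4)
        table = SpectraTable(np.zeros((len(labels), 4)), labels, grid)
        split = split_dataset(table, seed=7)
        assert len(table) == 11_038
        assert len(split.train) == 8280
        assert len(split.test) == 2758

    def test_smallest_exact_quarter(self):
        table = _table(8, grid=WavelengthGrid.linspace(975, 1646, 8),
                       labels=np.ones(4, int))
        split = split_dataset(table, 0)
        assert (len(split.train), len(split.test)) == (3, 1)

    def test_single_row_class_goes_to_train(self):
        table = _table(8, grid=WavelengthGrid.linspace(975, 1646, 8),
                       labels=np.array([1]))
        split = split_dataset(table, 0)
        assert (len(split.train), len(split.test)) == (1, 0)

    def test_determinism(self):
        table = _table(8, grid=WavelengthGrid.linspace(975, 1646, 8),
                       labels=np.repeat([1, 2], 10), seed=3)
        a = split_dataset(table, 5)
        b = split_dataset(table, 5)
        assert np.array_equal(a.test.region_ids, b.test.region_ids)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.lists(st.integers(1, 40), min_size=1, max_size=5),
        st.integers(0, 2**31 - 1),
    )
    def test_union_disjointness_and_quarter_bound(self, class_counts, seed):
        labels = np.repeat(np.arange(1, len(class_counts) + 1), class_counts)
        grid = WavelengthGrid.linspace(975, 1646, 3)
        rng = np.random.default_rng(0)
        table = SpectraTable(rng.uniform(0, 1, (len(labels), 3)), labels, grid)
        table.region_ids = np.arange(len(labels))  # unique row ids
        split = split_dataset(table, seed)
        train_ids = set(split.train.region_ids)
        test_ids = set(split.test.region_ids)
        assert train_ids.isdisjoint(test_ids)
        assert train_ids | test_ids == set(range(len(labels)))
        for cls, n in zip(np.arange(1, len(class_counts) + 1), class_counts):
            n_test = int(np.sum(split.test.labels == cls))
            frac = n_test / n
            assert 0 <= frac <= 0.25
            assert (frac == 0.25) == (n % 4 == 0)
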