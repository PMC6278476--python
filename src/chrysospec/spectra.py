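"""Per-sample spectra: extraction, band cropping, wavelet smoothing, splitting.

The measurement chain for one scene is: crop the noisy spectral edges (the
middle 200 of 256 bands, ~975-1646 nm, where a line-scan NIR system is
stable), smooth every pixel spectrum with a level-3 Daubechies-6 wavelet
low-pass, average the pixels of each segmented region into one mean spectrum
per sample, and collect the labeled rows into a table that is split 3:1 per
class into training and testing sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import pywt

from .envi import HyperCube, WavelengthGrid
from .exceptions import InvalidArgumentError
from .segmentation import SampleMask

__all__ = [
    "SpectraTable",
    "DatasetSplit",
    "PreprocessChain",
    "crop_bands",
    "wavelet_smooth",
    "mean_spectrum",
    "build_table",
    "split_dataset",
]

DEFAULT_CROP_TARGET = 200
DEFAULT_CROP_SPAN = (975.0, 1646.0)


@dataclass
class SpectraTable:
    """Mean spectra of samples with integer variety labels (1..K)."""

    spectra: np.ndarray  # (n, B) reflectance
    labels: np.ndarray  # (n,) int
    grid: WavelengthGrid
    region_ids: np.ndarray | None = None
    scene_ids: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=np.float64))
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.spectra.shape[0] != self.labels.shape[0]:
            raise InvalidArgumentError("row count does not match label count")
        if self.spectra.shape[0] and self.spectra.shape[1] != len(self.grid):
            raise InvalidArgumentError("spectra band count does not match grid")
        if self.spectra.size and not np.all(np.isfinite(self.spectra)):
            raise InvalidArgumentError("spectra must be finite")
        n = self.spectra.shape[0]
        if self.region_ids is None:
            self.region_ids = np.arange(1, n + 1)
        if self.scene_ids is None:
            self.scene_ids = np.zeros(n, dtype=np.int64)
        self.region_ids = np.asarray(self.region_ids)
        self.scene_ids = np.asarray(self.scene_ids)

    def __len__(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_bands(self) -> int:
        return self.spectra.shape[1] if self.spectra.size else len(self.grid)

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def take_rows(self, idx) -> "SpectraTable":
        idx = np.asarray(idx)
        return SpectraTable(
            self.spectra[idx],
            self.labels[idx],
            self.grid,
            self.region_ids[idx],
            self.scene_ids[idx],
            dict(self.meta),
        )

    def take_bands(self, band_indices) -> "SpectraTable":
        band_indices = np.asarray(band_indices)
        return SpectraTable(
            self.spectra[:, band_indices],
            self.labels,
            self.grid.subset(band_indices),
            self.region_ids,
            self.scene_ids,
            dict(self.meta),
        )

    def to_csv(self, path) -> Path:
        cols = {"region_id": self.region_ids, "scene": self.scene_ids, "label": self.labels}
        for j, w in enumerate(self.grid.centers):
            cols[f"{w:.1f}"] = self.spectra[:, j]
        path = Path(path)
        pd.DataFrame(cols).to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path) -> "SpectraTable":
        df = pd.read_csv(path)
        band_cols = [c for c in df.columns if c not in ("region_id", "scene", "label")]
        grid = WavelengthGrid(np.array([float(c) for c in band_cols]))
        return cls(
            df[band_cols].to_numpy(float),
            df["label"].to_numpy(int),
            grid,
            df["region_id"].to_numpy(),
            df["scene"].to_numpy(),
        )


@dataclass
class DatasetSplit:
    """Stratified 3:1 train/test partition of a spectra table."""

    train: SpectraTable
    test: SpectraTable
    seed: int


def crop_bands(
    obj,
    policy: str = "middle_run",
    index_range: tuple[int, int] | None = None,
    target: int = DEFAULT_CROP_TARGET,
    span: tuple[float, float] = DEFAULT_CROP_SPAN,
):
    """Drop the noisy spectral edges, keeping a contiguous run of bands.

    ``middle_run`` (default) keeps a run of ``target`` bands anchored at the
    band nearest ``span[0]`` (975 nm), i.e. the stable middle of a 256-band
    874-1734 nm grid: bands 30..229, centers ~975.2 to ~1646.3 nm.
    ``index_range`` keeps the inclusive 0-based range given explicitly. The
    retained range is recorded in the output's ``meta['crop_index_range']``.
    Works on a :class:`HyperCube` or a :class:`SpectraTable`.
    """
    grid = obj.grid
    B = len(grid)
    if policy == "middle_run":
        if B < target:
            raise InvalidArgumentError(f"grid has {B} bands, need at least {target}")
        start = grid.nearest_index(span[0])
        start = min(start, B - target)
        lo, hi = start, start + target - 1
    elif policy == "index_range":
        if index_range is None:
            raise InvalidArgumentError("index_range policy needs an index range")
        lo, hi = index_range
        if lo < 0 or hi >= B or hi < lo:
            raise InvalidArgumentError(f"index range [{lo}, {hi}] invalid for {B} bands")
    else:
        raise InvalidArgumentError(f"unknown crop policy {policy!r}")

    idx = np.arange(lo, hi + 1)
    if isinstance(obj, HyperCube):
        out = HyperCube(obj.data[:, :, idx], grid.subset(idx), kind=obj.kind,
                        meta=dict(obj.meta))
    elif isinstance(obj, SpectraTable):
        out = obj.take_bands(idx)
    else:
        raise InvalidArgumentError(f"cannot crop object of type {type(obj).__name__}")
    out.meta["crop_index_range"] = (int(lo), int(hi))
    return out


def wavelet_smooth(
    spectrum: np.ndarray,
    wavelet: str = "db6",
    level: int = 3,
    mode: str = "periodization",
    axis: int = -1,
) -> np.ndarray:
    """Wavelet low-pass: decompose to ``level``, zero the detail coefficients,
    reconstruct.

    With the default orthogonal Daubechies-6 basis and periodization
    extension this is an orthogonal projection onto the level-``level``
    approximation space, hence idempotent and strictly variance-reducing on
    noise. Output length equals input length.
    """
    spectrum = np.asarray(spectrum, dtype=np.float64)
    n = spectrum.shape[axis]
    if pywt.dwt_max_level(n, pywt.Wavelet(wavelet)) < level:
        raise InvalidArgumentError(
            f"spectrum of length {n} too short for level-{level} {wavelet} decomposition"
        )
    coeffs = pywt.wavedec(spectrum, wavelet, mode=mode, level=level, axis=axis)
    coeffs = [coeffs[0]] + [np.zeros_like(d) for d in coeffs[1:]]
    rec = pywt.waverec(coeffs, wavelet, mode=mode, axis=axis)
    # waverec can overshoot by one sample for odd lengths
    sl = [slice(None)] * rec.ndim
    sl[axis] = slice(0, n)
    return rec[tuple(sl)]


def mean_spectrum(
    cube: HyperCube,
    mask: SampleMask,
    region_id: int,
    smooth_first: bool = True,
    **wavelet_kwargs,
) -> np.ndarray:
    """Mean spectrum of one region: per-pixel smoothing first, then the
    unweighted average over the region's pixels."""
    inside = mask.pixels(region_id)  # raises on unknown region
    px = cube.data[inside].astype(np.float64)
    if px.shape[0] == 0:
        raise InvalidArgumentError(f"region {region_id} has no pixels")
    if smooth_first:
        px = wavelet_smooth(px, axis=-1, **wavelet_kwargs)
    return px.mean(axis=0)


def build_table(
    scenes: list[tuple[HyperCube, SampleMask, dict[int, int]]],
    smooth_first: bool = True,
    **wavelet_kwargs,
) -> SpectraTable:
    """One labeled mean-spectrum row per region across all scenes."""
    rows, labels, region_ids, scene_ids = [], [], [], []
    grid = None
    for scene_idx, (cube, mask, label_map) in enumerate(scenes):
        if grid is None:
            grid = cube.grid
        elif not np.array_equal(grid.centers, cube.grid.centers):
            raise InvalidArgumentError("scenes have inconsistent wavelength grids")
        for rid in mask.region_ids:
            if rid not in label_map:
                raise InvalidArgumentError(f"region {rid} in scene {scene_idx} has no label")
            rows.append(mean_spectrum(cube, mask, rid, smooth_first, **wavelet_kwargs))
            labels.append(label_map[rid])
            region_ids.append(rid)
            scene_ids.append(scene_idx)
    if not rows:
        grid = grid if grid is not None else WavelengthGrid(np.array([0.0, 1.0]))
        return SpectraTable(np.empty((0, len(grid))), np.empty(0, int), grid,
                            np.empty(0, int), np.empty(0, int))
    return SpectraTable(np.vstack(rows), np.array(labels), grid,
                        np.array(region_ids), np.array(scene_ids))


def split_dataset(table: SpectraTable, seed: int) -> DatasetSplit:
    """Per-class random 3:1 partition: floor(n/4) rows to test, rest to train.

    With the per-variety counts 1600, 1500, 1643, 1600, 1500, 1590, 1605 this
    allocation yields 8280 training and 2758 testing samples. Deterministic
    given ``seed``; train and test are disjoint and exhaustive.
    """
    rng = np.random.default_rng(seed)
    test_idx: list[np.ndarray] = []
    train_idx: list[np.ndarray] = []
    for cls in table.classes:
        members = np.flatnonzero(table.labels == cls)
        n_test = len(members) // 4
        perm = rng.permutation(len(members))
        test_idx.append(members[perm[:n_test]])
        train_idx.append(members[perm[n_test:]])
    train = np.sort(np.concatenate(train_idx)) if train_idx else np.empty(0, int)
    test = np.sort(np.concatenate(test_idx)) if test_idx else np.empty(0, int)
    return DatasetSplit(train=table.take_rows(train), test=table.take_rows(test), seed=seed)


@dataclass
class PreprocessChain:
    """The preprocessing a trained model expects, applied to cubes or tables.

    Order: band crop -> per-pixel wavelet smoothing -> (after averaging)
    optional band selection. ``band_indices`` index into the cropped grid.
    """

    crop_policy: str = "middle_run"
    crop_index_range: tuple[int, int] | None = None
    crop_target: int = DEFAULT_CROP_TARGET
    smooth: bool = True
    wavelet: str = "db6"
    level: int = 3
    wavelet_mode: str = "periodization"
    band_indices: np.ndarray | None = None

    def crop(self, obj):
        if self.crop_policy == "none":
            return obj
        return crop_bands(obj, policy=self.crop_policy,
                          index_range=self.crop_index_range, target=self.crop_target)

    def wavelet_kwargs(self) -> dict:
        return {"wavelet": self.wavelet, "level": self.level, "mode": self.wavelet_mode}

    def apply_to_table(self, table: SpectraTable) -> SpectraTable:
        """Band selection on an already cropped/smoothed mean-spectra table."""
        if self.band_indices is None:
            return table
        return table.take_bands(np.asarray(self.band_indices))

    def with_selection(self, band_indices) -> "PreprocessChain":
        return replace(self, band_indices=np.asarray(band_indices))
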