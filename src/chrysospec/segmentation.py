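"""Segmentation of sample regions from the dark conveyor background.

The standard recipe for line-scan scenes of bright samples on a black belt:
take the band image where sample/background contrast is high (1119 nm for
dried flower heads), threshold it (Otsu by default), clean the binary mask
with a morphological opening and a minimum-area filter, and label connected
components. The binary mask derived from one band is then applied unchanged
to every other band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from .envi import HyperCube
from .exceptions import DegenerateInputError, InvalidArgumentError

__all__ = ["SampleMask", "band_image", "threshold_mask", "clean_mask", "label_regions"]


@dataclass
class SampleMask:
    """Labeled region raster: 0 = background, 1..R = sample regions."""

    labels: np.ndarray
    region_areas: dict[int, int]

    @classmethod
    def from_labels(cls, labels: np.ndarray) -> "SampleMask":
        labels = np.asarray(labels)
        ids, counts = np.unique(labels[labels > 0], return_counts=True)
        return cls(labels=labels, region_areas={int(i): int(c) for i, c in zip(ids, counts)})

    @property
    def n_regions(self) -> int:
        return len(self.region_areas)

    @property
    def region_ids(self) -> list[int]:
        return sorted(self.region_areas)

    def pixels(self, region_id: int) -> np.ndarray:
        if region_id not in self.region_areas:
            raise InvalidArgumentError(f"unknown region id {region_id}")
        return self.labels == region_id


def band_image(cube: HyperCube, wavelength_nm: float) -> np.ndarray:
    """The band image whose center is nearest ``wavelength_nm``.

    Ties between two equidistant centers resolve to the lower index. A
    request outside the grid span by more than half the mean band spacing
    raises a warning; the nearest band is still returned.
    """
    lo, hi = cube.grid.span
    half = 0.5 * cube.grid.mean_spacing
    if wavelength_nm < lo - half or wavelength_nm > hi + half:
        warnings.warn(
            f"requested wavelength {wavelength_nm} nm is outside the grid span "
            f"[{lo:.1f}, {hi:.1f}] nm; returning the nearest band",
            RuntimeWarning,
            stacklevel=2,
        )
    return cube.band(cube.grid.nearest_index(wavelength_nm))


def threshold_mask(
    image: np.ndarray, method: str = "otsu", fixed_value: float | None = None
) -> np.ndarray:
    """Binary foreground mask of pixels above a threshold.

    ``otsu`` picks the threshold maximizing between-class variance of the
    histogram; ``fixed`` uses ``fixed_value``. A constant image has no Otsu
    threshold and raises :class:`DegenerateInputError`.
    """
    image = np.asarray(image)
    if not np.all(np.isfinite(image)):
        raise InvalidArgumentError("image must be finite")
    if method == "otsu":
        if np.ptp(image) == 0:
            raise DegenerateInputError("constant image: Otsu threshold undefined")
        thr = threshold_otsu(image)
    elif method == "fixed":
        if fixed_value is None:
            raise InvalidArgumentError("fixed method requires fixed_value")
        thr = fixed_value
    else:
        raise InvalidArgumentError(f"unknown threshold method {method!r}")
    return image > thr


def clean_mask(mask: np.ndarray, opening_radius: int = 1, min_area: int = 20) -> np.ndarray:
    """Morphological opening with a disk element, then small-object removal."""
    mask = np.asarray(mask, bool)
    if mask.size == 0 or not mask.any():
        return mask.copy()
    out = mask
    if opening_radius > 0:
        out = morphology.opening(out, morphology.disk(opening_radius))
    if min_area > 0:
        # drop components with area strictly below min_area
        out = morphology.remove_small_objects(out, max_size=min_area - 1)
    return out


def label_regions(mask: np.ndarray) -> SampleMask:
    """8-connected component labeling, ids in raster-scan order of first pixel."""
    mask = np.asarray(mask, bool)
    raw = measure.label(mask, connectivity=2)
    n = int(raw.max())
    if n == 0:
        return SampleMask.from_labels(np.zeros_like(raw, dtype=np.int32))
    # remap ids so region 1 is the component whose first pixel comes first
    # in raster order, region 2 the next, and so on
    flat = raw.ravel()
    first_pos = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    # reversed so earlier positions overwrite later ones
    first_pos[flat[nz[::-1]]] = nz[::-1]
    order = np.argsort(first_pos[1:], kind="stable")  # old_id-1 sorted by first pixel
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[order + 1] = np.arange(1, n + 1)
    return SampleMask.from_labels(remap[raw])
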