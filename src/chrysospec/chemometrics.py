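"""Chemometric analysis: PCA score images and 2nd-derivative band selection.

PCA on pooled masked pixel spectra gives per-pixel score images used for
qualitative inspection of variety differences. Savitzky-Golay second
derivatives of per-class mean spectra sharpen peaks and valleys; bands where
the class curves diverge most are retained as optimal wavelengths. The
reference manual selection is the eighteen NIR wavelengths (999-1633 nm)
associated with N-H, C-H and O-H overtone absorption of dried flower tissue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from sklearn.decomposition import PCA

from .envi import HyperCube, WavelengthGrid
from .exceptions import InvalidArgumentError, OutOfRangeError
from .segmentation import SampleMask

__all__ = [
    "REFERENCE_OPTIMAL_WAVELENGTHS_NM",
    "PCAModel",
    "ScoreImage",
    "BandSelection",
    "fit_pca",
    "score_image",
    "second_derivative",
    "select_bands",
]

#: Eighteen NIR wavelengths (nm) tied to N-H / C-H / O-H overtone absorption,
#: the reference manual band selection for dried Chrysanthemum discrimination.
REFERENCE_OPTIMAL_WAVELENGTHS_NM = (
    999, 1005, 1015, 1025, 1032,
    1136, 1190, 1214, 1244, 1301, 1311,
    1321, 1375, 1406, 1433, 1456, 1470,
    1633,
)


@dataclass
class PCAModel:
    """Mean-centered principal decomposition of pixel spectra.

    ``loadings`` is B x k with orthonormal columns in descending explained
    variance; the sign convention makes each loading's largest-magnitude
    element positive.
    """

    loadings: np.ndarray
    mean_vector: np.ndarray
    explained_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    @property
    def n_bands(self) -> int:
        return self.loadings.shape[0]

    def transform(self, spectra: np.ndarray) -> np.ndarray:
        return (np.asarray(spectra, float) - self.mean_vector) @ self.loadings


@dataclass
class ScoreImage:
    """Per-pixel projection on one principal component; background exactly 0."""

    values: np.ndarray
    pc_index: int


@dataclass
class BandSelection:
    """Retained bands: strictly ascending unique indices into a grid."""

    band_indices: np.ndarray
    wavelengths_nm: np.ndarray
    criterion_scores: np.ndarray

    def __post_init__(self) -> None:
        self.band_indices = np.asarray(self.band_indices, dtype=int)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.criterion_scores = np.asarray(self.criterion_scores, dtype=float)
        if self.band_indices.size and (
            np.any(np.diff(self.band_indices) <= 0) or np.any(self.band_indices < 0)
        ):
            raise InvalidArgumentError("band indices must be strictly ascending and unique")

    def __len__(self) -> int:
        return self.band_indices.size

    def to_csv(self, path) -> Path:
        ranks = np.empty(len(self), dtype=int)
        if len(self):
            order = np.argsort(-self.criterion_scores, kind="stable")
            ranks[order] = np.arange(1, len(self) + 1)
        df = pd.DataFrame(
            {
                "rank": ranks,
                "band_index": self.band_indices,
                "wavelength_nm": self.wavelengths_nm,
                "score": self.criterion_scores,
            }
        )
        path = Path(path)
        df.to_csv(path, index=False)
        return path


def fit_pca(pixel_spectra: np.ndarray, k: int) -> PCAModel:
    """Fit a k-component PCA to an n x B matrix of pixel spectra."""
    X = np.asarray(pixel_spectra, dtype=np.float64)
    if X.ndim != 2:
        raise InvalidArgumentError("pixel_spectra must be 2-D (n x B)")
    n, B = X.shape
    if k < 1 or k > min(n - 1, B):
        raise InvalidArgumentError(f"k={k} must satisfy 1 <= k <= min(n-1, B) = {min(n - 1, B)}")
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(X)
    loadings = pca.components_.T.copy()  # B x k
    # sign convention: largest-|.| element of each loading is positive
    for j in range(k):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] = -col
    return PCAModel(
        loadings=loadings,
        mean_vector=pca.mean_.copy(),
        explained_ratio=pca.explained_variance_ratio_.copy(),
    )


def score_image(
    cube: HyperCube, mask: SampleMask, model: PCAModel, pc: int
) -> ScoreImage:
    """Project every foreground pixel on one loading; background stays 0."""
    if cube.n_bands != model.n_bands:
        raise InvalidArgumentError(
            f"cube has {cube.n_bands} bands, PCA model expects {model.n_bands}"
        )
    if pc < 0 or pc >= model.n_components:
        raise InvalidArgumentError(f"pc index {pc} out of range (k={model.n_components})")
    fg = mask.labels > 0
    values = np.zeros(mask.labels.shape, dtype=np.float64)
    if fg.any():
        values[fg] = (cube.data[fg].astype(np.float64) - model.mean_vector) @ model.loadings[:, pc]
    return ScoreImage(values=values, pc_index=pc)


def second_derivative(
    spectra: np.ndarray,
    grid: WavelengthGrid | float,
    window: int = 9,
    polyorder: int = 2,
) -> np.ndarray:
    """Savitzky-Golay second derivative of each row, in reflectance / nm^2.

    ``grid`` supplies the band spacing (mean spacing of a
    :class:`WavelengthGrid`, or a scalar delta in nm). Edges are handled by
    evaluating the edge-window polynomial fit (``mode='interp'``).
    """
    X = np.atleast_2d(np.asarray(spectra, dtype=np.float64))
    if window % 2 == 0 or polyorder < 2 or window <= polyorder:
        raise InvalidArgumentError("need odd window > polyorder >= 2")
    if X.shape[1] < window:
        raise InvalidArgumentError(f"{X.shape[1]} bands < window {window}")
    delta = grid.mean_spacing if isinstance(grid, WavelengthGrid) else float(grid)
    if delta <= 0:
        raise InvalidArgumentError("band spacing must be positive")
    out = savgol_filter(X, window, polyorder, deriv=2, delta=delta, axis=-1, mode="interp")
    return out if np.asarray(spectra).ndim > 1 else out[0]


def _local_maxima(score: np.ndarray) -> np.ndarray:
    """Indices that are strict maxima vs the left neighbor and >= the right."""
    n = score.size
    left = np.empty(n, bool)
    right = np.empty(n, bool)
    left[0] = True
    left[1:] = score[1:] > score[:-1]
    right[-1] = True
    right[:-1] = score[:-1] >= score[1:]
    return np.flatnonzero(left & right)


def select_bands(
    deriv_class_means: np.ndarray,
    grid: WavelengthGrid,
    mode: str = "auto",
    manual_list=None,
    top_m: int = 18,
) -> BandSelection:
    """Pick discriminative bands from K x B class-mean 2nd-derivative spectra.

    ``auto`` scores every band by the between-class variance of the class
    means, keeps local maxima of the score curve, ranks them, and returns the
    ``top_m`` as an ascending selection. ``manual`` maps each requested
    wavelength to the nearest grid band (ties to the lower index); duplicates
    collapse with a warning, wavelengths outside the grid span raise
    :class:`OutOfRangeError`.
    """
    D = np.atleast_2d(np.asarray(deriv_class_means, dtype=np.float64))
    if mode == "manual":
        if manual_list is None or len(manual_list) == 0:
            raise InvalidArgumentError("manual mode needs a wavelength list")
        lo, hi = grid.span
        indices = []
        for w in manual_list:
            if w < lo or w > hi:
                raise OutOfRangeError(f"wavelength {w} nm outside grid span [{lo}, {hi}]")
            indices.append(grid.nearest_index(w))
        unique = sorted(set(indices))
        if len(unique) < len(indices):
            warnings.warn(
                f"{len(indices) - len(unique)} requested wavelengths map to duplicate "
                "bands; duplicates collapsed",
                RuntimeWarning,
                stacklevel=2,
            )
        idx = np.array(unique, dtype=int)
        scores = np.var(D[:, idx], axis=0) if D.shape[0] >= 2 else np.zeros(idx.size)
        return BandSelection(idx, grid.centers[idx], scores)

    if mode != "auto":
        raise InvalidArgumentError(f"unknown selection mode {mode!r}")
    K, B = D.shape
    if K < 2:
        raise InvalidArgumentError("auto mode needs at least 2 class means")
    if B != len(grid):
        raise InvalidArgumentError("class-mean band count does not match grid")
    score = np.var(D, axis=0)  # between-class variance per band
    # zero test relative to the data's scale: derivative units are tiny (nm^-2)
    scale = float(np.abs(D).max())
    if scale == 0.0 or float(score.max()) <= (1e-12 * scale) ** 2:
        warnings.warn("class means are identical; no bands selected", RuntimeWarning,
                      stacklevel=2)
        return BandSelection(np.empty(0, int), np.empty(0), np.empty(0))
    peaks = _local_maxima(score)
    ranked = peaks[np.argsort(-score[peaks], kind="stable")][:top_m]
    idx = np.sort(ranked)
    return BandSelection(idx, grid.centers[idx], score[idx])
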