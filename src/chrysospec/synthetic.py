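"""Synthetic hyperspectral scenes of dried flower heads on a dark belt.

Emulates the statistical structure a line-scan NIR imaging experiment
produces: quasi-circular samples of several varieties scattered on a
near-black conveyor background, recorded as a raw digital-number cube
together with white- and dark-reference cubes. Variety spectra share peak
positions near 1116/1308 nm and valleys near 1200/1460 nm, differing by a
class-wise reflectance offset and mild class-specific peak-amplitude
changes; pixels add i.i.d. Gaussian noise on top of a per-sample offset.

Everything is deterministic given the seed: a single ``SeedSequence`` fans
out to placement / sample / pixel-noise streams.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .envi import HyperCube, WavelengthGrid, write_envi
from .exceptions import InvalidArgumentError, PlacementError
from .segmentation import SampleMask

__all__ = [
    "DEFAULT_PEAK_CENTERS",
    "DEFAULT_VALLEY_CENTERS",
    "VarietyProfile",
    "SceneSpec",
    "SyntheticScene",
    "make_variety_profiles",
    "spectrum_at",
    "render_scene",
    "write_scene",
]

DEFAULT_PEAK_CENTERS = (1116.0, 1308.0)
DEFAULT_VALLEY_CENTERS = (1200.0, 1460.0)
_FEATURE_WIDTH_NM = 30.0


@dataclass(frozen=True)
class VarietyProfile:
    """Noiseless reflectance curve of one variety plus its noise levels.

    ``base_curve`` maps wavelength (nm) to reflectance before the class
    offset; ``class_offset`` shifts the whole curve; ``within_class_sd`` is
    the sd of the flat per-sample offset and ``pixel_noise_sd`` the sd of
    i.i.d. per-pixel/band noise.
    """

    class_id: int
    base_curve: Callable[[np.ndarray], np.ndarray]
    peak_centers: tuple[float, ...]
    valley_centers: tuple[float, ...]
    class_offset: float = 0.0
    within_class_sd: float = 0.005
    pixel_noise_sd: float = 0.01

    def mean_curve(self, grid_nm: np.ndarray) -> np.ndarray:
        """base_curve + class offset, kept inside [0.01, 0.99]."""
        return np.clip(self.base_curve(np.asarray(grid_nm, float)) + self.class_offset,
                       0.01, 0.99)


def _gaussian_mixture_curve(
    peaks: Sequence[float],
    valleys: Sequence[float],
    peak_amps: Sequence[float],
    valley_amps: Sequence[float],
    baseline: tuple[float, float] = (0.45, 0.05),
    width_nm: float = _FEATURE_WIDTH_NM,
) -> Callable[[np.ndarray], np.ndarray]:
    b0, b1 = baseline

    def curve(nm: np.ndarray) -> np.ndarray:
        nm = np.asarray(nm, float)
        t = (nm - 874.0) / 860.0
        y = b0 + b1 * t
        for c, a in zip(peaks, peak_amps):
            y = y + a * np.exp(-0.5 * ((nm - c) / width_nm) ** 2)
        for c, a in zip(valleys, valley_amps):
            y = y - a * np.exp(-0.5 * ((nm - c) / width_nm) ** 2)
        return y

    return curve


def make_variety_profiles(
    n_classes: int,
    seed: int,
    *,
    peak_centers: Sequence[float] = DEFAULT_PEAK_CENTERS,
    valley_centers: Sequence[float] = DEFAULT_VALLEY_CENTERS,
    class_offset_step: float = 0.05,
    within_class_sd: float = 0.005,
    pixel_noise_sd: float = 0.01,
    near_overlap_pair: bool = True,
    amplitude_jitter: float = 0.15,
) -> list[VarietyProfile]:
    """Build ``n_classes`` variety profiles sharing peak/valley positions.

    Classes share the peak centers (default 1116/1308 nm) and valley centers
    (default 1200/1460 nm) but differ by a class reflectance offset (uniform
    ladder with step ``class_offset_step``, centered on zero) and by small
    class-specific multiplicative perturbations of the peak/valley
    amplitudes. With ``near_overlap_pair`` and at least four classes, class 4
    is moved next to class 1 (offsets 0.25 steps apart) so that one pair of
    varieties is separable by curve shape but barely by level — mimicking
    variety pairs whose mean spectra nearly coincide over part of the range.

    Deterministic given ``seed``. ``n_classes == 1`` yields a single profile
    with offset 0.
    """
    if n_classes < 1:
        raise InvalidArgumentError("n_classes must be >= 1")
    rng = np.random.default_rng(seed)
    offsets = class_offset_step * (np.arange(n_classes) - (n_classes - 1) / 2.0)
    if n_classes == 1:
        offsets = np.zeros(1)
    if near_overlap_pair and n_classes >= 4:
        offsets[3] = offsets[0] + 0.25 * class_offset_step

    base_peak_amps = np.array([0.10, 0.08])[: len(peak_centers)]
    base_valley_amps = np.array([0.08, 0.15])[: len(valley_centers)]
    if len(peak_centers) > 2:
        base_peak_amps = np.resize(base_peak_amps, len(peak_centers))
    if len(valley_centers) > 2:
        base_valley_amps = np.resize(base_valley_amps, len(valley_centers))

    profiles = []
    for k in range(n_classes):
        pj = 1.0 + rng.normal(0.0, amplitude_jitter, size=len(peak_centers))
        vj = 1.0 + rng.normal(0.0, amplitude_jitter, size=len(valley_centers))
        curve = _gaussian_mixture_curve(
            peak_centers, valley_centers, base_peak_amps * pj, base_valley_amps * vj
        )
        profiles.append(
            VarietyProfile(
                class_id=k + 1,
                base_curve=curve,
                peak_centers=tuple(float(c) for c in peak_centers),
                valley_centers=tuple(float(c) for c in valley_centers),
                class_offset=float(offsets[k]),
                within_class_sd=within_class_sd,
                pixel_noise_sd=pixel_noise_sd,
            )
        )
    return profiles


def spectrum_at(
    profile: VarietyProfile, grid, rng: np.random.Generator
) -> np.ndarray:
    """Draw one pixel spectrum: mean curve + N(0, pixel_noise_sd), clipped to [0, 1].

    With ``pixel_noise_sd == 0`` this is exactly the offset base curve
    sampled on the grid. The same generator state reproduces the same draw.
    """
    centers = grid.centers if isinstance(grid, WavelengthGrid) else np.asarray(grid, float)
    if centers.size == 0:
        raise InvalidArgumentError("empty wavelength grid")
    if np.any(np.diff(centers) <= 0):
        raise InvalidArgumentError("grid must be ascending")
    y = profile.mean_curve(centers)
    if profile.pixel_noise_sd > 0:
        y = y + rng.normal(0.0, profile.pixel_noise_sd, size=centers.size)
    return np.clip(y, 0.0, 1.0)


@dataclass(frozen=True)
class SceneSpec:
    """Geometry and radiometry of one synthetic scene."""

    height: int = 160
    width: int = 160
    n_bands: int = 256
    wavelength_span: tuple[float, float] = (874.0, 1734.0)
    samples_per_class: int = 3
    sample_radius_range: tuple[int, int] = (6, 10)
    white_level: float = 4000.0
    illumination_amplitude: float = 0.05
    background_reflectance: float = 0.02
    dark_level_mean: float = 100.0
    dark_level_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bands < 2:
            raise InvalidArgumentError("n_bands must be >= 2")
        if self.samples_per_class < 0:
            raise InvalidArgumentError("samples_per_class must be >= 0")
        lo, hi = self.sample_radius_range
        if lo < 1 or hi < lo:
            raise InvalidArgumentError("invalid sample_radius_range")
        if 2 * hi + 2 >= min(self.height, self.width):
            raise InvalidArgumentError("sample disks cannot fit inside the frame")

    @property
    def grid(self) -> WavelengthGrid:
        return WavelengthGrid.linspace(*self.wavelength_span, self.n_bands)


@dataclass
class SyntheticScene:
    """Raw/white/dark cube triplet plus pixel-level ground truth."""

    raw_cube: HyperCube
    white_cube: HyperCube
    dark_cube: HyperCube
    truth_mask: SampleMask
    truth_labels: dict[int, int] = field(default_factory=dict)


def _place_disks(
    spec: SceneSpec, n_disks: int, rng: np.random.Generator, max_tries: int = 2000
) -> list[tuple[int, int, int]]:
    """Rejection-sample non-overlapping (row, col, radius) disks."""
    placed: list[tuple[int, int, int]] = []
    lo, hi = spec.sample_radius_range
    for _ in range(n_disks):
        for attempt in range(max_tries):
            r = int(rng.integers(lo, hi + 1))
            row = int(rng.integers(r + 1, spec.height - r - 1))
            col = int(rng.integers(r + 1, spec.width - r - 1))
            ok = all(
                (row - pr) ** 2 + (col - pc) ** 2 > (r + prr + 2) ** 2
                for pr, pc, prr in placed
            )
            if ok:
                placed.append((row, col, r))
                break
        else:
            raise PlacementError(
                f"could not place disk {len(placed) + 1}/{n_disks} "
                f"after {max_tries} tries"
            )
    return placed


def render_scene(spec: SceneSpec, profiles: Sequence[VarietyProfile]) -> SyntheticScene:
    """Render the raw/white/dark triplet for a scene of scattered samples.

    Inside each sample disk the reflectance is the profile's mean curve plus
    a flat per-sample offset (sd ``within_class_sd``) plus per-pixel noise;
    outside it is the flat background reflectance. The raw cube is composed
    as ``dark + (white - dark) * reflectance`` so that reference correction
    recovers the planted reflectance exactly up to the planted noise. A
    smooth quadratic illumination field across columns makes the correction
    non-trivial. Deterministic given ``spec.seed``.
    """
    if len(profiles) == 0:
        raise InvalidArgumentError("profiles must be non-empty")
    grid = spec.grid
    ss = np.random.SeedSequence(spec.seed)
    rng_place, rng_sample, rng_pixel, rng_dark = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]

    n_disks = len(profiles) * spec.samples_per_class
    disks = _place_disks(spec, n_disks, rng_place)

    H, W, B = spec.height, spec.width, spec.n_bands
    labels = np.zeros((H, W), dtype=np.int32)
    reflectance = np.full((H, W, B), spec.background_reflectance, dtype=np.float32)
    truth_labels: dict[int, int] = {}

    rows_idx, cols_idx = np.ogrid[:H, :W]
    region_id = 0
    for i, (row, col, radius) in enumerate(disks):
        profile = profiles[i // spec.samples_per_class] if spec.samples_per_class else None
        region_id += 1
        inside = (rows_idx - row) ** 2 + (cols_idx - col) ** 2 <= radius**2
        labels[inside] = region_id
        n_px = int(np.count_nonzero(inside))
        mean = profile.mean_curve(grid.centers)
        sample_offset = rng_sample.normal(0.0, profile.within_class_sd)
        px = mean[None, :] + sample_offset
        if profile.pixel_noise_sd > 0:
            px = px + rng_pixel.normal(0.0, profile.pixel_noise_sd, size=(n_px, B))
        reflectance[inside] = np.clip(px, 0.0, 1.0)
        truth_labels[region_id] = profile.class_id

    # smooth multiplicative illumination across columns
    u = np.linspace(-1.0, 1.0, W) if W > 1 else np.zeros(1)
    illum = 1.0 + spec.illumination_amplitude * (1.0 - 2.0 * u**2)

    dark = (
        spec.dark_level_mean
        + rng_dark.normal(0.0, spec.dark_level_sd, size=(H, W, B))
    ).astype(np.float32)
    white = (dark + spec.white_level * illum[None, :, None]).astype(np.float32)
    raw = dark + (white - dark) * reflectance
    # keep raw digital numbers between the references
    raw = np.clip(raw, dark, white).astype(np.float32)

    return SyntheticScene(
        raw_cube=HyperCube(raw, grid, kind="raw"),
        white_cube=HyperCube(white, grid, kind="white"),
        dark_cube=HyperCube(dark, grid, kind="dark"),
        truth_mask=SampleMask.from_labels(labels),
        truth_labels=truth_labels,
    )


def write_scene(scene: SyntheticScene, outdir, interleave: str = "bsq") -> dict[str, Path]:
    """Write a scene as ENVI cubes + truth mask raster + label CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, cube in (
        ("raw", scene.raw_cube),
        ("white", scene.white_cube),
        ("dark", scene.dark_cube),
    ):
        _, binary = write_envi(cube, outdir / f"{name}.img", interleave=interleave)
        paths[name] = binary
    # ground truth: single-band integer raster with a minimal ENVI header
    mask_path = outdir / "truth_mask.img"
    scene.truth_mask.labels.astype("<u2").tofile(mask_path)
    (outdir / "truth_mask.img.hdr").write_text(
        "ENVI\ndescription = {truth mask}\n"
        f"samples = {scene.truth_mask.labels.shape[1]}\n"
        f"lines = {scene.truth_mask.labels.shape[0]}\n"
        "bands = 1\nheader offset = 0\nfile type = ENVI Standard\n"
        "data type = 12\ninterleave = bsq\nbyte order = 0\n"
    )
    paths["truth_mask"] = mask_path
    labels_path = outdir / "truth_labels.csv"
    with open(labels_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["region_id", "class_id"])
        for rid in sorted(scene.truth_labels):
            writer.writerow([rid, scene.truth_labels[rid]])
    paths["truth_labels"] = labels_path
    return paths
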