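"""ENVI-format hyperspectral cube I/O and reflectance correction.

An ENVI dataset is a plain-text header (``*.hdr``) describing a flat binary
raster. Cubes are held in memory as ``(rows, cols, bands)`` arrays together
with their wavelength grid; the three interleaves (BSQ, BIL, BIP) differ only
in the axis order of the binary file.

Raw digital numbers are converted to reflectance with white (~100 %
reflectance tile) and dark (shutter closed) reference frames:

    R = (I_raw - I_dark) / (I_white - I_dark)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import FormatError, InvalidArgumentError

__all__ = [
    "WavelengthGrid",
    "HyperCube",
    "read_envi",
    "write_envi",
    "correct_reflectance",
]

# ENVI data-type codes supported here: 4 = float32, 12 = uint16.
_DTYPE_CODES = {4: np.dtype("<f4"), 12: np.dtype("<u2")}
_DTYPE_TO_CODE = {np.dtype("float32"): 4, np.dtype("uint16"): 12}

# axis order of the binary file, as (row, col, band) positions
_INTERLEAVE_AXES = {
    "bsq": (2, 0, 1),  # band, line, sample
    "bil": (0, 2, 1),  # line, band, sample
    "bip": (0, 1, 2),  # line, sample, band
}


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly ascending band-center wavelengths in nanometres."""

    centers: np.ndarray

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=float)
        if centers.ndim != 1 or centers.size < 2:
            raise InvalidArgumentError("wavelength grid needs at least 2 centers")
        if not np.all(np.diff(centers) > 0):
            raise InvalidArgumentError("wavelength centers must be strictly ascending")
        object.__setattr__(self, "centers", centers)

    def __len__(self) -> int:
        return self.centers.size

    @property
    def span(self) -> tuple[float, float]:
        return float(self.centers[0]), float(self.centers[-1])

    @property
    def mean_spacing(self) -> float:
        return float(np.mean(np.diff(self.centers)))

    def nearest_index(self, wavelength_nm: float) -> int:
        """Index of the band center nearest ``wavelength_nm``; ties go to the
        lower index (argmin returns the first minimum)."""
        return int(np.argmin(np.abs(self.centers - wavelength_nm)))

    def subset(self, indices) -> "WavelengthGrid":
        return WavelengthGrid(self.centers[np.asarray(indices)])

    @classmethod
    def linspace(cls, start_nm: float, stop_nm: float, n_bands: int) -> "WavelengthGrid":
        return cls(np.linspace(start_nm, stop_nm, n_bands))


@dataclass
class HyperCube:
    """A hyperspectral raster: ``data[row, col, band]`` plus its grid.

    ``kind`` records the radiometric meaning of the values: raw / white /
    dark cubes hold digital numbers, reflectance cubes hold values in [0, 1].
    """

    data: np.ndarray
    grid: WavelengthGrid
    kind: str = "reflectance"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise InvalidArgumentError("cube data must be 3-D (rows, cols, bands)")
        if self.data.shape[2] != len(self.grid):
            raise InvalidArgumentError(
                f"band count {self.data.shape[2]} does not match grid length {len(self.grid)}"
            )
        if self.kind not in ("raw", "white", "dark", "reflectance"):
            raise InvalidArgumentError(f"unknown cube kind {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band(self, index: int) -> np.ndarray:
        return self.data[:, :, index]


def _parse_header(text: str) -> dict:
    """Parse an ENVI header into a {lower-case key: string value} dict.

    Values in braces may span several lines; everything else is one line.
    """
    if not text.lstrip().lower().startswith("envi"):
        raise FormatError("not an ENVI header (missing ENVI magic line)")
    fields: dict[str, str] = {}
    # strip the magic line, then walk "key = value" entries
    body = text.split("\n", 1)[1] if "\n" in text else ""
    i = 0
    lines = body.split("\n")
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line or "=" not in line:
            continue
        key, _, value = line.partition("=")
        key = key.strip().lower()
        value = value.strip()
        if value.startswith("{") and "}" not in value:
            parts = [value]
            while i < len(lines) and "}" not in lines[i]:
                parts.append(lines[i])
                i += 1
            if i < len(lines):
                parts.append(lines[i])
                i += 1
            value = " ".join(parts)
        fields[key] = value
    return fields


def _binary_path(header_path: Path) -> Path:
    """Locate the binary that belongs to a header file."""
    if header_path.suffix.lower() == ".hdr":
        stem = header_path.with_suffix("")
        for candidate in (stem, stem.with_suffix(".img"), stem.with_suffix(".raw"),
                          stem.with_suffix(".dat")):
            if candidate.exists():
                return candidate
        raise FormatError(f"no binary file found for header {header_path}")
    raise FormatError(f"expected a .hdr header path, got {header_path}")


def read_envi(header_path) -> HyperCube:
    """Read an ENVI header + binary pair into a :class:`HyperCube`.

    The ``wavelength`` field is required; band count must match the binary
    size. Indexing of the returned cube is (row, col, band), 0-based.
    """
    header_path = Path(header_path)
    fields = _parse_header(header_path.read_text())
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise FormatError(f"header missing required field: {exc}") from exc
    if "wavelength" not in fields:
        raise FormatError("header has no wavelength field")
    if interleave not in _INTERLEAVE_AXES:
        raise FormatError(f"unsupported interleave {interleave!r}")
    if dtype_code not in _DTYPE_CODES:
        raise FormatError(f"unsupported data type code {dtype_code}")
    if int(fields.get("byte order", "0")) != 0:
        raise FormatError("only little-endian (byte order = 0) files are supported")

    wl_text = fields["wavelength"].strip().strip("{}")
    centers = np.array([float(v) for v in wl_text.replace(",", " ").split()])
    if centers.size != bands:
        raise FormatError(
            f"header lists {centers.size} wavelengths but declares {bands} bands"
        )

    dtype = _DTYPE_CODES[dtype_code]
    offset = int(fields.get("header offset", "0"))
    binary = _binary_path(header_path)
    flat = np.fromfile(binary, dtype=dtype, offset=offset)
    expected = samples * lines * bands
    if flat.size != expected:
        raise FormatError(
            f"binary holds {flat.size} values, header implies {expected} "
            f"({lines} lines x {samples} samples x {bands} bands)"
        )

    axes = _INTERLEAVE_AXES[interleave]
    file_shape = tuple((lines, samples, bands)[a] for a in axes)
    arr = flat.reshape(file_shape)
    # move file axes back to (row, col, band)
    arr = np.transpose(arr, np.argsort(axes))
    kind = fields.get("description", "").strip("{} ").lower()
    if kind not in ("raw", "white", "dark", "reflectance"):
        kind = "reflectance" if dtype_code == 4 else "raw"
    return HyperCube(np.ascontiguousarray(arr), WavelengthGrid(centers), kind=kind)


def write_envi(cube: HyperCube, path, interleave: str = "bsq") -> tuple[Path, Path]:
    """Write ``cube`` as an ENVI header/binary pair.

    ``path`` names the binary file; the header is written next to it as
    ``path + '.hdr'``. Returns (header_path, binary_path).
    """
    interleave = interleave.lower()
    if interleave not in _INTERLEAVE_AXES:
        raise InvalidArgumentError(f"unsupported interleave {interleave!r}")
    data = cube.data
    if data.dtype not in _DTYPE_TO_CODE:
        data = data.astype(np.float32)
    dtype_code = _DTYPE_TO_CODE[data.dtype]

    binary_path = Path(path)
    header_path = binary_path.with_suffix(binary_path.suffix + ".hdr")
    rows, cols, bands = data.shape
    axes = _INTERLEAVE_AXES[interleave]
    arr = np.transpose(data, axes)

    wavelengths = ", ".join(f"{w:.6f}" for w in cube.grid.centers)
    header = (
        "ENVI\n"
        f"description = {{{cube.kind}}}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {dtype_code}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wavelengths} }}\n"
    )
    try:
        header_path.write_text(header)
        arr.astype(data.dtype, copy=False).tofile(binary_path)
    except OSError as exc:
        raise IOError(f"cannot write ENVI files at {path}: {exc}") from exc
    return header_path, binary_path


def _broadcast_reference(ref: HyperCube, shape: tuple[int, int, int], name: str) -> np.ndarray:
    """Allow single-line reference frames, broadcast per column/band."""
    if ref.data.shape == shape:
        return ref.data
    if ref.data.shape == (1, shape[1], shape[2]):
        return np.broadcast_to(ref.data, shape)
    raise InvalidArgumentError(
        f"{name} reference shape {ref.data.shape} incompatible with raw shape {shape}"
    )


def correct_reflectance(
    raw: HyperCube, white: HyperCube, dark: HyperCube, clip: bool = True
) -> HyperCube:
    """Convert raw digital numbers to reflectance, R = (raw-dark)/(white-dark).

    White/dark frames may be full cubes or single-line references (broadcast
    over lines). Pixels where white == dark (dead pixels) yield 0 with a
    warning rather than NaN, so downstream ROI means stay finite. With
    ``clip`` the output is clamped to [0, 1].
    """
    for ref in (white, dark):
        if not np.array_equal(ref.grid.centers, raw.grid.centers):
            raise InvalidArgumentError("raw/white/dark wavelength grids differ")
    shape = raw.data.shape
    w = _broadcast_reference(white, shape, "white").astype(np.float64)
    d = _broadcast_reference(dark, shape, "dark").astype(np.float64)
    denom = w - d
    dead = denom == 0
    if np.any(dead):
        warnings.warn(
            f"{int(np.count_nonzero(dead))} pixel/band cells have white == dark; "
            "their reflectance is set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    out = np.zeros(shape, dtype=np.float64)
    np.divide(raw.data.astype(np.float64) - d, denom, out=out, where=~dead)
    if clip:
        np.clip(out, 0.0, 1.0, out=out)
    return HyperCube(out.astype(np.float32), raw.grid, kind="reflectance")
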