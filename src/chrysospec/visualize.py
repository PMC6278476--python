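"""Pixel-level classification maps.

Each segmented sample's mean spectrum is preprocessed exactly as the model's
training data was, classified once, and the predicted variety is painted
back onto every pixel of the sample; the background stays black. The default
palette is a colorblind-safe seven-color set (Okabe-Ito).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .envi import HyperCube
from .exceptions import InvalidArgumentError
from .segmentation import SampleMask
from .spectra import PreprocessChain, SpectraTable, mean_spectrum

__all__ = ["DEFAULT_PALETTE", "DEFAULT_CLASS_NAMES", "ClassMap", "classify_scene", "render_map"]

DEFAULT_PALETTE: dict[int, tuple[int, int, int]] = {
    1: (230, 159, 0),
    2: (86, 180, 233),
    3: (0, 158, 115),
    4: (240, 228, 66),
    5: (0, 114, 178),
    6: (213, 94, 0),
    7: (204, 121, 167),
}

DEFAULT_CLASS_NAMES = (
    "Boju", "Chuju", "Gongju", "Hangbaiju",
    "white Huaiju", "yellow Huaiju", "Qiju",
)


@dataclass
class ClassMap:
    """Predicted-variety raster (0 = background) with palette and legend."""

    labels: np.ndarray
    palette: dict[int, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_PALETTE)
    )
    legend: tuple[str, ...] = DEFAULT_CLASS_NAMES
    region_predictions: dict[int, int] = field(default_factory=dict)

    @property
    def present_classes(self) -> list[int]:
        return sorted(int(c) for c in np.unique(self.labels) if c > 0)


def classify_scene(
    cube: HyperCube,
    mask: SampleMask,
    model,
    chain: PreprocessChain | None = None,
) -> ClassMap:
    """Predict each region's variety from its mean spectrum and paint it back.

    ``cube`` is a reflectance cube on the acquisition grid; ``chain``
    replicates the model's training preprocessing (crop, per-pixel wavelet
    smoothing, optional band selection). All pixels of a region receive its
    predicted label; a band-count mismatch with the model raises.
    """
    chain = chain or PreprocessChain()
    work = chain.crop(cube)
    rows = []
    rids = mask.region_ids
    for rid in rids:
        rows.append(
            mean_spectrum(work, mask, rid, smooth_first=chain.smooth,
                          **chain.wavelet_kwargs())
        )
    labels_out = np.zeros(mask.labels.shape, dtype=np.int32)
    predictions: dict[int, int] = {}
    if rows:
        table = SpectraTable(np.vstack(rows), np.zeros(len(rows), int), work.grid,
                             np.asarray(rids))
        table = chain.apply_to_table(table)
        n_bands = getattr(model, "n_bands", None)
        if n_bands is not None and n_bands != table.n_bands:
            raise InvalidArgumentError(
                f"preprocessing yields {table.n_bands} bands but model expects {n_bands}"
            )
        preds = np.asarray(model.predict(table.spectra))
        for rid, pred in zip(rids, preds):
            predictions[int(rid)] = int(pred)
            labels_out[mask.labels == rid] = int(pred)
    return ClassMap(labels=labels_out, region_predictions=predictions)


def render_map(class_map: ClassMap, out_path, legend_height: int = 12) -> Path:
    """Write the class map as a PNG (black background, legend strip at the
    bottom) plus a JSON sidecar mapping region id to predicted class."""
    labels = class_map.labels
    present = class_map.present_classes
    missing = [c for c in present if c not in class_map.palette]
    if missing:
        raise InvalidArgumentError(f"palette has no entry for classes {missing}")
    h, w = labels.shape
    rgb = np.zeros((h, w, 3), dtype=np.uint8)
    for cls in present:
        rgb[labels == cls] = class_map.palette[cls]
    # legend strip: one swatch per palette class, in class-id order
    classes = sorted(class_map.palette)
    strip = np.zeros((legend_height, w, 3), dtype=np.uint8)
    if classes:
        bounds = np.linspace(0, w, len(classes) + 1).astype(int)
        for (cls, lo, hi) in zip(classes, bounds[:-1], bounds[1:]):
            strip[:, lo:hi] = class_map.palette[cls]
    img = np.vstack([rgb, strip])
    out_path = Path(out_path)
    Image.fromarray(img).save(out_path, format="PNG")
    sidecar = out_path.with_suffix(out_path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "region_predictions": class_map.region_predictions,
                "legend": list(class_map.legend),
                "palette": {str(k): list(v) for k, v in class_map.palette.items()},
            },
            indent=2,
            sort_keys=True,
        )
    )
    return out_path
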