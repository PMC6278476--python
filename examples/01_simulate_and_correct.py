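"""Render a synthetic scene, write it as ENVI cubes, and correct to reflectance.

Seven variety profiles share peaks at 1116/1308 nm and valleys at 1200/1460 nm
but differ in reflectance offset. The printed error shows that dividing
(raw - dark) by (white - dark) recovers each planted disk's mean reflectance
to within the planted noise.
"""

import tempfile
from pathlib import Path

import numpy as np

from chrysospec import (
    SceneSpec,
    correct_reflectance,
    make_variety_profiles,
    read_envi,
    render_scene,
    write_scene,
)

profiles = make_variety_profiles(n_classes=7, seed=42)
spec = SceneSpec(height=120, width=120, samples_per_class=3, seed=7)
scene = render_scene(spec, profiles)
print(f"scene: {spec.height}x{spec.width}x{spec.n_bands}, "
      f"{scene.truth_mask.n_regions} sample disks")

with tempfile.TemporaryDirectory() as tmp:
    paths = write_scene(scene, Path(tmp) / "scene")
    raw = read_envi(Path(str(paths["raw"]) + ".hdr"))
    white = read_envi(Path(str(paths["white"]) + ".hdr"))
    dark = read_envi(Path(str(paths["dark"]) + ".hdr"))

refl = correct_reflectance(raw, white, dark)
errors = []
for rid in scene.truth_mask.region_ids:
    profile = profiles[scene.truth_labels[rid] - 1]
    got = refl.data[scene.truth_mask.labels == rid].mean(axis=0)
    want = profile.mean_curve(refl.grid.centers)
    errors.append(np.max(np.abs(got - want)))
print(f"max |disk mean - planted curve| over 21 disks: {max(errors):.4f}")
print("(should be a few times the 0.005 within-class offset sd: the correction "
      "removes the illumination field and dark current exactly)")
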