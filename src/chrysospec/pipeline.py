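"""End-to-end pipeline: simulate -> correct -> segment -> extract -> split ->
select bands -> train -> evaluate -> visualize, with a manifest and JSON logs.

A single global seed fans out to per-stage seeds by fixed offsets, so a rerun
with the same config reproduces every deterministic artifact bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .chemometrics import (
    REFERENCE_OPTIMAL_WAVELENGTHS_NM,
    second_derivative,
    select_bands,
)
from .classify import DcnnConfig, LrConfig, SvmConfig, train_dcnn, train_lr, train_svm
from .envi import correct_reflectance, write_envi
from .exceptions import InvalidArgumentError
from .segmentation import band_image, clean_mask, label_regions, threshold_mask
from .spectra import PreprocessChain, build_table, split_dataset
from .synthetic import SceneSpec, make_variety_profiles, render_scene, write_scene
from .visualize import classify_scene, render_map

__all__ = ["PipelineConfig", "run_pipeline"]

# fixed per-stage seed offsets fanned out from the global seed
_SEED_OFFSETS = {"profiles": 1, "scenes": 2, "split": 3, "svm": 4, "dcnn": 5}


@dataclass
class PipelineConfig:
    """Everything one run needs; round-trips through YAML unchanged."""

    seed: int = 42
    n_classes: int = 7
    n_scenes: int = 2
    samples_per_class: int = 5
    scene_height: int = 160
    scene_width: int = 160
    n_bands: int = 256
    segment_band_nm: float = 1119.0
    opening_radius: int = 1
    min_area: int = 20
    crop_policy: str = "middle_run"
    crop_target: int = 200
    wavelet: str = "db6"
    wavelet_level: int = 3
    deriv_window: int = 9
    deriv_polyorder: int = 2
    band_selection_mode: str = "none"  # none | manual | auto
    band_selection_top_m: int = 18
    manual_wavelengths: list = field(
        default_factory=lambda: list(REFERENCE_OPTIMAL_WAVELENGTHS_NM)
    )
    models: list = field(default_factory=lambda: ["svm", "lr", "dcnn"])
    svm_grid_exponents_c: list = field(default_factory=lambda: [0, 2, 4, 6])
    svm_grid_exponents_g: list = field(default_factory=lambda: [-4, -2, 0])
    lr_penalty: str = "L2"
    lr_c_prime: float = 100.0
    lr_solver: str = "liblinear"
    dcnn_num_convs: int = 3
    dcnn_num_first_kernels: int = 16
    dcnn_epoch: int = 30
    dcnn_batch_size: int = 64
    dcnn_fc_hidden: int = 64

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


class _Run:
    """Bookkeeping for one run directory: manifest + JSON-line log."""

    def __init__(self, outdir: Path) -> None:
        self.outdir = outdir
        self.manifest: dict[str, dict] = {}
        self.log_path = outdir / "log.jsonl"
        self._log_fh = open(self.log_path, "a")

    def log(self, stage: str, **info) -> None:
        record = {"stage": stage, **info}
        self._log_fh.write(json.dumps(record, default=str) + "\n")
        self._log_fh.flush()

    def register(self, path: Path, stage: str) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.manifest[str(Path(path).relative_to(self.outdir))] = {
            "sha256": digest,
            "stage": stage,
        }

    def finish(self) -> None:
        # the manifest and log describe the run and are not listed in themselves
        manifest_path = self.outdir / "manifest.json"
        manifest_path.write_text(json.dumps(self.manifest, indent=2, sort_keys=True))
        self._log_fh.close()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage into ``outdir``; returns the evaluation summary.

    A stage failure aborts the run with the failing stage named.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run = _Run(outdir)
    config.to_yaml(outdir / "config.yaml")
    run.register(outdir / "config.yaml", "config")
    seed = config.seed
    stage = "simulate"
    try:
        t0 = time.time()
        profiles = make_variety_profiles(
            config.n_classes, seed + _SEED_OFFSETS["profiles"]
        )
        chain = PreprocessChain(
            crop_policy=config.crop_policy,
            crop_target=config.crop_target,
            wavelet=config.wavelet,
            level=config.wavelet_level,
        )
        entries = []
        scenes = []
        for i in range(config.n_scenes):
            spec = SceneSpec(
                height=config.scene_height,
                width=config.scene_width,
                n_bands=config.n_bands,
                samples_per_class=config.samples_per_class,
                seed=seed + _SEED_OFFSETS["scenes"] + i,
            )
            scene = render_scene(spec, profiles)
            scenes.append(scene)
            scene_dir = outdir / "scenes" / f"scene_{i:02d}"
            for path in write_scene(scene, scene_dir).values():
                run.register(path, "simulate")
                hdr = Path(str(path) + ".hdr")
                if hdr.exists():
                    run.register(hdr, "simulate")
        run.log(stage, n_scenes=config.n_scenes, seconds=round(time.time() - t0, 2))

        stage = "correct"
        refl_cubes = []
        for i, scene in enumerate(scenes):
            refl = correct_reflectance(scene.raw_cube, scene.white_cube, scene.dark_cube)
            refl_cubes.append(refl)
            hdr, binary = write_envi(refl, outdir / "scenes" / f"scene_{i:02d}" / "reflectance.img")
            run.register(hdr, stage)
            run.register(binary, stage)
        run.log(stage, n_scenes=len(refl_cubes))

        stage = "segment"
        masks = []
        for i, refl in enumerate(refl_cubes):
            img = band_image(refl, config.segment_band_nm)
            mask = threshold_mask(img, method="otsu")
            mask = clean_mask(mask, config.opening_radius, config.min_area)
            seg = label_regions(mask)
            masks.append(seg)
            mask_path = outdir / "scenes" / f"scene_{i:02d}" / "mask.img"
            seg.labels.astype("<u2").tofile(mask_path)
            run.register(mask_path, stage)
        run.log(stage, regions=[m.n_regions for m in masks])

        stage = "extract"
        entries = []
        for scene, refl, seg in zip(scenes, refl_cubes, masks):
            truth = scene.truth_mask.labels
            labels = {}
            for rid in seg.region_ids:
                overlap = truth[seg.labels == rid]
                overlap = overlap[overlap > 0]
                if overlap.size:
                    labels[rid] = scene.truth_labels[int(np.bincount(overlap).argmax())]
            entries.append((chain.crop(refl), seg, labels))
        table = build_table(entries, smooth_first=True, **chain.wavelet_kwargs())
        table_path = table.to_csv(outdir / "table.csv")
        run.register(table_path, stage)
        run.log(stage, n_rows=len(table), n_bands=table.n_bands)

        stage = "split"
        split = split_dataset(table, seed + _SEED_OFFSETS["split"])
        run.register(split.train.to_csv(outdir / "train.csv"), stage)
        run.register(split.test.to_csv(outdir / "test.csv"), stage)
        run.log(stage, n_train=len(split.train), n_test=len(split.test))

        stage = "select-bands"
        if config.band_selection_mode != "none":
            class_means = np.vstack(
                [split.train.spectra[split.train.labels == c].mean(axis=0)
                 for c in split.train.classes]
            )
            deriv = second_derivative(
                class_means, split.train.grid,
                window=config.deriv_window, polyorder=config.deriv_polyorder,
            )
            selection = select_bands(
                deriv,
                split.train.grid,
                mode=config.band_selection_mode,
                manual_list=config.manual_wavelengths
                if config.band_selection_mode == "manual" else None,
                top_m=config.band_selection_top_m,
            )
            run.register(selection.to_csv(outdir / "band_selection.csv"), stage)
            chain = chain.with_selection(selection.band_indices)
            split = type(split)(
                train=chain.apply_to_table(split.train),
                test=chain.apply_to_table(split.test),
                seed=split.seed,
            )
            run.log(stage, n_bands=len(selection))
        else:
            run.log(stage, skipped=True)

        stage = "train"
        reports = {}
        trained = {}
        if "svm" in config.models:
            cfg = SvmConfig(
                grid_c=tuple(10.0**e for e in config.svm_grid_exponents_c),
                grid_g=tuple(10.0**e for e in config.svm_grid_exponents_g),
                cv_folds=3,
            )
            trained["svm"], reports["svm"] = train_svm(
                split, cfg, seed=seed + _SEED_OFFSETS["svm"]
            )
        if "lr" in config.models:
            trained["lr"], reports["lr"] = train_lr(
                split, LrConfig(config.lr_penalty, config.lr_c_prime, config.lr_solver)
            )
        if "dcnn" in config.models:
            dcfg = DcnnConfig(
                num_convs=config.dcnn_num_convs,
                num_first_kernels=config.dcnn_num_first_kernels,
                epoch=config.dcnn_epoch,
                batch_size=config.dcnn_batch_size,
                fc_hidden=config.dcnn_fc_hidden,
            )
            trained["dcnn"], reports["dcnn"] = train_dcnn(
                split, dcfg, seed=seed + _SEED_OFFSETS["dcnn"]
            )
        for name, report in reports.items():
            path = outdir / f"report_{name}.json"
            report.to_json(path)
            run.register(path, stage)
            run.log(stage, model=name, train_accuracy=report.train_accuracy,
                    test_accuracy=report.test_accuracy)

        stage = "visualize"
        if trained:
            best = "dcnn" if "dcnn" in trained else sorted(trained)[0]
            cmap = classify_scene(refl_cubes[0], masks[0], trained[best], chain)
            map_path = render_map(cmap, outdir / "classification_map.png")
            run.register(map_path, stage)
            run.register(Path(str(map_path) + ".json"), stage)
            run.log(stage, model=best, classes=cmap.present_classes)
    except Exception as exc:
        run.log(stage, error=str(exc))
        run.finish()
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    run.finish()
    return {name: rep for name, rep in reports.items()}
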