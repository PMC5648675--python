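"""End-to-end orchestration: simulate -> segment -> jnd -> tem -> analyze.

A validated :class:`RunConfig` selects stages and carries the generator
specs, thresholds, and visual-system settings. Every run writes a manifest
recording the config hash, seed, and produced files; identical config and
seed give identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import image_pipeline as ip
from . import io as cio
from . import stats_analysis as sa
from . import synthetic_data as sd
from . import tem_morphometrics as tm
from . import visual_model as vm
from .spectra import read_spectrum_csv, write_spectrum_csv

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("chromaderm")

STAGES = ("simulate", "segment", "jnd", "tem", "analyze")


class RunConfig(BaseModel):
    """Validated pipeline configuration."""

    stages: list[str] = Field(default_factory=list)
    seed: int = 0
    out_dir: str = "chromaderm_run"
    orange_threshold: float = 0.20
    yellow_threshold: float = 0.15
    white_reflectance: float = 0.99
    reference_patch_index: int = 3
    visual_system: dict | None = None
    scene: dict = Field(default_factory=dict)
    micrograph: dict = Field(default_factory=dict)
    effect: dict = Field(default_factory=dict)
    skin_classes: list[str] = Field(
        default_factory=lambda: ["orange", "yellow", "dark_gray", "cream"])
    # external inputs for stages run without `simulate`
    image_path: str | None = None
    annotations_path: str | None = None
    mask_path: str | None = None
    table_path: str | None = None
    spectra_dir: str | None = None

    @field_validator("stages")
    @classmethod
    def _known_stages(cls, v: list[str]) -> list[str]:
        bad = [s for s in v if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stages {bad}; valid: {STAGES}")
        return v

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _check_inputs(config: RunConfig) -> None:
    """Fail before any stage runs if an external input is missing."""
    sim = "simulate" in config.stages
    needed: list[tuple[str, str | None]] = []
    if "segment" in config.stages and not sim:
        needed += [("image_path", config.image_path),
                   ("annotations_path", config.annotations_path)]
    if "tem" in config.stages and not sim:
        needed += [("mask_path", config.mask_path)]
    if "analyze" in config.stages and not sim:
        needed += [("table_path", config.table_path)]
    if "jnd" in config.stages and not sim:
        needed += [("spectra_dir", config.spectra_dir)]
    for key, value in needed:
        if value is None:
            raise FileNotFoundError(f"{key} is required when running without simulate")
        if not Path(value).exists():
            raise FileNotFoundError(f"{key}: {value} does not exist")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages in dependency order; return the manifest."""
    _check_inputs(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": [s for s in STAGES if s in config.stages],
        "outputs": {},
    }
    thresholds = ip.Thresholds(orange=config.orange_threshold,
                               yellow=config.yellow_threshold)
    system = (vm.VisualSystem.from_dict(config.visual_system)
              if config.visual_system else vm.VisualSystem.tawny_dragon())

    paths: dict = {}
    if "simulate" in manifest["stages"]:
        scene = sd.SceneSpec(**{**config.scene, "seed": config.seed})
        scene_out = sd.generate_throat_image(scene)
        img_path = out / "throat.tiff"
        ann_path = out / "throat.json"
        cio.write_rgb_image(img_path, scene_out["raw"], bit_depth=scene.bit_depth)
        ann_path.write_text(json.dumps(scene_out["annotations"]))
        paths["image"], paths["annotations"] = img_path, ann_path

        mspec = sd.MicrographSpec(**{**config.micrograph, "seed": config.seed + 1})
        mg = sd.generate_micrograph(mspec)
        mask_path = out / "micrograph.png"
        cio.write_micrograph(mg["micrograph"], mask_path)
        paths["mask"] = mask_path

        espec = sd.EffectSpec(**{**config.effect, "seed": config.seed + 2})
        table = sd.generate_longitudinal(espec)
        table_path = out / "longitudinal.csv"
        table.to_csv(table_path, index=False)
        paths["table"] = table_path

        spectra_dir = out / "spectra"
        spectra_dir.mkdir(exist_ok=True)
        for i, cls in enumerate(config.skin_classes):
            spec = sd.generate_reflectance(cls, seed=config.seed + 10 + i)
            write_spectrum_csv(spec, spectra_dir / f"{cls}.csv")
        paths["spectra_dir"] = spectra_dir
        manifest["outputs"]["simulate"] = sorted(
            str(p) for p in [img_path, ann_path, mask_path, table_path])
        log.info("simulate: wrote synthetic inputs to %s", out)
    else:
        paths = {"image": config.image_path, "annotations": config.annotations_path,
                 "mask": config.mask_path, "table": config.table_path,
                 "spectra_dir": config.spectra_dir}

    if "segment" in manifest["stages"]:
        raw = cio.read_rgb_image(paths["image"])
        ann = cio.read_annotations(paths["annotations"])
        patch_masks, reflectances, throat_mask = cio.annotation_masks(
            ann, raw.shape[:2])
        responses = np.stack([raw[m].mean(axis=0) for m in patch_masks])
        standards = ip.GrayStandardSet(np.asarray(reflectances), responses)
        calib = ip.fit_linearization(standards)
        linear = calib.linearize(raw)
        ref_i = config.reference_patch_index
        equalized = ip.equalize_image(linear, patch_masks[ref_i],
                                      reflectances[ref_i])
        seg = ip.segment_throat(equalized, throat_mask, thresholds)
        props_path = out / "proportions.csv"
        pd.DataFrame([seg.proportions]).to_csv(props_path, index=False)
        cio.write_rgb_image(out / "segmentation.png",
                            np.stack([seg.labels == 0, seg.labels == 1,
                                      seg.labels == 2], axis=-1).astype(float),
                            bit_depth=8)
        manifest["outputs"]["segment"] = [str(props_path)]
        log.info("segment: proportions %s", seg.proportions)

    if "jnd" in manifest["stages"]:
        rows = []
        for csv in sorted(Path(paths["spectra_dir"]).glob("*.csv")):
            spectrum = read_spectrum_csv(csv)
            res = vm.contrast_vs_white(spectrum, system,
                                       white_reflectance=config.white_reflectance)
            rows.append({"spectrum": csv.stem, **res})
        jnd_path = out / "contrasts.csv"
        pd.DataFrame(rows).to_csv(jnd_path, index=False)
        manifest["outputs"]["jnd"] = [str(jnd_path)]
        log.info("jnd: wrote %d contrasts", len(rows))

    if "tem" in manifest["stages"]:
        mask = cio.read_micrograph(paths["mask"])
        transects = tm.extract_transects(mask)
        grid, median_fill = tm.platelet_area_fraction(mask, n_plots=25,
                                                      seed=config.seed)
        morpho_path = out / "morphometry.csv"
        pd.DataFrame([{
            "median_iridophore_proportion": tm.median_iridophore_proportion(transects),
            "median_platelet_fraction": median_fill,
            "n_transects": len(transects),
            "n_plots": len(grid),
        }]).to_csv(morpho_path, index=False)
        manifest["outputs"]["tem"] = [str(morpho_path)]

    if "analyze" in manifest["stages"]:
        table = pd.read_csv(paths["table"])
        result = sa.fit_lmm(table)
        for name, df in (("anova", result.anova),
                         ("lsmeans", sa.lsmeans_table(result)),
                         ("contrasts", result.contrasts)):
            df.to_csv(out / f"{name}.csv", index=False)
        manifest["outputs"]["analyze"] = [str(out / "anova.csv"),
                                          str(out / "lsmeans.csv"),
                                          str(out / "contrasts.csv")]

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
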