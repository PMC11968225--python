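"""End-to-end reproducible runs: simulate -> ROI -> quantify -> phenotype -> stats.

A single YAML/dict config drives the whole pipeline. All randomness flows
from one root seed through named substreams (one per image and stage), so a
run is byte-reproducible. Each run directory receives the stage outputs as
CSV plus a provenance manifest (config hash, root seed, package version).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cell_phenotyping import phenotype_image
from .image import MultiplexImage
from .intensity_quant import (
    band_profile,
    colocalize_objects,
    count_objects,
    threshold_channel,
)
from .morphometry import fold_change, summarize_folds
from .roi_geometry import band_map, derive_roi, inner_outer_split
from .spatial_stats import (
    TrendModelSpec,
    fit_distance_trend,
    marginal_slopes,
    plot_trends,
    slope_contrasts,
)
from .synthetic_scene import (
    CaliperSeriesConfig,
    SceneConfig,
    generate_caliper_series,
    generate_cells,
    make_roi_mask,
    render_scene,
)

DEFAULT_RUN_CONFIG: dict = {
    "seed": 0,
    "band_width_um": 100.0,
    "band_stain": "DAPI",
    "threshold_methods": {},  # stain -> otsu|triangle|fixed (otsu default)
    "min_object_area_um2": 20.0,
    "colocalization_overlap": 0.25,
    "phenotype_rules": {},
    "design": {
        "groups": ["Hep", "NoHep"],
        "timepoints": [1, 12],
        "mice_per_group": 2,
        "replicates": 2,
    },
    "scene": {},  # SceneConfig overrides shared by all images
    "group_scene_overrides": {},  # group -> SceneConfig overrides
    "calipers": {"enabled": True, "noise_cv": 0.05},
    "stats": {"enabled": True, "adjust": "tukey"},
    "plots": False,
}


def validate_config(config: dict) -> dict:
    """Merge a user config over the defaults and validate it up front.

    All violations are collected and reported together before any stage
    runs.
    """
    cfg = {**DEFAULT_RUN_CONFIG, **(config or {})}
    for key in ("design", "calipers", "stats"):
        cfg[key] = {**DEFAULT_RUN_CONFIG[key], **(cfg.get(key) or {})}
    problems = []
    unknown = set(cfg) - set(DEFAULT_RUN_CONFIG)
    if unknown:
        problems.append(f"unknown config keys: {sorted(unknown)}")
    if cfg["band_width_um"] <= 0:
        problems.append("band_width_um must be positive")
    scene = cfg.get("scene") or {}
    if "pixel_size_um" in scene and scene["pixel_size_um"] <= 0:
        problems.append("scene.pixel_size_um must be positive")
    design = cfg["design"]
    for k in ("groups", "timepoints"):
        if not design.get(k):
            problems.append(f"design.{k} must be non-empty")
    for k in ("mice_per_group", "replicates"):
        if int(design.get(k, 0)) < 1:
            problems.append(f"design.{k} must be >= 1")
    try:
        _scene_config(cfg, (cfg["design"]["groups"] or ["g"])[0], 0)
    except (TypeError, ValueError) as exc:
        problems.append(f"scene config invalid: {exc}")
    if problems:
        raise ValueError("invalid run config:\n- " + "\n- ".join(problems))
    return cfg


def _substream_seed(root_seed: int, *path: int) -> int:
    ss = np.random.SeedSequence([int(root_seed), *[int(p) for p in path]])
    return int(ss.generate_state(1)[0] % (2**31))


def _scene_config(cfg: dict, group: str, seed: int) -> SceneConfig:
    overrides = {**(cfg.get("scene") or {}),
                 **((cfg.get("group_scene_overrides") or {}).get(group, {}))}
    if "image_size_px" in overrides:
        overrides["image_size_px"] = tuple(overrides["image_size_px"])
    return SceneConfig(**overrides, seed=seed)


def simulate_image(cfg: dict, group: str, seed: int, meta: dict):
    """Generate one synthetic multiplex image plus its ground truth."""
    scene = _scene_config(cfg, group, seed)
    roi = make_roi_mask(scene)
    truth = generate_cells(scene, roi)
    image = render_scene(truth, scene, meta=meta)
    return image, truth, scene


def _quantify_one(cfg: dict, image: MultiplexImage, meta: dict):
    """ROI -> bands -> band fractions + vessel counts + phenotypes for one image."""
    roi = derive_roi(image.channel("DAPI"), image.pixel_size_um)
    bands = band_map(roi, cfg["band_width_um"])
    methods = cfg.get("threshold_methods") or {}
    stain = cfg["band_stain"]
    smask = threshold_channel(
        image.channel(stain), roi, stain=stain, method=methods.get(stain, "otsu")
    )
    fractions = band_profile(smask, bands, meta)

    counts = []
    if "CD31" in image.channels:
        cd31 = threshold_channel(
            image.channel("CD31"), roi, stain="CD31",
            method=methods.get("CD31", "otsu"),
        )
        split = inner_outer_split(roi, 0.5)
        regions = {"whole": roi.mask, "inner": split.inner, "outer": split.outer}
        for name, region in regions.items():
            rec = count_objects(
                cd31, region, cfg["min_object_area_um2"], name,
                meta.get("image_id", ""), meta,
            )
            counts.append({**rec.to_dict(), "stain": "CD31"})
        if "Podo" in image.channels:
            podo = threshold_channel(
                image.channel("Podo"), roi, stain="Podo",
                method=methods.get("Podo", "otsu"),
            )
            for name, region in regions.items():
                rec = colocalize_objects(
                    cd31, podo, region, cfg["colocalization_overlap"],
                    cfg["min_object_area_um2"], name, meta.get("image_id", ""), meta,
                )
                counts.append({**rec.to_dict(), "stain": "CD31+Podo"})

    pheno = phenotype_image(image, roi, cfg.get("phenotype_rules"))
    return fractions, counts, pheno


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> Path:
    """Execute the full pipeline into ``out_dir``; returns the run directory.

    Stages: per-image simulation (or loading), ROI derivation, band
    quantification, vessel object counts, phenotyping, caliper morphometry
    and the distance-trend mixed model. Any stage failure aborts with the
    stage name; outputs and a provenance manifest are written on success.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root_seed = int(cfg["seed"])
    design = cfg["design"]

    all_fracs: list[pd.DataFrame] = []
    all_counts: list[dict] = []
    all_phenos: list[dict] = []
    truth_rows: list[dict] = []
    img_index = 0
    for gi, group in enumerate(design["groups"]):
        for mi in range(design["mice_per_group"]):
            mouse_id = f"{group}_m{mi:02d}"
            for ti, tp in enumerate(design["timepoints"]):
                for rep in range(design["replicates"]):
                    image_id = f"{group}_m{mi:02d}_t{tp}_r{rep}"
                    meta = {
                        "image_id": image_id,
                        "group": group,
                        "timepoint": tp,
                        "mouse_id": mouse_id,
                        "replicate": rep,
                    }
                    seed = _substream_seed(root_seed, gi, mi, ti, rep)
                    try:
                        image, truth, _ = simulate_image(cfg, group, seed, meta)
                    except Exception as exc:
                        raise RuntimeError(f"stage 'simulate' failed on {image_id}: {exc}") from exc
                    try:
                        fracs, counts, pheno = _quantify_one(cfg, image, meta)
                    except Exception as exc:
                        raise RuntimeError(f"stage 'quantify' failed on {image_id}: {exc}") from exc
                    all_fracs.append(fracs)
                    all_counts.extend(counts)
                    all_phenos.append(pheno.to_dict())
                    truth_rows.append({**meta, "n_true_cells": len(truth)})
                    img_index += 1

    band_fractions = pd.concat(all_fracs, ignore_index=True)
    band_fractions.to_csv(out / "band_fractions.csv", index=False)
    pd.DataFrame(all_counts).to_csv(out / "object_counts.csv", index=False)
    pd.DataFrame(all_phenos).to_csv(out / "phenotype_counts.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(out / "images.csv", index=False)

    if cfg["calipers"].get("enabled", True):
        try:
            series = []
            for gi, group in enumerate(design["groups"]):
                ccfg = CaliperSeriesConfig(
                    n_implants=design["mice_per_group"],
                    group=group,
                    noise_cv=float(cfg["calipers"].get("noise_cv", 0.05)),
                    seed=_substream_seed(root_seed, 9000, gi),
                )
                series.append(generate_caliper_series(ccfg))
            calipers = pd.concat(series, ignore_index=True)
            folds = fold_change(calipers)
            folds.to_csv(out / "caliper_folds.csv", index=False)
            summarize_folds(folds).to_csv(out / "fold_summary.csv", index=False)
        except Exception as exc:
            raise RuntimeError(f"stage 'morphometry' failed: {exc}") from exc

    if cfg["stats"].get("enabled", True):
        try:
            spec = TrendModelSpec()
            model = fit_distance_trend(band_fractions, spec)
            slopes = marginal_slopes(model)
            slopes.frame.to_csv(out / "slopes.csv", index=False)
            if len(slopes) >= 2:
                slope_contrasts(slopes, cfg["stats"].get("adjust", "tukey")).to_csv(
                    out / "contrasts.csv", index=False
                )
            with open(out / "model_summary.json", "w") as fh:
                json.dump(model.summary_dict(), fh, indent=2)
            if cfg.get("plots"):
                plot_trends(model, slopes, str(out / "trends.png"))
        except Exception as exc:
            raise RuntimeError(f"stage 'stats' failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": root_seed,
        "n_images": img_index,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "config": cfg,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out
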