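"""End-to-end pipeline: lasers -> normalize -> features -> label/sample ->
classify -> map, driven by a single flat configuration.

Every stage reads and writes only documented file formats (CSV, PNG,
YAML, GeoJSON); re-running with the same configuration reproduces
identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import __version__, classify, features as feat, geo, labeling, lasers, normalization as norm, sampling


@dataclass
class PipelineConfig:
    """Flat per-stage parameter block; defaults follow the published
    operating point where one is stated."""

    images_dir: str = "images"
    nav_csv: str = "nav.csv"
    template_yaml: str = "template.yaml"
    out_dir: str = "run"

    laser_coeff: float = 0.2
    laser_buffer_px: int = 250
    laser_spacing_cm: float = 40.0
    min_sep_fraction: float = 0.4

    crop_width: int | None = None  # None -> largest feasible crop
    crop_height: int | None = None
    clahe_clip_limit: float = 0.01
    clahe_tiles: int = 8

    entropy_radius: int = 5

    mode: str = "unsupervised"  # or "supervised"
    seeds_csv: str | None = None  # supervised mode: CSV image_id,label
    n_seeds: int = 50
    k_nn: int = 100
    split_fractions: tuple[float, float, float] = (0.80, 0.07, 0.13)
    sampling_strategy: str = "stratified"
    n_samples: int = 5000
    n_strata: int = 20
    n_gmm_components: int = 20
    k_min: int = 2
    k_max: int = 20
    iterations: int = 200

    max_gap_s: float = 30.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "split_fractions" in data:
            data["split_fractions"] = tuple(data["split_fractions"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["split_fractions"] = list(d["split_fractions"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _load_images(image_dir: Path) -> list[Path]:
    return sorted(p for p in image_dir.iterdir() if p.suffix.lower() in {".png", ".jpg", ".jpeg", ".tif", ".tiff"})


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in fixed order; returns the manifest dict."""
    t_start = time.perf_counter()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img_dir = Path(config.images_dir)
    if not img_dir.is_dir() or not _load_images(img_dir):
        raise FileNotFoundError(f"stage detect-lasers: no input images in {img_dir}")
    if not Path(config.nav_csv).is_file():
        raise FileNotFoundError(f"stage map: navigation table {config.nav_csv} missing")
    if not Path(config.template_yaml).is_file():
        raise FileNotFoundError(f"stage detect-lasers: laser template {config.template_yaml} missing")

    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    # ---- stage 1: laser detection / scales
    template = lasers.LaserTemplate.from_yaml(config.template_yaml)
    scales = lasers.detect_survey(
        img_dir, template, config.laser_coeff, min_sep_fraction=config.min_sep_fraction
    )
    scales_path = out / "scales.csv"
    scales.to_csv(scales_path, index=False)
    manifest["stages"]["detect_lasers"] = {"n_records": len(scales), "output": str(scales_path)}

    scaled = scales[scales["flag"] == "ok"].reset_index(drop=True)
    if len(scaled) == 0:
        raise RuntimeError("stage normalize: no scaled images available")

    # ---- stage 2: normalization + footprint standardization
    sc_m = norm.median_scale(scaled["scale_px_per_cm"].to_numpy())
    ref_id = norm.select_reference(scaled)
    ref_img = np.asarray(Image.open(img_dir / f"{ref_id}.png").convert("RGB"))
    ref_scale = float(scaled.set_index("image_id").loc[ref_id, "scale_px_per_cm"])
    profile = norm.ReferenceProfile.from_image(
        norm.enhance_contrast(
            norm.correct_illumination(ref_img),
            clip_limit=config.clahe_clip_limit, tiles=config.clahe_tiles,
        ),
        image_id=ref_id,
        scale=ref_scale,
    )
    profile.to_csv(out / "reference_profile.csv")

    if config.crop_width is None or config.crop_height is None:
        # largest crop every scaled image can support at the median scale
        h, w = ref_img.shape[:2]
        min_factor = sc_m / scaled["scale_px_per_cm"].max()
        crop_w = int(w * min_factor * 0.95)
        crop_h = int(h * min_factor * 0.95)
    else:
        crop_w, crop_h = config.crop_width, config.crop_height
    spec = norm.FootprintSpec(median_scale=sc_m, crop_width=crop_w, crop_height=crop_h)

    norm_dir = out / "normalized"
    norm_dir.mkdir(exist_ok=True)
    n_norm = 0
    for _, row in scaled.iterrows():
        img = np.asarray(Image.open(img_dir / f"{row.image_id}.png").convert("RGB"))
        colored = norm.normalize_image(
            img, profile, clip_limit=config.clahe_clip_limit, tiles=config.clahe_tiles
        )
        std = norm.standardize_footprint(colored, float(row.scale_px_per_cm), spec)
        Image.fromarray(std).save(norm_dir / f"{row.image_id}.png")
        n_norm += 1
    manifest["stages"]["normalize"] = {
        "n_records": n_norm,
        "median_scale": sc_m,
        "reference": ref_id,
        "crop": [crop_w, crop_h],
        "footprint_m2": spec.footprint_m2,
    }

    # ---- stage 3: features
    fdf = feat.features_from_dir(norm_dir, entropy_radius=config.entropy_radius)
    fm, emb, fdf = feat.feature_table(fdf)
    feat_path = out / "features.csv"
    fdf.to_csv(feat_path, index=False)
    manifest["stages"]["features"] = {"n_records": len(fdf), "output": str(feat_path)}

    ids = fdf["image_id"].to_numpy()
    X = fdf[feat.FEATURE_COLUMNS].to_numpy(dtype=float)

    # ---- stage 4+5: training set and classification
    nav = pd.read_csv(config.nav_csv)
    if config.mode == "unsupervised":
        n = min(config.n_samples, len(ids))
        entropy = fdf["total_entropy"].to_numpy()
        kwargs = {}
        if config.sampling_strategy == "spatial":
            kwargs = {"lon": nav["longitude"].to_numpy()[: len(ids)], "lat": nav["latitude"].to_numpy()[: len(ids)]}
        elif config.sampling_strategy in ("stratified", "probabilistic"):
            kwargs = {"entropy": entropy}
        sample_ids = sampling.draw_sample(
            config.sampling_strategy, ids, n, seed=config.seed,
            n_strata=config.n_strata, n_components=config.n_gmm_components, **kwargs,
        )
        pd.DataFrame({"image_id": sample_ids}).to_csv(out / "sample.csv", index=False)
        manifest["stages"]["sample"] = {"n_records": len(sample_ids), "strategy": config.sampling_strategy}

        sel = np.isin(ids, sample_ids)
        k = classify.select_k(X[sel], config.k_min, config.k_max, seed=config.seed)
        model = classify.fit_kmeans(X[sel], k, seed=config.seed)
        labels_arr = model.predict(X)
        pred_class = np.array([f"cluster_{c}" for c in labels_arr])
        # confidence: margin between nearest and second-nearest centroid
        Xs = (X - model.feature_means) / model.feature_stds
        d = np.linalg.norm(Xs[:, None, :] - model.centroids[None, :, :], axis=2)
        d.sort(axis=1)
        confidence = 1.0 - d[:, 0] / np.maximum(d[:, 0] + d[:, 1], 1e-12) if d.shape[1] > 1 else np.ones(len(X))
        manifest["stages"]["classify"] = {
            "n_records": len(pred_class), "mode": "unsupervised",
            "chosen_k": int(k), "silhouette": model.training_silhouette,
        }
    elif config.mode == "supervised":
        if config.seeds_csv is None or not Path(config.seeds_csv).is_file():
            raise FileNotFoundError("stage label: supervised mode needs seeds_csv (image_id,label)")
        seeds = pd.read_csv(config.seeds_csv)
        labeled = labeling.expand_labels(seeds, fm, k_nn=config.k_nn)
        labeled.table.to_csv(out / "labeled.csv", index=False)
        train, val, test = labeling.split_labeled(labeled, config.split_fractions, seed=config.seed)
        manifest["stages"]["label"] = {
            "n_records": labeled.n_total,
            "n_expanded": labeled.n_expanded,
            "splits": [len(train), len(val), len(test)],
        }
        idx_of = {iid: i for i, iid in enumerate(ids)}
        tr_idx = [idx_of[i] for i in train["image_id"]]
        backend = classify.FeatureBackend(iterations=config.iterations, seed=config.seed)
        backend.fit(X[tr_idx], train["label"].to_numpy())
        proba = backend.predict_proba(X)
        pred_class = backend.classes_[proba.argmax(axis=1)]
        confidence = proba.max(axis=1)
        manifest["stages"]["classify"] = {
            "n_records": len(pred_class), "mode": "supervised",
            "backend": backend.name, "classes": [str(c) for c in backend.classes_],
        }
    else:
        raise ValueError(f"unknown mode {config.mode!r}")

    pred = pd.DataFrame({"image_id": ids, "pred_class": pred_class, "confidence": confidence})
    pred_path = out / "predictions.csv"
    pred.to_csv(pred_path, index=False)

    # ---- stage 6: georeferenced class track
    # survey contract: one nav row per captured image, in filename order;
    # images dropped earlier (unscaled) keep their original slot
    all_ids = [p.stem for p in _load_images(img_dir)]
    img_times = pd.DataFrame(
        {"image_id": all_ids, "timestamp_utc": nav["timestamp_utc"].to_numpy()[: len(all_ids)]}
    )
    points = geo.build_classified_points(pred, img_times, nav, max_gap_s=config.max_gap_s)
    track_path = out / "track.geojson"
    geo.export_track(points, track_path)
    props = geo.class_proportions(points)
    (out / "proportions.json").write_text(json.dumps({str(k): float(v) for k, v in props.items()}, indent=1))
    manifest["stages"]["map"] = {"n_records": int(points["placed"].sum()), "output": str(track_path)}

    manifest["elapsed_s"] = time.perf_counter() - t_start
    config.to_yaml(out / "config.yaml")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
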