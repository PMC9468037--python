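"""Synthetic seafloor scene generator with known ground truth.

Renders towed-camera style photographs of a nodule-covered seabed: dark
elliptical blobs on light sediment at four density/size regimes (classes
A-D), a radial illumination drop-off, altitude-dependent image scale and
three red laser dots with a fixed real-world spacing.  A matching
navigation track is produced so every downstream stage has a
parameter-recovery oracle.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from scipy import ndimage

#: class presets: expected nodules per m^2 and lognormal blob radius
#: (mean, sd) in pixels at the reference scale.  Densities are strictly
#: ordered A < B < C; D has the largest radius.
CLASS_PRESETS: dict[str, dict[str, float]] = {
    "A": {"density": 2.0, "radius_px": 8.0, "radius_sd": 1.0},
    "B": {"density": 60.0, "radius_px": 10.0, "radius_sd": 1.0},
    "C": {"density": 250.0, "radius_px": 9.0, "radius_sd": 1.0},
    "D": {"density": 15.0, "radius_px": 34.0, "radius_sd": 2.5},
}

SEAFLOOR_CLASSES = tuple(CLASS_PRESETS)

#: px/cm at which the radius presets are defined (altitude 2 m at the
#: default focal constant).
REFERENCE_SCALE = 5.4

#: sediment base color (R, G, B): red is strongly attenuated under water.
SEDIMENT_RGB = (70.0, 108.0, 122.0)
NODULE_RGB = (16.0, 24.0, 30.0)

#: brightness attenuation per meter of extra altitude.
ATTENUATION_PER_M = 0.22

LASER_PEAK = 250.0
LASER_SIGMA_PX = 3.5
LASER_DISC_PX = 20.0  # nominal footprint of a rendered dot

_EPOCH = datetime(2021, 4, 1, tzinfo=timezone.utc)


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one rendered seafloor photograph."""

    image_width: int = 1120
    image_height: int = 1680
    altitude_m: float = 2.0
    laser_spacing_cm: float = 40.0
    #: px*m/cm constant; scale = focal_scale / altitude_m.  The default
    #: 10.8 gives 5.4 px/cm at 2 m on the quarter-size default frame
    #: (use 43.2 for a full-size 4480x6720 frame).
    focal_scale: float = 10.8
    nodule_density: float | None = None
    nodule_radius_px: tuple[float, float] | None = None
    seafloor_class: str = "B"
    vignette_strength: float = 0.5
    brightness_jitter: float = 1.0
    noise_sd: float = 4.0
    lasers_on: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.altitude_m <= 0:
            raise ValueError("altitude_m must be positive")
        if not 0.0 <= self.vignette_strength <= 1.0:
            raise ValueError("vignette_strength must be in [0, 1]")
        if self.seafloor_class not in CLASS_PRESETS:
            raise ValueError(f"unknown seafloor class {self.seafloor_class!r}")
        if self.brightness_jitter <= 0:
            raise ValueError("brightness_jitter must be positive")

    @property
    def scale_px_per_cm(self) -> float:
        """True image scale from the pinhole proportionality."""
        return self.focal_scale / self.altitude_m

    @property
    def density(self) -> float:
        if self.nodule_density is not None:
            return self.nodule_density
        return CLASS_PRESETS[self.seafloor_class]["density"]

    @property
    def radius_px(self) -> tuple[float, float]:
        if self.nodule_radius_px is not None:
            return self.nodule_radius_px
        p = CLASS_PRESETS[self.seafloor_class]
        return (p["radius_px"], p["radius_sd"])

    @property
    def footprint_m2(self) -> float:
        s = self.scale_px_per_cm
        return (self.image_width / s) * (self.image_height / s) / 1e4


@dataclass
class GroundTruth:
    """What the renderer actually drew."""

    true_scale_px_per_cm: float
    true_laser_points: np.ndarray  # (3, 2) as (x, y) = (col, row)
    true_class: str
    illumination_field: np.ndarray  # per-pixel multiplier (H, W)
    altitude_m: float
    nodule_count: int


def laser_triangle(params: SceneParams) -> np.ndarray:
    """Vertices (x, y) of the equilateral laser triangle, frame-centered.

    Raises ``ValueError("lasers out of frame")`` when the triangle (plus
    dot radius) does not fit, e.g. at very low altitude.
    """
    side = params.laser_spacing_cm * params.scale_px_per_cm
    circum = side / np.sqrt(3.0)
    cx = params.image_width / 2.0
    cy = params.image_height / 2.0
    angles = np.deg2rad([90.0, 210.0, 330.0])
    pts = np.stack([cx + circum * np.cos(angles), cy + circum * np.sin(angles)], axis=1)
    margin = LASER_DISC_PX / 2.0
    if (
        pts[:, 0].min() < margin
        or pts[:, 1].min() < margin
        or pts[:, 0].max() > params.image_width - margin
        or pts[:, 1].max() > params.image_height - margin
    ):
        raise ValueError("lasers out of frame")
    return pts


def _stamp_ellipse(alpha: np.ndarray, cx: float, cy: float, rx: float, ry: float, theta: float) -> None:
    """Accumulate an anti-aliased filled ellipse into coverage map `alpha`."""
    h, w = alpha.shape
    rmax = max(rx, ry) + 2.0
    x0, x1 = int(max(0, cx - rmax)), int(min(w, cx + rmax + 1))
    y0, y1 = int(max(0, cy - rmax)), int(min(h, cy + rmax + 1))
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    # signed distance proxy: radial coordinate in ellipse units
    q = np.sqrt((u / rx) ** 2 + (v / ry) ** 2)
    edge = 1.0 / max(min(rx, ry), 1.0)
    cover = np.clip((1.0 - q) / edge + 0.5, 0.0, 1.0)
    np.maximum(alpha[y0:y1, x0:x1], cover, out=alpha[y0:y1, x0:x1])


def render_image(params: SceneParams) -> tuple[np.ndarray, GroundTruth]:
    """Render one photograph; returns (H, W, 3) uint8 image and its truth."""
    rng = np.random.default_rng(params.rng_seed)
    h, w = params.image_height, params.image_width
    scale = params.scale_px_per_cm
    pts = laser_triangle(params) if params.lasers_on else None

    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = SEDIMENT_RGB
    # low-frequency sediment mottle (smoothed noise) + fine grain
    mottle = ndimage.gaussian_filter(rng.normal(0.0, 1.0, size=(h, w)), 25.0)
    mottle *= 4.0 / max(mottle.std(), 1e-9)
    img += mottle[..., None]
    img += rng.normal(0.0, 1.0, size=(h, w, 1))

    # nodules: count from the expected per-m^2 density over the footprint
    lam = params.density * params.footprint_m2
    n_nodules = int(rng.poisson(lam))
    alpha = np.zeros((h, w), dtype=np.float64)
    r_mean, r_sd = params.radius_px
    px_factor = scale / REFERENCE_SCALE
    if n_nodules > 0:
        mu = np.log(r_mean**2 / np.sqrt(r_mean**2 + r_sd**2))
        sig = np.sqrt(np.log(1.0 + (r_sd / r_mean) ** 2))
        for _ in range(n_nodules):
            cx = rng.uniform(0, w)
            cy = rng.uniform(0, h)
            r = float(rng.lognormal(mu, sig)) * px_factor
            ecc = rng.uniform(0.6, 1.0)
            theta = rng.uniform(0, np.pi)
            _stamp_ellipse(alpha, cx, cy, max(r, 1.0), max(r * ecc, 1.0), theta)
    shade = np.asarray(NODULE_RGB)
    img = img * (1.0 - alpha[..., None]) + shade * alpha[..., None]

    # radial vignette and altitude-dependent attenuation
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = ((xx - w / 2.0) / (w / 2.0)) ** 2 + ((yy - h / 2.0) / (h / 2.0)) ** 2
    vignette = 1.0 - params.vignette_strength * (r2 / 2.0)
    atten = float(np.exp(-ATTENUATION_PER_M * max(params.altitude_m - 1.0, 0.0)))
    field = vignette * atten
    img *= field[..., None]

    # lasers are their own light source: applied after the vignette
    if pts is not None:
        for x, y in pts:
            rr = (xx - x) ** 2 + (yy - y) ** 2
            bump = np.exp(-rr / (2.0 * LASER_SIGMA_PX**2))
            img[..., 0] = np.maximum(img[..., 0], LASER_PEAK * bump)
            img[..., 1] = np.maximum(img[..., 1], 40.0 * bump)
            img[..., 2] = np.maximum(img[..., 2], 40.0 * bump)

    # sensor noise, then exposure: jitter scales the noise as well so a
    # jittered pair differs by an exact global factor (pre-quantization)
    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape)
    img *= params.brightness_jitter
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    truth = GroundTruth(
        true_scale_px_per_cm=scale,
        true_laser_points=pts if pts is not None else np.empty((0, 2)),
        true_class=params.seafloor_class,
        illumination_field=field.astype(np.float32),
        altitude_m=params.altitude_m,
        nodule_count=n_nodules,
    )
    return img, truth


def _track_coords(start: tuple[float, float], end: tuple[float, float], n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.0])
    lon = start[0] + (end[0] - start[0]) * t
    lat = start[1] + (end[1] - start[1]) * t
    return np.stack([lon, lat], axis=1)


def generate_survey(
    out_dir: str | Path,
    class_sequence: list[str],
    *,
    track_start: tuple[float, float] = (-117.0, 11.8),
    track_end: tuple[float, float] = (-117.05, 11.85),
    interval_s: float = 10.0,
    altitude_range: tuple[float, float] = (1.0, 4.0),
    seed: int = 0,
    base_params: SceneParams | None = None,
    jitter_range: tuple[float, float] = (0.7, 1.3),
) -> dict[str, Path]:
    """Render a survey: one PNG, nav row and truth row per class label.

    Returns paths to ``images/``, ``nav.csv``, ``truth.csv`` and the
    parameter sidecar ``survey.yaml``.
    """
    if interval_s <= 0:
        raise ValueError("non-monotone timestamps: interval must be positive")
    for c in class_sequence:
        if c not in CLASS_PRESETS:
            raise ValueError(f"unknown seafloor class {c!r}")
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    base = base_params or SceneParams()
    rng = np.random.default_rng(seed)
    n = len(class_sequence)
    coords = _track_coords(track_start, track_end, n)

    nav_rows, truth_rows = [], []
    for i, cls in enumerate(class_sequence):
        alt = float(rng.uniform(*altitude_range))
        jit = float(rng.uniform(*jitter_range))
        params = dataclasses.replace(
            base,
            altitude_m=alt,
            seafloor_class=cls,
            brightness_jitter=jit,
            rng_seed=int(rng.integers(0, 2**31 - 1)),
        )
        img, truth = render_image(params)
        image_id = f"img_{i:05d}"
        Image.fromarray(img).save(img_dir / f"{image_id}.png")
        ts = (_EPOCH + timedelta(seconds=i * interval_s)).strftime("%Y-%m-%dT%H:%M:%SZ")
        nav_rows.append({"timestamp_utc": ts, "latitude": coords[i, 1], "longitude": coords[i, 0]})
        lp = truth.true_laser_points
        truth_rows.append(
            {
                "image_id": image_id,
                "timestamp_utc": ts,
                "true_class": cls,
                "altitude_m": alt,
                "true_scale_px_per_cm": truth.true_scale_px_per_cm,
                "laser_x1": lp[0, 0], "laser_y1": lp[0, 1],
                "laser_x2": lp[1, 0], "laser_y2": lp[1, 1],
                "laser_x3": lp[2, 0], "laser_y3": lp[2, 1],
                "nodule_count": truth.nodule_count,
            }
        )

    nav_path = out_dir / "nav.csv"
    truth_path = out_dir / "truth.csv"
    pd.DataFrame(nav_rows).to_csv(nav_path, index=False)
    pd.DataFrame(truth_rows).to_csv(truth_path, index=False)

    sidecar = out_dir / "survey.yaml"
    meta = {
        "n_images": n,
        "class_sequence": list(class_sequence),
        "track_start": list(track_start),
        "track_end": list(track_end),
        "interval_s": interval_s,
        "altitude_range": list(altitude_range),
        "jitter_range": list(jitter_range),
        "seed": seed,
        "base_params": {k: (list(v) if isinstance(v, tuple) else v) for k, v in dataclasses.asdict(base).items()},
    }
    sidecar.write_text(yaml.safe_dump(meta, sort_keys=False))
    return {"images": img_dir, "nav": nav_path, "truth": truth_path, "sidecar": sidecar}
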