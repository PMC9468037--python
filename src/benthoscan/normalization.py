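"""Illumination / color normalization chain and footprint standardization.

The chain is fixed: raw -> illumination drop-off correction (local
z-score against a Gaussian-estimated light field) -> contrast-limited
adaptive histogram equalization -> histogram matching against a
reference image -> rescale to the survey median scale and center crop,
so every processed image shares pixel dimensions and physical footprint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import exposure

DEFAULT_CROP = (2240, 3360)  # (width, height)
DEFAULT_CLIP_LIMIT = 0.01
DEFAULT_TILES = 8


@dataclass(frozen=True)
class ReferenceProfile:
    """Per-channel 256-bin ECDF of the reference image."""

    ecdf: np.ndarray  # (3, 256) cumulative fractions
    reference_image_id: str = ""
    reference_scale: float = float("nan")

    def __post_init__(self) -> None:
        e = np.asarray(self.ecdf, dtype=float)
        if e.shape != (3, 256):
            raise ValueError("ecdf must be (3, 256)")
        if np.any(np.diff(e, axis=1) < -1e-12) or np.any(e < -1e-12) or np.any(e > 1 + 1e-12):
            raise ValueError("ecdf must be monotone in [0, 1]")
        object.__setattr__(self, "ecdf", e)

    @classmethod
    def from_image(cls, image: np.ndarray, image_id: str = "", scale: float = float("nan")) -> "ReferenceProfile":
        img = _as_rgb_u8(image)
        ecdf = np.stack([_channel_ecdf(img[..., c]) for c in range(3)])
        return cls(ecdf=ecdf, reference_image_id=image_id, reference_scale=scale)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {"intensity": np.arange(256), "ecdf_r": self.ecdf[0], "ecdf_g": self.ecdf[1], "ecdf_b": self.ecdf[2]}
        )
        df.attrs["reference_image_id"] = self.reference_image_id
        with open(path, "w") as fh:
            fh.write(f"# reference_image_id={self.reference_image_id}\n")
            fh.write(f"# reference_scale={self.reference_scale}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReferenceProfile":
        meta = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                k, v = line[1:].strip().split("=", 1)
                meta[k.strip()] = v.strip()
        df = pd.read_csv(path, comment="#")
        ecdf = np.stack([df["ecdf_r"].to_numpy(), df["ecdf_g"].to_numpy(), df["ecdf_b"].to_numpy()])
        return cls(
            ecdf=ecdf,
            reference_image_id=meta.get("reference_image_id", ""),
            reference_scale=float(meta.get("reference_scale", "nan")),
        )


@dataclass(frozen=True)
class FootprintSpec:
    """Common output geometry: median survey scale plus a center crop."""

    median_scale: float
    crop_width: int = DEFAULT_CROP[0]
    crop_height: int = DEFAULT_CROP[1]

    @property
    def footprint_m2(self) -> float:
        return self.crop_width * self.crop_height / (self.median_scale**2 * 1e4)


def _as_rgb_u8(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError("RGB image required")
    if img.dtype != np.uint8:
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img[..., :3]


def _channel_ecdf(channel: np.ndarray) -> np.ndarray:
    hist = np.bincount(channel.ravel(), minlength=256).astype(float)
    return np.cumsum(hist) / hist.sum()


DEFAULT_MU_TARGET = 127.5
DEFAULT_SIGMA_TARGET = 35.0


def correct_illumination(
    image: np.ndarray,
    mu_target: float | tuple[float, float, float] = DEFAULT_MU_TARGET,
    sigma_target: float | tuple[float, float, float] = DEFAULT_SIGMA_TARGET,
    *,
    window_fraction: float = 0.25,
) -> np.ndarray:
    """Remove spatial illumination drop-off by local z-scoring.

    Per channel the local illumination field (Gaussian mean and std over
    a window of ~``window_fraction`` of the image diagonal) is removed
    and the result re-targeted to (mu_target, sigma_target).  Because the
    z-score is invariant to any global brightness rescaling and every
    channel lands on the same target mean, the output follows the
    gray-world assumption.
    """
    img = _as_rgb_u8(image).astype(np.float64)
    h, w = img.shape[:2]
    # Gaussian sigma such that the +-4 sigma support spans the window
    sigma = window_fraction * np.hypot(h, w) / 8.0
    out = np.empty_like(img)
    for c in range(3):
        ch = img[..., c]
        g_sd = float(ch.std())
        mt = _scalar_for(mu_target, c, DEFAULT_MU_TARGET)
        st = _scalar_for(sigma_target, c, DEFAULT_SIGMA_TARGET)
        if g_sd < 1e-9:
            warnings.warn(f"zero-variance channel {c}; passing through at target mean")
            out[..., c] = mt
            continue
        # two mean-removal passes: the second removes the smooth boundary
        # bias the truncated window leaves in the corners
        mu_loc = ndimage.gaussian_filter(ch, sigma, mode="reflect")
        resid = ch - mu_loc
        mu_loc += ndimage.gaussian_filter(resid, sigma, mode="reflect")
        resid = ch - mu_loc
        sd_loc = np.sqrt(np.clip(ndimage.gaussian_filter(resid**2, sigma, mode="reflect"), 1e-12, None))
        z = resid / np.maximum(sd_loc, 1e-6)
        out[..., c] = z * st + mt
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def _scalar_for(target, channel: int, default: float) -> float:
    if target is None:
        return default
    if np.isscalar(target):
        return float(target)
    return float(target[channel])


def enhance_contrast(
    image: np.ndarray,
    *,
    clip_limit: float = DEFAULT_CLIP_LIMIT,
    tiles: int = DEFAULT_TILES,
) -> np.ndarray:
    """Contrast-limited adaptive equalization on lightness, chroma kept.

    Applied to the value channel of HSV over a ``tiles x tiles`` grid;
    histogram entropy of the grayscale intensity never decreases on
    natural images.
    """
    img = _as_rgb_u8(image)
    f = img.astype(np.float64) / 255.0
    v = f.max(axis=2)
    if float(v.max() - v.min()) < 1e-9:
        return img.copy()
    kernel = (max(img.shape[0] // tiles, 1), max(img.shape[1] // tiles, 1))
    v_eq = exposure.equalize_adapthist(v, kernel_size=kernel, clip_limit=clip_limit)
    ratio = np.where(v > 1e-9, v_eq / np.clip(v, 1e-9, None), 0.0)
    out = f * ratio[..., None]
    return np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)


def histogram_entropy(image: np.ndarray, bins: int = 256) -> float:
    """Shannon entropy (bits) of the grayscale intensity histogram."""
    img = np.asarray(image)
    if img.ndim == 3:
        img = img[..., :3].astype(float).mean(axis=2)
    hist, _ = np.histogram(img.ravel(), bins=bins, range=(0, 255))
    p = hist.astype(float) / max(hist.sum(), 1)
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def select_reference(scales: pd.DataFrame | dict[str, float]) -> str:
    """Image with the maximum scale (closest to the seafloor); ties break
    to the earliest image id."""
    if isinstance(scales, pd.DataFrame):
        pairs = list(zip(scales["image_id"], scales["scale_px_per_cm"]))
    else:
        pairs = list(scales.items())
    pairs = [(i, s) for i, s in pairs if np.isfinite(s)]
    if not pairs:
        raise ValueError("no scaled images")
    best = max(sorted(pairs, key=lambda p: p[0]), key=lambda p: p[1])
    return best[0]


def match_histogram(image: np.ndarray, profile: ReferenceProfile) -> np.ndarray:
    """Per-channel quantile mapping onto the reference ECDF.

    Exact histogram specification: pixels are ranked (stable, so ties
    break by position) and each rank is sent through the reference
    inverse ECDF, which reproduces the reference distribution to within
    one intensity level even when the source histogram is coarse.
    """
    img = _as_rgb_u8(image)
    out = np.empty_like(img)
    n = img.shape[0] * img.shape[1]
    q = (np.arange(n) + 0.5) / n
    for c in range(3):
        ref = profile.ecdf[c]
        flat = img[..., c].ravel()
        order = np.argsort(flat, kind="stable")
        target = np.clip(np.searchsorted(ref, q, side="left"), 0, 255).astype(np.uint8)
        res = np.empty(n, dtype=np.uint8)
        res[order] = target
        out[..., c] = res.reshape(img.shape[:2])
    return out


def median_scale(scales: np.ndarray | list[float]) -> float:
    """Survey median scale: mean of the two central order statistics for
    even N, the central value for odd N."""
    arr = np.asarray(scales, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("no finite scales")
    return float(np.median(arr))


def standardize_footprint(image: np.ndarray, scale: float, spec: FootprintSpec) -> np.ndarray:
    """Resample to the median scale (cubic spline) and center crop.

    The linear resize factor is ``spec.median_scale / scale`` so that
    every image lands at the common scale before cropping.
    """
    img = _as_rgb_u8(image)
    factor = spec.median_scale / scale
    h, w = img.shape[:2]
    new_h, new_w = int(round(h * factor)), int(round(w * factor))
    if new_w < spec.crop_width or new_h < spec.crop_height:
        raise ValueError("footprint exceeds frame")
    if abs(factor - 1.0) < 1e-9:
        res = img.astype(np.float64)
    else:
        res = np.stack(
            [ndimage.zoom(img[..., c].astype(np.float64), (new_h / h, new_w / w), order=3) for c in range(3)],
            axis=2,
        )
    y0 = (res.shape[0] - spec.crop_height) // 2
    x0 = (res.shape[1] - spec.crop_width) // 2
    crop = res[y0 : y0 + spec.crop_height, x0 : x0 + spec.crop_width]
    return np.clip(np.rint(crop), 0, 255).astype(np.uint8)


def normalize_image(
    image: np.ndarray,
    profile: ReferenceProfile,
    *,
    clip_limit: float = DEFAULT_CLIP_LIMIT,
    tiles: int = DEFAULT_TILES,
) -> np.ndarray:
    """Full color chain: illumination -> contrast -> histogram matching."""
    il = correct_illumination(image)
    he = enhance_contrast(il, clip_limit=clip_limit, tiles=tiles)
    return match_histogram(he, profile)
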