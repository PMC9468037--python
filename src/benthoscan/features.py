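"""Texture/entropy feature extraction and 2-D embedding.

Each image yields a 6-dimensional vector from the connected components
of its dark-pixel mask (median convex-hull area, 75th-percentile area,
total area, density, count) plus the summed local entropy.  Vectors are
stacked, standardized column-wise, and projected to 2-D with linear
kernel PCA (equivalently, classical PCA scores).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import measure
from skimage.color import rgb2gray
from skimage.filters import threshold_otsu
from skimage.filters.rank import entropy as rank_entropy
from skimage.morphology import disk
from skimage.util import img_as_ubyte

FEATURE_COLUMNS = [
    "median_hull_area",
    "upper_quartile_area",
    "total_area",
    "density",
    "component_count",
    "total_entropy",
]

MIN_COMPONENT_AREA = 20  # px; smaller specks treated as sensor noise
DEFAULT_ENTROPY_RADIUS = 5  # px, tuned to the quarter-scale frames


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Luminance in [0, 1] floats."""
    img = np.asarray(image)
    if img.ndim == 3:
        return rgb2gray(img[..., :3])
    return img.astype(np.float64) / 255.0


def binarize_nodules(gray: np.ndarray, min_area: int = MIN_COMPONENT_AREA) -> np.ndarray:
    """Dark-pixel mask: Otsu threshold keeping the below-threshold set,
    with components below ``min_area`` removed (8-connectivity)."""
    gray = np.asarray(gray, dtype=np.float64)
    if float(gray.max() - gray.min()) < 1e-12:
        return np.zeros(gray.shape, dtype=bool)
    t = threshold_otsu(gray)
    mask = gray < t
    if min_area > 0:
        labels = measure.label(mask, connectivity=2)
        areas = np.bincount(labels.ravel())
        small = np.flatnonzero(areas < min_area)
        mask &= ~np.isin(labels, small[small > 0])
    return mask


def component_properties(mask: np.ndarray) -> tuple[float, float, float, float, float]:
    """(median hull area, q75 area, total area, density, count); zeros for
    an empty mask."""
    mask = np.asarray(mask, dtype=bool)
    labels = measure.label(mask, connectivity=2)
    n = int(labels.max())
    if n == 0:
        return (0.0, 0.0, 0.0, 0.0, 0.0)
    props = measure.regionprops(labels)
    areas = np.array([p.area for p in props], dtype=float)
    hulls = np.array([p.area_convex for p in props], dtype=float)
    total = float(areas.sum())
    density = total / mask.size
    return (
        float(np.median(hulls)),
        float(np.percentile(areas, 75)),
        total,
        float(density),
        float(n),
    )


def extract_entropy(gray: np.ndarray, radius: int = DEFAULT_ENTROPY_RADIUS) -> float:
    """Sum of the per-pixel Shannon entropy (bits, disc neighborhood)."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # img_as_ubyte precision warnings
        u8 = img_as_ubyte(np.clip(np.asarray(gray, dtype=np.float64), 0, 1))
    ent = rank_entropy(u8, disk(radius))
    return float(ent.sum())


def extract_features(image: np.ndarray, entropy_radius: int = DEFAULT_ENTROPY_RADIUS) -> np.ndarray:
    """6-D feature vector for one (normalized) image."""
    gray = to_grayscale(image)
    mask = binarize_nodules(gray)
    tex = component_properties(mask)
    ent = extract_entropy(gray, entropy_radius)
    return np.array([*tex, ent], dtype=float)


@dataclass
class FeatureMatrix:
    """Standardized N x 6 data matrix with its scaling parameters."""

    matrix: np.ndarray  # standardized
    image_ids: list[str]
    column_means: np.ndarray
    column_stds: np.ndarray

    @property
    def raw(self) -> np.ndarray:
        return self.matrix * self.column_stds + self.column_means


def build_matrix(vectors: np.ndarray, image_ids: list[str] | None = None) -> FeatureMatrix:
    """Stack feature vectors and standardize column-wise (mean 0, var 1).

    Constant columns get std 1 (with a warning) rather than dividing by
    zero.
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected an N x d matrix")
    if image_ids is None:
        image_ids = [f"img_{i:05d}" for i in range(X.shape[0])]
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    const = sd < 1e-12
    if const.any():
        warnings.warn(f"constant feature column(s) {np.flatnonzero(const).tolist()}; std set to 1")
        sd = np.where(const, 1.0, sd)
    return FeatureMatrix(matrix=(X - mu) / sd, image_ids=list(image_ids), column_means=mu, column_stds=sd)


@dataclass
class Embedding2D:
    coords: np.ndarray  # N x 2
    explained_variance_ratio: np.ndarray  # (2,)


def project_2d(fm: FeatureMatrix) -> Embedding2D:
    """Top-2 principal component scores of the standardized matrix.

    Linear-kernel PCA coincides with classical PCA; the sign of each axis
    is fixed by making the largest-|loading| coordinate positive.
    """
    X = fm.matrix
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    for k in range(min(2, Vt.shape[0])):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] = -Vt[k]
            U[:, k] = -U[:, k]
    scores = U[:, :2] * S[:2]
    var = S**2
    ratio = var[:2] / var.sum() if var.sum() > 0 else np.zeros(2)
    return Embedding2D(coords=scores, explained_variance_ratio=ratio)


def features_from_dir(
    image_dir: str | Path,
    entropy_radius: int = DEFAULT_ENTROPY_RADIUS,
) -> pd.DataFrame:
    """Extract features for every image in a directory (sorted by name)."""
    from PIL import Image

    image_dir = Path(image_dir)
    paths = sorted(p for p in image_dir.iterdir() if p.suffix.lower() in {".png", ".jpg", ".jpeg", ".tif", ".tiff"})
    rows = []
    for p in paths:
        img = np.asarray(Image.open(p).convert("RGB"))
        vec = extract_features(img, entropy_radius)
        rows.append({"image_id": p.stem, **dict(zip(FEATURE_COLUMNS, vec))})
    return pd.DataFrame(rows)


def feature_table(df: pd.DataFrame) -> tuple[FeatureMatrix, Embedding2D, pd.DataFrame]:
    """Build matrix + embedding from a features dataframe; returns the
    dataframe augmented with ``embed_1``/``embed_2`` columns."""
    fm = build_matrix(df[FEATURE_COLUMNS].to_numpy(), df["image_id"].tolist())
    emb = project_2d(fm)
    out = df.copy()
    out["embed_1"] = emb.coords[:, 0]
    out["embed_2"] = emb.coords[:, 1]
    return fm, emb, out
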