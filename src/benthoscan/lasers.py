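"""Laser-point detection and image scale estimation.

Three red laser dots with a known real-world spacing are projected onto
the seabed.  A signal image R - c*(B + G) highlights them; local maxima
inside a mask built from one hand-annotated template image are kept, and
the mean pairwise dot distance divided by the known spacing gives the
image scale in px/cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from skimage.draw import polygon
from skimage.feature import peak_local_max

DEFAULT_COEFF = 0.2
DEFAULT_BUFFER_PX = 250
DEFAULT_SPACING_CM = 40.0
#: fraction of the template pairwise distance enforced as minimum peak
#: separation (the spacing shrinks with altitude, so the full template
#: distance would reject valid detections high above the seabed).
DEFAULT_MIN_SEP_FRACTION = 0.4
#: peaks must exceed this multiple of the (positive) global signal median.
DEFAULT_FLOOR_FACTOR = 5.0


@dataclass(frozen=True)
class LaserTemplate:
    """One hand-annotated image defining the detection mask.

    Points use (x=col, y=row), 0-based.
    """

    annotated_points: np.ndarray  # (3, 2) float, (x, y)
    buffer_px: int = DEFAULT_BUFFER_PX
    known_spacing_cm: float = DEFAULT_SPACING_CM

    def __post_init__(self) -> None:
        pts = np.asarray(self.annotated_points, dtype=float)
        if pts.shape != (3, 2):
            raise ValueError("template needs exactly 3 (x, y) points")
        if len({tuple(p) for p in pts}) != 3:
            raise ValueError("template points must be distinct")
        if self.buffer_px < 0:
            raise ValueError("buffer_px must be >= 0")
        object.__setattr__(self, "annotated_points", pts)

    @property
    def expected_pairwise_px(self) -> float:
        """d_lp: mean pairwise distance of the annotated points."""
        d = [
            float(np.hypot(*(a - b)))
            for a, b in combinations(self.annotated_points, 2)
        ]
        return float(np.mean(d))

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "points": [[float(x), float(y)] for x, y in self.annotated_points],
            "buffer_px": int(self.buffer_px),
            "known_spacing_cm": float(self.known_spacing_cm),
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LaserTemplate":
        data = yaml.safe_load(Path(path).read_text())
        return cls(
            annotated_points=np.asarray(data["points"], dtype=float),
            buffer_px=int(data.get("buffer_px", DEFAULT_BUFFER_PX)),
            known_spacing_cm=float(data.get("known_spacing_cm", DEFAULT_SPACING_CM)),
        )


@dataclass
class LaserDetection:
    """Detected dots for one image."""

    points: np.ndarray  # (n_found, 2) as (x, y)
    pairwise_distances: list[float]
    scale_px_per_cm: float | None

    @property
    def n_found(self) -> int:
        return len(self.points)

    @property
    def flag(self) -> str:
        return "ok" if self.scale_px_per_cm is not None else "unscaled"


def laser_signal(image: np.ndarray, coeff: float = DEFAULT_COEFF) -> np.ndarray:
    """Signed laser signal R - coeff*(B + G) as float64."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] < 3:
        raise ValueError("three channels required")
    if not 0.0 <= coeff <= 1.0:
        raise ValueError("coeff must be in [0, 1]")
    img = image[..., :3].astype(np.float64)
    return img[..., 0] - coeff * (img[..., 1] + img[..., 2])


def build_mask(template: LaserTemplate, image_shape: tuple[int, int]) -> np.ndarray:
    """Filled annotation triangle dilated by buffer_px, clipped to frame."""
    h, w = image_shape[:2]
    pts = template.annotated_points
    # collinearity via the cross product of two edge vectors
    area2 = abs(
        (pts[1, 0] - pts[0, 0]) * (pts[2, 1] - pts[0, 1])
        - (pts[2, 0] - pts[0, 0]) * (pts[1, 1] - pts[0, 1])
    )
    if area2 < 1e-9:
        raise ValueError("degenerate triangle")
    if pts[:, 0].min() < 0 or pts[:, 1].min() < 0 or pts[:, 0].max() > w - 1 or pts[:, 1].max() > h - 1:
        raise ValueError("annotated points outside image frame")
    rr, cc = polygon(pts[:, 1], pts[:, 0], shape=(h, w))
    tri = np.zeros((h, w), dtype=bool)
    tri[rr, cc] = True
    if template.buffer_px == 0:
        return tri
    # Euclidean dilation via the distance transform of the complement
    dist = ndimage.distance_transform_edt(~tri)
    return dist <= template.buffer_px


def detect_laser_points(
    image: np.ndarray,
    template: LaserTemplate,
    coeff: float = DEFAULT_COEFF,
    *,
    mask: np.ndarray | None = None,
    min_sep_fraction: float = DEFAULT_MIN_SEP_FRACTION,
    floor_factor: float = DEFAULT_FLOOR_FACTOR,
) -> LaserDetection:
    """Find up to three laser dots; runs on the *original* (unenhanced) image.

    Peaks of the laser signal must exceed a noise floor, be mutually at
    least ``min_sep_fraction * d_lp`` apart, and fall inside the buffered
    template mask.  The top three by signal value are kept.  Zero points
    is a valid result.
    """
    sig = laser_signal(image, coeff)
    if mask is None:
        mask = build_mask(template, sig.shape)
    floor = floor_factor * max(float(np.median(sig)), 1e-6)
    min_dist = max(int(round(min_sep_fraction * template.expected_pairwise_px)), 1)
    peaks = peak_local_max(
        sig,
        min_distance=min_dist,
        threshold_abs=floor,
        exclude_border=False,
        labels=mask.astype(np.uint8),
        num_peaks=3,
    )
    # rank by signal value, descending
    if len(peaks):
        order = np.argsort(-sig[peaks[:, 0], peaks[:, 1]], kind="stable")
        peaks = peaks[order]
    pts = peaks[:, ::-1].astype(float)  # (row, col) -> (x, y)
    dists = [float(np.hypot(*(a - b))) for a, b in combinations(pts, 2)]
    scale = compute_scale_from_distances(dists, template.known_spacing_cm)
    return LaserDetection(points=pts, pairwise_distances=dists, scale_px_per_cm=scale)


def compute_scale_from_distances(distances: list[float], known_spacing_cm: float) -> float | None:
    if not distances:
        return None
    return float(np.mean(distances)) / known_spacing_cm


def compute_scale(detection: LaserDetection, known_spacing_cm: float = DEFAULT_SPACING_CM) -> float:
    """Image scale s = mean(pairwise distances) / known spacing, in px/cm."""
    if detection.n_found < 2:
        raise ValueError("unscaled: fewer than two laser points")
    return float(np.mean(detection.pairwise_distances)) / known_spacing_cm


def detect_survey(
    image_dir: str | Path,
    template: LaserTemplate,
    coeff: float = DEFAULT_COEFF,
    *,
    min_sep_fraction: float = DEFAULT_MIN_SEP_FRACTION,
    floor_factor: float = DEFAULT_FLOOR_FACTOR,
) -> pd.DataFrame:
    """Run detection over a directory of images; the mask is built once.

    Returns a frame with columns image_id, n_found, scale_px_per_cm, flag.
    """
    from PIL import Image

    image_dir = Path(image_dir)
    paths = sorted(p for p in image_dir.iterdir() if p.suffix.lower() in {".png", ".jpg", ".jpeg", ".tif", ".tiff"})
    mask = None
    rows = []
    for p in paths:
        img = np.asarray(Image.open(p).convert("RGB"))
        if mask is None or mask.shape != img.shape[:2]:
            mask = build_mask(template, img.shape[:2])
        det = detect_laser_points(
            img, template, coeff, mask=mask,
            min_sep_fraction=min_sep_fraction, floor_factor=floor_factor,
        )
        rows.append(
            {
                "image_id": p.stem,
                "n_found": det.n_found,
                "scale_px_per_cm": det.scale_px_per_cm if det.scale_px_per_cm is not None else np.nan,
                "flag": det.flag,
            }
        )
    return pd.DataFrame(rows)
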