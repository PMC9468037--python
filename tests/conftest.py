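"""Shared fixtures: small synthetic scenes sized so tests stay fast.

Frames are 280x420 to 560x840 with focal_scale chosen so the 40 cm laser
triangle fits at the altitudes under test.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from benthoscan import synthetic as syn
from benthoscan import lasers
from benthoscan import normalization as norm


@pytest.fixture(scope="session")
def base_params() -> syn.SceneParams:
    return syn.SceneParams(
        image_width=560, image_height=840, focal_scale=10.8, altitude_m=2.0, rng_seed=11
    )


@pytest.fixture(scope="session")
def rendered(base_params):
    """One rendered image + truth at 2 m altitude."""
    return syn.render_image(base_params)


@pytest.fixture(scope="session")
def template(rendered) -> lasers.LaserTemplate:
    """Template annotated from the 2 m ground truth (the one-image
    hand-annotation step)."""
    _, truth = rendered
    return lasers.LaserTemplate(truth.true_laser_points, buffer_px=150)


@pytest.fixture(scope="session")
def vignetted_pair():
    """Same scene with and without vignette, for illumination tests."""
    p = syn.SceneParams(
        image_width=560, image_height=840, vignette_strength=0.5, rng_seed=3
    )
    flat = dataclasses.replace(p, vignette_strength=0.0)
    return syn.render_image(p)[0], syn.render_image(flat)[0]


@pytest.fixture(scope="session")
def reference_profile(rendered) -> norm.ReferenceProfile:
    img, _ = rendered
    enhanced = norm.enhance_contrast(norm.correct_illumination(img))
    return norm.ReferenceProfile.from_image(enhanced, image_id="ref", scale=5.4)


@pytest.fixture(scope="session")
def small_survey(tmp_path_factory):
    """16-image 4-class survey on disk: images/, nav.csv, truth.csv."""
    out = tmp_path_factory.mktemp("survey")
    seq = [syn.SEAFLOOR_CLASSES[i % 4] for i in range(16)]
    paths = syn.generate_survey(
        out,
        seq,
        interval_s=10.0,
        altitude_range=(2.0, 2.3),
        seed=7,
        base_params=syn.SceneParams(image_width=280, image_height=420, focal_scale=5.4),
    )
    return paths


def corner_center_ratio(image: np.ndarray, margin: int = 40) -> float:
    g = image.astype(float).mean(axis=2)
    h, w = g.shape
    k = margin
    corners = np.mean(
        [g[:k, :k].mean(), g[:k, -k:].mean(), g[-k:, :k].mean(), g[-k:, -k:].mean()]
    )
    center = g[h // 2 - k : h // 2 + k, w // 2 - k : w // 2 + k].mean()
    return float(corners / center)
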