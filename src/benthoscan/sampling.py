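"""Training-set generation strategies for unsupervised classification.

Four ways to draw n training images from a survey: uniform random,
spatially uniform along the tow track, stratified cluster-based (k-means
over-clustering of an entropy feature, then uniform per-stratum draws),
and probabilistic weighted resampling (inverse-density weights under a
1-D Gaussian mixture fit to the entropy values).  A small harness times
each strategy and scores the resulting clusters.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

DEFAULT_N_SAMPLES = 5000
DEFAULT_N_STRATA = 20
DEFAULT_GMM_COMPONENTS = 20
PDF_FLOOR_FRACTION = 1e-6  # floor on the pdf as a fraction of its max


@dataclass
class StrategyReport:
    strategy: str
    n_samples: int
    time_to_fit_s: float
    silhouette: float
    chosen_k: int

    def to_dict(self) -> dict:
        return asdict(self)


def sample_random(ids: np.ndarray, n: int, seed: int = 0) -> np.ndarray:
    """Uniform sampling without replacement."""
    ids = np.asarray(ids)
    _check_n(n, len(ids))
    rng = np.random.default_rng(seed)
    return ids[np.sort(rng.choice(len(ids), size=n, replace=False))]


def sample_spatial(
    ids: np.ndarray,
    lon: np.ndarray,
    lat: np.ndarray,
    n: int,
    seed: int = 0,
) -> np.ndarray:
    """One draw per along-track bin.

    Images are ordered by cumulative along-track distance and split into
    n equal-count bins; one image is drawn per bin.
    """
    ids = np.asarray(ids)
    _check_n(n, len(ids))
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if len(lon) != len(ids) or len(lat) != len(ids):
        raise ValueError("coordinates required for every id")
    rng = np.random.default_rng(seed)
    # local-planar along-track distance; adequate at survey extents
    mlat = np.deg2rad(np.nanmean(lat))
    dx = np.diff(lon) * np.cos(mlat)
    dy = np.diff(lat)
    cum = np.concatenate([[0.0], np.cumsum(np.hypot(dx, dy))])
    order = np.argsort(cum, kind="stable")
    picks = []
    for chunk in np.array_split(order, n):
        if len(chunk):
            picks.append(chunk[rng.integers(len(chunk))])
    if len(picks) < n:
        warnings.warn(f"only {len(picks)} non-empty track bins for n={n}")
    return ids[np.sort(np.asarray(picks))]


def sample_stratified(
    ids: np.ndarray,
    entropy: np.ndarray,
    n: int,
    n_strata: int = DEFAULT_N_STRATA,
    seed: int = 0,
) -> np.ndarray:
    """Over-cluster the entropy feature with k-means, then sample each
    stratum uniformly; small strata are exhausted and their deficit
    redistributed proportionally."""
    ids = np.asarray(ids)
    _check_n(n, len(ids))
    x = np.asarray(entropy, dtype=float).reshape(-1, 1)
    k = min(n_strata, len(np.unique(x)))
    rng = np.random.default_rng(seed)
    if k <= 1:
        return sample_random(ids, n, seed)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    strata = km.fit_predict(x)
    groups = [np.flatnonzero(strata == s) for s in range(k)]
    quota = _allocate(np.array([len(g) for g in groups]), n)
    picks: list[int] = []
    for g, q in zip(groups, quota):
        take = rng.choice(len(g), size=q, replace=False)
        picks.extend(g[take])
    return ids[np.sort(np.asarray(picks))]


def sample_probabilistic(
    ids: np.ndarray,
    entropy: np.ndarray,
    n: int,
    n_components: int = DEFAULT_GMM_COMPONENTS,
    seed: int = 0,
) -> np.ndarray:
    """Inverse-density weighted sampling under a 1-D Gaussian mixture.

    Weights are 1/max(pdf, eps) with eps a small fraction of the pdf
    maximum, oversampling under-represented entropy regions.
    """
    ids = np.asarray(ids)
    _check_n(n, len(ids))
    x = np.asarray(entropy, dtype=float).reshape(-1, 1)
    k = min(n_components, len(np.unique(x)))
    rng = np.random.default_rng(seed)
    if k <= 1:
        return sample_random(ids, n, seed)
    gmm = GaussianMixture(n_components=k, random_state=seed)
    gmm.fit(x)
    pdf = np.exp(gmm.score_samples(x))
    floor = PDF_FLOOR_FRACTION * pdf.max()
    w = 1.0 / np.maximum(pdf, floor)
    p = w / w.sum()
    return ids[np.sort(rng.choice(len(ids), size=n, replace=False, p=p))]


def _check_n(n: int, population: int) -> None:
    if n < 0:
        raise ValueError("n must be >= 0")
    if n > population:
        raise ValueError("n exceeds population size")


def _allocate(sizes: np.ndarray, n: int) -> np.ndarray:
    """Uniform per-stratum quotas; deficits from small strata are
    redistributed proportionally to remaining capacity."""
    k = len(sizes)
    quota = np.minimum(sizes, np.full(k, n // k))
    # spread the remainder of n/k one by one over strata with capacity
    rem = n - quota.sum()
    while rem > 0:
        cap = sizes - quota
        open_idx = np.flatnonzero(cap > 0)
        if not len(open_idx):
            break
        # proportional to remaining capacity, at least 1 each pass
        share = np.maximum((cap[open_idx] / cap[open_idx].sum() * rem).astype(int), 0)
        if share.sum() == 0:
            share = np.zeros(len(open_idx), dtype=int)
            share[: min(rem, len(open_idx))] = 1
        share = np.minimum(share, cap[open_idx])
        quota[open_idx] += share
        rem = n - quota.sum()
    return quota


STRATEGIES = ("random", "spatial", "stratified", "probabilistic")


def draw_sample(
    strategy: str,
    ids: np.ndarray,
    n: int,
    *,
    entropy: np.ndarray | None = None,
    lon: np.ndarray | None = None,
    lat: np.ndarray | None = None,
    n_strata: int = DEFAULT_N_STRATA,
    n_components: int = DEFAULT_GMM_COMPONENTS,
    seed: int = 0,
) -> np.ndarray:
    if strategy == "random":
        return sample_random(ids, n, seed)
    if strategy == "spatial":
        if lon is None or lat is None:
            raise ValueError("spatial sampling needs lon/lat")
        return sample_spatial(ids, lon, lat, n, seed)
    if strategy == "stratified":
        if entropy is None:
            raise ValueError("stratified sampling needs entropy values")
        return sample_stratified(ids, entropy, n, n_strata, seed)
    if strategy == "probabilistic":
        if entropy is None:
            raise ValueError("probabilistic sampling needs entropy values")
        return sample_probabilistic(ids, entropy, n, n_components, seed)
    raise ValueError(f"unknown strategy {strategy!r}")


def evaluate_strategy(
    strategy: str,
    ids: np.ndarray,
    features: np.ndarray,
    n: int,
    *,
    k_range: tuple[int, int] = (2, 20),
    seed: int = 0,
    **kwargs,
) -> StrategyReport:
    """Time the full sample-then-fit path and score the clusters.

    Wall clock covers sampling through k-means convergence at the
    silhouette-selected k.
    """
    from .classify import select_k, fit_kmeans

    ids = np.asarray(ids)
    features = np.asarray(features, dtype=float)
    idx_of = {i: j for j, i in enumerate(ids)}
    t0 = time.perf_counter()
    sample = draw_sample(strategy, ids, n, seed=seed, **kwargs)
    sub = features[[idx_of[i] for i in sample]]
    k, sil = select_k(sub, k_min=k_range[0], k_max=k_range[1], seed=seed, return_score=True)
    fit_kmeans(sub, k, seed=seed)
    elapsed = time.perf_counter() - t0
    return StrategyReport(
        strategy=strategy,
        n_samples=len(sample),
        time_to_fit_s=elapsed,
        silhouette=float(sil),
        chosen_k=int(k),
    )
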