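"""Semi-automated labeled-set generation.

Seed images (analyst-picked, or proposed by farthest-point coverage of
the 2-D embedding) are expanded by nearest-neighbor sampling in the
standardized 6-D feature space; each non-seed image is claimed at most
once, contested images going to the closer seed.  Includes a stratified
train/val/test splitter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureMatrix

DEFAULT_N_SEEDS = 50
DEFAULT_K_NN = 100
DEFAULT_FRACTIONS = (0.80, 0.07, 0.13)


@dataclass
class LabeledSet:
    """Expanded labels: one row per image with its source."""

    table: pd.DataFrame  # image_id, label, source in {seed, expanded}
    n_seeds: int
    k_nn: int

    @property
    def n_expanded(self) -> int:
        return int((self.table["source"] == "expanded").sum())

    @property
    def n_total(self) -> int:
        return len(self.table)


def propose_seeds(coords: np.ndarray, n_seeds: int, seed: int = 0) -> np.ndarray:
    """Greedy farthest-point selection in the 2-D embedding.

    Approximates an analyst picking examples uniformly spread over the
    projected feature space.  Returns indices into ``coords``.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n_seeds > n:
        raise ValueError("n_seeds exceeds population")
    if n_seeds == n:
        return np.arange(n)
    rng = np.random.default_rng(seed)
    start = int(rng.integers(n))
    chosen = [start]
    dmin = np.linalg.norm(coords - coords[start], axis=1)
    for _ in range(n_seeds - 1):
        nxt = int(np.argmax(dmin))
        chosen.append(nxt)
        d = np.linalg.norm(coords - coords[nxt], axis=1)
        np.minimum(dmin, d, out=dmin)
    return np.array(chosen)


def expand_labels(
    seeds: pd.DataFrame,
    fm: FeatureMatrix,
    k_nn: int = DEFAULT_K_NN,
) -> LabeledSet:
    """Disjoint nearest-neighbor expansion of seed labels.

    Each seed claims its ``k_nn`` nearest unassigned non-seed images in
    the standardized feature space (Euclidean).  Contested images go to
    the closer seed; exact ties to the lower image id.  With a large
    enough population the result has ``n_seeds * (k_nn + 1)`` rows.
    """
    if k_nn < 0:
        raise ValueError("k_nn must be >= 0")
    seed_ids = seeds["image_id"].tolist()
    if len(set(seed_ids)) != len(seed_ids):
        raise ValueError("duplicate seed image_id")
    id_to_idx = {iid: i for i, iid in enumerate(fm.image_ids)}
    seed_idx = np.array([id_to_idx[i] for i in seed_ids])
    labels = seeds["label"].tolist()

    n = fm.matrix.shape[0]
    cand = np.setdiff1d(np.arange(n), seed_idx)
    rows = [
        {"image_id": iid, "label": lab, "source": "seed"}
        for iid, lab in zip(seed_ids, labels)
    ]
    if k_nn > 0 and len(cand):
        want = len(seed_idx) * k_nn
        if len(cand) < want:
            warnings.warn(
                f"population supports only {len(cand)} of {want} expansions; truncating"
            )
        # all (seed, candidate) distances, assigned greedily by increasing
        # distance so contested images end up with the closer seed
        D = np.linalg.norm(
            fm.matrix[seed_idx][:, None, :] - fm.matrix[cand][None, :, :], axis=2
        )
        cand_ids = np.array(fm.image_ids, dtype=object)[cand]
        s_flat, c_flat = np.unravel_index(np.arange(D.size), D.shape)
        order = np.lexsort((c_flat, D.ravel()))  # distance, then lower image idx
        quota = np.full(len(seed_idx), k_nn, dtype=int)
        taken = np.zeros(len(cand), dtype=bool)
        assigned = 0
        for f in order:
            s, c = s_flat[f], c_flat[f]
            if taken[c] or quota[s] == 0:
                continue
            taken[c] = True
            quota[s] -= 1
            rows.append({"image_id": cand_ids[c], "label": labels[s], "source": "expanded"})
            assigned += 1
            if assigned == min(want, len(cand)):
                break
    table = pd.DataFrame(rows, columns=["image_id", "label", "source"])
    return LabeledSet(table=table, n_seeds=len(seed_idx), k_nn=k_nn)


def split_labeled(
    labeled: LabeledSet | pd.DataFrame,
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Stratified-by-class random train/val/test split.

    Split sizes are exact per class up to rounding by largest remainder;
    the partitions are disjoint and exhaustive.
    """
    table = labeled.table if isinstance(labeled, LabeledSet) else labeled
    fr = np.asarray(fractions, dtype=float)
    if fr.min() < 0 or not np.isclose(fr.sum(), 1.0, atol=1e-6):
        raise ValueError("fractions must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    # global split sizes are exact (largest remainder); per-class cells
    # are the floor of their ideal plus at most one extra, with extras
    # routed to whichever split still lags its global target
    targets = _largest_remainder(len(table), fr)
    groups = [grp for _, grp in table.groupby("label", sort=True)]
    floors = [np.floor(fr * len(g)).astype(int) for g in groups]
    deficits = targets - np.sum(floors, axis=0)
    cell_sizes = []
    for grp, base in zip(groups, floors):
        sizes = base.copy()
        extras = len(grp) - sizes.sum()
        frac = fr * len(grp) - base
        for j in np.argsort(-(deficits + frac * 1e-6), kind="stable")[:extras]:
            sizes[j] += 1
            deficits[j] -= 1
        cell_sizes.append(sizes)
    parts: list[list[pd.DataFrame]] = [[], [], []]
    for grp, sizes in zip(groups, cell_sizes):
        idx = rng.permutation(len(grp))
        offs = np.concatenate([[0], np.cumsum(sizes)])
        for j in range(3):
            parts[j].append(grp.iloc[idx[offs[j] : offs[j + 1]]])
    out = []
    for j in range(3):
        df = pd.concat(parts[j]) if parts[j] else table.iloc[:0]
        out.append(df.sort_values("image_id").reset_index(drop=True))
    return tuple(out)


def _largest_remainder(total: int, fractions: np.ndarray) -> np.ndarray:
    ideal = fractions * total
    base = np.floor(ideal).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(ideal - base), kind="stable")
    base[order[:rem]] += 1
    return base
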