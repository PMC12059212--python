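"""Permutation tests of settlement against a colony-random null.

Two statistics are compared with the distribution obtained by re-drawing
every individual's settlement box uniformly at random from the colony
(with replacement across individuals, and without excluding the true box):

* the mean anchor-to-settlement distance, where each individual's anchor is
  either its prospecting centroid or its natal box ("closer than random",
  lower tail), and
* the number of individuals settling inside their own prospected circle
  ("more than random", upper tail).

p-values use the add-one rule p = (1 + #extreme) / (B + 1), so the smallest
attainable p is 1/(B+1) and the test is exact-valid for any B.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PermResult", "perm_mean_distance", "perm_in_area", "paired_t"]


@dataclass
class PermResult:
    observed_stat: float
    permuted_stats: np.ndarray
    p_value: float
    B: int
    seed: int

    @property
    def permuted_mean(self) -> float:
        return float(self.permuted_stats.mean())


def _box_coords(colony) -> np.ndarray:
    import pandas as pd

    if isinstance(colony, pd.DataFrame):
        return colony[["x", "y"]].to_numpy(dtype=float)
    return np.asarray(colony, dtype=float)


def perm_mean_distance(anchors: np.ndarray, settled: np.ndarray, colony,
                       B: int = 10_000, seed: int = 0) -> PermResult:
    """Is the mean anchor-to-settlement distance smaller than random?

    Parameters
    ----------
    anchors : (n, 2) array
        One anchor point per individual (prospecting centroid or natal box).
    settled : (n, 2) array
        The settlement box coordinates actually chosen.
    colony : DataFrame with x, y columns or (m, 2) array
        All candidate boxes of the colony from which the null draws.

    The observed statistic is the mean Euclidean distance; each of the B
    permutations replaces every settlement with a uniformly drawn colony box
    and recomputes the mean.  One-sided lower-tail p.
    """
    anchors = np.asarray(anchors, dtype=float)
    settled = np.asarray(settled, dtype=float)
    if len(anchors) == 0:
        raise ValueError("no individuals supplied")
    if anchors.shape != settled.shape:
        raise ValueError("anchors and settled must align")
    boxes = _box_coords(colony)
    rng = np.random.default_rng(seed)

    observed = float(np.hypot(*(anchors - settled).T).mean())
    n = len(anchors)
    idx = rng.integers(0, len(boxes), size=(B, n))
    perms = boxes[idx]  # (B, n, 2)
    permuted = np.hypot(perms[..., 0] - anchors[:, 0],
                        perms[..., 1] - anchors[:, 1]).mean(axis=1)
    p = (1.0 + np.sum(permuted <= observed)) / (B + 1.0)
    return PermResult(observed, permuted, float(p), B, seed)


def perm_in_area(centers: np.ndarray, radii: np.ndarray, settled: np.ndarray,
                 colony, B: int = 10_000, seed: int = 0) -> PermResult:
    """Do more individuals settle inside their own prospected circle than random?

    ``centers``/``radii`` define each individual's circle; the observed
    statistic counts individuals whose settled box lies inside it (boundary
    inclusive).  Permutations re-draw every settlement uniformly from the
    colony.  One-sided upper-tail p.
    """
    centers = np.asarray(centers, dtype=float)
    radii = np.asarray(radii, dtype=float)
    settled = np.asarray(settled, dtype=float)
    boxes = _box_coords(colony)
    rng = np.random.default_rng(seed)

    observed = int(np.sum(np.hypot(*(settled - centers).T) <= radii))
    n = len(centers)
    idx = rng.integers(0, len(boxes), size=(B, n))
    perms = boxes[idx]
    inside = np.hypot(perms[..., 0] - centers[:, 0],
                      perms[..., 1] - centers[:, 1]) <= radii
    permuted = inside.sum(axis=1).astype(float)
    p = (1.0 + np.sum(permuted >= observed)) / (B + 1.0)
    return PermResult(float(observed), permuted, float(p), B, seed)


def paired_t(x, y) -> tuple[float, int, float]:
    """Two-sided paired t-test; returns (t, df, p).

    t = mean(d) / (sd(d)/sqrt(n)) with d = x - y and df = n - 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length vectors with n >= 2")
    d = x - y
    if np.allclose(d.std(ddof=1), 0):
        raise ValueError("differences have zero variance")
    t, p = stats.ttest_rel(x, y)
    return float(t), len(x) - 1, float(p)
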