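"""Temporal and spatial autocorrelation of nest-box reproductive success.

For conspecific reproductive performance to be worth copying, fledging
success must be predictable in time and/or clustered in space.  Two checks:

* :func:`temporal_acf` — Pearson correlation of per-box annual fledged
  counts at year lags 1..max_lag, pooling within-box pairs across boxes
  (pooling is more stable than averaging per-box ACFs when series are short).
* :func:`morans_i` — Moran's I of the per-box across-year mean fledged
  count, by distance class, with permutation p-values.

Box-years under experimental manipulation are excluded by the callers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CorrelogramBin", "temporal_acf", "morans_i"]


@dataclass
class CorrelogramBin:
    lag: object  # int year lag, or (d_lo, d_hi) meters
    estimate: float
    p_value: float
    n_pairs: int


def temporal_acf(series: pd.DataFrame, max_lag: int = 3) -> list[CorrelogramBin]:
    """Lagged Pearson correlation of annual fledged counts within boxes.

    ``series`` needs columns ``box_id``, ``year``, ``fledged``.  For lag k,
    all within-box pairs (x_t, x_{t+k}) with consecutive records k years
    apart are pooled and correlated.  Bins whose pooled margins have zero
    variance are reported with NaN estimate.
    """
    out: list[CorrelogramBin] = []
    wide = series.pivot_table(index="box_id", columns="year", values="fledged")
    years = sorted(wide.columns)
    for k in range(1, max_lag + 1):
        xs, ys = [], []
        for y in years:
            if y + k not in wide.columns:
                continue
            a = wide[y].to_numpy(dtype=float)
            b = wide[y + k].to_numpy(dtype=float)
            ok = ~np.isnan(a) & ~np.isnan(b)
            xs.append(a[ok])
            ys.append(b[ok])
        if not xs:
            continue
        x = np.concatenate(xs)
        y_ = np.concatenate(ys)
        n = len(x)
        if n < 2 or x.std() == 0 or y_.std() == 0:
            out.append(CorrelogramBin(k, float("nan"), float("nan"), n))
            continue
        r, p = stats.pearsonr(x, y_)
        out.append(CorrelogramBin(k, float(r), float(p), n))
    return out


def _moran_stat(z: np.ndarray, w: np.ndarray) -> float:
    n = len(z)
    W = w.sum()
    return float(n / W * (z @ w @ z) / (z @ z))


def morans_i(values: np.ndarray, coords: np.ndarray,
             lag_width: float = 100.0, max_distance: float | None = None,
             n_perm: int = 999, seed: int = 0,
             row_standardize: bool = False) -> list[CorrelogramBin]:
    """Moran's I correlogram over equal-width distance classes.

    For each class [d_lo, d_hi), binary weights w_ij = 1 iff the pair
    distance falls in the class (i != j), and

        I = (n / W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

    with W the sum of weights.  Significance is assessed by ``n_perm``
    random permutations of the values over locations (two-sided, add-one
    rule).  Classes with no pairs are dropped.  The expected value under
    the null is -1/(n-1).

    ``row_standardize=True`` divides each row of the weight matrix by its
    row sum before computing I (an alternative normalization; the classical
    binary-weight form is the default).
    """
    x = np.asarray(values, dtype=float)
    pts = np.asarray(coords, dtype=float)
    n = len(x)
    if n < 8:
        raise ValueError("need at least 8 locations")
    if np.allclose(x, x[0]):
        raise ValueError("values are constant; Moran's I undefined")

    d = np.hypot(pts[:, 0, None] - pts[None, :, 0], pts[:, 1, None] - pts[None, :, 1])
    if max_distance is None:
        max_distance = d.max()
    edges = np.arange(0.0, max_distance + lag_width, lag_width)
    rng = np.random.default_rng(seed)
    z = x - x.mean()
    out: list[CorrelogramBin] = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        w = ((d >= lo) & (d < hi)).astype(float)
        np.fill_diagonal(w, 0.0)
        n_pairs = int(w.sum() / 2)
        if n_pairs == 0:
            continue
        if row_standardize:
            rs = w.sum(axis=1, keepdims=True)
            rs[rs == 0] = 1.0
            w = w / rs
        obs = _moran_stat(z, w)
        perm = np.empty(n_perm)
        for b in range(n_perm):
            zp = rng.permutation(z)
            perm[b] = _moran_stat(zp, w)
        # two-sided around the null expectation -1/(n-1)
        e0 = -1.0 / (n - 1)
        p = (1.0 + np.sum(np.abs(perm - e0) >= abs(obs - e0))) / (n_perm + 1.0)
        out.append(CorrelogramBin((float(lo), float(hi)), obs, float(p), n_pairs))
    return out
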