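"""Curation of experimental reference data from two asynchronous analyzers.

A benchtop (low-field) NMR and a high-resolution (high-field) reference NMR
monitor the same continuous process but sample at different times and with a
transport delay between flow cells. Building a trustworthy reference set
therefore takes four steps:

1. :func:`match_nearest` — pair every low-field timestamp with the
   nearest-in-time high-field result.
2. :func:`steady_state_mask` — keep only steady-state periods, found by a
   moving linear fit over 11 consecutive concentration values (per component:
   |slope| < 0.1 mol/h and residual std < 0.01 mol/L).
3. :func:`remove_outliers` — drop pairs where any component disagrees between
   the two analyzers by more than 0.04 mol/L.
4. :func:`kennard_stone_select` — pick a subset (e.g. 300 samples) with
   uniform coverage of concentration space via the Kennard-Stone max-min
   algorithm, countering the bias of process data towards the operating point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TimeSeriesTable",
    "match_nearest",
    "steady_state_mask",
    "remove_outliers",
    "kennard_stone_select",
]


@dataclass
class TimeSeriesTable:
    """Time-stamped per-component values from one analyzer.

    ``timestamps`` in hours, strictly increasing; ``values`` shape
    ``(n, n_components)`` in mol/L (concentrations) or a.u. (areas).
    """

    timestamps: np.ndarray
    values: np.ndarray
    source: str = ""
    component_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != self.timestamps.shape[0]:
            self.values = self.values.T
        if self.values.shape[0] != self.timestamps.shape[0]:
            raise ValueError("values rows must match timestamps")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("values must not contain missing entries")

    def __len__(self) -> int:
        return len(self.timestamps)

    def to_frame(self) -> pd.DataFrame:
        names = self.component_names or tuple(
            f"comp{i+1}" for i in range(self.values.shape[1])
        )
        df = pd.DataFrame(self.values, columns=list(names))
        df.insert(0, "time_h", self.timestamps)
        return df


def match_nearest(target: TimeSeriesTable, reference: TimeSeriesTable) -> pd.DataFrame:
    """Pair each target timestamp with the reference row nearest in time.

    Exact midpoint ties resolve to the *earlier* reference row. Returns a
    DataFrame with ``time_h``, target columns (``lf_*``), matched reference
    columns (``hf_*``) and the matched reference index/time.
    """
    if len(reference) == 0 or len(target) == 0:
        raise ValueError("both tables must be non-empty")
    rt = reference.timestamps
    # searchsorted gives the right neighbour; compare with the left one,
    # preferring the earlier row on ties
    right = np.searchsorted(rt, target.timestamps)
    right = np.clip(right, 0, len(rt) - 1)
    left = np.clip(right - 1, 0, len(rt) - 1)
    d_left = np.abs(target.timestamps - rt[left])
    d_right = np.abs(rt[right] - target.timestamps)
    idx = np.where(d_left <= d_right, left, right)

    t_names = target.component_names or tuple(
        f"comp{i+1}" for i in range(target.values.shape[1])
    )
    r_names = reference.component_names or tuple(
        f"comp{i+1}" for i in range(reference.values.shape[1])
    )
    out = {"time_h": target.timestamps}
    for j, nm in enumerate(t_names):
        out[f"lf_{nm}"] = target.values[:, j]
    for j, nm in enumerate(r_names):
        out[f"hf_{nm}"] = reference.values[idx, j]
    out["ref_index"] = idx
    out["ref_time_h"] = rt[idx]
    return pd.DataFrame(out)


def steady_state_mask(
    series: TimeSeriesTable,
    window: int = 11,
    slope_max: float = 0.1,
    std_max: float = 0.01,
    mark: str = "center",
) -> np.ndarray:
    """Flag steady-state samples by a moving linear fit.

    For every run of ``window`` consecutive samples and every component, an
    ordinary least-squares line against the true timestamps is fitted; the
    window is steady iff for *all* components ``|slope| < slope_max`` (mol/h)
    and the residual standard deviation about the fitted line is
    ``< std_max`` (mol/L) — strict inequalities. ``mark="center"`` flags the
    center sample of each qualifying window; ``mark="window"`` flags all of
    its samples. Series shorter than the window yield an all-false mask.
    """
    n = len(series)
    mask = np.zeros(n, dtype=bool)
    if n < window:
        logger.warning("series length %d < window %d: no steady states", n, window)
        return mask
    if mark not in ("center", "window"):
        raise ValueError("mark must be 'center' or 'window'")
    t = series.timestamps
    v = series.values
    half = window // 2
    for start in range(n - window + 1):
        sl = slice(start, start + window)
        tw = t[sl]
        ok = True
        for j in range(v.shape[1]):
            yw = v[sl, j]
            coef = np.polyfit(tw, yw, 1)
            resid = yw - np.polyval(coef, tw)
            if not (abs(coef[0]) < slope_max and resid.std() < std_max):
                ok = False
                break
        if ok:
            if mark == "center":
                mask[start + half] = True
            else:
                mask[sl] = True
    return mask


def remove_outliers(pairs: pd.DataFrame, max_dev: float = 0.04) -> pd.DataFrame:
    """Drop paired rows where any component's |hf - lf| exceeds ``max_dev``
    (strictly greater; a deviation of exactly ``max_dev`` is kept)."""
    lf_cols = [c for c in pairs.columns if c.startswith("lf_")]
    keep = np.ones(len(pairs), dtype=bool)
    for lc in lf_cols:
        hc = "hf_" + lc[3:]
        if hc not in pairs.columns:
            continue
        # strict "greater than": a deviation of exactly max_dev is kept;
        # tiny slack absorbs binary representation error at the boundary
        keep &= np.abs(pairs[hc].to_numpy() - pairs[lc].to_numpy()) <= max_dev + 1e-12
    dropped = int((~keep).sum())
    if dropped:
        logger.info("remove_outliers: dropped %d of %d rows", dropped, len(pairs))
    return pairs.loc[keep].reset_index(drop=True)


def kennard_stone_select(points: np.ndarray, k: int) -> np.ndarray:
    """Classic Kennard-Stone max-min selection of ``k`` uniformly covering rows.

    Starts from the two points at maximal Euclidean distance, then repeatedly
    adds the point whose minimal distance to the already-selected set is
    largest. Deterministic; ties break towards the lowest index. Returns the
    selected indices in selection order, so the first ``k'`` entries of a
    ``k``-selection equal the ``k'``-selection (prefix-chain property).
    """
    x = np.asarray(points, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    if k > n:
        raise ValueError(f"cannot select {k} of {n} points")
    if k <= 0:
        return np.empty(0, dtype=int)
    if n == 1:
        return np.array([0])

    d2 = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=-1)
    # farthest pair; lowest (i, j) on ties, order (smaller index first)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    first = [min(i, j), max(i, j)]
    if k == 1:
        return np.array(first[:1])
    selected = list(first)
    min_d2 = np.minimum(d2[selected[0]], d2[selected[1]])
    min_d2[selected] = -np.inf
    while len(selected) < k:
        nxt = int(np.argmax(min_d2))  # argmax takes the lowest index on ties
        selected.append(nxt)
        min_d2 = np.minimum(min_d2, d2[nxt])
        min_d2[nxt] = -np.inf
    return np.asarray(selected, dtype=int)
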