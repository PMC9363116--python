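"""Cross- and auto-correlograms of population activity during immobility.

The estimator is the Pearson correlation, at each integer-bin lag, between
the per-frame fraction of active cells of one type and the lagged fraction
of another, restricted to a frame set (typically immobility).  Lag pairs
whose two frames fall in different contiguous segments of the restriction
are dropped, so correlations are never computed across movement gaps.
Positive lag means the second signal follows the first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import ActivityRaster


@dataclass
class Correlogram:
    """Correlation coefficient per lag; NaN where too few pairs were available."""

    lags: np.ndarray          # seconds, symmetric around 0
    values: np.ndarray
    bin_s: float
    max_lag_s: float
    n_pairs: np.ndarray

    def value_at(self, lag_s: float) -> float:
        return float(self.values[np.argmin(np.abs(self.lags - lag_s))])


def population_signal(
    raster: ActivityRaster, cell_type: str, frames: Optional[np.ndarray] = None
) -> np.ndarray:
    """Per-frame fraction of active cells of one type, NaN outside ``frames``."""
    cells = raster.cells_of_type(cell_type)
    if len(cells) == 0:
        raise ValueError(f"no cells of type {cell_type!r}")
    signal = raster.activity[cells].mean(axis=0).astype(float)
    if frames is not None:
        mask = np.zeros(raster.n_frames, dtype=bool)
        mask[np.asarray(frames, dtype=int)] = True
        signal = np.where(mask, signal, np.nan)
    return signal


def _segment_ids(valid: np.ndarray) -> np.ndarray:
    """Label contiguous runs of valid frames; invalid frames get -1."""
    ids = np.full(len(valid), -1, dtype=int)
    seg = -1
    prev = False
    for i, v in enumerate(valid):
        if v and not prev:
            seg += 1
        if v:
            ids[i] = seg
        prev = v
    return ids


def crosscorrelogram(
    a: np.ndarray,
    b: np.ndarray,
    bin_s: float = 0.1,
    max_lag_s: float = 10.0,
    min_pairs: int = 10,
) -> Correlogram:
    """Pearson correlation of two series at integer-bin lags.

    ``a`` and ``b`` share the same frame grid (``bin_s`` seconds per frame)
    and restriction (NaN frames excluded).  At lag ``+k`` the correlation is
    ``corr(a[t], b[t + k])`` over pairs whose frames lie in the same
    contiguous valid segment; lags with fewer than ``min_pairs`` pairs are
    reported as NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must share the frame grid")
    valid = ~(np.isnan(a) | np.isnan(b))
    seg = _segment_ids(valid)
    max_lag = int(round(max_lag_s / bin_s))
    lags = np.arange(-max_lag, max_lag + 1)
    values = np.full(len(lags), np.nan)
    n_pairs = np.zeros(len(lags), dtype=int)
    n = len(a)
    for i, k in enumerate(lags):
        if k >= 0:
            t0 = np.arange(0, n - k)
        else:
            t0 = np.arange(-k, n)
        t1 = t0 + k
        ok = (seg[t0] >= 0) & (seg[t0] == seg[t1])
        x, y = a[t0[ok]], b[t1[ok]]
        n_pairs[i] = len(x)
        if len(x) < min_pairs or x.std() == 0 or y.std() == 0:
            continue
        values[i] = float(np.corrcoef(x, y)[0, 1])
    return Correlogram(
        lags=lags * bin_s, values=values, bin_s=bin_s, max_lag_s=max_lag_s, n_pairs=n_pairs
    )
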