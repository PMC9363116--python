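"""Movement-locked population statistics and developmental trend fits.

The peri-movement time histogram (PMTH) summarizes, in a 20-s window
centered on movement onset, the percentage of active cells (or the summed
dF/F) per imaging frame: per-bin 25th/median/75th percentiles over all
movements of a session, normalized by the number of imaged cells.  Chance
levels come from circularly shifted surrogate rasters: the 5th/median/95th
percentiles of the surrogate median PMTHs.

Movement-related inhibition uses a 4-s window centered on onset: the
post-movement activity of a movement is the number of cells active in the
2 s from onset divided by the number of cells active anywhere in the 4-s
window; movements with a ratio below 40% are "inhibiting" movements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .core import ActivityRaster, SessionBundle
from .events import _RunIndex

logger = logging.getLogger("pupdyn")


@dataclass
class PMTH:
    """Peri-movement percentile curves plus a surrogate envelope (% of cells)."""

    bin_centers: np.ndarray          # seconds relative to movement onset
    q25: np.ndarray
    median: np.ndarray
    q75: np.ndarray
    surrogate_p5: np.ndarray
    surrogate_p50: np.ndarray
    surrogate_p95: np.ndarray
    n_movements: int
    signal_kind: str = "active_fraction"

    @property
    def above_chance(self) -> np.ndarray:
        """Bins where the observed median exceeds the surrogate 95th percentile."""
        return self.median > self.surrogate_p95

    @property
    def below_chance(self) -> np.ndarray:
        """Bins where the observed median falls below the surrogate 5th percentile."""
        return self.median < self.surrogate_p5


def _window_matrix(signal: np.ndarray, onsets: np.ndarray, half: int) -> np.ndarray:
    """Stack signal windows [onset-half, onset+half] for in-bounds onsets."""
    usable = onsets[(onsets - half >= 0) & (onsets + half < len(signal))]
    if len(usable) < len(onsets):
        logger.info("dropped %d movements with incomplete windows", len(onsets) - len(usable))
    return np.stack([signal[o - half : o + half + 1] for o in usable]) if len(usable) else np.empty((0, 2 * half + 1))


def pmth_session(
    bundle: SessionBundle,
    signal_kind: str = "active_fraction",
    n_surrogates: int = 500,
    seed=None,
    cell_type: Optional[str] = None,
    categories: Optional[Sequence[str]] = None,
    window_s: float = 10.0,
) -> PMTH:
    """PMTH of one session, optionally restricted to one cell type.

    ``signal_kind`` selects the per-frame signal: ``"active_fraction"`` (the
    number of active cells) or ``"dff"`` (the summed dF/F trace); either is
    divided by the cell count and expressed in %.
    """
    raster = bundle.raster
    fr = raster.frame_rate
    half = int(round(window_s * fr))
    onsets = bundle.movements.onsets(categories)
    if cell_type is None:
        cells = np.arange(raster.n_cells)
    else:
        cells = raster.cells_of_type(cell_type)
        if len(cells) == 0:
            raise ValueError(f"no cells of type {cell_type!r}")
    if signal_kind == "active_fraction":
        source = raster.activity[cells].astype(np.float64)
    elif signal_kind == "dff":
        if bundle.traces is None:
            raise ValueError("signal_kind='dff' requires fluorescence traces")
        source = bundle.traces.dff[cells]
    else:
        raise ValueError(f"unknown signal_kind {signal_kind!r}")
    scale = 100.0 / len(cells)
    signal = source.sum(axis=0)

    windows = _window_matrix(signal, onsets, half)
    if windows.shape[0] == 0:
        raise ValueError("no movement has a complete peri-movement window")
    q25, q50, q75 = np.percentile(windows, [25, 50, 75], axis=0) * scale

    rng = np.random.default_rng(seed)
    n_frames = raster.n_frames
    surr_medians = np.empty((n_surrogates, 2 * half + 1))
    runs = _RunIndex(raster.activity[cells]) if signal_kind == "active_fraction" else None
    frame_idx = np.arange(n_frames)[None, :]
    for s in range(n_surrogates):
        shifts = rng.integers(1, n_frames + 1, size=len(cells))
        if runs is not None:
            surr_signal = runs.rotated_counts(shifts).astype(float)
        else:
            idx = (frame_idx - shifts[:, None]) % n_frames
            surr_signal = np.take_along_axis(source, idx, axis=1).sum(axis=0)
        surr_medians[s] = np.median(_window_matrix(surr_signal, onsets, half), axis=0)
    p5, p50, p95 = np.percentile(surr_medians, [5, 50, 95], axis=0) * scale

    return PMTH(
        bin_centers=np.arange(-half, half + 1) / fr,
        q25=q25, median=q50, q75=q75,
        surrogate_p5=p5, surrogate_p50=p50, surrogate_p95=p95,
        n_movements=windows.shape[0],
        signal_kind=signal_kind,
    )


def pmth_group(session_pmths: Sequence[PMTH]) -> PMTH:
    """Group PMTH: per-bin percentiles of the stacked session medians.

    Surrogate envelopes are combined the same way, taking the per-bin median
    across sessions of each envelope curve.
    """
    if not session_pmths:
        raise ValueError("need at least one session PMTH")
    ref = session_pmths[0].bin_centers
    for p in session_pmths[1:]:
        if len(p.bin_centers) != len(ref) or not np.allclose(p.bin_centers, ref):
            raise ValueError("session PMTHs have mixed binning")
    medians = np.stack([p.median for p in session_pmths])
    q25, q50, q75 = np.percentile(medians, [25, 50, 75], axis=0)
    return PMTH(
        bin_centers=ref,
        q25=q25, median=q50, q75=q75,
        surrogate_p5=np.median(np.stack([p.surrogate_p5 for p in session_pmths]), axis=0),
        surrogate_p50=np.median(np.stack([p.surrogate_p50 for p in session_pmths]), axis=0),
        surrogate_p95=np.median(np.stack([p.surrogate_p95 for p in session_pmths]), axis=0),
        n_movements=sum(p.n_movements for p in session_pmths),
        signal_kind=session_pmths[0].signal_kind,
    )


def post_movement_activity(
    raster: ActivityRaster, movement_onset: int, half_window_s: float = 2.0
) -> float:
    """Fraction of window-active cells that are active after movement onset.

    The window is the ``2 * half_window_s`` span centered on onset; the post
    sub-window starts at the onset frame (inclusive).  Returns NaN when no
    cell is active anywhere in the window (the movement is then skipped by
    callers).
    """
    half = int(round(half_window_s * raster.frame_rate))
    onset = int(movement_onset)
    if onset - half < 0 or onset + half > raster.n_frames:
        raise ValueError("4-s window does not fit inside the session")
    window = raster.activity[:, onset - half : onset + half]
    post = raster.activity[:, onset : onset + half]
    n_window = int((window.any(axis=1)).sum())
    if n_window == 0:
        return float("nan")
    return float((post.any(axis=1)).sum() / n_window)


def movement_activity_ratios(
    bundle: SessionBundle,
    half_window_s: float = 2.0,
    categories: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Post-movement activity for every movement with a defined ratio."""
    ratios = []
    skipped = 0
    for onset in bundle.movements.onsets(categories):
        half = int(round(half_window_s * bundle.raster.frame_rate))
        if onset - half < 0 or onset + half > bundle.raster.n_frames:
            skipped += 1
            continue
        r = post_movement_activity(bundle.raster, onset, half_window_s)
        if np.isnan(r):
            skipped += 1
            continue
        ratios.append(r)
    if skipped:
        logger.info("skipped %d movements without a defined activity ratio", skipped)
    return np.array(ratios)


def inhibiting_movement_proportion(
    bundle: SessionBundle,
    threshold: float = 0.40,
    half_window_s: float = 2.0,
    categories: Optional[Sequence[str]] = None,
) -> float:
    """Proportion of movements whose post-movement activity is < ``threshold``."""
    ratios = movement_activity_ratios(bundle, half_window_s, categories)
    if len(ratios) == 0:
        raise ValueError("no movement with a defined post-movement activity ratio")
    return float((ratios < threshold).mean())


def epoch_associated_cells(
    raster: ActivityRaster,
    epoch_frames: np.ndarray,
    n_shifts: int = 100,
    percentile: float = 99.0,
    seed=None,
):
    """Flag cells whose transient onsets concentrate in the given epochs.

    For each cell, its observed onset count inside the epoch set is compared
    with the ``percentile``-th percentile of counts obtained by circularly
    shifting its onsets ``n_shifts`` times; the cell is flagged when the
    observed count is strictly above.  Returns ``(flags, fraction)``.
    """
    epoch_frames = np.asarray(epoch_frames, dtype=int)
    if len(epoch_frames) == 0:
        raise ValueError("epoch set is empty")
    n_frames = raster.n_frames
    mask = np.zeros(n_frames, dtype=bool)
    mask[epoch_frames] = True
    rng = np.random.default_rng(seed)
    flags = np.zeros(raster.n_cells, dtype=bool)
    for c, onset_array in enumerate(raster.onsets()):
        if len(onset_array) == 0:
            continue
        observed = int(mask[onset_array].sum())
        shifts = rng.integers(1, n_frames, size=n_shifts)
        shifted = mask[(onset_array[None, :] + shifts[:, None]) % n_frames].sum(axis=1)
        if observed > np.percentile(shifted, percentile):
            flags[c] = True
    return flags, float(flags.mean())


# ---------------------------------------------------------------------------
# developmental trend fits
# ---------------------------------------------------------------------------

def sigmoid(x, bottom, top, v50, k):
    """Four-parameter logistic: bottom + (top - bottom) / (1 + exp(-k (x - v50)))."""
    return bottom + (top - bottom) / (1.0 + np.exp(-k * (x - v50)))


@dataclass
class TrendFit:
    """Least-squares fit of a developmental trend."""

    model: str
    params: dict
    r2: float
    predict: Callable[[np.ndarray], np.ndarray] = field(repr=False, default=None)  # type: ignore[assignment]


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 0.0
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def fit_trend(x, y, model: str = "linear") -> TrendFit:
    """Fit a linear, fourth-order polynomial, or sigmoid trend to (x, y).

    The sigmoid uses multi-start least squares (start grid over the midpoint
    and slope) and reports V50, the age of half-maximal transition.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n_params = {"linear": 2, "poly4": 5, "sigmoid": 4}[model]
    if len(x) < n_params + 1:
        raise ValueError(f"{model} fit needs at least {n_params + 1} points")
    if model == "linear":
        slope, intercept = np.polyfit(x, y, 1)
        predict = lambda t: slope * np.asarray(t) + intercept
        return TrendFit("linear", {"slope": slope, "intercept": intercept},
                        _r2(y, predict(x)), predict)
    if model == "poly4":
        coeffs = np.polyfit(x, y, 4)
        predict = lambda t: np.polyval(coeffs, np.asarray(t))
        return TrendFit("poly4", {"coeffs": coeffs}, _r2(y, predict(x)), predict)
    if model != "sigmoid":
        raise ValueError(f"unknown model {model!r}")

    if np.allclose(y, y[0]):
        predict = lambda t: np.full_like(np.asarray(t, dtype=float), y[0])
        return TrendFit("sigmoid", {"bottom": y[0], "top": y[0],
                                    "v50": float(np.median(x)), "k": 0.0}, 0.0, predict)
    span = y.max() - y.min()
    best = None
    for v50_0 in np.quantile(x, [0.25, 0.5, 0.75]):
        for k0 in (0.5, 1.0, 2.0, 5.0):
            try:
                popt, _ = curve_fit(
                    sigmoid, x, y,
                    p0=[y.min(), y.max(), v50_0, k0],
                    bounds=([y.min() - span, y.min() - span, x.min() - 5, 1e-3],
                            [y.max() + span, y.max() + span, x.max() + 5, 100.0]),
                    maxfev=20000,
                )
            except RuntimeError:
                continue
            r2 = _r2(y, sigmoid(x, *popt))
            if best is None or r2 > best[1]:
                best = (popt, r2)
    if best is None:
        raise RuntimeError("sigmoid fit did not converge from any start point")
    popt, r2 = best
    predict = lambda t: sigmoid(np.asarray(t, dtype=float), *popt)
    return TrendFit("sigmoid",
                    {"bottom": popt[0], "top": popt[1], "v50": popt[2], "k": popt[3]},
                    r2, predict)
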