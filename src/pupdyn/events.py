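"""Synchrony detection and single-cell activity statistics.

Synchronous calcium events (SCEs) are imaging frames where the number of
co-active cells exceeds a chance level estimated by a reshuffling method:
each cell's activity row is circularly shifted by an independent random
amount, the per-frame co-active counts of many such surrogates are pooled,
and their 99th percentile becomes the detection threshold.  Peaks of
synchrony above the threshold separated by at least five imaging frames
(500 ms at 10 Hz) are the SCE frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ActivityRaster


@dataclass
class SCEResult:
    """Detected SCE frames with the surrogate-derived threshold."""

    threshold: float
    sce_frames: np.ndarray
    n_surrogates: int = 300
    percentile: float = 99.0
    min_separation_frames: int = 5
    coactive_counts: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


class _RunIndex:
    """Maximal active runs of a raster, flattened for fast rotated counting.

    Rotating each cell's binary row and summing over cells is equivalent to
    scattering +1/-1 at the rotated run boundaries into a difference array
    and taking a cumulative sum — O(total runs) per surrogate instead of
    O(cells x frames).
    """

    def __init__(self, activity: np.ndarray):
        self.n_cells, self.n_frames = activity.shape
        starts, lens, cells = [], [], []
        padded = np.zeros((self.n_cells, self.n_frames + 2), dtype=np.int8)
        padded[:, 1:-1] = activity
        d = np.diff(padded, axis=1)
        for c in range(self.n_cells):
            on = np.flatnonzero(d[c] == 1)
            off = np.flatnonzero(d[c] == -1)
            starts.append(on)
            lens.append(off - on)
            cells.append(np.full(len(on), c))
        self.starts = np.concatenate(starts) if starts else np.array([], dtype=int)
        self.lens = np.concatenate(lens) if lens else np.array([], dtype=int)
        self.cells = np.concatenate(cells) if cells else np.array([], dtype=int)

    def rotated_counts(self, shifts: np.ndarray) -> np.ndarray:
        """Per-frame co-active counts after shifting cell c by shifts[c]."""
        n = self.n_frames
        a = (self.starts + shifts[self.cells]) % n
        b = a + self.lens
        diff = np.zeros(n + 1, dtype=np.int32)
        wrap = b > n
        np.add.at(diff, a, 1)
        np.add.at(diff, np.where(wrap, n, b), -1)
        if wrap.any():
            diff[0] += int(wrap.sum())
            np.add.at(diff, b[wrap] - n, -1)
        return np.cumsum(diff[:n])


def circular_shift_surrogate(raster: ActivityRaster | np.ndarray, seed=None) -> np.ndarray:
    """Independently rotate each cell's activity row by a nonzero amount.

    Shifts are uniform on [1, n_frames - 1], so a surrogate row never equals
    the original; per-cell total activity and transient durations are
    conserved exactly.
    """
    activity = raster.activity if isinstance(raster, ActivityRaster) else np.asarray(raster)
    n_cells, n_frames = activity.shape
    if n_frames < 2:
        raise ValueError("circular shift requires at least 2 frames")
    rng = np.random.default_rng(seed)
    shifts = rng.integers(1, n_frames, size=n_cells)
    idx = (np.arange(n_frames)[None, :] - shifts[:, None]) % n_frames
    return np.take_along_axis(activity, idx, axis=1)


def detect_sces(
    raster: ActivityRaster,
    n_surrogates: int = 300,
    percentile: float = 99.0,
    min_separation_frames: int = 5,
    seed=None,
) -> SCEResult:
    """Detect SCE frames against a circular-shift surrogate threshold.

    The threshold is the ``percentile``-th percentile of the per-frame
    co-active counts pooled over all surrogates.  Candidate frames are local
    maxima of the observed co-active count strictly above the threshold
    (plateaus resolved to their first frame); candidates closer than
    ``min_separation_frames`` are merged keeping the larger count, the
    earlier frame on ties.
    """
    activity = raster.activity
    n_cells, n_frames = activity.shape
    counts = activity.sum(axis=0).astype(int)
    if counts.sum() == 0:
        return SCEResult(
            threshold=0.0,
            sce_frames=np.array([], dtype=int),
            n_surrogates=n_surrogates,
            percentile=percentile,
            min_separation_frames=min_separation_frames,
            coactive_counts=counts,
        )
    rng = np.random.default_rng(seed)
    runs = _RunIndex(activity)
    pooled = np.empty((n_surrogates, n_frames), dtype=np.int32)
    for s in range(n_surrogates):
        shifts = rng.integers(1, n_frames, size=n_cells)
        pooled[s] = runs.rotated_counts(shifts)
    threshold = float(np.percentile(pooled.ravel(), percentile))

    peaks = _local_maxima(counts)
    peaks = peaks[counts[peaks] > threshold]
    sce_frames = _merge_peaks(peaks, counts, min_separation_frames)
    return SCEResult(
        threshold=threshold,
        sce_frames=sce_frames,
        n_surrogates=n_surrogates,
        percentile=percentile,
        min_separation_frames=min_separation_frames,
        coactive_counts=counts,
    )


def _local_maxima(counts: np.ndarray) -> np.ndarray:
    """Strict local maxima of an integer series; plateaus yield their first frame."""
    n = len(counts)
    peaks = []
    f = 0
    while f < n:
        start = f
        while f + 1 < n and counts[f + 1] == counts[start]:
            f += 1
        left_ok = start == 0 or counts[start - 1] < counts[start]
        right_ok = f == n - 1 or counts[f + 1] < counts[start]
        if left_ok and right_ok and counts[start] > 0:
            peaks.append(start)
        f += 1
    return np.array(peaks, dtype=int)


def _merge_peaks(peaks: np.ndarray, counts: np.ndarray, min_sep: int) -> np.ndarray:
    """Greedily merge peaks closer than ``min_sep``, keeping larger counts first."""
    if len(peaks) == 0:
        return peaks
    # order candidates by (count desc, frame asc); accept if far from all kept
    order = sorted(range(len(peaks)), key=lambda i: (-counts[peaks[i]], peaks[i]))
    kept: list[int] = []
    for i in order:
        f = int(peaks[i])
        if all(abs(f - g) >= min_sep for g in kept):
            kept.append(f)
    return np.array(sorted(kept), dtype=int)


def transients_in_sce_ratio(raster: ActivityRaster, sce: SCEResult):
    """Per-cell fraction of transients that cross an SCE frame, and their mean.

    A transient counts as in-SCE when any frame of its closed onset-to-peak
    interval is an SCE frame.  Cells without transients are excluded (NaN);
    if no cell has a transient the per-animal mean is undefined and a
    ``ValueError`` is raised.
    """
    sce_mask = np.zeros(raster.n_frames, dtype=bool)
    sce_mask[np.asarray(sce.sce_frames, dtype=int)] = True
    ratios = np.full(raster.n_cells, np.nan)
    for c, transients in enumerate(raster.transients):
        if not transients:
            continue
        hits = sum(1 for onset, peak in transients if sce_mask[onset : peak + 1].any())
        ratios[c] = hits / len(transients)
    if np.all(np.isnan(ratios)):
        raise ValueError("no cell has any transient; in-SCE ratio undefined")
    return ratios, float(np.nanmean(ratios))


def transient_frequency(raster: ActivityRaster):
    """Per-cell transient onsets per minute, and the mean over cells."""
    duration_min = raster.duration_s / 60.0
    if duration_min <= 0:
        raise ValueError("recording duration must be positive")
    per_cell = np.array([len(tr) for tr in raster.transients]) / duration_min
    return per_cell, float(per_cell.mean())
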