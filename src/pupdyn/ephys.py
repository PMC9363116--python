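"""EMG vigilance-state scoring and early-sharp-wave (eSW) detection.

Vigilance scoring follows a two-threshold protocol on the rectified,
high-pass-filtered nuchal EMG: five 1-s representative windows of high and
of low muscle tone define a midpoint threshold (wake above) and a quarter
point (active sleep below, transition in between), applied to 1-s bin
averages.  Twitches are super-threshold deflections (mean + 5 SD of the low
tone samples) inside active-sleep bins.

eSWs are deflections of the stratum radiatum minus stratum oriens
difference trace exceeding 4 SD, kept only when the two layers deflect with
opposite signs while the stratum pyramidale trace sits near zero (the
polarity reversal across the CA1 layer axis).  Inter-hemispheric
co-occurrence is the histogram of contralateral-minus-ipsilateral event
time differences in 10-ms bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import butter, decimate, find_peaks, sosfiltfilt

# ---------------------------------------------------------------------------
# result types
# ---------------------------------------------------------------------------

@dataclass
class Hypnogram:
    """Per-second vigilance states with twitch times and the thresholds used."""

    states: np.ndarray                 # object array in {wake, active_sleep, transition}
    twitch_times_s: np.ndarray
    bin_s: float = 1.0
    thresholds: dict = field(default_factory=dict)


@dataclass
class SWEventSet:
    """Detected sharp-wave times with the whole-recording occurrence rate."""

    event_times_s: np.ndarray
    rate_per_min: float
    threshold_sd: float = 4.0


# ---------------------------------------------------------------------------
# EMG
# ---------------------------------------------------------------------------

def _rectify_emg(emg: np.ndarray, fs: float) -> tuple[np.ndarray, float]:
    """Downsample to 1 kHz, high-pass at 300 Hz, rectify."""
    emg = np.asarray(emg, dtype=float)
    if fs < 1000:
        raise ValueError("EMG sampling rate must be >= 1000 Hz")
    if fs > 1000:
        q = int(round(fs / 1000))
        emg = decimate(emg, q)
        fs = fs / q
    sos = butter(4, 300.0, btype="highpass", fs=fs, output="sos")
    return np.abs(sosfiltfilt(sos, emg)), fs


def score_vigilance(
    emg: np.ndarray,
    fs: float,
    high_windows_s: Sequence[float],
    low_windows_s: Sequence[float],
    twitch_group_gap_s: float = 0.05,
) -> Hypnogram:
    """Score 1-s bins as wake / active sleep / transition and find twitches.

    ``high_windows_s`` and ``low_windows_s`` give the start times of the
    representative 1-s windows of high and low EMG tone.  Raises when the
    two conditions are not separated (degenerate thresholds).
    """
    rect, fs1k = _rectify_emg(emg, fs)
    n_s = int(len(rect) / fs1k)

    def window_samples(starts):
        chunks = []
        for t0 in starts:
            i = int(round(t0 * fs1k))
            j = i + int(fs1k)
            if i < 0 or j > len(rect):
                raise ValueError(f"sample window at {t0}s outside the record")
            chunks.append(rect[i:j])
        return np.concatenate(chunks)

    high = window_samples(high_windows_s)
    low = window_samples(low_windows_s)
    high_mean, low_mean = float(high.mean()), float(low.mean())
    if high_mean <= low_mean:
        raise ValueError("high/low tone samples are not separated; thresholds degenerate")
    midpoint = (high_mean + low_mean) / 2.0
    quarterpoint = low_mean + (high_mean - low_mean) / 4.0
    twitch_level = float(low.mean() + 5.0 * low.std())

    samples_per_bin = int(fs1k)
    bin_means = rect[: n_s * samples_per_bin].reshape(n_s, samples_per_bin).mean(axis=1)
    states = np.empty(n_s, dtype=object)
    states[bin_means >= midpoint] = "wake"
    states[bin_means < quarterpoint] = "active_sleep"
    states[(bin_means >= quarterpoint) & (bin_means < midpoint)] = "transition"

    # twitches: super-threshold samples inside active-sleep bins, grouped
    sleep_mask = np.repeat(states == "active_sleep", samples_per_bin)
    sleep_mask = np.pad(sleep_mask, (0, len(rect) - len(sleep_mask)), constant_values=False)
    above = np.flatnonzero((rect > twitch_level) & sleep_mask)
    twitch_times = []
    if len(above):
        gap = int(round(twitch_group_gap_s * fs1k))
        group_start = above[0]
        prev = above[0]
        for idx in above[1:]:
            if idx - prev > gap:
                twitch_times.append(group_start / fs1k)
                group_start = idx
            prev = idx
        twitch_times.append(group_start / fs1k)
    return Hypnogram(
        states=states,
        twitch_times_s=np.array(twitch_times),
        thresholds={
            "midpoint": midpoint,
            "quarterpoint": quarterpoint,
            "twitch_level": twitch_level,
        },
    )


# ---------------------------------------------------------------------------
# LFP
# ---------------------------------------------------------------------------

def preprocess_lfp(lfp: np.ndarray, fs: float, band=(2.0, 100.0)):
    """Downsample to 1 kHz, zero-phase band-pass, subtract the common reference.

    Returns ``(filtered, fs_out)`` with the per-timepoint channel mean
    removed.  The band-pass is a zero-phase Butterworth filter covering the
    requested band.
    """
    lfp = np.atleast_2d(np.asarray(lfp, dtype=float))
    if fs < 250:
        raise ValueError("LFP sampling rate must be >= 250 Hz")
    if fs > 1000:
        q = int(round(fs / 1000))
        lfp = decimate(lfp, q, axis=1)
        fs = fs / q
    sos = butter(4, band, btype="bandpass", fs=fs, output="sos")
    filtered = sosfiltfilt(sos, lfp, axis=1)
    filtered = filtered - filtered.mean(axis=0, keepdims=True)
    return filtered, fs


def detect_esw(
    so: np.ndarray,
    sp: np.ndarray,
    sr: np.ndarray,
    fs: float,
    threshold_sd: float = 4.0,
    min_separation_s: float = 0.1,
    sp_reversal_ratio: float = 0.5,
    dominance_window_s: float = 0.3,
) -> SWEventSet:
    """Detect layer-reversing sharp waves on band-passed (2-45 Hz) traces.

    Candidate peaks of |SR - SO| above ``threshold_sd`` standard deviations
    of the difference trace are kept when the SO and SR deflections around
    the peak have opposite signs and |SP| stays below
    ``sp_reversal_ratio * min(|SO|, |SR|)`` (the reversal test); events
    closer than ``min_separation_s`` are merged.  A candidate must also be
    the largest deflection within ``dominance_window_s``, which rejects the
    flanking ripples that band-passing imprints around each sharp wave.
    """
    sos_band = butter(4, (2.0, 45.0), btype="bandpass", fs=fs, output="sos")
    so_f, sp_f, sr_f = (sosfiltfilt(sos_band, np.asarray(x, dtype=float)) for x in (so, sp, sr))
    diff = sr_f - so_f
    sd = diff.std()
    if sd == 0:
        return SWEventSet(np.array([]), 0.0, threshold_sd)
    thr = threshold_sd * sd
    distance = max(1, int(round(min_separation_s * fs)))
    peaks, _ = find_peaks(np.abs(diff), height=thr, distance=distance)

    kept = []
    dom = max(1, int(round(dominance_window_s * fs)))
    absdiff = np.abs(diff)
    for p in peaks:
        lo = max(0, p - dom)
        if absdiff[p] < absdiff[lo : p + dom + 1].max():
            continue
        so_v, sp_v, sr_v = so_f[p], sp_f[p], sr_f[p]
        if so_v * sr_v >= 0:
            continue
        if abs(sp_v) >= sp_reversal_ratio * min(abs(so_v), abs(sr_v)):
            continue
        kept.append(p / fs)
    times = np.array(kept)
    minutes = len(so_f) / fs / 60.0
    return SWEventSet(times, float(len(times) / minutes) if minutes > 0 else 0.0, threshold_sd)


def esw_cooccurrence(
    ipsi_times_s: np.ndarray,
    contra_times_s: np.ndarray,
    bin_s: float = 0.010,
    max_lag_s: float = 0.5,
):
    """Histogram of contra - ipsi time differences in 10-ms bins.

    Returns ``(lag_centers, counts, peak_lag_s)``.
    """
    ipsi = np.asarray(ipsi_times_s, dtype=float)
    contra = np.asarray(contra_times_s, dtype=float)
    if len(ipsi) == 0 or len(contra) == 0:
        raise ValueError("need at least one event per hemisphere")
    diffs = (contra[None, :] - ipsi[:, None]).ravel()
    diffs = diffs[np.abs(diffs) <= max_lag_s]
    n_bins = int(round(2 * max_lag_s / bin_s))
    edges = -max_lag_s + np.arange(n_bins + 1) * bin_s
    counts, _ = np.histogram(diffs, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return centers, counts, float(centers[np.argmax(counts)])
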