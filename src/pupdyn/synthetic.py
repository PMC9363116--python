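"""Seeded generators for synthetic sessions, EMG, LFP, and image phantoms.

Every generator is a pure function of a design dataclass plus a seed and
returns ground truth alongside the signal, so each analysis stage can be
tested end-to-end without external data.

The session generator emulates the statistical structure of neonatal CA1
population recordings:

* baseline calcium-transient onsets as independent per-cell Bernoulli
  hazards (approximately Poisson at the configured transients/min);
* discontinuous population bursts (synchronous calcium events, SCEs) in
  which a random subset of cells emits time-locked onsets;
* movement epochs with log-normal durations (brief twitches vs complex
  movements lasting >= 2 s) laid down as a Poisson process;
* cell-type-specific movement coupling: a multiplicative hazard applied in
  the 2 s after each movement onset.  Interneurons keep a positive gain at
  all ages; the pyramidal gain moves from strong activation to strong
  suppression as age crosses ``switch_age_days``.  The transition is a steep
  sigmoid in age (scale 0.35 days, i.e. essentially complete within ~2 days)
  interpolated on the log-gain scale, since the hazard is multiplicative;
* dF/F traces as the raster convolved with an exponential kernel of
  characteristic time 2 s (GCaMP6s-like decay) plus white Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import fftconvolve

from .core import (
    ActivityRaster,
    FluorescenceTraces,
    MovementEpochs,
    SessionBundle,
    raster_from_transients,
)

# ---------------------------------------------------------------------------
# designs
# ---------------------------------------------------------------------------

@dataclass
class CouplingDesign:
    """Cell-type-specific movement modulation of the transient-onset hazard.

    Gains are multiplicative on the baseline hazard inside a
    ``window_s``-long window after each movement onset.  The pyramidal gain
    is ``pyr_pre`` well before the switch age and ``pyr_post`` well after;
    in between it follows a sigmoid of age (scale ``switch_width_days``)
    interpolated in log-gain.
    """

    pyr_pre: float = 6.0
    pyr_post: float = 0.05
    interneuron: float = 2.5
    window_s: float = 2.0
    switch_width_days: float = 0.35
    #: strength of interneuron->pyramidal feedback suppression after the
    #: switch: the pyramidal hazard is multiplied by
    #: exp(-feedback_beta * w(age) * interneuron active fraction), lagged by
    #: feedback_delay_s (the di-synaptic route through interneurons)
    feedback_beta: float = 10.0
    feedback_delay_s: float = 0.3

    def switch_weight(self, age_days: float, switch_age_days: float) -> float:
        """0 well before the switch age, 1 well after (sigmoid in age)."""
        z = (age_days - switch_age_days) / self.switch_width_days
        return float(1.0 / (1.0 + np.exp(-z)))

    def pyramidal_gain(self, age_days: float, switch_age_days: float) -> float:
        w = self.switch_weight(age_days, switch_age_days)
        return float(np.exp((1 - w) * np.log(self.pyr_pre) + w * np.log(self.pyr_post)))


@dataclass
class SessionDesign:
    """Parameters of one synthetic imaging session."""

    n_pyr: int = 200
    n_int: int = 10
    duration_s: float = 600.0
    frame_rate: float = 10.0
    baseline_rate: float = 1.0          # transient onsets / min / pyramidal cell
    int_rate_factor: float = 4.0        # interneurons fire ~4x more often
    movement_rate: float = 3.0          # movements / min
    movement_mu: float = float(np.log(0.4))   # log-normal log-mean of duration (s)
    movement_sigma: float = 0.8
    twitch_fraction: Optional[float] = None   # None: implied by the duration law
    coupling: CouplingDesign = field(default_factory=CouplingDesign)
    sce_rate: float = 1.0               # population bursts / min
    sce_participation: float = 0.25     # fraction of cells per burst
    switch_age_days: float = 9.0
    rise_frames: tuple[int, int] = (2, 5)     # onset-to-peak duration range
    dff_noise_sd: float = 0.1
    gcamp_tau_s: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baseline_rate", "movement_rate", "sce_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.sce_participation <= 1:
            raise ValueError("sce_participation must be in [0, 1]")
        if self.twitch_fraction is not None and not 0 <= self.twitch_fraction <= 1:
            raise ValueError("twitch_fraction must be in [0, 1]")


@dataclass
class EMGDesign:
    """Two-level nuchal-EMG emulation with super-threshold twitches.

    The trace is a 350 Hz carrier whose envelope follows the vigilance-state
    schedule: ``high_amp`` during wakefulness, ``low_amp`` during active
    sleep.  Twitches are 100-ms envelope bursts of ``twitch_amp`` inserted in
    sleep bouts; ``twitch_amp`` must exceed the mean + 5 SD of the rectified
    low-tone signal (for a rectified sine that is ~2.2x the low amplitude).
    """

    fs: float = 1000.0
    duration_s: float = 300.0
    wake_bout_s: float = 30.0
    sleep_bout_s: float = 60.0
    low_amp: float = 1.0
    high_amp: float = 5.0
    twitch_amp: float = 8.0
    twitch_dur_s: float = 0.1
    n_twitches: int = 10
    carrier_hz: float = 350.0
    noise_sd: float = 0.0
    seed: int = 0


@dataclass
class LFPDesign:
    """Multi-channel LFP emulation with layer-reversing sharp waves.

    Sharp-wave templates are Gaussian deflections of width ``sw_width_ms``
    with opposite polarity in stratum oriens (negative) and stratum radiatum
    (positive) and near-zero amplitude in stratum pyramidale (the reversal
    point).  Contralateral copies are shifted by ``lag_ms``.
    """

    fs: float = 1000.0
    duration_s: float = 240.0
    sw_times_s: Optional[Sequence[float]] = None
    sw_rate_per_min: float = 3.0
    lag_ms: float = 0.0
    sw_amp: float = 10.0
    sw_width_ms: float = 40.0
    sp_leak: float = 0.03               # residual template amplitude at SP
    noise_sd: float = 1.0
    seed: int = 0


@dataclass
class PhantomDesign:
    """Image/movie phantom: axonal branch polylines or bouton particles."""

    shape: tuple[int, ...] = (100, 64, 64)       # (t, y, x) for movies
    branches: Sequence[Sequence[tuple[float, float]]] = ()
    branch_width_px: int = 1
    psf_sigma_px: float = 1.0
    noise_sd: float = 0.02
    pixel_size_um: float = 0.156
    particle_areas_um2: Sequence[float] = ()
    n_z: int = 8
    amplitude: float = 1.0
    seed: int = 0


# ---------------------------------------------------------------------------
# movements
# ---------------------------------------------------------------------------

def generate_movements(design: SessionDesign, seed: Optional[int] = None) -> MovementEpochs:
    """Poisson-count movement onsets with log-normal durations.

    Draws labelled ``twitch`` when shorter than 2 s and ``complex``
    otherwise; overlapping draws are rejected.  Raises ``ValueError`` when
    the expected movement occupancy exceeds 80% of the session.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    n_frames = int(round(design.duration_s * design.frame_rate))
    mean_dur = float(np.exp(design.movement_mu + design.movement_sigma**2 / 2))
    expected_occupancy = design.movement_rate / 60.0 * mean_dur
    if expected_occupancy > 0.8:
        raise ValueError(
            f"movement density infeasible: expected occupancy {expected_occupancy:.2f} > 0.8"
        )
    n_mov = rng.poisson(design.movement_rate * design.duration_s / 60.0)
    epochs: list[tuple[int, int, str]] = []
    occupied = np.zeros(n_frames, dtype=bool)
    for _ in range(n_mov):
        for _attempt in range(100):
            if design.twitch_fraction is None:
                dur_s = float(rng.lognormal(design.movement_mu, design.movement_sigma))
            else:
                want_twitch = rng.random() < design.twitch_fraction
                for _draw in range(1000):
                    dur_s = float(rng.lognormal(design.movement_mu, design.movement_sigma))
                    if (dur_s < 2.0) == want_twitch:
                        break
            dur_f = max(1, int(round(dur_s * design.frame_rate)))
            onset = int(rng.integers(0, max(1, n_frames - dur_f)))
            if not occupied[onset : onset + dur_f].any():
                occupied[onset : onset + dur_f] = True
                cat = "twitch" if dur_s < 2.0 else "complex"
                epochs.append((onset, onset + dur_f, cat))
                break
    return MovementEpochs(epochs=sorted(epochs), n_frames=n_frames)


# ---------------------------------------------------------------------------
# sessions
# ---------------------------------------------------------------------------

def gcamp_kernel(tau_s: float, frame_rate: float) -> np.ndarray:
    """Causal exponential kernel normalized to unit peak."""
    n = max(2, int(round(5 * tau_s * frame_rate)))
    t = np.arange(n) / frame_rate
    return np.exp(-t / tau_s)


def generate_session(
    design: SessionDesign, age_days: float, seed: Optional[int] = None
) -> SessionBundle:
    """Generate one full synthetic session for a pup of the given age."""
    base_seed = design.seed if seed is None else seed
    rng = np.random.default_rng(base_seed)
    n_frames = int(round(design.duration_s * design.frame_rate))
    n_cells = design.n_pyr + design.n_int
    cell_types = np.array(
        ["pyramidal"] * design.n_pyr + ["interneuron"] * design.n_int, dtype=object
    )

    movements = generate_movements(design, seed=int(rng.integers(2**31)))

    # movement coupling: a multiplicative hazard gain in the post-onset
    # window, plus (after the switch) feedback suppression of pyramidal
    # cells by the delayed interneuron population activity
    coup = design.coupling
    h0 = design.baseline_rate / 60.0 / design.frame_rate
    g_pyr = coup.pyramidal_gain(age_days, design.switch_age_days)
    g_int = coup.interneuron
    w_switch = coup.switch_weight(age_days, design.switch_age_days)
    window_f = int(round(coup.window_s * design.frame_rate))
    in_window = np.zeros(n_frames, dtype=bool)
    for onset in movements.onsets():
        in_window[onset : min(n_frames, onset + window_f)] = True

    # SCE bursts: synchronized extra onsets in a random subset of cells
    n_sce = rng.poisson(design.sce_rate * design.duration_s / 60.0)
    sce_frames = np.sort(rng.integers(0, n_frames, size=n_sce))
    k = int(round(design.sce_participation * n_cells))
    sce_cells = [rng.choice(n_cells, size=k, replace=False) for _ in sce_frames]

    lo, hi = design.rise_frames

    def accept(candidate_row: np.ndarray) -> list[tuple[int, int]]:
        cell_tr: list[tuple[int, int]] = []
        last_peak = -1
        for onset in np.flatnonzero(candidate_row):
            if onset <= last_peak:
                continue
            peak = min(n_frames - 1, onset + int(rng.integers(lo, hi + 1)))
            cell_tr.append((int(onset), int(peak)))
            last_peak = peak
        return cell_tr

    # interneurons first: their activity drives the feedback term
    h_int = np.minimum(0.5, h0 * design.int_rate_factor * np.where(in_window, g_int, 1.0))
    int_candidate = rng.random((design.n_int, n_frames)) < h_int
    for f, cells in zip(sce_frames, sce_cells):
        hit = cells[cells >= design.n_pyr] - design.n_pyr
        int_candidate[hit, f] = True
    int_transients = [accept(int_candidate[c]) for c in range(design.n_int)]
    int_activity = raster_from_transients(int_transients, n_frames) if design.n_int else np.zeros((0, n_frames))
    int_frac = int_activity.mean(axis=0) if design.n_int else np.zeros(n_frames)

    delay_f = int(round(coup.feedback_delay_s * design.frame_rate))
    delayed_frac = np.concatenate([np.zeros(delay_f), int_frac])[:n_frames]
    feedback = np.exp(-coup.feedback_beta * w_switch * delayed_frac)

    h_pyr = np.minimum(0.5, h0 * np.where(in_window, g_pyr, 1.0) * feedback)
    pyr_candidate = rng.random((design.n_pyr, n_frames)) < h_pyr
    for f, cells in zip(sce_frames, sce_cells):
        pyr_candidate[cells[cells < design.n_pyr], f] = True
    transients = [accept(pyr_candidate[c]) for c in range(design.n_pyr)] + int_transients

    raster = ActivityRaster(
        activity=raster_from_transients(transients, n_frames),
        frame_rate=design.frame_rate,
        cell_types=cell_types,
        transients=transients,
    )

    kernel = gcamp_kernel(design.gcamp_tau_s, design.frame_rate)
    dff = fftconvolve(raster.activity.astype(float), kernel[None, :], mode="full")
    dff = dff[:, :n_frames]
    dff += rng.normal(0.0, design.dff_noise_sd, size=dff.shape)
    traces = FluorescenceTraces(dff=dff)

    meta = {
        "animal_id": f"synthetic-{base_seed}",
        "age_days": float(age_days),
        "session_id": f"synthetic-{base_seed}-P{age_days:g}",
    }
    return SessionBundle(raster=raster, movements=movements, traces=traces, meta=meta)


# ---------------------------------------------------------------------------
# EMG
# ---------------------------------------------------------------------------

def generate_emg(design: EMGDesign):
    """Two-level EMG trace with injected twitches.

    Returns ``(trace, truth)`` where ``truth`` is a dict with the designed
    1-s-bin state sequence (``states``), twitch times in seconds
    (``twitch_times_s``), and suggested 1-s sample windows for the high and
    low tone conditions (``high_windows_s``, ``low_windows_s``).
    """
    rng = np.random.default_rng(design.seed)
    fs = design.fs
    n = int(round(design.duration_s * fs))
    t = np.arange(n) / fs

    envelope = np.empty(n)
    n_bins = int(design.duration_s)
    states = np.empty(n_bins, dtype=object)
    pos = 0.0
    state = "active_sleep"
    bouts: list[tuple[float, float, str]] = []
    while pos < design.duration_s:
        dur = design.sleep_bout_s if state == "active_sleep" else design.wake_bout_s
        bouts.append((pos, min(design.duration_s, pos + dur), state))
        pos += dur
        state = "wake" if state == "active_sleep" else "active_sleep"
    for a, b, st in bouts:
        i, j = int(a * fs), int(b * fs)
        envelope[i:j] = design.high_amp if st == "wake" else design.low_amp
        states[int(a) : int(np.ceil(b))] = st

    # twitches: brief envelope bursts centered inside sleep bouts
    sleep_bouts = [(a, b) for a, b, st in bouts if st == "active_sleep" and b - a > 2]
    twitch_times = []
    for k in range(design.n_twitches):
        a, b = sleep_bouts[k % len(sleep_bouts)]
        tt = a + 1.0 + (k // len(sleep_bouts) + rng.random()) * (b - a - 2) / max(
            1, int(np.ceil(design.n_twitches / len(sleep_bouts)))
        )
        twitch_times.append(min(tt, b - 1.0))
    twitch_times = sorted(twitch_times)
    half = design.twitch_dur_s / 2
    for tt in twitch_times:
        i, j = int((tt - half) * fs), int((tt + half) * fs)
        envelope[i:j] = design.twitch_amp

    trace = envelope * np.sin(2 * np.pi * design.carrier_hz * t)
    if design.noise_sd > 0:
        trace = trace + rng.normal(0, design.noise_sd, size=n)

    wake_bouts = [(a, b) for a, b, st in bouts if st == "wake"]
    high_windows = [wake_bouts[k % len(wake_bouts)][0] + 1.0 + k for k in range(5)]
    low_windows = [sleep_bouts[k % len(sleep_bouts)][0] + 0.2 + 0.1 * k for k in range(5)]
    truth = {
        "states": states,
        "twitch_times_s": np.array(twitch_times),
        "high_windows_s": high_windows,
        "low_windows_s": low_windows,
    }
    return trace, truth


# ---------------------------------------------------------------------------
# LFP
# ---------------------------------------------------------------------------

def _sw_template(fs: float, width_ms: float) -> np.ndarray:
    half = int(3 * width_ms / 1000 * fs)
    t = np.arange(-half, half + 1) / fs
    return np.exp(-0.5 * (t / (width_ms / 1000)) ** 2)


def generate_lfp(design: LFPDesign):
    """Six-channel LFP (SO/SP/SR x ipsi/contra) with reversing SW templates.

    Returns ``(channels, truth)``; ``channels`` maps ``(hemisphere, layer)``
    to a trace, ``truth`` holds the designed event times per hemisphere.
    """
    rng = np.random.default_rng(design.seed)
    n = int(round(design.duration_s * design.fs))
    if design.sw_times_s is not None:
        ipsi_times = np.asarray(design.sw_times_s, dtype=float)
    else:
        n_sw = rng.poisson(design.sw_rate_per_min * design.duration_s / 60.0)
        ipsi_times = np.sort(
            rng.uniform(2.0, design.duration_s - 2.0, size=n_sw)
        )
    contra_times = ipsi_times + design.lag_ms / 1000.0
    template = _sw_template(design.fs, design.sw_width_ms)
    half = len(template) // 2

    channels = {}
    for hemi, times in (("ipsi", ipsi_times), ("contra", contra_times)):
        for layer, gain in (("so", -1.0), ("sp", design.sp_leak), ("sr", 1.0)):
            tr = rng.normal(0, design.noise_sd, size=n) if design.noise_sd > 0 else np.zeros(n)
            for tt in times:
                c = int(round(tt * design.fs))
                i, j = c - half, c + half + 1
                if i < 0 or j > n:
                    continue
                tr[i:j] += gain * design.sw_amp * template
            channels[(hemi, layer)] = tr
    truth = {"ipsi_times_s": ipsi_times, "contra_times_s": contra_times}
    return channels, truth


# ---------------------------------------------------------------------------
# image phantoms
# ---------------------------------------------------------------------------

def generate_axon_movie(design: PhantomDesign):
    """Movie of blurred branch polylines, each following its own time course.

    Returns ``(movie, truth)`` with per-branch boolean masks and the drawn
    intensity time courses.
    """
    from skimage.draw import line
    from skimage.morphology import dilation, footprint_rectangle

    rng = np.random.default_rng(design.seed)
    n_t, h, w = design.shape
    masks = []
    for poly in design.branches:
        mask = np.zeros((h, w), dtype=bool)
        pts = [(int(round(y)), int(round(x))) for y, x in poly]
        for (y0, x0), (y1, x1) in zip(pts, pts[1:]):
            rr, cc = line(y0, x0, y1, x1)
            keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            mask[rr[keep], cc[keep]] = True
        if design.branch_width_px > 1:
            size = design.branch_width_px
            mask = dilation(mask, footprint_rectangle((size, size)))
        masks.append(mask)

    traces = []
    for _ in masks:
        # sparse calcium-transient-like time course: exponential decays
        tr = np.zeros(n_t)
        n_ev = max(1, rng.poisson(n_t / 30))
        for f in rng.integers(0, max(1, n_t - 5), size=n_ev):
            decay = np.exp(-np.arange(n_t - f) / 8.0)
            tr[f:] += decay
        traces.append(0.2 + tr / max(1e-9, tr.max()))

    movie = np.zeros(design.shape, dtype=float)
    for mask, tr in zip(masks, traces):
        blurred = gaussian_filter(mask.astype(float), design.psf_sigma_px)
        movie += tr[:, None, None] * blurred[None, :, :]
    if design.noise_sd > 0:
        movie += rng.normal(0, design.noise_sd, size=design.shape)
    truth = {"masks": masks, "traces": [np.asarray(t) for t in traces]}
    return movie, truth


def generate_syt2_image(design: PhantomDesign):
    """Z-stack phantom of bright bouton-like particles on a noisy background.

    Particles are squares of the requested areas (in µm²) placed without
    overlap in the top slices of the stack.  Returns ``(stack, truth)``;
    ``truth["coverage_percent"]`` is the ground-truth coverage counting only
    particles with drawn area in the 0.4-4 µm² band.
    """
    rng = np.random.default_rng(design.seed)
    if len(design.shape) == 2:
        h, w = design.shape
    else:
        _, h, w = design.shape
    px_area = design.pixel_size_um**2
    stack = np.zeros((design.n_z, h, w), dtype=float)
    placed = np.zeros((h, w), dtype=bool)
    retained_px = 0
    particle_areas = []
    for area in design.particle_areas_um2:
        side = max(1, int(round(np.sqrt(area) / design.pixel_size_um)))
        drawn_area = side * side * px_area
        for _attempt in range(200):
            y = int(rng.integers(0, h - side))
            x = int(rng.integers(0, w - side))
            region = np.s_[y : y + side, x : x + side]
            pad = np.s_[max(0, y - 2) : y + side + 2, max(0, x - 2) : x + side + 2]
            if not placed[pad].any():
                placed[region] = True
                z0 = int(rng.integers(0, max(1, design.n_z // 2)))
                stack[(z0, *region)] = design.amplitude
                particle_areas.append(drawn_area)
                if 0.4 <= drawn_area <= 4.0:
                    retained_px += side * side
                break
    if design.noise_sd > 0:
        stack += rng.normal(0, design.noise_sd, size=stack.shape)
        stack = np.clip(stack, 0, None)
    truth = {
        "coverage_percent": 100.0 * retained_px / (h * w),
        "particle_areas_um2": particle_areas,
    }
    return stack, truth
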