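"""Two-population excitatory/inhibitory network models.

A rate model and a sparse leaky integrate-and-fire (LIF) network, each with
one excitatory (E) and one inhibitory (I) population coupled by interaction
strengths J_ab (the effect of population b on a; J_EI and J_II enter with a
negative sign).  External input is a constant plus a white-noise term;
movement-like feedforward input is a train of short pulses.  The
developmental surge of perisomatic inhibition is modelled by increasing
J_EI — the I->E weight in the rate model, the I->E in-degree in the LIF
network.  Strengthening J_EI flips the pulse response of E cells from a
peak to a trough and deepens a post-pulse undershoot, and creates a
negative excursion of the I->E cross-correlogram at positive lags.

For the noise-driven rate model linearized around its fixed point, the
stationary covariance solves the continuous Lyapunov equation and lagged
covariances follow the matrix exponential of the Jacobian, giving analytic
correlation predictions that the simulated correlograms must match.

All simulated signals are convolved with an exponential kernel of
characteristic time 2 s before comparison, to account for the slow decay of
the GCaMP6s calcium indicator; LIF activity is summarized as the fraction
of cells active per 100-ms bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import expm, solve_continuous_lyapunov

from .correlations import Correlogram, crosscorrelogram

# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class RateModelParams:
    """Two-population rate model with threshold-linear transfer.

    tau_a dr_a/dt = -r_a + phi(sum_b ±J_ab r_b + I_ext_a + pulse(t)) + noise,
    phi(x) = max(x, 0).  Defaults give a stable fixed point with positive
    rates for J_EI up to ~3 and slow (synaptic-scale) time constants.
    """

    J_EE: float = 0.4
    J_EI: float = 1.0
    J_IE: float = 1.0
    J_II: float = 0.2
    tau_E: float = 0.5
    tau_I: float = 0.5
    I_ext_E: float = 2.0
    I_ext_I: float = 0.6
    noise_sigma: float = 0.02
    pulse_amp: float = 1.0
    #: feedforward pulse gain onto the I population; movement-like drive
    #: recruits interneurons at least as strongly as pyramidal cells
    pulse_amp_I: float = 1.5
    pulse_dur_s: float = 0.4
    dt: float = 0.01
    T_s: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.tau_E, self.tau_I) <= 0:
            raise ValueError("time constants must be positive")
        if self.dt >= min(self.tau_E, self.tau_I) / 10:
            raise ValueError("dt must be < min(tau)/10 for stable integration")
        if self.pulse_dur_s <= 0:
            raise ValueError("pulse_dur_s must be positive")

    def jacobian(self) -> np.ndarray:
        """Jacobian of the linearized dynamics at an interior fixed point."""
        return np.array([
            [(self.J_EE - 1.0) / self.tau_E, -self.J_EI / self.tau_E],
            [self.J_IE / self.tau_I, -(1.0 + self.J_II) / self.tau_I],
        ])

    def fixed_point(self) -> np.ndarray:
        """Interior fixed point (r_E*, r_I*); raises if any rate is <= 0."""
        M = np.array([[1.0 - self.J_EE, self.J_EI], [-self.J_IE, 1.0 + self.J_II]])
        r = np.linalg.solve(M, [self.I_ext_E, self.I_ext_I])
        if np.any(r <= 0):
            raise ValueError(f"fixed point {r} not interior (some rate <= 0)")
        return r


@dataclass
class LIFParams:
    """Sparse LIF network with exponentially decaying postsynaptic currents.

    ``C_ab`` is the number of presynaptic b-neurons per a-neuron (fixed
    in-degree, targets drawn uniformly without replacement); ``w_ab`` the
    corresponding synaptic weight (inhibitory weights are subtracted).
    Voltage is in threshold units (V_th = 1, V_reset = 0).  Synaptic decay
    constants are slow (150 ms) to reflect immature synaptic kinetics.
    """

    N_E: int = 400
    N_I: int = 100
    C_EE: int = 40
    C_EI: int = 10
    C_IE: int = 40
    C_II: int = 10
    w_EE: float = 0.02
    w_EI: float = 0.08
    w_IE: float = 0.04
    w_II: float = 0.04
    tau_m: float = 0.02
    V_th: float = 1.0
    V_reset: float = 0.0
    tau_ref: float = 0.005
    tau_syn_E: float = 0.15
    tau_syn_I: float = 0.15
    ext_mean_E: float = 0.75
    ext_mean_I: float = 0.65
    ext_sigma: float = 0.28
    pulse_amp: float = 0.25
    pulse_dur_s: float = 0.4
    dt: float = 0.001
    T_s: float = 100.0
    bin_s: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.V_th <= self.V_reset:
            raise ValueError("V_th must exceed V_reset")
        for c, pop in ((self.C_EE, self.N_E), (self.C_IE, self.N_E),
                       (self.C_EI, self.N_I), (self.C_II, self.N_I)):
            if c > pop:
                raise ValueError("in-degree exceeds presynaptic population size")


@dataclass
class SimResult:
    """Simulation output: continuous rates or binned active-cell fractions."""

    time: np.ndarray
    rates: Optional[np.ndarray] = None        # (n_steps, 2): r_E, r_I
    bin_time: Optional[np.ndarray] = None
    active_frac: Optional[np.ndarray] = None  # (n_bins, 2): E, I fractions
    pulse_times: np.ndarray = field(default_factory=lambda: np.array([]))
    dt: float = 0.01


# ---------------------------------------------------------------------------
# GCaMP kernel
# ---------------------------------------------------------------------------

def gcamp_convolve(signal: np.ndarray, tau_s: float = 2.0, fs: float = 10.0) -> np.ndarray:
    """Causal convolution with exp(-t/tau) normalized to unit peak."""
    signal = np.asarray(signal, dtype=float)
    n_k = max(2, int(round(5 * tau_s * fs)))
    kernel = np.exp(-np.arange(n_k) / (tau_s * fs))
    return np.convolve(signal, kernel)[: len(signal)]


# ---------------------------------------------------------------------------
# rate model
# ---------------------------------------------------------------------------

def _pulse_drive(n_steps: int, dt: float, pulse_times: Sequence[float],
                 amp: float, dur_s: float) -> np.ndarray:
    drive = np.zeros(n_steps)
    for t0 in pulse_times:
        i, j = int(round(t0 / dt)), int(round((t0 + dur_s) / dt))
        drive[max(0, i) : min(n_steps, j)] += amp
    return drive


def simulate_rate(params: RateModelParams, pulse_times: Sequence[float] = ()) -> SimResult:
    """Euler–Maruyama integration of the stochastic rate equations."""
    rng = np.random.default_rng(params.seed)
    n_steps = int(round(params.T_s / params.dt))
    base_drive = _pulse_drive(n_steps, params.dt, pulse_times, 1.0, params.pulse_dur_s)
    amp = np.array([params.pulse_amp, params.pulse_amp_I])
    tau = np.array([params.tau_E, params.tau_I])
    I_ext = np.array([params.I_ext_E, params.I_ext_I])
    W = np.array([[params.J_EE, -params.J_EI], [params.J_IE, -params.J_II]])
    r = params.fixed_point().copy()
    out = np.empty((n_steps, 2))
    sqdt = np.sqrt(params.dt)
    noise = (
        rng.standard_normal((n_steps, 2)) * (params.noise_sigma * sqdt / tau)
        if params.noise_sigma > 0 else None
    )
    for s in range(n_steps):
        inp = W @ r + I_ext + amp * base_drive[s]
        r = r + params.dt / tau * (-r + np.maximum(inp, 0.0))
        if noise is not None:
            r = r + noise[s]
        r = np.maximum(r, 0.0)
        if np.any(np.abs(r) > 1e6):
            raise RuntimeError(
                f"rate model diverged at t={s * params.dt:.2f}s; "
                f"parameter regime unstable (J_EE={params.J_EE}, J_EI={params.J_EI})"
            )
        out[s] = r
    return SimResult(
        time=np.arange(n_steps) * params.dt,
        rates=out,
        pulse_times=np.asarray(pulse_times, dtype=float),
        dt=params.dt,
    )


def analytic_rate_correlation(
    params: RateModelParams,
    gcamp_tau_s: float = 2.0,
    max_lag_s: float = 10.0,
    bin_s: float = 0.1,
) -> dict:
    """Analytic correlation functions of the GCaMP-filtered linearized model.

    Returns a dict with ``lags`` (s) and correlation arrays ``EE``, ``II``,
    ``EI`` and ``IE``; ``IE[tau]`` is corr(I(t), E(t + tau)), so feedback
    inhibition shows as a negative excursion of ``IE`` at positive lags.
    """
    A = params.jacobian()
    eig = np.linalg.eigvals(A)
    if np.any(eig.real >= 0):
        raise ValueError(f"linearized system unstable (eigenvalues {eig})")
    params.fixed_point()  # validates interior regime
    sig = params.noise_sigma if params.noise_sigma > 0 else 1.0
    Q = np.diag([(sig / params.tau_E) ** 2, (sig / params.tau_I) ** 2])
    C0 = solve_continuous_lyapunov(A, -Q)

    pad = 5.0 * gcamp_tau_s
    n_half = int(round((max_lag_s + pad) / bin_s))
    lags_ext = np.arange(-n_half, n_half + 1) * bin_s
    cov = np.empty((len(lags_ext), 2, 2))
    eAdt = expm(A.T * bin_s)
    M = np.linalg.matrix_power(eAdt, 0)
    # C(tau) = E[x(t) x(t+tau)^T] = C0 expm(A^T tau) for tau >= 0
    for i in range(n_half + 1):
        cov[n_half + i] = C0 @ M
        M = M @ eAdt
    for i in range(1, n_half + 1):
        cov[n_half - i] = cov[n_half + i].T

    # GCaMP filtering multiplies the cross-spectrum by |K|^2: convolve the
    # lagged covariance with the kernel autocorrelation exp(-|tau|/tau_g)
    s_kernel = np.exp(-np.abs(lags_ext) / gcamp_tau_s)
    filt = np.empty_like(cov)
    for i in range(2):
        for j in range(2):
            filt[:, i, j] = np.convolve(cov[:, i, j], s_kernel, mode="same") * bin_s
    keep = np.abs(lags_ext) <= max_lag_s + 1e-9
    lags = lags_ext[keep]
    norm = np.sqrt(filt[n_half, 0, 0] * filt[n_half, 1, 1])
    out = {
        "lags": lags,
        "EE": filt[keep, 0, 0] / filt[n_half, 0, 0],
        "II": filt[keep, 1, 1] / filt[n_half, 1, 1],
        # EI[tau] = corr(E(t), I(t+tau)); IE[tau] = corr(I(t), E(t+tau))
        "EI": filt[keep, 0, 1] / norm,
        "IE": filt[keep, 1, 0] / norm,
    }
    return out


def empirical_rate_correlogram(
    params: RateModelParams,
    gcamp_tau_s: float = 2.0,
    max_lag_s: float = 10.0,
    bin_s: float = 0.1,
    n_reps: int = 4,
) -> dict:
    """Simulate the rate model and estimate correlograms with the data estimator.

    Runs ``n_reps`` independent simulations of length ``params.T_s`` and
    averages the per-lag correlations, reducing the finite-duration Monte
    Carlo error.  Returns the same keys as
    :func:`analytic_rate_correlation`; ``IE[tau]`` is corr(I(t), E(t+tau)).
    """
    stride = int(round(bin_s / params.dt))
    fs = 1.0 / bin_s
    burn = int(round(10 * gcamp_tau_s / bin_s))
    acc: dict[str, list[np.ndarray]] = {"EE": [], "II": [], "EI": [], "IE": []}
    lags = None
    for rep in range(n_reps):
        sim = simulate_rate(replace(params, seed=params.seed + rep))
        e = gcamp_convolve(sim.rates[::stride, 0], gcamp_tau_s, fs)[burn:]
        i = gcamp_convolve(sim.rates[::stride, 1], gcamp_tau_s, fs)[burn:]
        for key, (x, y) in {"EE": (e, e), "II": (i, i), "EI": (e, i), "IE": (i, e)}.items():
            cg = crosscorrelogram(x, y, bin_s=bin_s, max_lag_s=max_lag_s)
            acc[key].append(cg.values)
            lags = cg.lags
    out = {key: np.nanmean(np.stack(vals), axis=0) for key, vals in acc.items()}
    out["lags"] = lags
    return out


# ---------------------------------------------------------------------------
# LIF network
# ---------------------------------------------------------------------------

def _fixed_indegree(rng, n_post: int, pre_indices: np.ndarray, c: int,
                    n_total: int, weight: float) -> sparse.csr_matrix:
    """(n_total x n_total) matrix mapping presynaptic spikes to targets."""
    rows, cols = [], []
    for post in range(n_post):
        pres = rng.choice(pre_indices, size=c, replace=False)
        rows.extend([post] * c)
        cols.extend(pres.tolist())
    data = np.full(len(rows), weight)
    return sparse.csr_matrix((data, (rows, cols)), shape=(n_total, n_total))


def simulate_lif(params: LIFParams, pulse_times: Sequence[float] = ()) -> SimResult:
    """Simulate the sparse LIF network; returns 100-ms-bin active fractions."""
    rng = np.random.default_rng(params.seed)
    N = params.N_E + params.N_I
    e_idx = np.arange(params.N_E)
    i_idx = np.arange(params.N_E, N)

    W_exc = sparse.csr_matrix((N, N))
    W_inh = sparse.csr_matrix((N, N))
    if params.N_E and params.C_EE:
        W_exc += _pad_rows(_fixed_indegree(rng, params.N_E, e_idx, params.C_EE, N, params.w_EE), 0)
    if params.N_I and params.C_IE:
        W_exc += _pad_rows(_fixed_indegree(rng, params.N_I, e_idx, params.C_IE, N, params.w_IE), params.N_E)
    if params.N_E and params.C_EI:
        W_inh += _pad_rows(_fixed_indegree(rng, params.N_E, i_idx, params.C_EI, N, params.w_EI), 0)
    if params.N_I and params.C_II:
        W_inh += _pad_rows(_fixed_indegree(rng, params.N_I, i_idx, params.C_II, N, params.w_II), params.N_E)

    dt = params.dt
    n_steps = int(round(params.T_s / dt))
    drive = _pulse_drive(n_steps, dt, pulse_times, params.pulse_amp, params.pulse_dur_s)
    mu = np.concatenate([
        np.full(params.N_E, params.ext_mean_E), np.full(params.N_I, params.ext_mean_I)
    ])
    decay_E = np.exp(-dt / params.tau_syn_E)
    decay_I = np.exp(-dt / params.tau_syn_I)
    noise_scale = params.ext_sigma * np.sqrt(dt / params.tau_m)
    ref_steps = max(1, int(round(params.tau_ref / dt)))

    V = np.full(N, params.V_reset, dtype=float)
    sE = np.zeros(N)
    sI = np.zeros(N)
    ref_until = np.zeros(N, dtype=int)

    n_bins = int(np.ceil(params.T_s / params.bin_s))
    bin_stride = int(round(params.bin_s / dt))
    active = np.zeros((n_bins, N), dtype=bool)
    rate_window = int(round(1.0 / dt))
    spike_counts = np.zeros(n_steps, dtype=np.int32)

    for s in range(n_steps):
        sE *= decay_E
        sI *= decay_I
        I_total = sE - sI + mu + drive[s]
        dV = dt / params.tau_m * (-V + I_total)
        if params.ext_sigma > 0:
            dV += noise_scale * rng.standard_normal(N)
        refractory = ref_until > s
        V = np.where(refractory, params.V_reset, V + dV)
        spiked = V >= params.V_th
        if spiked.any():
            V[spiked] = params.V_reset
            ref_until[spiked] = s + ref_steps
            sp = spiked.astype(float)
            sE += W_exc @ sp
            sI += W_inh @ sp
            active[min(n_bins - 1, s // bin_stride)] |= spiked
            spike_counts[s] = int(spiked.sum())
        if s >= rate_window and s % rate_window == 0:
            pop_rate = spike_counts[s - rate_window : s].sum() / N / 1.0
            if pop_rate > 500.0:
                raise RuntimeError(f"population rate exploded ({pop_rate:.0f} Hz) at t={s*dt:.1f}s")

    frac = np.stack([
        active[:, : params.N_E].mean(axis=1) if params.N_E else np.zeros(n_bins),
        active[:, params.N_E :].mean(axis=1) if params.N_I else np.zeros(n_bins),
    ], axis=1)
    return SimResult(
        time=np.arange(n_steps) * dt,
        bin_time=(np.arange(n_bins) + 0.5) * params.bin_s,
        active_frac=frac,
        pulse_times=np.asarray(pulse_times, dtype=float),
        dt=dt,
    )


def _pad_rows(mat: sparse.csr_matrix, row_offset: int) -> sparse.csr_matrix:
    """Shift the rows of a matrix built for one postsynaptic population."""
    if row_offset == 0:
        return mat
    coo = mat.tocoo()
    return sparse.csr_matrix(
        (coo.data, (coo.row + row_offset, coo.col)), shape=mat.shape
    )


def lif_single_neuron_rate(params: LIFParams, I: float) -> float:
    """Closed-form firing rate of one LIF neuron under constant current I."""
    if I <= params.V_th:
        return 0.0
    isi = params.tau_ref + params.tau_m * np.log(
        (I - params.V_reset) / (I - params.V_th)
    )
    return 1.0 / isi


# ---------------------------------------------------------------------------
# pulse-triggered summaries
# ---------------------------------------------------------------------------

def model_pmth(
    sim: SimResult,
    window_s: float = 20.0,
    gcamp_tau_s: float = 2.0,
    population: str = "E",
    bin_s: float = 0.1,
):
    """Pulse-triggered average of the GCaMP-filtered population signal.

    For rate-model results the population rate is resampled to ``bin_s``;
    for LIF results the per-bin active-cell fraction is used directly.
    Returns ``(bin_centers, curve, baseline)`` with the window centered on
    pulse onsets, matching the peri-movement-histogram binning contract.
    """
    if len(sim.pulse_times) == 0:
        raise ValueError("simulation has no pulses")
    col = {"E": 0, "I": 1}[population]
    if sim.rates is not None:
        stride = int(round(bin_s / sim.dt))
        signal = sim.rates[::stride, col]
    else:
        signal = sim.active_frac[:, col]
        bin_s = float(np.diff(sim.bin_time[:2])[0]) if len(sim.bin_time) > 1 else bin_s
    fs = 1.0 / bin_s
    signal = gcamp_convolve(signal, gcamp_tau_s, fs)
    half = int(round(window_s / 2 * fs))
    onsets = np.round(sim.pulse_times * fs).astype(int)
    # drop pulses inside the kernel's initial transient (causal convolution
    # of a nonzero baseline ramps up over ~5 tau)
    burn = int(round(5 * gcamp_tau_s * fs))
    usable = onsets[(onsets - half >= burn) & (onsets + half < len(signal))]
    if len(usable) == 0:
        raise ValueError("no pulse has a complete window")
    windows = np.stack([signal[o - half : o + half + 1] for o in usable])
    curve = windows.mean(axis=0)
    baseline = float(curve[: half // 2].mean())
    return np.arange(-half, half + 1) / fs, curve, baseline


def pulse_response_metrics(curve: np.ndarray, bin_centers: np.ndarray, baseline: float):
    """Peak height and post-peak undershoot depth relative to baseline."""
    post = bin_centers >= 0
    peak = float(curve[post].max() - baseline)
    trough = float(baseline - curve[post].min())
    return peak, trough


def sweep_JEI(
    base: RateModelParams,
    jei_values: Sequence[float],
    n_pulses: int = 20,
    pulse_interval_s: float = 30.0,
) -> pd.DataFrame:
    """Summary table of pulse response and correlogram metrics across J_EI.

    Pulse metrics come from a noise-free simulation (deterministic); the
    positive-lag correlogram minimum comes from the analytic prediction.
    """
    if len(jei_values) < 2:
        raise ValueError("sweep needs at least two J_EI values")
    rows = []
    T = (n_pulses + 1) * pulse_interval_s
    pulses = (np.arange(n_pulses) + 0.5) * pulse_interval_s
    for jei in jei_values:
        params = replace(base, J_EI=float(jei), noise_sigma=0.0, T_s=T)
        sim = simulate_rate(params, pulse_times=pulses)
        bins, curve, baseline = model_pmth(sim, window_s=20.0)
        peak, undershoot = pulse_response_metrics(curve, bins, baseline)
        undershoot = max(0.0, undershoot)  # no excursion below baseline
        corr = analytic_rate_correlation(replace(base, J_EI=float(jei)))
        pos = corr["lags"] > 0
        rows.append({
            "J_EI": float(jei),
            "peak_response": peak,
            "undershoot_depth": undershoot,
            "undershoot_ratio": undershoot / peak if peak > 0 else np.inf,
            "corr_min_pos_lag": float(corr["IE"][pos].min()),
        })
    return pd.DataFrame(rows)
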