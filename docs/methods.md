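# Methods

This note documents the models, statistical procedures, and design choices
behind `pupdyn`, in the order the analysis runs.

## Activity rasters and session bundles

The central substrate is a binary matrix `activity[c, f]` that is 1 exactly
when frame `f` lies in the closed `[onset, peak]` interval of a calcium
transient of cell `c`.  Frame indexing is 0-based; intervals are closed
because a neuron is treated as active from transient onset to peak.
Overlapping transients within a cell are merged with a logged warning.
The frame rate is carried as data (default 10 Hz, matching the convention
that 5 frames = 500 ms in the synchrony-merge rule) rather than hard-coded,
since acquisition rates vary slightly between sessions.  Cells labelled
`noise` by upstream classification are dropped at load time.  Bundles are
directories of CSV tables plus `meta.json`, chosen over a binary container
so that fixtures stay human-readable and bit-exact under round-trip.

## Synchronous calcium events (SCEs)

Chance synchrony is estimated by circularly shifting each cell's activity
row by an independent uniform amount in `[1, n_frames - 1]` (never 0, so a
surrogate row never equals the original; row sums and transient durations
are conserved exactly).  The detection threshold is the 99th percentile of
the per-frame co-active counts **pooled over all 300 surrogates** — the
pooled form is the stationary interpretation when no per-frame structure
survives shifting.  SCE frames are strict local maxima of the observed
co-active count above threshold; plateaus resolve to their first frame, and
peaks closer than 5 frames are merged keeping the larger count (earlier
frame on ties).  The merge rule is a declared convention.  "Co-active"
counts cells active at the frame (any frame of the onset→peak interval),
following the binary-raster definition of activity.

Expected calibration: on independent-cell null rasters the flagged-frame
fraction is at or slightly below the nominal 1% — below because co-active
counts are discrete, so the strict `> threshold` rule loses mass to ties.

## Peri-movement time histograms

A 20-s window is centered on each movement onset; the per-frame signal is
either the number of active cells or the summed dF/F.  Bins are single
imaging frames.  Per bin, the 25th/median/75th percentiles over movements
are divided by the number of cells and scaled to %.  The surrogate envelope
is built from 500 whole-raster circular shifts: each surrogate contributes
its median PMTH, and the envelope is the 5th/median/95th percentile of
those medians per bin.  Group-level PMTHs stack session medians and take
per-bin 25th/median/75th percentiles; surrogate envelope curves are
combined as per-bin medians across sessions.  Movements whose window
exceeds the session bounds are dropped (logged), not padded.  Significant
activation (suppression) is a median above the 95th (below the 5th)
surrogate percentile.

## Movement-related inhibition

For each movement, the post-movement activity ratio is the number of cells
with at least one active frame in the 2 s from onset (the onset frame
belongs to the post window — declared convention) divided by the number of
cells active anywhere in the 4-s window centered on onset.  Movements with
no active cell in the window are skipped.  A movement is *inhibiting* when
the ratio is strictly below 0.40 ("less than 40%"), and the per-animal
statistic is the proportion of inhibiting movements.  All movement
categories are pooled by default, with an optional category filter.

## Epoch-associated cells

Per cell, the observed count of transient onsets inside the epoch set
(movement or immobility frames) is compared with the 99th percentile of the
counts from 100 circular shifts of that cell's own onsets (onset-only
shifts, not whole-interval shifts).  The cell is flagged when strictly
above.  Cells without transients are never flagged.  With only 100 shifts
and discrete counts the realized false-positive rate sits at or below 1%.

## Trend fits

Linear and fourth-order polynomial fits use ordinary least squares; the
sigmoid `bottom + (top - bottom)/(1 + exp(-k (x - V50)))` is fit by
multi-start bounded least squares (start grid over the x-quartiles for V50
and slopes 0.5–5), keeping the best r².  Constant data returns a flat fit
with r² = 0 by convention.

## Immobility correlograms

Population signals are per-frame fractions of active cells of one type.
The estimator is the Pearson correlation at each integer-frame lag over
pairs `(t, t + k)` whose two frames lie in the same contiguous immobility
segment — pairs straddling a movement gap are dropped, avoiding spurious
long-lag structure.  Lags with fewer than 10 valid pairs are reported
missing.  The same estimator is applied to model output, so the
model-to-data comparison is internally consistent.  No normalization or
binning convention for the correlogram is inherited from elsewhere; the
estimator above is the package's declared choice, used uniformly.

## Two-population models

**Rate model.**  `tau_a dr_a/dt = -r_a + φ(Σ_b ±J_ab r_b + I_ext_a +
pulse(t)) + noise`, with threshold-linear φ, Euler–Maruyama integration,
and rates clipped at zero.  The transfer function is threshold-linear so
that, in the small-fluctuation regime around an interior fixed point, the
linearization is exact and correlation predictions are analytic.  Default
parameters (τ = 0.5 s, J_EE = 0.4, J_IE = 1.0, J_II = 0.2, external drives
2.0/0.6) are the package's own choices, selected for a stable interior
fixed point across the J_EI sweep (0–3), slow synaptic-scale time constants,
and the weak-versus-strong-inhibition contrast; no parameter table is
inherited.  The feedforward pulse drives both populations, the I population
1.5× more strongly — movement-like input recruits interneurons at least as
strongly as pyramidal cells — which is what lets strong J_EI flip the E
response from a peak to a trough.

**Analytic correlations.**  With Jacobian `A` and noise covariance
`Q = diag((σ/τ_a)²)`, the stationary covariance `C0` solves
`A C0 + C0 Aᵀ + Q = 0` (continuous Lyapunov equation) and lagged
covariances follow `C(τ) = C0 exp(Aᵀ τ)` for τ ≥ 0, mirrored by transpose
for τ < 0.  Indicator filtering multiplies the cross-spectrum by |K(ω)|²,
implemented as convolution with the kernel autocorrelation
`exp(-|τ|/τ_g)`, then normalization to correlation.  The empirical check
averages correlograms over four independent 2000-s simulations to reduce
Monte Carlo error below the 0.05 comparison band.

**LIF network.**  Fixed in-degree connectivity (presynaptic partners drawn
uniformly without replacement), exponentially decaying postsynaptic
currents (τ_syn = 150 ms, slow to match immature synaptic kinetics),
membrane τ_m = 20 ms, threshold units V_th = 1, V_reset = 0, 5-ms
refractory period, white-noise external drive standing in for fast
dynamics the calcium indicator cannot follow.  J_EI is manipulated as the
number of I→E connections (in-degree), versus the weight in the rate
model.  Output is the fraction of cells with ≥ 1 spike per 100-ms bin.
Default weights keep the network stable and movement-responsive for C_EI
between ~5 and ~20; very large C_EI silences the excitatory population.

All simulated signals are convolved with a causal exponential kernel of
characteristic time 2 s (unit peak) before any comparison, emulating
GCaMP6s decay.  Post-pulse undershoot depth is measured on the filtered
pulse-triggered average and clipped at zero; because the GCaMP kernel
low-passes the dynamics, the *absolute* undershoot saturates and can shrink
again at very strong inhibition even as the analytic correlogram undershoot
keeps deepening — the sweep table reports both.

## EMG vigilance scoring

Downsample to 1 kHz, high-pass at 300 Hz (zero-phase Butterworth), rectify.
Five 1-s representative windows of high and of low tone define the midpoint
(wake at or above) and quarter point (active sleep below; transition
between), applied to 1-s bin averages.  Twitches are samples above the mean
+ 5 SD of the pooled low-tone windows inside active-sleep bins, grouped
into events when closer than 50 ms (a rectified oscillatory trace dips
below threshold within a single twitch; the 50-ms gap is the declared
grouping rule replacing manual inspection).  Degenerate thresholds (high
tone not above low tone) raise an error.

## Sharp-wave detection

LFP preprocessing downsamples to 1 kHz, band-passes 2–100 Hz with a
zero-phase Butterworth filter — used here as the band-pass behind the
wavelet-filter description, and verified by its frequency response (gain
> 0.7 at 50 Hz, < 0.1 at 200 Hz) — and subtracts the per-timepoint channel
mean.  Detection band-passes 2–45 Hz, forms the SR − SO difference, and
takes candidate peaks above 4 SD of the whole trace.  A candidate is kept
when (1) SO and SR deflect with opposite signs at the peak, (2) |SP| stays
below half the smaller layer deflection (the operational reversal test),
and (3) it is the largest deflection within 300 ms — band-passing a
transient imprints flanking ripples, and the dominance window rejects them.
Events are ≥ 100 ms apart; the rate is normalized to 1 min.  Co-occurrence
is the histogram of contra-minus-ipsi time differences in 10-ms bins.

## Image quantification

**Syt2 coverage.**  Max-intensity projection of the top 6 µm, rolling-ball
background removal, subtraction of the mean of a user-supplied background
ROI (clipped at zero), binarization with Kapur's maximum-entropy threshold
(implemented directly on the histogram: the level maximizing the sum of
below- and above-threshold Shannon entropies), connected components, and
retention of particles with area in [0.4, 4] µm².  Coverage is retained
area over analyzed area.  The histogram-based threshold makes coverage
invariant to global intensity scaling.

**Axon pipeline.**  A 3-D Gaussian-smoothed, time-averaged summary image is
histogram-equalized, smoothed, adaptively thresholded (block 51 px, offset
0 — exposed in the API), and thinned to a skeleton (2-D thinning of the 2-D
summary).  Two guards handle noise: foreground must also stand out of the
*pre-equalized* summary at Otsu's level, and the Otsu split must separate
foreground from background by at least 4 background standard deviations
(pure-noise fields fail this and yield no branches).  Branches are skeleton
segments split at junction pixels (> 2 neighbors); a junction where exactly
two segments meet is a thinning staircase artifact and the pair is merged,
while true ≥ 3-way branch points stay split.  Branch validation computes
the sample skewness of pixel intensities along the branch at the frame of
its largest smoothed-trace excursion (the declared reading of "during a
calcium transient"; pooling all super-threshold frames is a noted
alternative), keeping branches with |skewness| ≤ 1 (default cutoff, not
inherited); pixels within 2 px of the branch tips are excluded because the
point-spread function dims tips of even uniformly lit branches; constant
branches have skewness 0 by convention; branches under 5 px are rejected.
Clustering uses 1 − Spearman ρ distances, a t-SNE embedding (perplexity
clipped to the sample count) and HDBSCAN; with ≤ 4 branches single-linkage
on the distances replaces the embedding, and identical traces
short-circuit to one cluster; unassigned branches become singletons.

## Synthetic data: what it emulates and what it does not

The session generator reproduces the statistical structure the analyses
assume: per-cell Bernoulli transient-onset hazards (≈ Poisson at 1
transient/min for pyramidal cells; interneurons fire ~4× more often,
matching their several-fold higher baseline active fractions), SCE bursts
as synchronized onsets in a random 25% of cells, onset-to-peak rises of
0.2–0.5 s, movement epochs as a Poisson process (3/min) with log-normal
durations (μ = log 0.4 s, σ = 0.8 — the duration law's parameters are
exposed, defaults are the package's choice; draws under 2 s are twitches,
longer draws complex movements), and dF/F as the raster convolved with the
2-s exponential kernel plus white noise.

Movement coupling is a multiplicative hazard gain inside the 2-s
post-onset window.  Interneurons keep a constant gain (2.5) at all ages.
The pyramidal gain moves from 6 (activation) to 0.05 (suppression) as age
crosses the switch age (default P9), interpolated on the log-gain scale —
hazards are multiplicative, so log-space is the symmetric parameterization
— through a sigmoid of age with scale 0.35 days, i.e., a transition
essentially complete within ~2 days rather than a hard step: a step
between integer ages would make the designed switch age unidentifiable to
within a day.  After the switch an explicit feedback term also suppresses
the pyramidal hazard by `exp(-β w(age) · interneuron active fraction)`
delayed by 0.3 s (β = 10), modeling di-synaptic perisomatic inhibition.
This term is what gives post-switch sessions the asymmetric
interneuron→pyramidal correlogram (negative excursion at positive lags
only) and, as a side effect, a dip in overall pyramidal event frequency
around the switch age.

Defaults (200 pyramidal cells, 10 interneurons, 10 min at 10 Hz) put the
pre-switch pyramidal PMTH baseline near 0.7% with peaks 4–7× baseline, the
pre-switch inhibiting-movement proportion near 0, and the post-switch
proportion near 45% — the regime the analyses were designed for.

What the generator does **not** emulate: spatial cell arrangement, sensor
nonlinearity and saturation, slow drift and motion artifacts, correlated
noise across cells, behavioral state structure beyond the movement
process, and any pyramidal→interneuron coupling.  Passing tests therefore
demonstrate that the analysis chain recovers designed effects of realistic
size under clean statistical assumptions — not that it is robust to every
artifact of real recordings.

## Problem sizes

The test suite and the acceptance script run at desk scale by design:
50 null rasters of 100 × 5000 frames for calibration; 24 sessions
(8 ages × 3 animals) for switch recovery; three sessions per group for
PMTHs with 500 surrogates; 4 × 2000 s of rate-model simulation for the
correlation comparison; a 20-s LIF single-neuron run at dt = 0.1 ms and
~200-s network runs at dt = 1 ms; 4-min LFP and 5-min EMG records; 64–96 px
image phantoms.  Circular-shift surrogate counting uses a run-length
difference-array algorithm (O(total transients) per surrogate instead of
O(cells × frames)), which is what keeps 15 000 surrogate rasters cheap.

## Known limitations

- The NWB:N reader is not implemented; sessions enter through the CSV
  bundle dialect.
- Rate-model and LIF parameters are package defaults satisfying the
  qualitative contracts, not a published parameter table.
- The Morlet-wavelet band-pass is realized as an equivalent zero-phase
  Butterworth filter, verified by frequency response only.
- The sigmoid fit can place V50 slightly off the designed switch age when
  the proportion curve saturates asymmetrically; across seeds the recovery
  stays within ±0.5 days under the default design.
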