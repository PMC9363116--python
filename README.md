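# pupdyn — population dynamics of the developing hippocampus

`pupdyn` re-implements, as a tested and reusable Python package, the
population-dynamics analyses and network models used to characterize how
the neonatal mouse CA1 region *disengages* from self-motion at the end of
the first postnatal week.  In two-photon calcium imaging of non-anesthetized
pups (P5–P12), spontaneous movements initially *activate* CA1 pyramidal
cells; around P9 this coupling flips sign and movements *suppress*
pyramidal activity, while GABAergic interneurons remain movement-activated
throughout.  A two-population excitatory/inhibitory model reproduces the
flip by strengthening the inhibition-onto-excitation coupling J_EI — the
developmental surge of perisomatic (parvalbumin-basket-cell) innervation.

The package covers the full analysis chain on binary activity rasters
(cells × frames, a neuron is active from the onset to the peak of each
calcium transient), plus the supporting electrophysiology and histology
quantifications:

- **Synchrony** (`pupdyn.events`): synchronous calcium events (SCEs) are
  frames where the number of co-active cells exceeds the 99th percentile of
  co-active counts pooled over 300 circular-shift surrogate rasters; peaks
  closer than 5 frames (500 ms) are merged.  Per-cell transient-in-SCE
  ratios and transient frequencies quantify the discontinuous-to-continuous
  transition.
- **Movement coupling** (`pupdyn.coupling`): peri-movement time histograms
  (PMTH; 20-s window, per-frame % of active cells, 25th/median/75th
  percentiles over movements) with a 5th/median/95th surrogate envelope from
  500 shuffles; *post-movement activity* (cells active in the 2 s after
  onset ÷ cells active in the 4-s window centered on onset); movements with
  a ratio < 40% are *inhibiting* movements; movement/immobility-associated
  cells via 100 circular shifts of transient onsets at the 99th percentile;
  linear / fourth-order polynomial / sigmoid developmental trend fits
  (the sigmoid `y = bottom + (top-bottom)/(1 + exp(-k (x - V50)))` reports
  V50, the age of half-maximal transition).
- **Correlations** (`pupdyn.correlations`): Pearson cross-correlograms of
  cell-type population signals restricted to immobility, segment-aware so
  no lag pair straddles a movement gap.  Feedback inhibition appears as a
  negative excursion of the interneuron→pyramidal correlogram at positive
  lags.
- **E/I models** (`pupdyn.eimodel`): a threshold-linear rate model
  `tau_a dr_a/dt = -r_a + φ(Σ_b ±J_ab r_b + I_ext + pulse(t)) + noise` and
  a sparse LIF network with exponentially decaying postsynaptic currents;
  analytic correlation predictions from the Lyapunov equation of the
  linearized dynamics; movement-like pulse inputs; a `sweep_JEI` summary of
  peak response, post-pulse undershoot, and correlogram minimum.  All model
  signals pass through an exponential GCaMP6s kernel (τ = 2 s); LIF
  activity is summarized as the fraction of cells active per 100-ms bin.
- **Ephys** (`pupdyn.ephys`): EMG vigilance scoring (1-s bins, midpoint /
  quarter-point thresholds from five representative 1-s windows per tone
  condition, twitches above mean + 5 SD of the low tone), LFP preprocessing
  (1 kHz, 2–100 Hz zero-phase band-pass, common reference), early-sharp-wave
  detection (4 SD on the SR−SO difference with a polarity-reversal test at
  the pyramidal layer), and 10-ms-bin inter-hemispheric co-occurrence.
- **Imaging** (`pupdyn.imaging`): synaptotagmin-2 bouton coverage of the
  pyramidal layer (max projection of the top 6 µm, background subtraction,
  Kapur max-entropy threshold, particles of 0.4–4 µm²) and an axon pipeline
  (skeletonize a movie summary, split branches at junctions, validate by
  pixel-skewness uniformity, cluster branch traces with 1 − Spearman ρ,
  t-SNE and HDBSCAN).
- **Synthetic data** (`pupdyn.synthetic`): seeded generators for sessions
  (baseline transient hazards, SCE bursts, log-normal movement durations,
  age-dependent movement coupling with a configurable switch age and
  interneuron→pyramidal feedback), EMG, multi-layer LFP, axon movies and
  bouton phantoms — every generator returns its ground truth, so each
  analysis stage is testable end to end without external data.

Session bundles are directories of plain CSV tables plus `meta.json`
(`pupdyn.core.save_session` / `load_session`); reading NWB:N archives
directly is not required for any functionality here.

## Worked example

```python
from pupdyn import (SessionDesign, generate_session, detect_sces,
                    transients_in_sce_ratio, transient_frequency,
                    inhibiting_movement_proportion, pmth_session)

for age in (6, 12):
    b = generate_session(SessionDesign(seed=1), age_days=age)
    sce = detect_sces(b.raster, seed=1)
    _, in_sce = transients_in_sce_ratio(b.raster, sce)
    _, freq = transient_frequency(b.raster)
    prop = inhibiting_movement_proportion(b)
    p = pmth_session(b, n_surrogates=500, seed=1, cell_type="pyramidal")
    post = (p.bin_centers >= 0) & (p.bin_centers <= 2)
    print(f"P{age}: threshold={sce.threshold:.0f} cells, n_SCEs={len(sce.sce_frames)}, "
          f"in-SCE ratio={in_sce:.2f}, freq={freq:.2f}/min, inhibiting={prop:.2f}, "
          f"PMTH peak={p.median.max():.1f}%, "
          f"above/below chance = {(p.median[post] > p.surrogate_p95[post]).sum()}"
          f"/{(p.median[post] < p.surrogate_p5[post]).sum()} of {post.sum()} bins")
```

prints

```
P6:  threshold=8 cells, n_SCEs=79, in-SCE ratio=0.41, freq=2.04/min, inhibiting=0.00, PMTH peak=5.0%, above/below chance = 20/0 of 21 bins
P12: threshold=6 cells, n_SCEs=23, in-SCE ratio=0.38, freq=1.34/min, inhibiting=0.30, PMTH peak=1.0%, above/below chance = 0/20 of 21 bins
```

The P6 session is burst-dominated and every post-onset PMTH bin sits above
the surrogate 95th percentile (movement activates pyramidal cells); the P12
session shows fewer synchronous events, 30% inhibiting movements, and a
PMTH below the 5th percentile after movement onset — the developmental
sign flip.

A `pupdyn` console command exposes the same stages from the shell
(`pupdyn simulate`, `sce`, `pmth`, `inhib`, `epoch-cells`, `xcorr`,
`trend`, `model-sweep`).

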