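# calimetry

Analysis engine for multi-well calcium-imaging experiments on cultured
neurons (e.g. hiPSC-derived cultures expressing GCaMP6s or jRCaMP1b).
Given time-lapse fluorescence videos, ROI label masks and a plate map, it
produces per-cell ΔF/F₀ traces, deconvolved activity, calcium-event
features, network correlation, and — for all-optical experiments —
optogenetically evoked-response statistics. It also ships the standard
instance-segmentation evaluation metrics (Dice, PQ, SoftPQ, mAP) for
benchmarking the masks fed into it, and a synthetic-data generator with
full ground truth so every stage of the pipeline can be validated without
a microscope.

## What it computes

For each ROI *i* with raw trace *F*:

* **Baseline and ΔF/F₀** — F₀(t) is the 10th percentile of *F* over a
  sliding window centred on *t* (default 30 s); ΔF/F₀ = (F − F₀)/F₀.
* **Deconvolution** — the calcium kernel is AR(1): c_t = γ·c_{t−1} + s_t
  with s_t ≥ 0. The denoised trace is the unique minimizer of
  ½·Σ(c_t − y_t)² + λ·Σ s_t subject to those constraints, solved exactly
  by a pool-adjacent-violators forward pass (the OASIS active-set scheme).
  γ is estimated per ROI from low-lag autocovariances, and the noise σ
  from the high-frequency half of the power spectrum.
* **Events** — peaks on the denoised trace filtered by height (either
  k·σ per ROI or a global absolute value), topographic prominence
  (k_p·σ) and a minimum inter-peak distance; per-ROI features: event
  frequency, inter-event intervals, amplitudes, cell size, % active.
* **Network** — pairwise Pearson correlation of denoised ΔF/F₀, full
  recording or restricted to stimulation epochs (±250 ms around each
  pulse) vs their complement, with stimulated-first sorting and
  within-group medians.
* **Evoked activity** — ROIs are "stimulated" when >10% of their area
  overlaps the stimulation mask; peaks within a five-frame window after a
  pulse onset are "evoked" (binary-search matching); LED power maps to
  irradiance through linear / quadratic / exponential / power-law /
  logarithmic calibrations; evoked amplitudes are summarized as
  mean ± SEM per irradiance level and ROI class.
* **Segmentation metrics** — binary-foreground Dice; PQ = Σ IoU /
  (TP + ½FP + ½FN) at IoU > 0.5; SoftPQ with sublinear partial credit for
  overlaps between 0.05 and 0.5; score-free mAP averaged over IoU
  thresholds 0.50:0.05:0.95.

## Worked example

Simulate a two-condition plate (spontaneous rates 0.05 vs 0.15 Hz, 20
cells per field of view, 120 s at 10 Hz) and run the full pipeline:

```python
from calimetry import (AnalysisConfig, Condition, PlateMap, SimParams,
                       analyze_experiment, simulate_plate)

conditions = {
    "control": SimParams(duration_s=120.0, spike_rate_hz=0.05),
    "hyperexcitable": SimParams(duration_s=120.0, spike_rate_hz=0.15),
}
recordings, well_conditions, truth = simulate_plate(
    conditions, wells_per_condition=2, fovs_per_well=2, seed=7
)
plate_map = PlateMap({w: Condition(c) for w, c in well_conditions.items()})
results, features = analyze_experiment(recordings, plate_map, AnalysisConfig())

print(features.groupby("condition")[["event_frequency_hz",
                                     "amplitude_mean"]].mean().round(4))
first = results[0]
print(f"median pairwise r = {first.correlation.median_all:.3f}")
```

prints

```
                event_frequency_hz  amplitude_mean
condition
control                     0.0482          1.0549
hyperexcitable              0.1474          1.1436
median pairwise r = -0.015
```

The recovered mean event frequencies (0.048 and 0.147 Hz) sit within a few
percent of the generative rates, the mean amplitudes are close to the unit
ΔF/F₀ transient the generator emits (slightly above 1 because coincident
spikes stack), and the near-zero median correlation reflects cells spiking
independently (no shared network drive in this simulation).

The same chain is available from the shell:

```bash
calimetry simulate --params params.yaml --out exp/
calimetry analyze exp/ --plate-map map.yaml --out out/
calimetry segeval --pred pred_masks/ --ref ref_masks/ --out scores.csv
```

`analyze` writes one long-format CSV per feature plus a combined table and
per-FOV correlation matrices/heatmaps; `segeval` scores predicted vs
reference label masks (per image, plus mean and SD rows).

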