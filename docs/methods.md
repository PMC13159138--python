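# Methods

This note documents the models, conventions and numerical choices behind
calimetry, in the order the pipeline applies them, and states what the
synthetic benchmark does and does not establish.

## Trace extraction and ΔF/F₀

Per-ROI raw traces are the arithmetic mean of the video over the ROI's
pixels (the standard statistic for somatic ROIs; median or sum would
change amplitudes, not timing). The baseline F₀(t) is a low percentile of
the raw trace over a sliding temporal window:

* **Window alignment** — centred on *t*, shrinking at the recording
  edges (for even lengths the extra frame falls on the left). A trailing
  window would bias the first seconds of short in-vitro recordings; edge
  shrinkage avoids padding artefacts. Configurable.
* **Window length** — default 30 s × frame rate (300 frames at 10 Hz):
  long relative to an indicator transient (~1 s decay for GCaMP6s), short
  relative to slow drift, so the percentile tracks drift without tracking
  activity.
* **Percentile** — default 10th, computed by linear interpolation
  between order statistics at rank p/100·(n−1). The rule is pinned so the
  computation is bit-reproducible and the test oracle can re-derive it
  independently.
* **Degenerate baselines** — ΔF/F₀ divides by F₀, so ROIs whose baseline
  falls below ε = 10⁻⁶ × the median raw intensity are excluded from the
  field of view (and reported) rather than aborting the analysis.

ΔF/F₀ is scale-equivariant (multiplying the video by k > 0 leaves it
unchanged) and the baseline is shift-equivariant; both are property-tested.

## Noise and kernel estimation

The measurement noise σ of each ΔF/F₀ trace is estimated from the mean
one-sided power spectral density over the 0.25–0.5 band of the sampling
frequency (Welch segments of length min(256, T), Hann window): calcium
kernels at 10–20 Hz are essentially low-pass, so the high band reflects
white noise alone, and σ = √(mean PSD / 2).

The AR(1) coefficient γ is fitted from the autocovariance recursion
acov(k+1) = γ·acov(k) by least squares over lags 1–3. Lags ≥ 1 are
unbiased under white measurement noise; the zero-lag term (which the
noise inflates by σ²) is used only as a detectability guard — if the
noise-corrected signal variance acov(0) − σ² is below 5% of the total
variance the trace carries no fittable autocorrelation and γ = 0 is
returned with a warning. An alternative estimator, acov(1)/(acov(0) − σ²),
was rejected: for sparse transients the PSD σ̂ absorbs some transient
power, the corrected variance is underestimated, and γ̂ saturates at the
clamp. Estimates are clamped to [0, 0.99]; a config option pools γ per
field of view (median over ROIs) for very short or sparse recordings.

## Deconvolution

Denoising solves

  min_c ½·Σ (c_t − y_t)² + λ·Σ s_t  s.t. s_t = c_t − γ·c_{t−1} ≥ 0, s_0 = c_0 ≥ 0

by the online active-set (pool-adjacent-violators) scheme: the L1 term is
absorbed into the target, each frame opens a unit pool, adjacent pools
merge while the inter-pool constraint is violated, and negative pool
heights are clamped to zero on output. The program is strictly convex, so
the minimizer is unique; the test suite certifies exactness against an
exhaustive active-set enumeration (all 2^T constraint patterns) on short
random traces to < 10⁻⁶.

λ defaults to 0 — downstream peak detection does the thresholding — with
a noise-constrained mode that bisects λ until the residual norm reaches
σ√T. AR order is fixed at 1, matching slow indicators at 10–20 Hz; AR(2)
rise dynamics are out of scope.

## Event detection and features

Peaks are detected on the **denoised** trace. Conventions, all pinned for
determinism and mirrored by the brute-force reference detector:

* candidate peaks are strict local maxima; a plateau of equal values
  counts once, at its **first** frame;
* height threshold: k_h·σ per ROI (default k_h = 3) or a global absolute
  value; prominence threshold: always k_p·σ (default k_p = 2, unlimited
  window);
* minimum inter-peak distance is enforced greedily in descending
  amplitude, the **earlier** frame winning exact ties;
* filters apply in the order height → prominence → distance.

Amplitude is the denoised ΔF/F₀ value at the peak frame (prominence is
only a filter). Frequency = count/duration; IEIs are successive
peak-frame differences over the frame rate; a cell is *active* when it
has ≥ 1 detected event — the simplest consistent definition behind
"percentage of active cells". Frame indices are 0-based and time in
seconds is frame/rate throughout.

## Network correlation

Pearson correlation between denoised ΔF/F₀ traces of the same field of
view, optionally over an epoch mask. The ±250 ms stimulation epoch maps
to frames by **ceiling** (never dropping a stimulus-adjacent frame at
10 Hz, where 2.5 frames is ambiguous) and is centred on pulse onset.
Epoch correlations require ≥ 10 frames. Constant ROIs over the selection
are excluded and listed. Summary medians use upper-triangle off-diagonal
entries only; with stimulated/non-stimulated labels the matrix is sorted
stimulated-first and group medians come from the within-group diagonal
blocks, matching the block structure of sorted correlation heatmaps.

## Evoked activity

A ROI is *stimulated* iff strictly more than 10% of its pixels fall in
the stimulation mask (no morphological preprocessing — the mask is taken
as provided). A peak is *evoked* iff a pulse onset p satisfies
p ≤ f ≤ p + 4 (the onset frame is the first of the five-frame window,
since at 10 Hz a 100 ms pulse spans the onset frame where the rise
begins; the window is configurable). The preceding pulse is located by
binary search; a peak inside two overlapping windows is attributed to the
later pulse (the nearest preceding cause). All qualifying peaks are
labelled — no first-peak-per-pulse constraint is enforced.

LED calibrations: linear, quadratic and logarithmic are linear least
squares; power-law is closed-form log-log regression; the exponential
a·e^(bx) + c profiles b (for fixed b, a and c are a linear solve) over a
coarse grid plus bounded refinement, then polishes with full nonlinear
least squares. Irradiance-response tables group evoked amplitudes by the
exact irradiance of the attributed pulse (discrete power steps; binning
is available for continuous calibrations) and report n, mean, and SEM
(sample SD / √n; undefined for n = 1).

## Segmentation metrics

* **Dice** is binary-foreground 2|P∩R|/(|P|+|R|); an instance-mean
  variant is available behind a flag.
* **Matching** pairs instances at IoU strictly above the threshold,
  greedily by descending IoU; at thresholds ≥ 0.5 this equals the unique
  one-to-one matching.
* **PQ** = Σ IoU/(TP + ½FP + ½FN) at threshold 0.5, with the SQ·RQ
  factorization.
* **SoftPQ** — partial matches (low < IoU ≤ high, defaults 0.05/0.5;
  predictions single-use, references reusable so fragmented references
  get credit) contribute √(IoU·high) to the numerator — the geometric
  mean of the pair's IoU and the hard threshold: sublinear in IoU and
  continuous with the full-match credit at IoU = high — and one unit to
  the denominator. With low = high it reduces to PQ bit-exactly; on pure
  under-segmentations it exceeds PQ, which is the verifiable contract of
  the score.
* **mAP** — label masks carry no confidence scores, so AP at each
  threshold is TP/(TP+FP+FN), averaged over 0.50:0.05:0.95 (configurable).
* Two empty masks score 1.0 on every metric; set summaries report the
  mean and **population** SD (ddof = 0) per metric.

## Synthetic data

The generator emulates widefield recordings of indicator-expressing
cultures: non-overlapping disk somata (rejection sampling on a jittered
grid, deterministic under the seed), Poisson spontaneous spiking
optionally mixed with a shared network drive (mixing preserves the
per-cell expected rate), AR(1) calcium with γ = exp(−Δt/1 s) by default
(mimicking GCaMP6s decay at 10 Hz and matching the deconvolution model,
so noiseless recovery is exact), fluorescence
F = baseline·(1 + a·c) + drift·sin(2πt/period) + N(0, σ²), clipped at
zero. The single slow sinusoid (90 s period, 5% of baseline) is the
simplest drift that defeats a global-percentile baseline and so
exercises the sliding window. An optional refractory gap thins
spontaneous spikes closer than a set number of frames — used when exact
event recovery is the question, which is only well-posed for isolated
spikes.

Evoked mode adds pulse-locked spikes: cells inside the stimulation box
respond with higher probability and gain than cells outside (network
propagation), with a saturating irradiance dependence
irr/(irr + half-sat); defaults place half-saturation at 16 mW cm⁻² so
responses flatten within a 4–100 mW cm⁻² sweep. The stimulation box
boundary can be placed between cell-grid rows so that the >10% overlap
rule resolves every cell unambiguously.

Default conditions (10 Hz, 20 cells, 120 s, 0.1 Hz spiking, unit ΔF/F₀
transients on 100 counts of baseline with σ = 2 counts) are desk-scale:
one field of view simulates and analyzes in seconds on one CPU.

**What the benchmark shows — and does not.** Passing tests establish
that the implementation recovers the generative parameters of data that
obey its own model (AR(1) kernel, white noise, disk ROIs, perfect
segmentation). Real recordings add photobleaching, neuropil and motion
contamination, indicator nonlinearity, segmentation errors and
non-Poisson burst statistics, none of which the generator emulates; the
synthetic results bound what the algorithms can do, not what any given
culture will yield. Two further intrinsic limits: a spike in the first
or last frame of a recording produces no local maximum and cannot be
detected, and events closer than the peak-distance constraint merge.

## Problem sizes

The test suite and acceptance script use 96×96-pixel fields of view with
20 cells and 120–140 s recordings, 2 wells × 2 FOVs per condition for
plate-level checks, 100–500 random traces per oracle sweep, and
exhaustive enumeration up to length-8 traces for the deconvolution
oracle — sizes at which every check runs in seconds while the oracles
remain tractable.
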