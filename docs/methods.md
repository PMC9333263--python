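# Methods

This note documents the models, conventions, numerical choices and
limitations of the `voicegate` pipeline, and what the synthetic generator
does and does not emulate.

## Conventions

All sample indices are 0-based. All analysis windows are half-open
`[start, end)` in milliseconds relative to stimulus onset, applied uniformly
across epoching, baselines, onset/sustained means and decoding windows. At
the 100 Hz HGA rate each sample is labelled by the start of its 10 ms bin;
the post-offset clip keeps bins starting up to and including `offset+900` ms
so the last sliding decoding window of the standard grid (centers −50…1,500
ms for VL, −50…2,450 ms for NatS) always contains data.

## Preprocessing

* **Re-referencing.** Common average reference (CAR): the instantaneous
  across-channel mean is subtracted. CAR is idempotent and removes
  common-mode noise exactly, but with small channel counts it leaks a
  fraction of the mean evoked response into every channel (−1/n of the summed
  responses). Real montages have 50–250 contacts, where the leak is
  negligible; the synthetic test cohorts have ~6, so ground-truth-recovery
  tests run the chain without CAR and exercise CAR separately on its own
  contract (common-mode rejection, idempotence).
* **Epochs.** −1,000 ms to offset + 1,450 ms (VL) or offset + 1,000 ms
  (NatS). With half-open windows a NatS epoch has exactly 4,000 samples at
  1 kHz.
* **Normalization.** Per channel, mean/SD pooled over the prestimulus samples
  of *all* trials (not per trial), then applied to whole epochs. The same
  pooled convention is used for per-band amplitude normalization; band
  statistics are per channel (pooling across channels is a documented
  alternative the data do not force).
* **Filter bank.** 8 Butterworth bandpass filters of order 6, applied
  forward-and-reverse (`sosfiltfilt`), i.e. zero-phase with an effective
  order of 12 — the standard reading of a "sixth order" zero-phase design.
  Centers form a geometric progression 70→150 Hz, bandwidths 16→64 Hz; band
  *i* spans center ± bandwidth/2. Band edges must stay below Nyquist.
* **Baseline for band z-scoring.** The earliest 100 ms of the prestimulus
  span are discarded (filter edge effects), as are the 100 ms immediately
  before onset (low-latency response contamination), leaving [−900, −100) ms.
  No extra padding is applied beyond the 1,000 ms prestimulus span itself.
* **Downsampling.** Mean over consecutive non-overlapping 10-sample bins of
  the 1 kHz amplitude series. The amplitude is non-negative and slowly
  varying, so bin-averaging is an adequate anti-alias choice and preserves
  window means exactly on bin boundaries.

## Inference machinery

* **Cluster permutation test.** Per-window critical values are percentiles of
  that window's permutation null (`numpy.quantile`, linear interpolation);
  clusters are maximal suprathreshold runs; the cluster mass is the **sum of
  statistic values** in the run (not exceedances); each permutation
  contributes its maximum |mass| (0 if nothing is suprathreshold); cluster
  p = fraction of null maxima ≥ |observed mass|. Single-channel *t*-series
  are clustered two-sided with α/2 per signed tail (the variant is not
  dictated by the data; signed-tail two-sided is the documented default);
  decoding accuracy is clustered one-sided (upper tail). Exhaustive label
  enumeration replaces random shuffles on small instances, giving exact
  p-values used as the oracle in tests.
* **Separability.** Sum of |mass| over clusters with p < 0.001 on the
  single-trial vocal-vs-nonvocal pooled-variance t-series at the native
  100 Hz resolution. Summing all significant clusters (rather than taking
  the max) credits channels whose separability arrives in several bursts.
* **Separability onset.** Start time of a channel's earliest significant
  cluster. ROI-level onset is the median over the top-50 % channels by
  separability (`ceil(n/2)`, ties broken by channel id) because onset
  estimates in weakly separable channels are dominated by noise.
* **HGA ratio.** Negative window means (responses below baseline, ~7 % of
  separable channels in the source data) are clipped to 0 before the ratio;
  0/0 is defined as 0 (a silent channel has no preference). The ratio is
  scale-invariant, which is the reason for the normalization: doubling a
  channel's overall response must not change its preference. Ratios are only
  interpreted for channels with nonzero separability.
* **ROI contrasts.** Rank-sum for unpaired channel-group contrasts, sign-rank
  for paired onset-vs-sustained contrasts, Fisher's exact test for
  separable-channel proportions, pooled across patients.

## Decoding

5 stratified outer folds; features z-scored and inverse-prevalence
observation weights computed on each outer training+validation set only
(weights are normalized to sum to n, so the weighted label mean is ½); a
20-value penalty path from λ_max — the smallest L1 penalty that zeroes every
coefficient of the weighted problem, λ_max = max_j |Σᵢ wᵢ xᵢⱼ (yᵢ − ½)| —
down to λ_max·10⁻³, searched by 10-fold stratified inner CV minimizing mean
weighted binomial deviance. Solver: liblinear. Reported accuracy is balanced
and pooled over outer-fold confusion counts (mean-of-folds is the documented
alternative). Cross-task models train once on all data of one task, apply
the training z-statistics to the other task, and are restricted to window
centers ≤ 550 ms (the shorter stimulus). Full-model significance uses label
shuffles with complete refits, p = (1 + #{null ≥ obs})/(1 + n_perm),
Bonferroni-multiplied across simultaneous models.

## Encoding

Features are standardized before PCA (summary acoustic features have
heterogeneous units); the vocal indicator is appended unstandardized (0/1)
and never enters the PCA. k is the smallest component count with cumulative
explained variance ≥ 0.9999. Outlier stimuli are excluded via an explicit id
list (no automatic rule). LOOCV R² uses the hat-matrix identity
eᵢ/(1 − hᵢᵢ) — exact and O(n) after one fit. The LRT uses Gaussian ML with
variance profiled out, 2·ΔLL = n·ln(RSS_nested/RSS_full), df = 1 for the
single added indicator. Designs must satisfy n > p + 1 and full rank.

## Synthetic generator

Each channel is 1/f-spectrum background noise (spectral shaping of white
noise) plus a 70–150 Hz band-limited carrier (bandpassed white noise)
multiplied by `1 + g(t)`, where `g(t)` steps to the channel's onset gain for
0–500 ms and its sustained gain thereafter (category-dependent, delayed by
the channel latency, 50 ms linear ramps to avoid spectral splatter).
Optional shared 1/f common-mode noise exercises the CAR, and an optional
sinusoid emulates residual line noise. Gains are in baseline-SD units of the
carrier envelope; because the HGA estimator z-scores each band against its
own baseline, the designed vocal/nonvocal gain pair maps onto the estimated
HGA ratio through the same (V−NV)/(V+NV) formula — so ground truth and
estimate share a scale, up to onset-into-sustained bleed (latency + ramp) and
in-band background dilution. Channels with `acoustic_weights` add
`weights · latent` (clipped at 0) to both window gains, coupling neural
responses to the acoustic feature table.

Trial schedules present every stimulus at least `n_presentations` times
(3 NatS / 2 VL by default) in shuffled order with uniform 1–2 s ISIs;
1-back repeats are inserted immediate re-presentations at a rate of ~16 % of
trials. Acoustic feature tables are low-rank: `features = latent·loadings' +
noise`, 88 columns by default, with latent class means separated by a
configurable `category_shift` so category is partially but not fully
recoverable from acoustics. The small default feature noise (SD 0.01)
keeps the table strongly collinear, as real summary features are, so the
99.99 % PCA cut lands near the latent rank. All randomness derives from one
integer seed via `numpy.random.SeedSequence` spawning (one child per channel
and stage), making fixtures bit-reproducible.

What the generator does **not** emulate: biophysical LFP detail, epileptiform
or movement artifacts, cross-channel correlated evoked variability,
heterogeneous per-trial latencies, non-stationary baselines, or genuinely
voice-like acoustic structure. Passing tests therefore demonstrate that the
pipeline recovers what it is pointed at under its own model class — correct
arithmetic, calibrated inference, monotone recovery — not that it would be
free of bias on clinical recordings. No quantitative SNR for real high-gamma
responses is assumed; generator gains (≈2–4 baseline SDs) were chosen for
testability.

## Test and acceptance problem sizes

Synthetic cohorts in the test suite use 16 stimuli (8 vocal / 8 nonvocal),
2 presentations, and ≤ 6 channels; calibration runs use 250 null simulations
at 200 permutations (cluster familywise error), 600 null fits (LRT), and 60
null cross-validated decoders at the published 37/128 class imbalance.
These sizes are the package's own desk-scale defaults for routine runs; all
counts are parameters, and the published permutation counts (1,000 decoding;
10,000 single-channel/encoding) are the config defaults.

## Known limitations

* No notch filtering (the source amplifier applies it in hardware) and no
  bipolar re-referencing; channels farther than 3 mm from cortex are expected
  to be excluded upstream via the channel metadata.
* Decoding is binary (vocal/nonvocal); multiclass category decoding and
  coefficient-map interpretation are out of scope.
* Encoding is window-mean only (onset/sustained), not time-resolved, and
  the acoustic features are consumed as a table — feature extraction from
  audio is a hook, not a stage.
* The λ grid, fold stratification and the exact two-sidedness of the
  single-channel cluster threshold are documented defaults where the
  protocol leaves them open; all live in `AnalysisConfig`.
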