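# Methods

This note documents the models, the calibration machinery, the synthetic
data the package ships, and the numerical and design choices that were
genuinely open.

## Detection model

The system answers a binary question per 4 s window — pulse present
(H1) or absent (H0) — and never reports an absolute heart rate. The
window length τ = 4 s is derived from the detection floor: the slowest
admissible pulse (30 BPM) must complete two full cycles inside one
window, so τ = 2·60/min_BPM. All windowing is non-overlapping
(`segment_stream` exposes no overlap; overlapping analysis would
correlate consecutive decisions and complicate the calibration's
independence assumptions).

The test statistic is S_max, the largest magnitude of the unnormalized
one-sided DFT of the mean-removed window inside 0.5–4.0 Hz. Three
consequences of that definition matter in practice:

* **Scale.** Amplitudes carry a factor of N_IR, so thresholds are only
  meaningful at the (f_s, τ) they were calibrated with.
  `DetectorCalibration` stores both and the CLI applies them together.
  Any absolute threshold quoted for other hardware (e.g. values in the
  tens of thousands at 500 Hz) is comparable only if the same
  unnormalized convention was used there.
* **DC hygiene.** Mean subtraction is the only high-pass step. The DC
  bin remains in the spectrum object but can never win the peak search
  because f_min = 0.5 Hz > 0. Residual sub-0.5 Hz drift leaks into the
  band edge ∝ 1/m; the drift amplitudes considered here keep that
  leakage 1–2 orders of magnitude below a worn pulse fundamental.
* **Ties.** The in-band argmax breaks ties toward the lowest frequency,
  and the final comparison S_max ≥ T_h accepts H1 on equality; the
  motion comparison is strict (S > threshold). The asymmetry is
  deliberate: the pulse rule errs toward "alive", the motion rule
  toward "still".

## Threshold calibration

Under H1 the density of S_max is estimated by a Gaussian KDE,

    f̂(x) = (1 / (√(2π) n h σ)) Σᵢ exp(−(x−xᵢ)² / (2h²σ²)),

with the Scott factor h = n^(−1/5) and σ the sample standard deviation
(n−1 denominator; the convention is not forced by the estimator, so it
is fixed here once). The CDF is the matching mixture of normal CDFs —
exact, monotone and cheap — and the threshold for an assumed miss
probability P_MD is its unique P_MD-quantile, found by `brentq` on a
bracket of the sample range padded by 10 effective bandwidths (doubled
up to 5 times; for P ∈ (0,1) the mixture tails make the expanded
bracket sufficient in practice). The same machinery produces the
two-sided S_AVG wear range (default 2.5% per tail — the "personal
margin" absorbing skin tone and placement) and the upper quantile used
by `calibrate_motion_threshold`.

Quantile-recovery behaviour: when a corpus is split half/half and the
held-out miss fraction is compared with the assumed P_MD, the deviation
has standard deviation ≈ √2 × the binomial SE of the test half alone,
because the calibration-half quantile estimate contributes noise of the
same order. Single fixed-seed runs therefore sit within the plain
binomial band most but not all of the time; the mean deviation across
seeds is small (|bias| ≲ 0.01, slightly negative at large P_MD from
kernel oversmoothing of the left tail).

## Wear and motion rules

Wear requires both an in-range backscatter mean (inclusive at both
ends — the bounds are themselves estimated quantiles, so boundary
equality is treated as membership) and contact temperature strictly
above T_ht. T_ht defaults to 27 °C, the midpoint rule between worn and
free-lying mean temperatures (`midpoint_temperature_threshold` computes
it when both means are available). A missing temperature leaves wear
*undetermined* rather than false; wear never alters the transmitted
lifesign code — it annotates the "no pulse" states in logs. An optional
flag (`suppress_when_unworn`) downgrades pulse decisions on a provably
unworn band for deployments that prefer suppression.

The motion indicator averages, over an 8-triplet buffer per window, the
per-axis absolute deviations from the buffer mean, summed across axes.
Higher-rate streams are decimated to 8 triplets by uniform striding.
The shipped threshold default of 0.05 g comes from the synthetic
calibration procedure: the rest-state indicator population (sensor
noise ≈ 0.01 g per axis) has its 99th percentile near 0.03 g, while the
walking population's minimum sits near 0.4 g; 0.05 g separates the two
with margin on both sides. A KDE-quantile calibrator is provided for
re-deriving the threshold from recorded rest data; note that a pure
0.99-rest-quantile threshold by construction lets ~1% of rest windows
read "moving", which is why the shipped default adds margin above it.

## Synthetic scenarios

The generator emulates the bench conditions the detectors must
separate, at the device's adopted settings (LED drive 170, f_s = 1 kHz):

| scenario | baseline (counts) | noise sd | pulse | artifact |
|---|---|---|---|---|
| free_lying | 3000 + 10·drive (~4.7e3) | 70 | – | – |
| artificial_skin | 1050·drive (~2.1e5 at 200) | 300 | – | – |
| fingertip | 1050·drive | 300 | clean, dicrotic 0.25, jitter 2% | – |
| wrist_rest | 1050·drive | 300 | dicrotic 0.4, per-beat jitter sd 20% | – |
| wrist_moving | 1050·drive | 300 | as wrist_rest | 0.5·S_pp rms, 0.5–3 Hz |
| not_worn_moving | as free_lying | 70 | – | 0.5·noise-sd rms |

Pulse peak-to-peak amplitude follows the LED drive through a
piecewise-linear saturating curve through (20, 220) and (200, 2770)
with a knee at drive 130 (post-knee slope 10% of pre-knee); LED current
is the linear fit through (10, 1.8 mA) and (190, 32.21 mA). The pulse
cycle is a declared shape, not a physiological model: an asymmetric
systolic peak (Gaussian in beat phase, width 0.07) plus a delayed
dicrotic bump (0.45, width 0.10). The widths keep the cycle bimodal
while letting harmonics decay fast enough that the fundamental remains
the strongest in-band line even when it falls between DFT bins — with a
much narrower systolic peak, a 40 BPM pulse's exactly-on-bin third
harmonic can outweigh its off-bin fundamental, which would make the
generator contradict its own ground truth. Each stream also carries a
per-stream subject/placement offset (1% of baseline) and slow (<0.05 Hz)
baseline drift (0.2% rms), which give the wear calibration a real S_AVG
distribution to estimate. The worn-moving artifact is band-limited
(0.5–3 Hz, 1/f-weighted) noise that deliberately overlaps the pulse
band; the not-worn-moving wobble is small because without a reflective
surface the optical coupling barely changes. The free-lying noise sd
(70) and on-skin sd (300) are sample standard deviations in ADC counts —
the printed variability figures carry no explicit definition, and this
is the declared interpretation.

What the generator does **not** emulate: respiration-modulated
baselines, SpO₂ two-wavelength physics, skin-tone-dependent coupling,
saturation/clipping, real gait spectra, or beat-to-beat rate
variability. Passing tests therefore demonstrate the pipeline's
correctness and its calibration logic under the declared conditions,
not clinical performance on human data.

## Evaluation harness and problem sizes

Corpora are pooled from many short streams (20 windows each, with
per-stream heart rates drawn from 55–95 BPM at rest, 75–130 BPM
moving), mimicking a multi-subject panel. This matters: every
constant-rate stream shares a single spectral-leakage loss (up to ~35%
of amplitude depending on where its rate falls relative to the 0.25 Hz
bin grid), so a corpus built from a handful of long streams behaves
like a tiny subject panel and its calibrated tail quantiles are
unstable. Fifty streams per thousand windows keeps the pooled quantiles
stable, in the same spirit as pooling the 22 subjects of the external
reference dataset.

Default problem sizes — a 1000-window calibration corpus and 250-window
scenarios for the four-scenario experiment, 2000 windows for the
half/half quantile-recovery experiment, 2000 test windows for the
headline detection rate — are large enough that binomial noise on the
reported percentages is ≲1–2 points while a full run stays in the
seconds-to-a-minute range on one core. Under these conditions the
four-scenario experiment reproduces the structural rows exactly (100%
code 0 not-worn/still, 100% code 1 not-worn/moving: the off-skin noise
floor's S_max sits two orders of magnitude below any calibrated worn
threshold) and worn-window detection at P_MD = 0.1 lands at ~85–97%
across seeds, against the project's 80% bar.

## Known limitations

* Absolute thresholds are hardware- and convention-specific; published
  threshold magnitudes can only be matched if the same unnormalized DFT
  at the same (f_s, τ) was used.
* The KDE uses a single global bandwidth; strongly multimodal S_max
  corpora (very heterogeneous panels) bias extreme-tail quantiles.
* Wear verification is calibrated per-population, not per-person; the
  2.5% tails mean ~5% of genuinely worn windows fall outside the range
  by design.
* Message parsing normalizes a Unicode minus to ASCII on input and
  always serializes ASCII.
* The external 500 Hz multi-subject PPG dataset used for independent
  validation of the calibration protocol requires a download and is
  not part of the shipped test suite; the package's CSV readers accept
  its exported per-channel text form at f_s = 500, τ = 4.
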