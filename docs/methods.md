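# Methods

## Optical forward model

The synthesizer treats each LED channel as a large baseline intensity
(DC) with a small multiplicative cardiac modulation, a weaker respiratory
modulation, additive sensor noise and occasional motion bursts:

```
I_λ(t) = DC·κ · (1 + m_λ(t)·p(t) + a_r·sin(2π f_r t) + g·m_ir·b(t) + n(t))
```

where `κ ∈ (0,1]` is a skin-attenuation factor (a proxy for pigmentation
and optical coupling), `p(t)` a unit-variance asymmetric cardiac pulse
(fundamental plus one harmonic, so amplitude estimation is exercised on a
non-pure tone), `b(t)` the shared motion disturbance and `n(t)` white
sensor noise scaled to a fraction of DC. The modulation depth follows the
Beer–Lambert mixture extinction of the pulsatile arterial compartment,

```
m_λ(t) ∝ s(t)·ε_HbO₂(λ) + (1−s(t))·ε_Hb(λ),
```

normalized so the infrared perfusion (AC/DC) equals the subject's
`perfusion_scale`; the red/infrared depth ratio is then exactly the
closed-form modulation ratio R(s), which the DSP tests use as an oracle.
The green channel pulses with a fixed saturation-independent depth — it
carries no oximetric information and serves the network as a denoising
reference. Extinction coefficients ship as package data
(`data/optical_defaults.yaml`, values from the standard compiled in-vitro
hemoglobin spectra, in L·mmol⁻¹·cm⁻¹) and can be swapped without touching
code. Assumptions: single effective path per wavelength, no multiple
scattering model, no venous pulsation, no carboxy-/methemoglobin. These
keep R(s) exactly monotone and nearly linear — adequate for testing the
estimation machinery, not a claim about tissue optics.

Key defaults: sampling rate 25 Hz (typical wrist-wearable rate; makes the
8-s window 200 samples), infrared perfusion 2% (wrist reflectance is an
order of magnitude weaker than the fingertip), sensor noise 1% of DC,
respiratory amplitude 0.5% of DC.

## Synthetic hypoxia studies

The study generator emulates a controlled desaturation protocol: per run,
a 75 s room-air stage then five plateaus (92, 87, 82, 77, 70%), each
preceded by a 45 s transition following a normalized exponential (time
constant 20 s — inspired gas switches abruptly, saturation responds
physiologically) that reaches the target exactly at the plateau start;
two runs separated by a 120 s recovery toward 99%. Plateau jitter is a
slow sinusoid with amplitude 0.1–0.3%, recentred at the extreme targets
so the trajectory stays inside 70–100%; within-plateau range stays well
under the 1% stability criterion.

Blood draws: two per stage, 30 s apart, the second skipped with
probability 0.08 (standing in for destabilized plateaus), values =
true saturation + 0.3% co-oximeter noise. At 14 subjects this yields
≈ 322 reference samples in expectation — the scale of a real two-run,
five-plateau validation cohort.

Each subject gets two device records ("right"/"left" wrist) synthesized
from the trajectory shifted by a per-wrist lag drawn from
Normal(−4.5 s, 9.5 s) truncated to ±30 s; negative lag means the device
lags the co-oximeter. The left wrist receives a higher motion-burst rate
(1.2 vs 0.5 per minute) to reproduce the conclusiveness asymmetry caused
by blood draws from the left arm. Subject physiology is drawn per
subject: heart rate U(55, 95) bpm, respiratory rate U(12, 18)/min,
perfusion lognormal around 2% (σ = 0.25 in log), skin attenuation
U(0.4, 1.0).

What the simulator does **not** emulate: baseline wander and ambient-light
transients, arrhythmia, venous pooling, real skin-optics spectra,
temperature-dependent perfusion, device quantization. Passing tests
therefore demonstrate that the algorithms are correct and well-behaved
under the stated physics, not that a physical device meets any accuracy
bound on humans.

## Ratio-of-ratios path

DC is a 2 s centered moving average (edges shrink); AC is a 2 s centered
moving standard deviation of the 0.5–2.5 Hz zero-phase Butterworth
(order 3, forward–backward) bandpass — the passband covers heart rates
40–150 bpm and rejects respiration. Filtering is zero-phase so this path
adds no lag of its own; the device-vs-reference lag is modeled and
estimated separately. Points with vanishing infrared perfusion are masked
invalid rather than set to sentinels. The calibration is OLS of reference
saturation on R, requiring ≥ 10 pairs spanning ≥ 15 saturation points;
outputs clip to [50, 100]%.

## Network path and fusion

Both networks share one topology: three valid (unpadded) 1D conv blocks,
kernel 5, channels 8→16→32, stride 2, ReLU, global average pooling,
linear head — ~3.4 k parameters, well under the 50 k budget and trainable
in tens of seconds with plain numpy (layers and Adam are implemented in
`nnet.py` with manual backprop, gradient-checked against finite
differences). Inputs are 8 s windows of the three LED channels, each
standardized as (x − DC)/DC. Regression targets are ground-truth
saturation at window centers (plateau-dominated trajectories make the
interpolation unbiased), normalized as (y − 85)/15. Training: mini-batch
Adam (batch 128, lr 2e-3, 30 epochs), early stopping on validation loss,
fully seeded.

The training study has 6 subjects (a deliberately desk-scale stand-in for
the multi-study calibration cohorts real devices use), split 2:1 by
subject: the networks train on the fit split (the regressor on
artifact-free windows only), while the ratio calibration and the fusion
weights are estimated on windows the networks never saw. A window counts
as artifact-contaminated when it overlaps a motion burst by ≥ 0.5 s (the
burst taper width) — sub-taper grazes look clean and would only blur the
quality labels. Fusion is OLS of reference on (ratio estimate, network
estimate) with intercept; collinear inputs trigger a warned fallback to
the ratio path alone. The quality classifier's decision threshold is
chosen on the validation split by maximum Youden index over a probability
grid.

## Gating

Precedence: not_worn > motion > poor_signal > conclusive (the order is a
reporting convention; the underlying checks are independent). Worn =
mean infrared perfusion ≥ 0.002 AND a dominant cardiac-band spectral
peak: Welch spectrum over ~4 s segments, peak-to-median power ratio in
0.5–2.5 Hz ≥ 6. Welch averaging tightens the broadband-noise null — on
calibration fixtures, clean cardiac windows score ≥ 9 while white noise
at physiological DC stays below ~7.6 (p99 ≈ 5) — so one threshold
separates the two. Still = per-axis accelerometer SD < 0.04 g over the
window (quiet baseline is 0.01 g; bursts are ~0.5 g). Poor signal = the
classifier probability above its fitted threshold. All thresholds live in
the run config.

## Validation statistics

Lag is the argmax of normalized cross-correlation between the fused
device series and the reference trajectory on the window grid, searched
over ±30 s; negative = device lags. Plateau matching averages conclusive
device readings within ±15 s of each lag-corrected draw time (the
halfwidth is a package default; draws with no conclusive reading in the
window are dropped and counted). Bias CI uses the normal approximation
bias ± 1.96·SD/√n with SD = √(Arms² − bias²) (a t-based CI is available
by flag); Bland–Altman limits use the n−1 sample SD of the differences;
stratification (≤80, 80–90, >90, inclusive upper bounds) is by the
device value, with stratification by reference available as an option.
Reports round percentages to one decimal and statistics to two.

The accuracy gates (Arms ≤ 3.5% and ≤ 4.0%, ≥ 200 pairs from ≥ 10
subjects) are arithmetic threshold checks only, not a regulatory claim.

## Problem sizes and runtime

Default end-to-end run: 6-subject training study + 14-subject validation
study, two wrists each, ~26.5 min of 25 Hz signal per record, windows at
2 s stride (~790 per record), ~320 blood draws. The full
simulate→train→validate cycle takes about a minute on one CPU core; the
test suite runs in under two minutes.

## Numerical choices and degenerate inputs

Zero-phase filtering throughout; moving statistics use shrinking edge
windows; division guards mask rather than raise; intensities are floored
at 1% of DC so extreme motion excursions cannot go non-positive;
saturation fractions tolerate 1e-9 endpoint round-off; all estimates clip
to [50, 100]%. Flat series make lag and correlation undefined and raise;
empty label lists, single-class training sets and sub-window records
raise with explicit messages. Every random draw descends from one run
seed through named blake2s-derived sub-streams, so changing one stage's
randomness leaves the others untouched.

## Known limitations

The network path alone is weaker than the ratio path on this simulator
(the fusion typically weights the ratio estimate ~0.6), because the
synthetic artifacts are easier to gate out than real-world ones — on real
wrist data the learned filter bank would carry more of the load.
Conclusiveness percentages depend directly on the injected motion rates;
they are study conditions, not predictions. Lag estimation at the 2 s
window stride quantizes recovered lags accordingly. The simulator's
linear R(s) makes the calibration problem benign; real reflectance
calibration curves bend at low saturation.
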