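# wristox

Wrist-worn **reflective pulse oximetry**, end to end: a physics-based
multichannel PPG simulator, the classical ratio-of-ratios SpO₂ estimator, a
small 1D convolutional direct estimator with linear fusion, conclusiveness
gating (worn / still / signal quality), and the agreement statistics used to
validate oximeters against arterial blood references in controlled hypoxia
studies.

It is written for biomedical-signal-processing practitioners who want to
prototype, stress-test and validate wrist SpO₂ pipelines without clinical
data: every input the validation statistics need — desaturation-plateau
protocols, co-oximeter blood draws, two-wrist device traces with realistic
lag, perfusion, pigmentation, noise and motion artifacts — is generated by
the built-in simulator.

## The model

Oxygenated and deoxygenated hemoglobin absorb red (~660 nm) and infrared
(~940 nm) light very differently. Writing AC and DC for the pulsatile
amplitude and baseline of each PPG channel, the **modulation ratio**

```
R = (AC_red / DC_red) / (AC_ir / DC_ir)
```

is, under a Beer–Lambert model of the pulsatile arterial compartment,

```
R(s) ≈ [s·ε_HbO₂(660) + (1−s)·ε_Hb(660)] / [s·ε_HbO₂(940) + (1−s)·ε_Hb(940)]
```

a strictly decreasing, nearly linear function of the arterial saturation
`s`, calibrated to SpO₂ by linear regression against co-oximeter references
(`SpO₂ = a + b·R`, `b < 0`). Because wrist reflectance signals are weakly
perfused and artifact-prone, a second, independent estimator — a small 1D
convolutional network over 8-second standardized red/infrared/green
windows — regresses saturation directly, and the two estimates are merged
by a fitted linear fusion. A same-topology classifier plus pulse-presence
and stillness heuristics gate each window as conclusive or inconclusive
(not worn / motion / poor signal).

Validation follows oximeter-accuracy practice: cross-correlation lag
estimation, plateau matching of device readings to blood draws, bias and
Arms (RMS error) with stratified breakdown (≤80, 80–90, >90%),
Bland–Altman limits of agreement, Pearson association, and the arithmetic
accuracy gates Arms ≤ 3.5% / ≤ 4.0% with ≥ 200 pairs from ≥ 10 subjects.

## Worked example

```python
from wristox.pipeline import run_experiment

result, models, study = run_experiment(seed=1)
for wrist, v in sorted(result.wrists.items()):
    r = v.report
    print(f"{wrist:>5}: n={r.n_pairs}  bias={r.bias:+.2f}%  Arms={r.rmse:.2f}%  "
          f"r={r.pearson_r:.3f}  conclusive={v.conclusiveness['percent']['conclusive']}%")
print("compliance:", result.compliance())
```

prints

```
 left: n=315  bias=+0.08%  Arms=1.01%  r=0.994  conclusive=76.6%
right: n=318  bias=+0.16%  Arms=0.98%  r=0.995  conclusive=87.8%
compliance: {'arms_fda': True, 'arms_iso': True, 'enough_pairs': True, 'enough_subjects': True}
```

This simulates a 6-subject training hypoxia study, fits the ratio
calibration, both networks and the fusion, then simulates a fresh
14-subject validation study (two wrists each, ~320 blood draws total),
runs the full estimation + gating pipeline, aligns and pairs device
readings with the blood draws, and scores each wrist. `n` is the number of
conclusive device–reference pairs; `bias`/`Arms` are mean and RMS error in
saturation percentage points; `conclusive` is the fraction of windows
passing all three gates (the left wrist gets more motion artifact by
design, mimicking blood draws from the left arm). The same objects expose
stratified accuracy, Bland–Altman limits and lag summaries
(`result.wrists["right"].report`).

The same pipeline is scriptable from the shell:

```sh
wristox simulate --seed 3 --n-subjects 14 --out bundle/
wristox train bundle/ --seed 3 --out models.json
wristox estimate bundle/subject_00/right.csv --models models.json --out series.csv
wristox validate bundle/ --models models.json --out report.json --plots
```

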