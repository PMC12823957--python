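# ripsensors

Epoch-level **software sensors** for sleep monitoring: estimate heart rate,
nasal airflow magnitude and esophageal pressure magnitude from signals that
are comfortable to record — respiratory inductance plethysmography (RIP)
belts and pneumoflow masks — instead of the cumbersome or invasive sensors
that normally measure them.

Monitoring sleep-disordered breathing usually requires a pulse sensor, a
flow mask and sometimes an esophageal pressure catheter.  Because the
cardiovascular and respiratory systems are tightly coupled (respiratory
sinus arrhythmia, mechanical heart-lung interaction, effort-to-flow and
effort-to-pressure coupling), the thoracoabdominal motion captured by RIP
belts carries information about all of these quantities.  `ripsensors`
implements four linear models that exploit this interconnectedness, plus
the full pipeline around them: artifact screening, 60-s epoch segmentation,
FFT feature extraction, ordinary-least-squares fitting with a complete
statistics panel, 10-fold cross-validation (pooled and per-subject), and a
mechanistic synthetic polysomnography generator so the whole pipeline is
testable end to end without clinical data.

## The four models

Signals are cut into non-overlapping 60-s epochs (12,000 samples at 200 Hz;
15,000 at 250 Hz).  For each epoch the one-sided magnitude spectrum
|X_k| of the unnormalized DFT, X_k = Σ_n x_n e^(−j2πkn/N), is summarized
either inside a band (mean of |X_k| over bins with low ≤ k·Δf < high) or
over the full band excluding DC.  The models are ordinary least squares on
raw feature scales:

| model | equation | estimates | from |
|---|---|---|---|
| HR   | pulse = β₀ + β₁·Xband1 + β₂·Xband2 + β₃·Xband3 + β₄·RMS + β₅·Skewness | epoch-average pulse (bpm) | abdominal belt |
| NPF  | NPF = β₀ + β₁·X_AB + β₂·X_TH | nasal flow spectral magnitude | both belts |
| P1es | Pes = β₀ + β₁·X_NPF + β₂·X_OPF | esophageal pressure magnitude | flow mask |
| P2es | Pes = β₀ + β₁·X_AB + β₂·X_TH | esophageal pressure magnitude | both belts |

The HR model's bands are 0.07–0.3, 0.3–1.7 and 1.7–5 Hz (slow breathing
dynamics, ordinary respiratory oscillations, and subtle cardiac-frequency
components that leak into the belts).  Every fit reports per-coefficient
SE / t / p, and R², adjusted R², the F test against the constant model and
residual RMSE; error degrees of freedom are valid epochs minus estimated
parameters.

Before modelling, epochs are screened: pulse values outside 40–180 bpm or
jumping by more than 40 bpm between consecutive 1-s samples, near-flat
segments (sensor disconnection), and corrupted esophageal pressure reject
an epoch.  Esophageal spikes beyond ±2 cmH₂O are repaired by linear
interpolation plus median filtering.  Recordings with under 4 h of valid
epochs are excluded.

## Worked example

Simulate a small cohort and calibrate the belt-based esophageal pressure
sensor per subject:

```
$ ripsensors simulate --config sim.yaml --out cohort --n-subjects 4 --seed 11
seed=11 subjects=4 duration_s=1800
wrote 4 EDF files and cohort/cohort_metadata.csv

$ ripsensors fit --in cohort --model pes2 --scope per-subject \
      --k-folds 5 --seed 3 --min-valid-hours 0.4 --out fits
seed=3 model=PES2 scope=per-subject subjects=4 models_written=4
cohort mean PCC = 0.905, mean RMSE = 0.692
```

(`sim.yaml` here contains just `duration_s: 1800`; 30-min recordings keep
the example quick, hence the lowered inclusion threshold.)  The cohort mean
PCC of 0.905 is the average across subjects of each subject's mean held-out
Pearson correlation between predicted and observed Pes magnitude over the
5 cross-validation folds.  `fits/` then holds one JSON model per subject —
coefficients, their SE/t/p, fit statistics and the feature conventions the
model was trained under — plus a report CSV with one row per subject
(mean/std PCC and RMSE, n_obs, error dof, R², adjusted R², F, p) and a
trailing cohort-summary row.  `ripsensors predict --model-path
fits/PES2_subj000.json --recording cohort/subj000.edf --out pred.csv`
applies a saved model epoch by epoch; it refuses to run (exit code 4) if
the extraction conventions differ from those the model was trained with.

The same pipeline is available as a library:

```python
from ripsensors import (SyntheticConfig, generate_recording, evaluate_cohort,
                        ModelKind, CleaningConfig)

cohort = [generate_recording(SyntheticConfig(duration_s=3600, seed=100 + i),
                             f"s{i:02d}")[0] for i in range(10)]
report = evaluate_cohort(cohort, ModelKind.HR, scope="per_subject",
                         cleaning=CleaningConfig(min_valid_hours=0.5), seed=7)
print(round(report.cohort["mean_pcc"], 3))   # 0.949
```

## Scope

The package estimates signal magnitudes at the epoch level; it does not
reconstruct time-domain waveforms, score sleep stages, compute
apnea-hypopnea indices or make diagnostic claims.  See `docs/methods.md`
for the model assumptions, the synthetic generator's design and known
limitations.
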