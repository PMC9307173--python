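# oxsleep

Rodent EEG/EMG sleep analysis for orexin-agonist pharmacology.

Narcolepsy-cataplexy follows the loss of hypothalamic orexin neurons, and
orexin-knockout (OXKO) mice reproduce its two dark-phase signatures:
cataplexy-like episodes and sleep/wake fragmentation (abnormally frequent
wake↔NREM transitions with short bouts). Evaluating whether an
OX2R-selective agonist rescues these phenotypes requires a chain of
analyses — vigilance-state staging from EEG/EMG, cataplexy-like-episode
detection, sleep-architecture metrics, receptor potency/selectivity from
Ca²⁺-mobilisation dose-response curves, and a conditioned-place-preference
score for abuse liability. `oxsleep` implements that chain as a tested,
reusable library, together with a synthetic-recording generator so every
stage can be exercised and validated without animal data.

## What it computes

- **Simulation** (`oxsleep.sim`): semi-Markov vigilance-state tracks
  (gamma bout durations; cataplexy hazard acting on sustained wake;
  decoy theta-atonia events with short prior wake) and state-conditioned
  EEG/EMG signals built from band-limited noise mixtures.
- **Spectral features** (`oxsleep.spectral`): per-epoch FFT power from 1
  to 30 Hz in 1-Hz bins; delta (1–4 Hz), theta (6–9 Hz) and fast
  (10–30 Hz) band sums; EMG RMS and variance.
- **Staging** (`oxsleep.staging`): Wake/NREM/REM classification of 20-s
  or 4-s epochs — NREM on delta dominance with low EMG, REM on theta
  dominance with atonia, wake otherwise — with per-recording EMG
  calibration and the predominant-state rule for mixed epochs.
- **Cataplexy detection** (`oxsleep.events`): episodes with (i) ≥10 s of
  atonia, (ii) theta-dominant EEG, (iii) ≥40 s of continuous prior
  wakefulness, at 1-s resolution.
- **Architecture metrics** (`oxsleep.metrics`): state totals, episode
  counts and mean durations (total time / episode count), all six ordered
  transition counts, hourly wake profiles, NREM delta power, and the CPP
  score (post-conditioning minus pre-conditioning time on the drug-paired
  side).
- **Dose-response** (`oxsleep.doseresponse`): four-parameter logistic
  fits, `r(c) = baseline + (emax − baseline) / (1 + (EC50/c)^hill)`,
  with fold-selectivity (EC50 ratio across receptors) and potency ratios
  (EC50 ratio across agonists at one receptor).
- **I/O and pipeline** (`oxsleep.io`, `oxsleep.pipeline`, `oxsleep` CLI):
  EDF and CSV recordings, hypnogram/event/feature CSVs, and an
  end-to-end `simulate → features → score → detect → summarize` run.

## Worked example

```python
from oxsleep import fit_4pl, fold_selectivity, potency_ratio, simulate_curve

NM = 1e-9
curves = {
    ("OXA", "OX2R"): (0.20 * NM, 100.0),
    ("AL-OXB", "OX1R"): (58.0 * NM, 99.54),
    ("AL-OXB", "OX2R"): (0.055 * NM, 92.83),
}
fits = {
    key: fit_4pl(simulate_curve(*key, ec50=ec50, emax=emax, n_doses=10,
                                replicates=3, noise_sd_pct=2.0, seed=101 + i))
    for i, (key, (ec50, emax)) in enumerate(curves.items())
}
print(fold_selectivity(fits[("AL-OXB", "OX1R")], fits[("AL-OXB", "OX2R")]))
print(potency_ratio(fits[("OXA", "OX2R")], fits[("AL-OXB", "OX2R")]))
```

Running `python examples/dose_response.py` prints:

```
agonist receptor     EC50 (nM)  Emax (%)   Hill
OXA     OX1R             0.509    100.36   0.93
OXA     OX2R             0.215    101.03   0.97
AL-OXB  OX1R              59.5     99.34   1.03
AL-OXB  OX2R            0.0534     92.74   1.03

AL-OXB OX2R selectivity (OX1R/OX2R EC50): 1115-fold
AL-OXB potency advantage over OXA at OX2R: 4.0x
```

The fitted EC50s recover the generating potencies; the ~1000-fold OX1R/OX2R
EC50 ratio is what qualifies AL-OXB as OX2R-selective, and the potency
ratio quantifies how much more potent it is than OXA at OX2R.

The other scripts in `examples/` each show one capability:
`simulate_and_stage.py` (staging recovery against ground truth, ~94%
epoch agreement), `cataplexy_detection.py` (episode detection with
onset/duration/prior-wake), `drug_effect.py` (seed-paired drug vs vehicle
architecture comparison) and `cpp_score.py`.

A thin CLI mirrors the pipeline stages:

```sh
oxsleep simulate --duration 10800 --seed 1 --out scratch/demo
oxsleep score --edf scratch/demo.edf --epoch 20 --out scratch/demo_hyp.csv
oxsleep detect-cataplexy --edf scratch/demo.edf --out scratch/demo_events.csv
```

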