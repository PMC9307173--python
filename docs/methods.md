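# Methods

This note documents the models, conventions and numerical choices behind
`oxsleep`, and what the synthetic-data experiments do and do not show.

## Vigilance-state simulator

States {Wake, NREM, REM, Cataplexy} evolve as a semi-Markov chain at 1-s
label resolution. Bout durations are gamma-distributed with shape 2
(mean set per state); the shape-2 choice avoids the pile-up of 1-s bouts
an exponential model would produce, which would destabilise epoch-level
statistics downstream. Transitions are Wake → NREM, NREM → REM with
probability `rem_entry_prob` (else NREM → Wake), REM → Wake. REM is never
entered directly from wakefulness: direct wake-to-theta-atonia is
reserved for the cataplexy channel, which is the narcoleptic signature
the detector looks for.

Cataplexy is a competing risk on wakefulness: an exponential clock with
rate `cataplexy_hazard` (events per hour of sustained wake) races the
wake bout's end. When it fires, the preceding wake run is extended to at
least `min_wake_before_cataplexy_s` (40 s) so the episode genuinely
qualifies, and a cataplexy bout (gamma, mean 40 s, floor 10 s) is
inserted before wakefulness resumes. A fraction `decoy_fraction` (10%)
of these events is instead preceded by a short wake run drawn uniformly
from [10, 39] s; these decoys are spectrally identical to cataplexy but
fail the prior-wake criterion, giving the detector true negatives to
reject. The default hazard is 2 events/h of wake: because each event
truncates a wake bout and inserts a short pre-event run, larger hazards
visibly bias the emitted wake-bout mean away from `mean_bout(Wake)`; at
2/h the pooled bias stays under ~10%, within the generator's contract
that emitted bout means track the configured means.

All duration/rate defaults are invented: the source phenomenology
(fragmented dark-phase sleep, frequent wake↔NREM transitions, occasional
cataplexy) is qualitative, so the defaults (wake 120 s, NREM 100 s, REM
60 s mean bouts; REM entry 0.15) were chosen once as a plausible
fragmented dark-phase architecture and are exposed in `SimConfig`.

## Signal synthesis

EEG is a sum of three band-limited noise components (zero-phase
Butterworth bandpass of white noise at 1–4, 6–9 and 10–30 Hz, each
normalised to unit RMS) scaled per second by the square root of the
current state's band weight, so band *powers* realise the configured
weights: wake (0.25, 0.25, 0.50), NREM (0.60, 0.15, 0.25), REM and
cataplexy (0.15, 0.65, 0.20), total EEG RMS 50 µV. EMG is white Gaussian
noise with per-state RMS (wake 40 µV, NREM 12 µV, atonia 4 µV); the wake
level fluctuates second-to-second with CV 0.30 to emulate variable
muscle tone. Envelopes are crossfaded over 0.1 s at state boundaries —
continuous, but sharp enough that an episode at the 10-s detection floor
keeps its nominal duration in the features. No quantitative spectral or
EMG parameters exist for OXKO mice in the source material; all of these
numbers are documented conventions.

What the generator does *not* emulate: artifacts, electrode drift,
circadian modulation within the dark phase, chocolate-triggered
cataplexy clustering, spindles/phasic REM events, or 1/f background
structure. Passing recovery tests therefore shows the pipeline is
correct under its own signal model, not that thresholds transfer
unchanged to real recordings — on real data the staging thresholds and
calibration quantile are the knobs to revisit.

## Spectral features

Within each scoring epoch the EEG is cut into non-overlapping 1-s
rectangular windows, each mean-detrended; one-sided periodograms are
averaged over the epoch. A 1-s rectangular window puts FFT bins exactly
1 Hz apart, which is the stated analysis resolution; no taper is applied
(the windowing/normalisation scheme of the original MATLAB analysis is
unspecified, so this simplest convention is documented and swappable).
Reported bins run 1–30 Hz; delta = bins 1–4, theta = bins 6–9, fast =
bins 10–30; 5 Hz belongs to no named band. EMG RMS and variance are
computed over the raw epoch samples. Trailing partial epochs are
dropped.

## Staging

The qualitative staging criteria (wake: fast EEG, high variable EMG;
NREM: delta-dominant EEG, low EMG; REM: theta-dominant EEG, atonia) are
made operational as ratio/threshold rules with per-recording
calibration. The wake-reference EMG is the 0.9 quantile of epoch EMG RMS
(rodent recordings spend enough epochs at waking muscle tone for the
upper tail to track it); decision order is REM before NREM because
atonia is the more specific condition, with wake as the fall-through.
Defaults: theta dominance ≥1.5, delta dominance ≥1.5, EMG low ≤0.5 and
atonia ≤0.2 of the wake reference. All are invented conventions (the
original scoring was semiautomatic with unpublished thresholds) and are
exposed in `StagingThresholds`. No post-hoc hypnogram smoothing is
applied, so the epoch-length comparisons below are not confounded.

Mixed epochs in ground-truth hypnograms take the predominant state (most
seconds); ties go to the previous epoch's label when it is among the
tied states, else fixed priority Wake > NREM > REM. Ground-truth
cataplexy seconds map to REM for the 3-state alphabet — theta plus
atonia is spectrally REM-like, and separating cataplexy from REM is the
event detector's job, applied at 1-s resolution.

Scoring the same recording at 20-s and 4-s epochs reproduces the known
epoch-length effect: longer epochs give larger mean episode durations
and fewer stage transitions, while seed-paired drug/vehicle comparisons
reach the same qualitative conclusion at both lengths.

## Cataplexy detection

Criteria: (i) atonia ≥10 s, (ii) theta-dominant EEG during the episode,
(iii) ≥40 s of wakefulness immediately before. Detection runs on
per-second flags because a 10-s floor is sub-epoch at 20-s scoring.
Qualifying runs separated by <2 s of non-qualifying seconds are merged
before the criteria are tested (configurable); the preceding wake run is
scanned backwards tolerating single-second non-wake gaps, and
`prior_wake_s` is reported as the span from the earliest counted wake
second to onset. "Abrupt" is thus operationalised as: no ≥2-s non-wake
run between the wake period and the episode.

Per-second features are noisy — a 1-s periodogram gives each band only
~8 degrees of freedom, so raw theta/delta dominance flags flip on ~10%
of seconds. Before thresholding, band powers are therefore smoothed
with a centred 5-s mean and EMG RMS with a 5-s running median; the
median is edge-preserving, so episode onsets/offsets stay in place
while interior dropouts up to 2 s vanish. The detection rule itself is
unchanged by this smoothing and is verified against an independent
brute-force enumerator on raw flag tracks.

Counting convention: an episode belongs to an analysis window if its
onset lies inside it; latency to the first episode is right-censored at
the window length when none occurs.

## Architecture metrics

Total time per state is summed epoch time; mean episode duration is
total time divided by the number of episodes (maximal same-label runs).
Episodes truncated by the analysis-window edge still count — the
defining formula divides totals by counts with no exclusion rule.
Hourly profiles use 3600-s bins aligned to the window start (the
administration time); an episode spanning an hour boundary is split at
the boundary, each fragment counting in its own bin (a documented
convention; assigning whole episodes to their onset bin is the
alternative). NREM delta power averages un-normalised delta power (µV²)
over NREM-labelled epochs only. The CPP score is post-conditioning
minus pre-conditioning time on the drug-paired side, both bounded by
the 900-s test duration; negative scores (aversion) are legal. Group
inference (ANOVA etc.) is deliberately out of scope; the module emits
per-recording summaries from which group tables are built with standard
tools.

## Dose-response fitting

The 4PL model `r(c) = baseline + (emax − baseline)/(1 + (EC50/c)^hill)`
is fitted by bounded least squares (scipy `curve_fit`, trust-region
reflective) on log10 concentration with a deterministic initialiser:
baseline = min response, emax = max response, EC50 = dose nearest the
half-range response, hill = 1. Bounds: log10 EC50 within the dose range
widened by two decades; hill ∈ [0.1, 10]; asymptotes within half a
response span of the data extremes. Replicates are fitted pointwise,
never pre-averaged. Flat response data is flagged unconverged rather
than raising, as is any fit with emax ≤ baseline. Whether the original
Prism analysis constrained asymptotes is unknown; this bounded 4PL is
the package's own convention. Fitted EC50s are scale-equivariant in
dose and the derived ratios are invariant to response-axis rescaling.

## Problem sizes and determinism

Test batteries use six 3-h recordings per arm at 250 Hz (the in-vivo
design used six animals per group over a 3-h post-administration
window), seeds fixed in the suite; Monte-Carlo fits use 20 seeded
repetitions. Every public entry point that draws random numbers takes
an explicit seed, and `scripts/acceptance.py` derives all streams from
its single `--seed`. The EDF writer emits 16-bit samples with symmetric
physical scaling (quantisation error ≤ physmax/32767); round trips are
exact to that quantisation.

## Known limitations

- Staging recovery (~94% epoch agreement) is bounded by bout-boundary
  epochs, where the EMG's quadratic mixing biases mixed epochs toward
  wake; real semiautomatic scoring faces the same ambiguity.
- The detector's prior-wake criterion makes recall sensitive to
  single-second label noise exactly at the 40-s floor; events generated
  at the floor are the ones occasionally missed.
- The simulator's drug effect is a two-parameter caricature (wake-bout
  multiplier, hazard multiplier); it reproduces directions of effect,
  not magnitudes, and says nothing about pharmacokinetics.
- The CSV recording dialect stores one row per sample and is only
  sensible for short test recordings; EDF is the working container.
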