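# cfctrack

Adaptive single-frequency tracking and cross-frequency coupling analysis
for EEG-like signals.

## The problem

Cross-frequency couplings — statistical dependencies between oscillatory
components in different frequency bands — are a candidate mechanism for
integrating neuronal activity across temporal scales. They are usually
quantified from phase information, but phases are only physically
meaningful for narrow-band signals, and fixed band-pass filters ignore the
signal's own dynamics: an oscillation whose instantaneous frequency drifts
across a band edge is split in two, and any broad-band noise or in-band
interferer corrupts the extracted phase.

`cfctrack` implements an **adaptive single-frequency tracker (SFT)**: a
one-pole complex band-pass filter whose centre frequency is recursively
steered to the dominant oscillation. Operating on the analytic
representation *x(n)* of a band-limited real signal:

```
y(n)     = β · e^{jω̂(n)} · y(n−1) + (1 − β) · x(n)
q(n)     = δ · q(n−1) + (1 − δ) · y(n) · conj(y(n−1))
ω̂(n+1)  = arg q(n)
```

The filter has **unit gain and zero phase** at the tracked frequency
ω̂(n), so the phase of the extracted component *y(n)* can be used directly
for coupling measures; β ∈ (0,1) sets the bandwidth (default: a 2 Hz 3 dB
bandwidth at 250 Hz, β ≈ 0.975) and the forgetting factor δ (default
0.99) sets the adaptation speed of the frequency estimate ω̂.

On top of the tracker the package provides the full analysis chain used in
event-related EEG studies:

* zero-phase preprocessing: resampling, power-line notch, spatial
  averaging over an electrode cluster, a fixed Butterworth filter bank
  (1–4, 4–8, 8–12, 15–25, 35–45, 45–55, 55–65, 65–75 Hz), mirror-padded
  tracker initialization;
* **phase–amplitude** PLV `|E exp(j(φ_low − φ_ampHigh))|` and **n:m
  phase–phase** PLV `|E exp(j(n·φ₁ − m·φ₂))|` over 300 ms sliding windows
  shifted by 10 ms, with the coefficient-validity rule for (n, m) pairs;
* phase-randomized surrogates (identical amplitude spectrum, stationary
  null);
* group statistics: arcsine variance stabilization, per-window
  randomized-block ANOVA (subject as random block), and a run-length
  permutation test (1000 label permutations of the maximal run of
  consecutive significant windows, with a ≥ 4-window rule);
* fully specified synthetic generators so every stage is testable without
  any recording.

Intended users: researchers analysing oscillatory coupling in EEG/MEG-like
data, and methodologists comparing adaptive against fixed-filter phase
extraction.

## Worked example

Broad-band noise resilience (`python examples/snr_sweep.py`): two
sinusoids at normalized frequencies 0.05 and 0.35 are perfectly phase
locked, so their 7:1 phase–phase PLV is 1 without noise. In white noise:

```
 SNR (dB)  PLV tracked    PLV fixed
        0        0.223        0.103
        5        0.521        0.106
       10        0.965        0.298
       15        0.995        0.674
       20        0.998        0.885
```

The fixed-filter PLV collapses to the chance floor (≈ 0.10 for 75-sample
windows) already at moderate noise, while the tracked PLV degrades slowly:
adaptive narrow-band extraction preserves usable phase far below 10 dB
SNR.

Other examples: `track_a_tone.py` (frequency recovery),
`interference_rejection.py` (a transient 36 Hz interferer inside the
35–45 Hz band disrupts fixed-filter phase but not the tracker),
`surrogate_signals.py` (surrogate construction), `group_analysis.py`
(end-to-end two-condition group pipeline with the run-length permutation
test).

A thin CLI mirrors the pipeline stages:

```bash
cfctrack simulate --seed 1 --subjects 9 --trials 12 --effect 0.5 group.csv
cfctrack pipeline --seed 1 group.csv significance.csv
cfctrack sweep --seed 1 --reps 500 sweep.csv --plot sweep.png
```

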