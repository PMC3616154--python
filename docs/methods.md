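# Methods

This note records the models, parameter choices and numerical decisions
behind `cfctrack`, in the order the pipeline applies them.

## Single frequency tracker

The tracker is a time-varying one-pole complex band-pass applied to the
analytic representation of a band-limited real signal:

* filter: `y(n) = β·e^{jω̂(n)}·y(n−1) + (1−β)·x(n)`, with frequency
  response `H(e^{jω}) = (1−β)/(1−β·e^{j(ω̂−ω)})`. At ω = ω̂ the response
  is exactly `1 + 0j` — unit gain, zero phase — which is what makes the
  output phase directly usable for coupling measures. |H| is strictly
  decreasing away from ω̂.
* frequency estimator: `q(n) = δ·q(n−1) + (1−δ)·y(n)·conj(y(n−1))`,
  `ω̂(n+1) = arg q(n)`. `y(n)·conj(y(n−1))` is a one-sample phase
  increment; q is its exponentially forgotten average, so arg q estimates
  the instantaneous frequency in radians/sample.

Parameters, units, defaults:

* **β** (dimensionless, (0,1)): bandwidth. Solved in closed form from the
  half-power condition `|H|² = 1/2` at the half-bandwidth offset
  Δ = π·B/fs; the default B = 2 Hz at fs = 250 Hz gives β ≈ 0.97517
  (`beta_for_bandwidth`). Narrower bands (β → 1) reject more noise but
  adapt more slowly.
* **δ** (dimensionless, (0,1)): forgetting factor of the frequency
  estimator; default 0.99, i.e. a ~100-sample (400 ms at 250 Hz) memory.
  Small variations around these values change results only marginally.
* **ω̂(0)**: initialized at the centre of the analysis band
  (`SFTParams.for_band`).

Numerical choices: ω̂ is clamped to (ε, π−ε) with ε = 1e−6 so the
instantaneous filter stays a meaningful band-pass; when |q| underflows
(silent stretches) the estimate holds its previous value instead of
emitting `arg 0` (no NaN propagation); q starts at 0 and the mirrored
500 ms head of the input provides burn-in before the first genuine
sample. On a stationary tone the recursion has the tone frequency as a
fixed point (verified to machine precision) and converges from any
in-band initialization; with bounded inputs and β, δ ∈ (0,1) the state is
bounded (stress-tested over 10⁶ noise samples). The per-sample recursion
is JIT-compiled with numba when available; a pure-Python fallback gives
identical results.

Known limitation: adaptation is not instantaneous. After sharp changes in
the input (amplitude ramps, interferer onsets) the estimate needs on the
order of 100–200 ms to re-centre, which delays coupling effects measured
on the tracked path relative to the fixed-filter path.

## Preprocessing

All filters are applied forward and reverse (zero phase): Butterworth
band-passes (SOS form, prototype order 4; one octave outside each band
the two-pass attenuation exceeds 30 dB), a second-order IIR notch
(−3 dB width 1 Hz, default 60 Hz), and polyphase anti-aliased resampling
(default 500 → 250 Hz, line-extrapolated edges). Mirror padding reflects
the first 500 ms excluding the boundary sample (`x[1..n_pad]` reversed);
`trim_head` inverts it exactly. Samples whose analysis windows include
filter transients at the epoch borders remain susceptible to edge
effects; the window constructor exposes which windows lie fully inside
the epoch.

## Analytic signal and phases

Phases and envelopes come from the FFT-based discrete Hilbert transform.
For the two-sinusoid experiment the analytic signal is computed with a
Tukey taper confined to the 500-sample guard regions that are discarded
afterwards (`analytic_signal(..., edge_taper=400)`): the taper removes
the circular-discontinuity leakage of the finite DFT (which otherwise
leaves ~1e−5 phase error even in the interior) without touching any
retained sample. Elsewhere the plain transform is used.

## Coupling measures

* Phase–amplitude PLV (per window): `|mean exp(j(φ_low − φ_ampHigh))|`,
  where φ_ampHigh is the phase of the high component's amplitude
  envelope. By default the envelope is mean-removed and band-passed to
  the low component's band before phase extraction
  (`envelope_mode="band_filtered"`), so the measure picks up envelope
  fluctuations at the modulating rhythm only; `envelope_mode="raw"`
  keeps the literal envelope phase. Both paths are supported because the
  processing of the envelope prior to phase extraction is a genuine
  design choice in the PLV literature.
* n:m phase–phase PLV: `|mean exp(j(n·φ₁ − m·φ₂))|` with n on the
  low-band phase; the grid is 4:3, 3:2, 2:1, 3:1 … 9:1. A pair (n, m)
  is valid for a band pair iff [n·f_lo₁, n·f_hi₁] and
  [m·f_lo₂, m·f_hi₂] overlap with positive length (touching endpoints do
  not count).
* Windows: 300 ms long, shifted 10 ms (75 samples at 250 Hz,
  `round(win_ms·fs)` with the start at centre − ⌊75/2⌋). Post-stimulus
  centres 0–1000 ms give 101 windows.
* Pooling: the sample mean runs over all window samples of all of a
  subject's trials in a condition, giving one value per
  subject × condition × window. Pooling over time and trials jointly
  maximizes the per-window sample count; per-trial PLVs averaged
  afterwards would weight trials equally instead — the pooled choice is
  fixed here and documented.

## Group statistics

PLV features are arcsine-transformed (`asin(√v)`, the standard
variance stabilizer for proportion-like quantities) before testing; mean
frequency is not (it is already approximately Gaussian by averaging).
Per window, a randomized-block ANOVA tests the two-level fixed effect
(dataset or condition) with subject as the block:
`F = MS_group / MS_{group×subject}` on (1, S−1) degrees of freedom —
with two groups this equals the squared paired t statistic. The
implementation is vectorized sums-of-squares; it is cross-checked in the
test suite against a literal sums-of-squares oracle and against
statsmodels' repeated-measures ANOVA.

The decision statistic is the maximal run of consecutive windows with
p < 0.05. Its null distribution is estimated from 1000 permutations that
flip condition labels within subjects — one flip pattern per subject
applied to all windows, preserving subject identity and the windows'
temporal correlation. Flip patterns are drawn uniformly with replacement
from the 2^S possibilities. The run p-value is the fraction of
permutations whose maximal run is at least the observed one (ties count
toward rejection — conservative). An effect is declared only when the
run p-value is below 5% **and** the observed run spans ≥ 4 windows, so
punctual differences are never reported. The run-length distribution is
discrete; with strongly overlapping windows (10 ms shift on 300 ms
windows) it is well spread and the empirical type-I error calibrates
close to the nominal 5% (checked by simulation at 200 datasets × 1000
permutations).

## Synthetic generators

* **Two-sinusoid model**: `x₁ = cos(2π·0.05·n + φ₁) + e₁`,
  `x₂ = (1/3)·cos(2π·0.35·n + φ₂) + e₂`; φᵢ uniform on [0, 2π), phases
  and noises from independent generator substreams. The 1/3 scale mimics
  the 1/f-like power decrease of high-frequency EEG activity. SNR (dB) is
  applied per signal as sinusoid power over noise power *after* the 1/3
  scale, so both signals share the stated SNR and the sweep is symmetric.
  Length 1075 samples: discarding 500 guard samples per end leaves
  exactly one 75-sample phase window (the length of a 300 ms window at
  250 Hz). Since the two phases advance in an exact 7:1 ratio, the 7:1
  PLV is 1 in the noiseless limit — the calibration point of the sweep.
* **EEG-mimicking pair** (fs 250 Hz, 500 samples = 2000 ms): locked
  components at 5.5 and 44 Hz share a time-varying amplitude
  `a(n) = 1 + 10·w(n−125)` with w a 250-sample Hann window (support
  125–374, peak at sample 250 = 1000 ms, centred on the 600–1400 ms
  effect interval); the high channel adds a 36 Hz interferer with its own
  150-sample Hann envelope of peak amplitude 15 on samples 150–299
  (600–1200 ms) and white noise of variance 4, the low channel white
  noise of variance 25. The interferer subsides before the effect
  interval ends, so the fixed-filter PLV recovers late in the interval —
  the signature the experiment checks. Envelope placement, interferer
  amplitude and on/off profile are configuration fields of
  `EEGMimicModel`.
* **Group fixture**: 9 subjects × 2 conditions × 12 trials of 2000 ms
  epochs (stimulus onset 500 ms) with channels `low`
  (5.5 Hz + noise) and `high` (44 Hz, amplitude modulated by the low
  phase with depth κ, + noise). κ has per-subject baseline
  0.30 ± 0.05 (the subject random effect) and condition B gains
  `condition_effect` inside 600–1400 ms. With `condition_effect = 0` the
  conditions are exchangeable, which is what the type-I calibration
  relies on.
* **Surrogates**: positive-frequency DFT phases redrawn uniformly,
  conjugate-mirrored; DC and (even length) Nyquist bins left untouched
  since their phases are constrained to {0, π}. Magnitudes are preserved
  bin-exactly, the output is real, and total energy is conserved
  (Parseval).

What the generators do **not** emulate: volume conduction, electrode
geometry, realistic broadband 1/f spectra, artifacts, or
trial-to-trial latency jitter. Passing tests therefore demonstrate the
correctness and calibration of the algorithms under the stated models,
not performance on real recordings.

## Problem sizes

Monte Carlo defaults are 500 repetitions per condition (the direction of
every tracked-vs-fixed contrast is confirmed at 99% bootstrap
confidence at this size); `--reps` exposes larger runs. The acceptance
script uses 300 repetitions for the two sweeps and 200 datasets × 1000
permutations for the type-I calibration.

## Known limitations

* Single-component tracking only: no harmonic or multi-signal trackers.
* The tracker's adaptation delay shifts detected intervals in time
  relative to the fixed-filter path; no delay compensation is attempted.
* The statistics stage handles exactly two groups with a balanced,
  one-observation-per-cell layout; no multi-level designs, no
  cluster-mass statistics, no correction across band pairs (inference is
  controlled per feature).
* Real-EEG ingestion is limited to pre-cleaned epochs (CSV/npz, optional
  EDF via mne); no artifact rejection or re-referencing is provided.
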