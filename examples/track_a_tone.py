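"""Track a noisy oscillation and recover its instantaneous frequency.

Builds a 40 Hz tone in noise, band-passes it to 35-45 Hz, runs the
adaptive single-frequency tracker, and prints the recovered frequency.
"""

import numpy as np

from cfctrack import BandDefinition, TimeSeries, bandpass, extract_oscillation

fs = 250.0
rng = np.random.default_rng(0)
n = np.arange(1500)
x = np.cos(2 * np.pi * 40.0 / fs * n) + 0.5 * rng.normal(size=n.size)

band = BandDefinition(35, 45)
tracked = extract_oscillation(bandpass(TimeSeries(x, fs=fs), band), band=band)

mean_f = tracked.frequency_hz[250:].mean()
print(f"true frequency        : 40.00 Hz")
print(f"recovered frequency   : {mean_f:.2f} Hz (mean after burn-in)")
print(f"oscillation amplitude : {np.abs(tracked.y[250:]).mean():.2f} (true 1.00)")
print()
print("The tracker's one-pole complex band-pass follows the oscillation with")
print("unit gain and zero phase at its centre frequency, so the phase of the")
print("output can be used directly for coupling measures.")
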