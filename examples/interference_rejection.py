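"""Oscillatory interference: a transient 36 Hz component inside the 35-45 Hz
analysis band.

The EEG-mimicking pair carries perfectly 8:1-locked components at 5.5 and
44 Hz whose amplitude peaks in the 600-1400 ms interval; a 36 Hz
interferer is active 600-1200 ms.  The fixed-filter phase mixes 36 and
44 Hz and the windowed PLV collapses mid-interval, while the tracker
stays centred on the 44 Hz component.
"""

import argparse

import numpy as np

from cfctrack import run_interference_experiment

ap = argparse.ArgumentParser()
ap.add_argument("--reps", type=int, default=100)
ap.add_argument("--seed", type=int, default=0)
args = ap.parse_args()

res = run_interference_experiment(n_reps=args.reps, seed=args.seed)
c = res.window_centers_ms
print(f"{'window span (ms)':>18} {'PLV tracked':>12} {'PLV fixed':>12}")
for lo, hi in [(200, 600), (600, 1000), (1000, 1400), (1400, 1800)]:
    m = (c >= lo) & (c < hi)
    print(f"{f'{lo}-{hi}':>18} {res.mean_plv_tracked[m].mean():12.3f} "
          f"{res.mean_plv_untracked[m].mean():12.3f}")
adv = np.mean(res.span_plv_tracked) - np.mean(res.span_plv_untracked)
print()
print(f"mean tracked advantage over 800-1400 ms: {adv:+.3f}")
print("The tracked PLV stays high through the whole effect interval (after a")
print("short adaptation delay); the fixed-filter PLV dips while the")
print("interference is strong and recovers only as its amplitude drops.")
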