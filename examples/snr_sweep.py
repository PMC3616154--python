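"""Broad-band noise resilience: tracked vs. fixed-filter 7:1 phase locking.

Two sinusoids with an exact 7:1 frequency ratio (normalized frequencies
0.05 and 0.35) are embedded in white noise; without noise their 7:1
phase-phase PLV is exactly 1.  The sweep measures the mean PLV across an
SNR grid with and without adaptive tracking (reduced repetitions for a
quick run; increase --reps to tighten the estimates).
"""

import argparse

from cfctrack import run_snr_sweep

ap = argparse.ArgumentParser()
ap.add_argument("--reps", type=int, default=200)
ap.add_argument("--seed", type=int, default=0)
args = ap.parse_args()

res = run_snr_sweep(n_reps=args.reps, seed=args.seed, snr_grid_db=[0, 5, 10, 15, 20])
print(f"{'SNR (dB)':>9} {'PLV tracked':>12} {'PLV fixed':>12}")
for snr, pt, pu in zip(res.snr_grid, res.mean_plv_tracked, res.mean_plv_untracked):
    print(f"{snr:9.0f} {pt:12.3f} {pu:12.3f}")
print()
print("At low SNR the fixed-filter PLV collapses toward the chance floor")
print("while the adaptive tracker keeps isolating the sinusoids, so its PLV")
print("degrades far more slowly (at the cost of higher variance).")
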