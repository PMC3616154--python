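"""Group-level analysis: injected coupling change, run-length permutation test.

Simulates a balanced two-condition experiment (9 subjects) in which
condition B gains extra phase-amplitude coupling in a post-stimulus
window, then runs the full feature + statistics pipeline on both the
tracked and the fixed-filter path and prints the significance table.
"""

import argparse

import pandas as pd

from cfctrack import gen_group_dataset, run_full_pipeline

ap = argparse.ArgumentParser()
ap.add_argument("--effect", type=float, default=0.5)
ap.add_argument("--subjects", type=int, default=9)
ap.add_argument("--trials", type=int, default=8)
ap.add_argument("--perms", type=int, default=500)
ap.add_argument("--seed", type=int, default=0)
args = ap.parse_args()

ds = gen_group_dataset(args.subjects, args.trials, args.effect, seed=args.seed)
table = run_full_pipeline(ds, n_perm=args.perms, seed=args.seed, envelope_mode="raw")

pd.set_option("display.width", 120)
print(table.to_string(index=False))
print()
print("Each row: the longest run of consecutive windows whose per-window")
print("block ANOVA rejects at 5%, its permutation p-value, and the decision")
print("(run p < 0.05 AND at least 4 successive windows).  The injected")
print("phase-amplitude effect should be flagged; the mean-frequency feature")
print("exists only on the tracked path.")
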