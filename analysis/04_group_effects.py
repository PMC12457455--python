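"""Compare amount and rate of forest change across transition land covers.

Reads the per-cell records of the pipeline run and reports, per trajectory
direction and response, the per-transition-LC summary table (n, quartiles,
mean, SD, mean minus pooled mean) and pairwise Cliff's deltas with 95%
confidence intervals.  Writes results/group_effects.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from foresttraj.stats import pairwise_cliffs_delta, summaries_frame, summarize_groups


def main():
    rec_path = Path("results/run/records.csv")
    if not rec_path.exists():
        print("run 03_run_pipeline.py first", file=sys.stderr)
        return 1
    df = pd.read_csv(rec_path)
    kept = df[df.retained]
    rows = []
    for direction, sub in kept.groupby("trajectory_class"):
        for response in ("amount_of_change", "rate_of_change"):
            sf = summaries_frame(summarize_groups(sub[response], sub["transition_lc_name"]))
            sf.insert(0, "response", response)
            sf.insert(0, "direction", direction)
            rows.append(sf)
            print(f"\n{direction} / {response}:")
            print(sf.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
            if sub["transition_lc_name"].nunique() >= 2:
                dd = pairwise_cliffs_delta(sub[response], sub["transition_lc_name"])
                big = dd.loc[dd.delta.abs().idxmax()]
                print(f"  largest |Cliff's delta|: {big.group_x} vs {big.group_y}: "
                      f"{big.delta:+.3f} [{big.ci_low:+.3f}, {big.ci_high:+.3f}]")
    out = pd.concat(rows, ignore_index=True)
    out.to_csv("results/group_effects.csv", index=False)
    print("\nwrote results/group_effects.csv")


if __name__ == "__main__":
    sys.exit(main())
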