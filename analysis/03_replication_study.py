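"""Synthetic internal-replication study.

Builds pools of randomized trials that share an outcome model but differ by
a covariate mean shift, then assembles artificial non-randomized comparisons
by pairing arms across trials:

* negative-control mode pairs same-treatment arms (true ATT = 0) and reports
  MAE/MSE against zero, CI width and coverage of zero;
* RCT-replication mode pairs a treatment arm with another trial's control
  arm and scores pseudo-bias, pseudo-MSE, estimate agreement and regulatory
  agreement against the within-trial randomized estimate.

Writes per-mode reports and comparison tables under results/replication/.
"""

import argparse
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from eca_bench import ScenarioConfig, generate_trial_pool
from eca_bench.runner import run_replication_study

METHODS = ("unadjusted", "psm", "iptw", "gcomp", "ddml")


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--trials", type=int, default=3)
    ap.add_argument("--n-per-trial", type=int, default=400)
    ap.add_argument("--shift", type=float, default=1.0)
    ap.add_argument("--bootstrap", type=int, default=100)
    ap.add_argument("--seed", type=int, default=3)
    ap.add_argument("--out", type=str, default="results/replication")
    args = ap.parse_args()

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    pool = generate_trial_pool(args.trials, 2, args.shift,
                               ScenarioConfig(n=args.n_per_trial, seed=args.seed),
                               rng=args.seed)
    pool.save(out / "pool")

    for mode in ("negative_control", "rct_replication"):
        reports, table = run_replication_study(pool, mode, methods=METHODS,
                                               n_boot=args.bootstrap,
                                               seed=args.seed)
        rep_df = pd.DataFrame([asdict(r) for r in reports.values()])
        rep_df = rep_df.drop(columns=["details"])
        rep_df.to_csv(out / f"{mode}_report.csv", index=False, float_format="%.10g")
        table.to_csv(out / f"{mode}_comparisons.csv", index=False,
                     float_format="%.10g")
        cols = [c for c in ("method", "n_comparisons", "pseudo_bias", "mae",
                            "pseudo_mse", "mean_ci_width", "coverage",
                            "estimate_agreement", "regulatory_agreement")
                if c in rep_df.columns]
        print(f"\n{mode} ({rep_df.n_comparisons.iloc[0]} comparisons, "
              f"shift {args.shift}):")
        print(rep_df[cols].to_string(index=False))
    print("\nExpected: adjusted methods shrink MSE relative to the unadjusted "
          "contrast once the shift induces confounding; gcomp narrowest CIs.")
    print(f"Outputs under {out.resolve()}")


if __name__ == "__main__":
    main()
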