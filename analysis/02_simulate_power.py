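"""Power, bias, error and CI-width study under the alternative hypothesis.

Draws treatment effects from the N(0, 0.4-variance) prior, runs all five
estimators with full inference, and tabulates power at P < 0.05, bias, MAE,
MSE and the matched-Gaussian log CI width per sample size — for either
simulation scenario (homogeneous or heterogeneous effects).

Writes results/power*/summary.csv and prints the per-method tables.
"""

import argparse
from pathlib import Path

from eca_bench.runner import StudyConfig, run_simulation_study


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--reps", type=int, default=100)
    ap.add_argument("--bootstrap", type=int, default=100)
    ap.add_argument("--ddml-splits", type=int, default=5)
    ap.add_argument("--sizes", type=int, nargs="+", default=[250, 500, 1000])
    ap.add_argument("--scenario", type=int, default=1, choices=[1, 2])
    ap.add_argument("--seed", type=int, default=2)
    ap.add_argument("--out", type=str, default="results/power")
    args = ap.parse_args()

    cfg = StudyConfig(scenarios=(args.scenario,), sample_sizes=tuple(args.sizes),
                      hypotheses=("alternative",),
                      methods=("unadjusted", "psm", "iptw", "gcomp", "ddml"),
                      n_replicates=args.reps, n_boot=args.bootstrap,
                      ddml_splits=args.ddml_splits, master_seed=args.seed,
                      out_dir=args.out)
    summary, _ = run_simulation_study(cfg)
    for metric in ("power", "bias", "mae", "mse", "ci_log_width"):
        print(f"\n{metric} (scenario {args.scenario}, {args.reps} replicates):")
        print(summary.pivot(index="method", columns="n", values=metric).to_string())
    print("\nExpected: outcome-model methods (gcomp, ddml) least biased; "
          "gcomp narrowest CIs and highest power; DDML conservative at small n.")
    print(f"Tables under {Path(args.out).resolve()}")


if __name__ == "__main__":
    main()
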