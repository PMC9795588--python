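"""Type-I-error study: all five ATT estimators under the scenario-1 null.

Generates confounded two-arm datasets with a zero treatment effect at
n = 250, 500, 1000 and measures how often each estimator rejects at
P < 0.05. The unadjusted contrast shows the inflation induced by
confounding; the four adjusted methods should stay near the nominal 5%.

Writes results/null_summary.csv and prints the rejection-rate table.
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
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=str, default="results/null")
    args = ap.parse_args()

    cfg = StudyConfig(scenarios=(args.scenario,), sample_sizes=tuple(args.sizes),
                      hypotheses=("null",),
                      methods=("unadjusted", "psm", "iptw", "gcomp", "ddml"),
                      n_replicates=args.reps, n_boot=args.bootstrap,
                      ddml_splits=args.ddml_splits, master_seed=args.seed,
                      out_dir=args.out)
    summary, _ = run_simulation_study(cfg)
    table = summary.pivot(index="method", columns="n", values="type_I_error")
    print(f"\nType I error at P<0.05 (scenario {args.scenario}, "
          f"{args.reps} replicates):\n")
    print(table.to_string())
    print("\nExpected: unadjusted well above 0.05 and growing with n; "
          "adjusted methods near or below 0.05 (DDML conservative).")
    print(f"Tables under {Path(args.out).resolve()}")


if __name__ == "__main__":
    main()
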