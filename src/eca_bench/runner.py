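"""Seeded orchestration of Monte Carlo simulation studies and replication
experiments.

Every replicate seed is a deterministic function of (master seed, condition,
replicate index) through :class:`numpy.random.SeedSequence`, so a study is
reproducible end to end and each replicate can be regenerated in isolation.
Two independent streams are derived per replicate: one for data generation
and one for estimation (CV folds, bootstrap resamples, DDML splits).
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import ScenarioConfig, TrialPool
from .dgp import generate_dataset
from .inference import estimate_att_many
from .metrics import ReplicationReport, replication_metrics, summarize_replicates

__all__ = ["StudyConfig", "run_simulation_study", "run_replication_study",
           "replicate_seed"]

logger = logging.getLogger(__name__)

ALL_METHODS = ("unadjusted", "psm", "iptw", "gcomp", "ddml")


@dataclass
class StudyConfig:
    """Configuration of a Monte Carlo simulation study."""

    scenarios: tuple = (1,)
    sample_sizes: tuple = (250, 500, 1000)
    hypotheses: tuple = ("null", "alternative")
    methods: tuple = ALL_METHODS
    n_replicates: int = 300
    n_boot: int = 300
    ddml_folds: int = 2
    ddml_splits: int = 20
    caliper: float = 0.25
    cv_folds: int = 5
    master_seed: int = 0
    out_dir: str | None = None

    def conditions(self):
        return list(itertools.product(self.scenarios, self.sample_sizes, self.hypotheses))

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), default=list, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "StudyConfig":
        d = json.loads(text)
        for k in ("scenarios", "sample_sizes", "hypotheses", "methods"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def replicate_seed(master_seed: int, scenario: int, n: int, null: bool,
                   rep: int, stream: int) -> np.random.Generator:
    """Deterministic per-replicate RNG; ``stream`` 0 = data, 1 = estimation."""
    ss = np.random.SeedSequence([int(master_seed), int(scenario), int(n),
                                 int(null), int(rep), int(stream)])
    return np.random.default_rng(ss)


def _condition_replicates(config: StudyConfig, scenario: int, n: int, null: bool):
    """Yield (rep, dataset, truth, estimation rng) for one condition."""
    for rep in range(config.n_replicates):
        data_rng = replicate_seed(config.master_seed, scenario, n, null, rep, 0)
        seed = int(data_rng.integers(2 ** 31))
        cfg = ScenarioConfig(scenario=scenario, n=n, null_hypothesis=null, seed=seed)
        data, truth = generate_dataset(cfg)
        est_rng = replicate_seed(config.master_seed, scenario, n, null, rep, 1)
        yield rep, data, truth, est_rng


def run_simulation_study(config: StudyConfig):
    """Run the full Monte Carlo study.

    Returns ``(summary, estimates)``: a tidy per-(condition, method) summary
    table and the per-replicate estimate table. Estimator failures on a
    replicate are recorded as missing and reported, not fatal. If
    ``config.out_dir`` is set, both tables and a run manifest are written
    there with fixed float formatting (byte-identical for a fixed seed).
    """
    rows = []
    summaries = []
    for scenario, n, hyp in config.conditions():
        null = hyp == "null"
        n_missing = 0
        per_method = {m: [] for m in config.methods}
        truths = {m: [] for m in config.methods}
        for rep, data, truth, est_rng in _condition_replicates(config, scenario, n, null):
            try:
                ests = estimate_att_many(
                    data, config.methods, n_boot=config.n_boot,
                    caliper=config.caliper, cv_folds=config.cv_folds,
                    ddml_folds=config.ddml_folds, ddml_splits=config.ddml_splits,
                    rng=est_rng)
            except (ValueError, RuntimeError) as exc:
                n_missing += 1
                logger.warning("replicate %d of condition (%d, %d, %s) failed: %s",
                               rep, scenario, n, hyp, exc)
                continue
            for m, e in ests.items():
                per_method[m].append(e)
                truths[m].append(truth.att)
                rows.append({
                    "scenario": scenario, "n": n, "hypothesis": hyp,
                    "replicate": rep, "method": m, "att_true": truth.att,
                    "att_hat": e.att, "se": e.se, "ci_low": e.ci_low,
                    "ci_high": e.ci_high, "p_value": e.p_value,
                })
        for m in config.methods:
            if not per_method[m]:
                continue
            s = summarize_replicates(per_method[m], truths[m], method=m)
            s.n_missing = n_missing
            summaries.append({
                "scenario": scenario, "n": n, "hypothesis": hyp, "method": m,
                "n_replicates": s.n_replicates, "n_missing": n_missing,
                "bias": s.bias, "mae": s.mae, "mse": s.mse,
                "type_I_error": s.rejection_rate if null else np.nan,
                "power": np.nan if null else s.rejection_rate,
                "coverage": s.coverage, "mean_ci_width": s.mean_ci_width,
                "ci_log_width": s.ci_log_width,
            })
        logger.info("condition (scenario=%d, n=%d, %s): %d replicates, %d failed",
                    scenario, n, hyp, config.n_replicates, n_missing)
    summary = pd.DataFrame(summaries)
    estimates = pd.DataFrame(rows)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "summary.csv", index=False, float_format="%.10g")
        estimates.to_csv(out / "estimates.csv", index=False, float_format="%.10g")
        manifest = {"config": json.loads(config.to_json()), "version": __version__}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return summary, estimates


def _negative_control_comparisons(pool: TrialPool):
    for label in pool.treatment_labels:
        for i, j in itertools.permutations(range(pool.n_trials), 2):
            yield {"label": label, "experimental_trial": i, "control_trial": j,
                   "data": pool.trials[i].two_arm(label, label, pool.trials[j])}


def _rct_comparisons(pool: TrialPool):
    active = [l for l in pool.treatment_labels if l != "control"]
    for label in active:
        for i, j in itertools.permutations(range(pool.n_trials), 2):
            yield {"label": label, "experimental_trial": i, "control_trial": j,
                   "data": pool.trials[i].two_arm(label, "control", pool.trials[j]),
                   "rct_data": pool.trials[i].two_arm(label, "control")}


def run_replication_study(pool: TrialPool, mode: str, methods=ALL_METHODS,
                          n_boot: int = 300, caliper: float = 0.25,
                          cv_folds: int = 5, ddml_folds: int = 2,
                          ddml_splits: int = 20, seed: int = 0,
                          point_only: bool = False):
    """Evaluate estimators on all artificial comparisons a pool supports.

    ``negative_control`` pairs same-treatment arms from distinct trials (true
    ATT = 0); ``rct_replication`` pairs a treatment arm with another trial's
    control arm and benchmarks against the within-trial randomized estimate.
    With ``point_only`` the bootstrap is skipped (point estimates; metrics
    needing CIs or p-values are then undefined for bootstrap methods).

    Returns ``(reports, comparisons)``: per-method
    :class:`~eca_bench.metrics.ReplicationReport` and a tidy per-comparison
    table.
    """
    if mode == "negative_control":
        comparisons = list(_negative_control_comparisons(pool))
    elif mode == "rct_replication":
        comparisons = list(_rct_comparisons(pool))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not comparisons:
        raise ValueError("pool supports no comparison in this mode")

    ss = np.random.SeedSequence([int(seed), {"negative_control": 0,
                                             "rct_replication": 1}[mode]])
    child = ss.spawn(len(comparisons))
    per_method = {m: [] for m in methods}
    rct_refs = []
    rows = []
    for comp, cs in zip(comparisons, child):
        rng = np.random.default_rng(cs)
        if point_only:
            from .inference import _fit_and_point
            from .estimators import estimate_ddml
            from .datatypes import ATTEstimate
            boot = [m for m in methods if m != "ddml"]
            pts, _ = _fit_and_point(comp["data"], boot, caliper, cv_folds,
                                    None, None, rng)
            ests = {m: ATTEstimate(method=m, att=pts[m]) for m in boot}
            if "ddml" in methods:
                ests["ddml"] = estimate_ddml(comp["data"], ddml_folds, ddml_splits,
                                             cv_folds, rng=rng)
        else:
            ests = estimate_att_many(comp["data"], methods, n_boot=n_boot,
                                     caliper=caliper, cv_folds=cv_folds,
                                     ddml_folds=ddml_folds, ddml_splits=ddml_splits,
                                     rng=rng)
        if mode == "rct_replication":
            from .inference import bootstrap_joint
            rct_refs.append(bootstrap_joint(comp["rct_data"], ("unadjusted",),
                                            B=n_boot, rng=rng)["unadjusted"])
        for m in methods:
            e = ests[m]
            row = {"mode": mode, "label": comp["label"],
                   "experimental_trial": comp["experimental_trial"],
                   "control_trial": comp["control_trial"], "method": m,
                   "att_hat": e.att, "se": e.se, "ci_low": e.ci_low,
                   "ci_high": e.ci_high, "p_value": e.p_value}
            if mode == "rct_replication":
                row["rct_att"] = rct_refs[-1].att
                row["rct_p"] = rct_refs[-1].p_value
            rows.append(row)
            per_method[m].append(e)

    reports = {}
    for m in methods:
        reports[m] = replication_metrics(
            per_method[m], rct_refs if mode == "rct_replication" else None,
            mode=mode, method=m)
    return reports, pd.DataFrame(rows)
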