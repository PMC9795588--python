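"""Evaluation metrics for Monte Carlo studies and replication experiments.

Monte Carlo summaries report, per method and condition: bias, mean absolute
error, mean squared error, the rejection rate at a significance cutoff
(type I error under the null, power under the alternative), CI coverage of
the truth, and a confidence-interval width statistic expressed as the log
variance of a Gaussian whose 95% interval would have the observed mean width.

Replication summaries mirror the internal-replication designs: against a
known null (negative-control comparisons) or against a reference randomized
estimate (pseudo-bias, pseudo-MSE, estimate agreement — the fraction of
non-randomized estimates inside the RCT's 95% CI — and regulatory agreement
— the fraction of comparisons where both analyses make the same significance
call at P < 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SimulationSummary",
    "ReplicationReport",
    "summarize_replicates",
    "ci_log_width",
    "replication_metrics",
]

Z975 = 1.959964


@dataclass
class SimulationSummary:
    """Per-method Monte Carlo metrics over replicates of one condition."""

    method: str
    n_replicates: int
    bias: float
    mae: float
    mse: float
    rejection_rate: float
    coverage: float
    mean_ci_width: float
    ci_log_width: float
    is_null: bool
    alpha: float = 0.05
    n_missing: int = 0

    @property
    def type_I_error(self):
        return self.rejection_rate if self.is_null else None

    @property
    def power(self):
        return None if self.is_null else self.rejection_rate


@dataclass
class ReplicationReport:
    """Per-method metrics over a set of artificial two-arm comparisons."""

    method: str
    mode: str
    n_comparisons: int
    pseudo_bias: float
    mae: float
    pseudo_mse: float
    mean_ci_width: float
    coverage: float | None = None
    estimate_agreement: float | None = None
    estimate_agreement_counts: tuple | None = None
    regulatory_agreement: float | None = None
    regulatory_agreement_counts: tuple | None = None
    details: dict = field(default_factory=dict)


def summarize_replicates(estimates, truths, alpha: float = 0.05,
                         method: str = "") -> SimulationSummary:
    """Summarize replicate-level ATT estimates against their ground truths.

    ``estimates`` is a sequence of :class:`~eca_bench.datatypes.ATTEstimate`;
    ``truths`` the matching true ATT values. The rejection rate is the
    fraction of p-values below ``alpha`` (type I error when every truth is 0,
    power otherwise); coverage is the fraction of CIs containing the truth.
    """
    estimates = list(estimates)
    truths = np.asarray(truths, float)
    if len(estimates) == 0 or len(estimates) != truths.size:
        raise ValueError("estimates and truths must be non-empty and matched")
    att = np.array([e.att for e in estimates])
    p = np.array([e.p_value for e in estimates])
    lo = np.array([e.ci_low for e in estimates])
    hi = np.array([e.ci_high for e in estimates])
    err = att - truths
    is_null = bool(np.all(truths == 0.0))
    widths = hi - lo
    return SimulationSummary(
        method=method or (estimates[0].method if estimates else ""),
        n_replicates=len(estimates),
        bias=float(err.mean()),
        mae=float(np.abs(err).mean()),
        mse=float((err ** 2).mean()),
        rejection_rate=float((p < alpha).mean()),
        coverage=float(((lo <= truths) & (truths <= hi)).mean()),
        mean_ci_width=float(widths.mean()),
        ci_log_width=ci_log_width(widths) if np.all(widths > 0) else float("nan"),
        is_null=is_null,
        alpha=alpha,
    )


def ci_log_width(ci_widths) -> float:
    """CI width on the matched-Gaussian log-variance scale.

    The mean width w over replicates is matched to the Gaussian whose 95%
    interval has that width: sd = w / (2 * 1.959964). Returns log(sd^2)
    (natural log).
    """
    w = np.asarray(ci_widths, float)
    if w.size == 0 or np.any(w <= 0):
        raise ValueError("CI widths must be positive")
    sd = w.mean() / (2.0 * Z975)
    return float(np.log(sd ** 2))


def replication_metrics(eca_estimates, rct_references=None,
                        mode: str = "negative_control",
                        method: str = "", alpha: float = 0.05) -> ReplicationReport:
    """Aggregate ECA estimates over artificial comparisons.

    ``negative_control`` mode: the truth is 0 for every comparison
    (``rct_references`` must be None or all zeros); reports MAE/MSE against
    zero, mean CI width and coverage of zero.

    ``rct_replication`` mode: ``rct_references`` supplies the randomized
    benchmark per comparison as objects with ``att``, ``ci_low``, ``ci_high``
    and ``p_value`` (e.g. ATTEstimate). Reports pseudo-bias and pseudo-MSE
    (randomized minus non-randomized), estimate agreement and regulatory
    agreement, with numerator/denominator counts retained.
    """
    eca = list(eca_estimates)
    n = len(eca)
    if n == 0:
        raise ValueError("no comparisons supplied")
    att = np.array([e.att for e in eca])
    widths = np.array([e.ci_high - e.ci_low for e in eca])

    if mode == "negative_control":
        if rct_references is not None:
            ref = np.asarray([getattr(r, "att", r) for r in rct_references], float)
            if np.any(ref != 0.0):
                raise ValueError("negative-control mode requires null references")
        err = att - 0.0
        cover = np.array([(e.ci_low <= 0.0 <= e.ci_high) for e in eca])
        return ReplicationReport(
            method=method, mode=mode, n_comparisons=n,
            pseudo_bias=float(err.mean()), mae=float(np.abs(err).mean()),
            pseudo_mse=float((err ** 2).mean()),
            mean_ci_width=float(widths.mean()),
            coverage=float(cover.mean()),
        )

    if mode == "rct_replication":
        if rct_references is None or len(list(rct_references)) != n:
            raise ValueError("rct_replication mode needs one reference per comparison")
        refs = list(rct_references)
        diff = np.array([r.att for r in refs]) - att
        inside = np.array([r.ci_low <= e.att <= r.ci_high for e, r in zip(eca, refs)])
        agree = np.array([(e.p_value < alpha) == (r.p_value < alpha)
                          for e, r in zip(eca, refs)])
        return ReplicationReport(
            method=method, mode=mode, n_comparisons=n,
            pseudo_bias=float(diff.mean()), mae=float(np.abs(diff).mean()),
            pseudo_mse=float((diff ** 2).mean()),
            mean_ci_width=float(widths.mean()),
            estimate_agreement=float(inside.mean()),
            estimate_agreement_counts=(int(inside.sum()), n),
            regulatory_agreement=float(agree.mean()),
            regulatory_agreement_counts=(int(agree.sum()), n),
        )

    raise ValueError(f"unknown mode {mode!r}")
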