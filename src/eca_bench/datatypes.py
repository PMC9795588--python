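"""Core containers for external-control-arm ATT analysis.

The package works on two-arm tabular comparisons: a continuous outcome ``Y``,
a binary treatment indicator ``T`` (1 = experimental arm, 0 = control /
external arm) and a real covariate matrix ``X``. The estimand throughout is
the average treatment effect on the treated,

    ATT = E[Y^1 - Y^0 | T = 1].
"""

from __future__ import annotations

import dataclasses
import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ObservationalDataset",
    "ATTEstimate",
    "MatchResult",
    "ScenarioConfig",
    "GroundTruth",
    "Trial",
    "TrialPool",
]


@dataclass(frozen=True)
class ObservationalDataset:
    """One two-arm comparison: covariates ``X`` (n x d), treatment ``T`` and outcome ``Y``.

    Complete cases only: no missing values are allowed, and each arm must hold
    at least two units so that variances are estimable.
    """

    X: np.ndarray
    T: np.ndarray
    Y: np.ndarray

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        T = np.asarray(self.T)
        Y = np.asarray(self.Y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        n = X.shape[0]
        if T.shape != (n,) or Y.shape != (n,):
            raise ValueError("X, T, Y must share their first dimension")
        if not np.isin(T, (0, 1)).all():
            raise ValueError("T must be binary (0 = control, 1 = experimental)")
        if not (np.isfinite(X).all() and np.isfinite(Y).all()):
            raise ValueError("missing or non-finite values are not supported")
        T = T.astype(np.int64)
        if (T == 1).sum() < 2 or (T == 0).sum() < 2:
            raise ValueError("each arm needs at least 2 units")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "T", T)
        object.__setattr__(self, "Y", Y)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def n_treated(self) -> int:
        return int((self.T == 1).sum())

    @property
    def n_control(self) -> int:
        return int((self.T == 0).sum())

    def subset(self, idx: np.ndarray) -> "ObservationalDataset":
        return ObservationalDataset(self.X[idx], self.T[idx], self.Y[idx])

    # --- CSV interface: header y,t,x1,...,xd; one row per patient ----------
    def to_frame(self) -> pd.DataFrame:
        cols = {"y": self.Y, "t": self.T}
        for j in range(self.d):
            cols[f"x{j + 1}"] = self.X[:, j]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        # fixed float formatting keeps output byte-identical across runs
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    def to_csv_string(self) -> str:
        buf = io.StringIO()
        self.to_csv(buf)
        return buf.getvalue()

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ObservationalDataset":
        xcols = [c for c in df.columns if c.startswith("x")]
        xcols.sort(key=lambda c: int(c[1:]))
        return cls(df[xcols].to_numpy(float), df["t"].to_numpy(), df["y"].to_numpy(float))

    @classmethod
    def from_csv(cls, path) -> "ObservationalDataset":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class ATTEstimate:
    """Point estimate of the ATT with its inference summary."""

    method: str
    att: float
    se: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    p_value: float = float("nan")
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.isfinite(self.se) and self.se < 0:
            raise ValueError("se must be non-negative")
        if np.isfinite(self.p_value) and not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")

    @property
    def ci_width(self) -> float:
        return self.ci_high - self.ci_low


@dataclass
class MatchResult:
    """Outcome of greedy 1:1 propensity matching without replacement."""

    pairs: list  # (treated index, control index), in selection order
    caliper: float
    discarded_treated: list

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


@dataclass
class ScenarioConfig:
    """Parameterization of one synthetic data draw.

    Scenario 1 has a homogeneous treatment effect (constant shift theta);
    scenario 2 adds treatment-covariate interactions so the effect is
    heterogeneous. ``theta_variance`` is the variance (not the sd) of the
    Gaussian prior on the effect size under the alternative.
    """

    scenario: int = 1
    n: int = 500
    d: int = 20
    n_exposure_covariates: int = 5
    n_outcome_covariates: int = 10
    theta_variance: float = 0.4
    null_hypothesis: bool = False
    cov_alpha: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in (1, 2):
            raise ValueError("scenario must be 1 or 2")
        if self.n_exposure_covariates > self.d or self.n_outcome_covariates > self.d:
            raise ValueError("covariate subset sizes cannot exceed d")
        if self.theta_variance <= 0:
            raise ValueError("theta_variance must be positive")
        if not 0.0 <= self.cov_alpha <= 1.0:
            raise ValueError("cov_alpha must lie in [0, 1]")

    def replace(self, **kw) -> "ScenarioConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """True generative quantities attached to a synthetic dataset."""

    theta: float
    att: float
    beta: np.ndarray
    omega: np.ndarray | None = None       # scenario 1 outcome permutation
    omega0: np.ndarray | None = None      # scenario 2 control-arm permutation
    omega1: np.ndarray | None = None      # scenario 2 treated-arm permutation


@dataclass
class Trial:
    """A randomized trial in a synthetic pool: one cohort split into labelled arms."""

    trial_id: str
    arms: dict                      # label -> (X, Y)
    shift: np.ndarray               # covariate mean shift of this trial's population

    @property
    def labels(self) -> list:
        return list(self.arms)

    def two_arm(self, experimental_label: str, control_label: str,
                control_trial: "Trial | None" = None) -> ObservationalDataset:
        """Assemble a two-arm dataset, optionally replacing the control arm
        with an arm from another trial (the external-control construction)."""
        Xe, Ye = self.arms[experimental_label]
        src = control_trial if control_trial is not None else self
        Xc, Yc = src.arms[control_label]
        X = np.vstack([Xe, Xc])
        T = np.concatenate([np.ones(len(Ye), dtype=int), np.zeros(len(Yc), dtype=int)])
        Y = np.concatenate([Ye, Yc])
        return ObservationalDataset(X, T, Y)


@dataclass
class TrialPool:
    """A pool of randomized trials sharing the outcome model but differing in
    covariate distributions, from which artificial non-randomized comparisons
    are assembled."""

    trials: list
    treatment_labels: list
    treatment_effects: dict         # label -> additive effect on the outcome
    shift_scale: float
    seed: int

    def __post_init__(self):
        if len(self.trials) < 2:
            raise ValueError("a pool needs at least 2 trials to build an ECA")
        d = {t.arms[l][0].shape[1] for t in self.trials for l in t.labels}
        if len(d) != 1:
            raise ValueError("all trials must share the covariate dimension")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {
            "treatment_labels": self.treatment_labels,
            "treatment_effects": {k: float(v) for k, v in self.treatment_effects.items()},
            "shift_scale": float(self.shift_scale),
            "seed": int(self.seed),
            "trials": [],
        }
        for t in self.trials:
            entry = {"trial_id": t.trial_id, "shift": [float(v) for v in t.shift], "arms": {}}
            for label, (X, Y) in t.arms.items():
                fname = f"{t.trial_id}_{label}.csv"
                df = pd.DataFrame(Y[:, None], columns=["y"]).join(
                    pd.DataFrame(X, columns=[f"x{j + 1}" for j in range(X.shape[1])])
                )
                df.to_csv(out / fname, index=False, float_format="%.12g")
                entry["arms"][label] = fname
            manifest["trials"].append(entry)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, in_dir) -> "TrialPool":
        src = Path(in_dir)
        manifest = json.loads((src / "manifest.json").read_text())
        trials = []
        for entry in manifest["trials"]:
            arms = {}
            for label, fname in entry["arms"].items():
                df = pd.read_csv(src / fname)
                xcols = sorted([c for c in df.columns if c.startswith("x")],
                               key=lambda c: int(c[1:]))
                arms[label] = (df[xcols].to_numpy(float), df["y"].to_numpy(float))
            trials.append(Trial(entry["trial_id"], arms, np.asarray(entry["shift"], float)))
        return cls(
            trials=trials,
            treatment_labels=manifest["treatment_labels"],
            treatment_effects=manifest["treatment_effects"],
            shift_scale=manifest["shift_scale"],
            seed=manifest["seed"],
        )
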