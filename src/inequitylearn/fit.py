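"""Per-subject maximum-likelihood fitting and AIC model comparison.

The estimator follows the statsmodels idiom: ``ChoiceModelMLE`` binds a
choice model to one subject's Learning-phase trial sequence, ``fit()`` runs
bounded multi-start optimization (uniform random starts in each parameter's
box, log-uniform for scale parameters) and returns a ``ChoiceModelResults``
carrying the best parameters, the negative log-likelihood in nats, the AIC
and optimizer diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .models import MODELS, ChoiceModel, get_model
from .models._kernels import nll_preference_inference, nll_qtable, nll_similarity
from .models.learners import N_TYPES, SimilarityRL
from .models.primitives import PROB_FLOOR
from .task import OFFER_LABELS

_TYPE_TO_IDX = {lab: i for i, lab in enumerate(OFFER_LABELS)}
_ACTION_CODE = {"accept": 0, "reject": 1, 0: 0, 1: 1, False: 0, True: 1}


class FittingError(RuntimeError):
    """Raised when no optimization start converges; carries diagnostics."""

    def __init__(self, message: str, diagnostics: list | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


@dataclass(frozen=True)
class TrialData:
    """One subject's ordered trial sequence, in likelihood-ready arrays."""

    type_idx: np.ndarray  # 0..4, ordered 90:10 .. 10:90
    share: np.ndarray  # noisy receiver share, float
    action: np.ndarray  # 1 = reject, 0 = accept
    teacher: np.ndarray  # 1/0, or -1 on no-feedback trials
    weight: np.ndarray  # 1.0 where the choice contributes to the likelihood

    def __post_init__(self):
        n = len(self.type_idx)
        for name in ("share", "action", "teacher", "weight"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"trial array {name!r} length mismatch")

    @property
    def n_trials(self) -> int:
        return int(len(self.type_idx))

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        phase: str | None = "learning",
        include_no_feedback: bool = True,
    ) -> "TrialData":
        """Build from a tidy trial-record frame (one subject).

        ``include_no_feedback=False`` keeps no-feedback trials in the
        sequence (their predictions still advance through time) but removes
        their choices from the likelihood.
        """
        if phase is not None and "phase" in df.columns:
            df = df[df["phase"] == phase]
        if "action" not in df.columns:
            raise ValueError("trial frame has no 'action' column")
        if df["action"].isna().any():
            bad = df.index[df["action"].isna()][0]
            raise ValueError(f"missing action at row {bad}")
        if "trial" in df.columns:
            df = df.sort_values("trial", kind="stable")
        type_idx = df["offer_type"].map(_TYPE_TO_IDX).to_numpy(dtype=np.int64)
        share = df["receiver_share"].to_numpy(dtype=float)
        action = df["action"].map(_ACTION_CODE).to_numpy(dtype=np.int64)
        if "teacher_action" in df.columns:
            teacher = (
                df["teacher_action"]
                .map(_ACTION_CODE)
                .astype("float")
                .fillna(-1)
                .to_numpy(dtype=np.int64)
            )
        else:
            teacher = np.full(len(df), -1, dtype=np.int64)
        weight = np.ones(len(df))
        if not include_no_feedback:
            weight[teacher < 0] = 0.0
        return cls(type_idx=type_idx, share=share, action=action, teacher=teacher, weight=weight)


def negative_log_likelihood(
    model: ChoiceModel | int | str,
    theta: np.ndarray,
    data: TrialData,
    method: str = "fast",
) -> float:
    """NLL (nats) of a parameter vector on one subject's trial sequence.

    ``method='fast'`` dispatches to vectorized/compiled evaluators;
    ``method='loop'`` runs the literal per-trial loop over the model object
    API. The two agree to 1e-10 and the loop route is the reference.
    """
    model = get_model(model)
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (model.k,):
        raise ValueError(f"{model.name} expects {model.k} parameters, got {theta.shape}")
    if not np.all(np.isfinite(theta)):
        raise ValueError(f"non-finite parameters: {theta}")
    if method == "loop":
        return _nll_loop(model, theta, data)
    if method != "fast":
        raise ValueError(f"unknown method {method!r}")
    return _nll_fast(model, theta, data)


def _nll_loop(model: ChoiceModel, theta: np.ndarray, data: TrialData) -> float:
    state = model.init_state(theta)
    total = 0.0
    for t in range(data.n_trials):
        p = model.predict_reject(theta, state, int(data.type_idx[t]), float(data.share[t]))
        p_choice = p if data.action[t] == 1 else 1.0 - p
        ll = math.log(max(p_choice, PROB_FLOOR))
        if math.isnan(ll):
            raise FloatingPointError(f"NaN likelihood at trial {t}")
        total -= data.weight[t] * ll
        if data.teacher[t] >= 0:
            model.update(
                theta,
                state,
                int(data.type_idx[t]),
                float(data.share[t]),
                int(data.action[t]),
                int(data.teacher[t]),
            )
    return total


def _nll_fast(model: ChoiceModel, theta: np.ndarray, data: TrialData) -> float:
    mid = model.model_id
    if mid == 1:
        p = theta[data.type_idx]
    elif mid == 2:
        alpha, beta, tau = theta
        u_acc = (
            data.share
            - alpha * np.maximum(50.0 - data.share, 0.0)
            - beta * np.maximum(data.share - 50.0, 0.0)
        )
        p = expit(-tau * u_acc)
    elif mid == 3:
        total = nll_qtable(
            np.full(N_TYPES, theta[0]),
            theta[1],
            np.full(N_TYPES, 0.5),
            data.type_idx,
            data.action,
            data.teacher,
            data.weight,
        )
        return float(total)
    elif mid == 4:
        return float(
            nll_qtable(
                np.ascontiguousarray(theta[:N_TYPES]),
                theta[N_TYPES],
                np.full(N_TYPES, 0.5),
                data.type_idx,
                data.action,
                data.teacher,
                data.weight,
            )
        )
    elif mid == 5:
        return float(
            nll_qtable(
                np.full(N_TYPES, theta[0]),
                theta[1],
                np.ascontiguousarray(theta[2:]),
                data.type_idx,
                data.action,
                data.teacher,
                data.weight,
            )
        )
    elif mid == 6:
        return float(
            nll_preference_inference(
                theta[0], theta[1], theta[2], theta[3],
                data.share, data.action, data.teacher, data.weight,
            )
        )
    elif mid == 7:
        return float(
            nll_similarity(
                theta[0], theta[1], theta[2], theta[3], theta[4],
                SimilarityRL.Q0_ACCEPT,
                data.share, data.action, data.teacher, data.weight,
            )
        )
    else:  # pragma: no cover
        raise KeyError(f"no fast evaluator for model id {mid}")
    # stateless vectorized branch (models 1 and 2)
    p = np.clip(p, PROB_FLOOR, 1.0 - PROB_FLOOR)
    p_choice = np.where(data.action == 1, p, 1.0 - p)
    return float(-(data.weight * np.log(np.maximum(p_choice, PROB_FLOOR))).sum())


def aic(nll: float, k: int) -> float:
    """Akaike information criterion: 2k + 2*NLL (lower is better)."""
    if k < 0:
        raise ValueError(f"parameter count must be nonnegative, got {k}")
    return 2.0 * k + 2.0 * nll


def random_starts(model: ChoiceModel, n_starts: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random starts in each parameter's box (log-uniform where flagged)."""
    b = model.bounds
    u = rng.uniform(size=(n_starts, model.k))
    starts = b[:, 0] + u * (b[:, 1] - b[:, 0])
    ls = model.log_scale
    if ls.any():
        lo, hi = np.log(b[ls, 0]), np.log(b[ls, 1])
        starts[:, ls] = np.exp(lo + u[:, ls] * (hi - lo))
    return starts


@dataclass
class ChoiceModelResults:
    """Best-fit result for one subject under one model."""

    model: ChoiceModel
    params: pd.Series
    nll: float
    n_trials: int
    n_starts: int
    n_converged: int
    seed: int | None = None
    subject: str | None = None
    message: str = ""

    @property
    def k(self) -> int:
        return self.model.k

    @property
    def aic(self) -> float:
        return aic(self.nll, self.k)

    def summary(self) -> str:
        lines = [
            f"{self.model.name} (model {self.model.model_id})  "
            f"subject={self.subject or '-'}",
            f"  n_trials={self.n_trials}  NLL={self.nll:.4f} nats  "
            f"k={self.k}  AIC={self.aic:.4f}",
            f"  starts converged: {self.n_converged}/{self.n_starts}",
            "  parameters:",
        ]
        for name, value in self.params.items():
            lo, hi = self.model.bounds[self.model.param_names.index(name)]
            lines.append(f"    {name:>12s} = {value:10.4f}   (bounds [{lo:g}, {hi:g}])")
        return "\n".join(lines)

    def to_row(self) -> dict:
        row = {
            "subject": self.subject,
            "model_id": self.model.model_id,
            "model": self.model.name,
            "k": self.k,
            "nll": self.nll,
            "aic": self.aic,
            "n_trials": self.n_trials,
            "n_converged": self.n_converged,
        }
        row.update({name: float(v) for name, v in self.params.items()})
        return row


class ChoiceModelMLE:
    """Maximum-likelihood estimator binding one model to one trial sequence."""

    def __init__(self, model: ChoiceModel | int | str, data: TrialData):
        self.model = get_model(model)
        self.data = data

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        model: ChoiceModel | int | str,
        phase: str | None = "learning",
        include_no_feedback: bool = True,
    ) -> "ChoiceModelMLE":
        return cls(model, TrialData.from_frame(df, phase, include_no_feedback))

    def nll(self, theta, method: str = "fast") -> float:
        return negative_log_likelihood(self.model, theta, self.data, method=method)

    def fit(
        self,
        n_starts: int = 100,
        seed: int | None = None,
        subject: str | None = None,
    ) -> ChoiceModelResults:
        """Multi-start bounded optimization; returns the best converged start."""
        if n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        rng = np.random.default_rng(seed)
        starts = random_starts(self.model, n_starts, rng)
        bounds = [tuple(b) for b in self.model.bounds]
        objective = lambda th: negative_log_likelihood(self.model, th, self.data)

        best = None
        n_converged = 0
        failures = []
        for x0 in starts:
            res = minimize(
                objective,
                x0,
                method="L-BFGS-B",
                bounds=bounds,
                options={"ftol": 1e-9, "maxiter": 500},
            )
            if not res.success:
                failures.append(res.message)
                continue
            n_converged += 1
            if best is None or res.fun < best.fun:  # ties: first-found wins
                best = res
        if best is None:
            raise FittingError(
                f"no optimization start converged for {self.model.name}",
                diagnostics=failures,
            )
        params = pd.Series(best.x, index=self.model.param_names)
        return ChoiceModelResults(
            model=self.model,
            params=params,
            nll=float(best.fun),
            n_trials=self.data.n_trials,
            n_starts=n_starts,
            n_converged=n_converged,
            seed=seed,
            subject=subject,
            message=str(best.message),
        )


def fit_subject(
    model: ChoiceModel | int | str,
    data: TrialData | pd.DataFrame,
    n_starts: int = 100,
    seed: int | None = None,
    subject: str | None = None,
    include_no_feedback: bool = True,
) -> ChoiceModelResults:
    """Convenience wrapper around :class:`ChoiceModelMLE`."""
    if isinstance(data, pd.DataFrame):
        data = TrialData.from_frame(data, include_no_feedback=include_no_feedback)
    return ChoiceModelMLE(model, data).fit(n_starts=n_starts, seed=seed, subject=subject)


def fit_cohort(
    records: pd.DataFrame,
    models: Iterable | str = "all",
    n_starts: int = 100,
    seed: int | None = None,
    include_no_feedback: bool = True,
) -> pd.DataFrame:
    """Fit every subject in a trial-record frame with every candidate model.

    Returns a tidy frame: one row per subject x model with NLL, AIC and the
    named parameters as columns. Each (subject, model) pair gets its own
    deterministic seed stream derived from ``seed``.
    """
    from .models import EXP2_MODEL_IDS

    if isinstance(models, str):
        if models == "all":
            model_list = [MODELS[i] for i in sorted(MODELS)]
        elif models == "exp2":
            model_list = [MODELS[i] for i in EXP2_MODEL_IDS]
        else:
            model_list = [get_model(models)]
    else:
        model_list = [get_model(m) for m in models]

    rows = []
    subjects = sorted(records["subject"].unique())
    for si, subj in enumerate(subjects):
        sub_df = records[records["subject"] == subj]
        data = TrialData.from_frame(sub_df, include_no_feedback=include_no_feedback)
        for m in model_list:
            child_seed = (
                None
                if seed is None
                else int(np.random.SeedSequence([seed, si, m.model_id]).generate_state(1)[0] % (2**31))
            )
            res = ChoiceModelMLE(m, data).fit(n_starts=n_starts, seed=child_seed, subject=str(subj))
            rows.append(res.to_row())
    return pd.DataFrame(rows)


@dataclass
class ComparisonTable:
    """AIC model comparison across a cohort."""

    table: pd.DataFrame  # per model: k, sum_aic, mean_aic, n_best
    winner_id: int

    def summary(self) -> str:
        out = ["AIC model comparison (lower is better):", self.table.to_string()]
        out.append(f"winning model: {self.winner_id}")
        return "\n".join(out)


def compare_models(fits: pd.DataFrame) -> ComparisonTable:
    """Summed/mean AIC and per-subject best-fit counts from a cohort fit frame."""
    grid = fits.pivot_table(index="subject", columns="model_id", values="aic")
    if grid.isna().any().any():
        missing = grid.isna().sum().to_dict()
        raise ValueError(f"ragged subject x model grid; missing fits per model: {missing}")
    # per-subject winner, ties to the lowest model id
    best_counts = grid.idxmin(axis=1).value_counts()
    table = pd.DataFrame(
        {
            "model": [MODELS[i].name for i in grid.columns],
            "k": [MODELS[i].k for i in grid.columns],
            "sum_aic": grid.sum(axis=0),
            "mean_aic": grid.mean(axis=0),
            "n_best": [int(best_counts.get(i, 0)) for i in grid.columns],
        },
        index=grid.columns,
    )
    winner = int(table["sum_aic"].idxmin())
    return ComparisonTable(table=table, winner_id=winner)
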