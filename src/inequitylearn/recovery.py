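"""Validation by simulation: posterior-predictive learning curves,
parameter recovery, and model recovery (confusion matrices).

Parameter recovery follows the standard protocol: draw ground-truth
parameters uniformly from the fitting boxes, simulate Learning-phase
choices on the task schedule, re-fit with the same multi-start MLE
pipeline, and summarize true-vs-recovered agreement per parameter. Rank
(Spearman) correlation is the headline statistic because box-uniform truths
pile up against parameter bounds after fitting. Note the inverse
temperature's known identifiability ceiling: once tau is large enough that
every choice is effectively deterministic, all larger values produce the
same likelihood, so recovery of tau's magnitude is only possible below that
saturation point (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .fit import FittingError, TrialData, ChoiceModelMLE, fit_cohort, compare_models
from .models import ChoiceModel, get_model
from .simulate import draw_agent, default_priors, play_learning_phase
from .task import (
    CONDITIONS,
    OFFER_LABELS,
    TeacherProfile,
    default_teacher_profile,
    make_schedule,
    teacher_preferred_action,
)


@dataclass
class LearningCurves:
    """Mean simulated rejection-rate curves, by condition and offer type."""

    curves: pd.DataFrame  # condition, offer_type, type_trial, mean_reject, se, n
    param_trajectories: pd.DataFrame  # condition, trial, alpha_mean, beta_mean (model 6)


def _within_type_index(labels: list[str]) -> list[int]:
    seen: dict[str, int] = {}
    out = []
    for lab in labels:
        seen[lab] = seen.get(lab, 0) + 1
        out.append(seen[lab])
    return out


def _simulate_traces(
    model: ChoiceModel,
    theta: np.ndarray,
    teacher: TeacherProfile,
    schedule,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """One simulated Learning phase, with per-trial state traces for model 6."""
    state = model.init_state(theta)
    type_to_idx = {lab: i for i, lab in enumerate(OFFER_LABELS)}
    rows = []
    for spec in schedule:
        lab = spec.offer.offer_type.label
        s = float(spec.offer.receiver_share)
        k = type_to_idx[lab]
        p = model.predict_reject(theta, state, k, s)
        action = 1 if rng.random() < p else 0
        if spec.feedback_available:
            t_act = 1 if teacher_preferred_action(teacher, lab, rng) == "reject" else 0
            model.update(theta, state, k, s, action, t_act)
        row = {
            "trial": spec.trial_index,
            "offer_type": lab,
            "reject": action,
            "feedback_available": spec.feedback_available,
        }
        if model.model_id == 6:
            row["alpha_t"] = state["alpha"]
            row["beta_t"] = state["beta"]
        rows.append(row)
    df = pd.DataFrame(rows)
    df["type_trial"] = _within_type_index(df["offer_type"].tolist())
    return df


def posterior_predictive(
    fits: pd.DataFrame,
    n_sims: int = 100,
    experiment: int = 1,
    seed: int | None = None,
    teacher_profiles: dict[str, TeacherProfile] | None = None,
) -> LearningCurves:
    """Simulate Learning-phase behaviour under each subject's fitted model.

    ``fits`` must carry one row per subject with columns ``subject``,
    ``condition``, ``model_id`` and that model's named parameters (the
    frame produced by :func:`inequitylearn.fit.fit_cohort`, joined with
    condition assignments). Each subject is replayed ``n_sims`` times
    against their condition's Teacher on a fresh randomized schedule, and
    the curves are averaged.
    """
    required = {"subject", "condition", "model_id"}
    if not required.issubset(fits.columns):
        raise ValueError(f"fits frame must have columns {sorted(required)}")
    if fits.empty:
        raise ValueError("no fits supplied")
    rng = np.random.default_rng(seed)
    sims, trajs = [], []
    for _, row in fits.iterrows():
        model = get_model(int(row["model_id"]))
        theta = np.array([row[name] for name in model.param_names], dtype=float)
        condition = row["condition"]
        teacher = (teacher_profiles or {}).get(condition) or default_teacher_profile(condition)
        for _ in range(n_sims):
            schedule = make_schedule(experiment, "learning", rng=rng)
            df = _simulate_traces(model, theta, teacher, schedule, rng)
            df["condition"] = condition
            df["subject"] = row["subject"]
            sims.append(df[["subject", "condition", "offer_type", "type_trial", "reject", "feedback_available"]])
            if model.model_id == 6:
                trajs.append(df[["condition", "trial", "alpha_t", "beta_t"]])

    pooled = pd.concat(sims, ignore_index=True)
    # average within subject first, then across subjects (between-subject SE)
    per_subject = (
        pooled.groupby(["condition", "offer_type", "type_trial", "subject"])["reject"]
        .mean()
        .reset_index()
    )
    curves = (
        per_subject.groupby(["condition", "offer_type", "type_trial"])["reject"]
        .agg(mean_reject="mean", se="sem", n="count")
        .reset_index()
    )
    if trajs:
        traj = (
            pd.concat(trajs, ignore_index=True)
            .groupby(["condition", "trial"])[["alpha_t", "beta_t"]]
            .mean()
            .rename(columns={"alpha_t": "alpha_mean", "beta_t": "beta_mean"})
            .reset_index()
        )
    else:
        traj = pd.DataFrame(columns=["condition", "trial", "alpha_mean", "beta_mean"])
    return LearningCurves(curves=curves, param_trajectories=traj)


# ---------------------------------------------------------------------------
# parameter recovery


@dataclass
class RecoveryReport:
    """True-vs-recovered pairs and per-parameter agreement statistics."""

    model_id: int
    pairs: pd.DataFrame  # subject, condition, parameter, true, recovered
    summary: pd.DataFrame  # parameter, spearman, pearson, bias, rmse
    failures: list = field(default_factory=list)


def _recovery_summary(pairs: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for name, grp in pairs.groupby("parameter", sort=False):
        t, r = grp["true"].to_numpy(), grp["recovered"].to_numpy()
        ok = np.isfinite(t) & np.isfinite(r)
        t, r = t[ok], r[ok]
        if len(t) >= 3:
            rho = float(spearmanr(t, r).statistic)
            pear = float(pearsonr(t, r).statistic)
        else:
            rho = pear = np.nan
        rows.append(
            {
                "parameter": name,
                "n": int(len(t)),
                "spearman": rho,
                "pearson": pear,
                "bias": float(np.mean(r - t)) if len(t) else np.nan,
                "rmse": float(np.sqrt(np.mean((r - t) ** 2))) if len(t) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def simulate_learning_cohort(
    model: ChoiceModel | int | str,
    n_subjects: int,
    experiment: int = 1,
    seed: int | None = None,
    param_priors: dict[str, tuple[float, float]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Learning-phase-only cohort with box-uniform ground truth.

    Subjects are split evenly between the two Teacher conditions. Returns
    (records, truth) frames; records carry only the Learning phase.
    """
    model = get_model(model)
    priors = default_priors(model)
    if param_priors:
        priors.update(param_priors)
    rng = np.random.default_rng(seed)
    records, truth_rows = [], []
    for i in range(n_subjects):
        condition = CONDITIONS[i % 2]
        teacher = default_teacher_profile(condition)
        agent = draw_agent(model, priors, rng)
        schedule = make_schedule(experiment, "learning", rng=rng)
        rows, _ = play_learning_phase(model, agent.learning_params, teacher, schedule, rng)
        df = pd.DataFrame(rows)
        df.insert(0, "subject", f"s{i:04d}")
        df.insert(1, "condition", condition)
        df.insert(2, "experiment", experiment)
        records.append(df)
        truth = {"subject": f"s{i:04d}", "condition": condition}
        truth.update(dict(zip(model.param_names, agent.learning_params)))
        truth_rows.append(truth)
    if not records:
        empty = pd.DataFrame()
        return empty, pd.DataFrame(truth_rows)
    return pd.concat(records, ignore_index=True), pd.DataFrame(truth_rows)


def parameter_recovery(
    model: ChoiceModel | int | str,
    n_subjects: int = 200,
    experiment: int = 1,
    n_starts: int = 25,
    seed: int | None = None,
    param_priors: dict[str, tuple[float, float]] | None = None,
) -> RecoveryReport:
    """Simulate-and-refit recovery check for one model's parameters."""
    model = get_model(model)
    if n_subjects == 0:
        return RecoveryReport(
            model_id=model.model_id,
            pairs=pd.DataFrame(columns=["subject", "condition", "parameter", "true", "recovered"]),
            summary=pd.DataFrame(columns=["parameter", "n", "spearman", "pearson", "bias", "rmse"]),
        )
    records, truth = simulate_learning_cohort(
        model, n_subjects, experiment, seed=seed, param_priors=param_priors
    )
    pair_rows, failures = [], []
    ss = np.random.SeedSequence(0 if seed is None else seed)
    fit_seeds = ss.generate_state(n_subjects + 1)[1:] % (2**31)
    for i, (subj, grp) in enumerate(records.groupby("subject", sort=True)):
        data = TrialData.from_frame(grp, phase=None)
        true_row = truth[truth["subject"] == subj].iloc[0]
        try:
            res = ChoiceModelMLE(model, data).fit(
                n_starts=n_starts, seed=int(fit_seeds[i]), subject=subj
            )
        except FittingError as err:  # recorded, not fatal
            failures.append((subj, str(err)))
            continue
        for name in model.param_names:
            pair_rows.append(
                {
                    "subject": subj,
                    "condition": true_row["condition"],
                    "parameter": name,
                    "true": float(true_row[name]),
                    "recovered": float(res.params[name]),
                }
            )
    pairs = pd.DataFrame(pair_rows)
    return RecoveryReport(
        model_id=model.model_id,
        pairs=pairs,
        summary=_recovery_summary(pairs) if not pairs.empty else pd.DataFrame(),
        failures=failures,
    )


# ---------------------------------------------------------------------------
# model recovery


@dataclass
class ModelRecoveryResult:
    """Dataset-level AIC confusion between generating and fitted models."""

    confusion: pd.DataFrame  # rows: generating model id; cols: winning model id
    winners: pd.DataFrame  # generating_model, dataset, winner_id

    def diagonal_fraction(self) -> pd.Series:
        counts = self.confusion
        return pd.Series(
            {g: counts.loc[g, g] / counts.loc[g].sum() if counts.loc[g].sum() else np.nan
             for g in counts.index},
            name="diagonal_fraction",
        )


def model_recovery(
    generating_models,
    candidate_models=None,
    n_datasets: int = 20,
    n_subjects: int = 20,
    experiment: int = 1,
    n_starts: int = 25,
    seed: int | None = None,
    param_priors: dict[str, tuple[float, float]] | None = None,
) -> ModelRecoveryResult:
    """Generate cohorts from each model and score which model wins the AIC.

    Each of ``n_datasets`` replicate cohorts per generating model is fit by
    every candidate; the dataset-level winner is the candidate with minimal
    summed AIC.
    """
    gen = [get_model(m) for m in generating_models]
    if len(gen) < 1:
        raise ValueError("need at least one generating model")
    cand = [get_model(m) for m in (candidate_models or generating_models)]
    if len(cand) < 2:
        raise ValueError("need at least two candidate models")
    base = 0 if seed is None else seed
    winner_rows = []
    for g in gen:
        for d in range(n_datasets):
            ds_seed = int(np.random.SeedSequence([base, g.model_id, d]).generate_state(1)[0] % (2**31))
            records, _ = simulate_learning_cohort(
                g, n_subjects, experiment, seed=ds_seed, param_priors=param_priors
            )
            fits = fit_cohort(
                records, models=[c.model_id for c in cand], n_starts=n_starts, seed=ds_seed
            )
            table = compare_models(fits)
            winner_rows.append(
                {"generating_model": g.model_id, "dataset": d, "winner_id": table.winner_id}
            )
    winners = pd.DataFrame(winner_rows)
    confusion = pd.crosstab(winners["generating_model"], winners["winner_id"])
    confusion = confusion.reindex(
        index=[g.model_id for g in gen], columns=[c.model_id for c in cand], fill_value=0
    )
    return ModelRecoveryResult(confusion=confusion, winners=winners)
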