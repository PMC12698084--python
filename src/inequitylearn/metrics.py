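"""Descriptive behavioural statistics and the end-to-end pipeline runner.

Rejection rates per subject and offer type, Baseline-to-Transfer contagion
deltas, and within-type Learning-phase trends. These are deliberately
descriptive (between-subject standard errors of per-subject statistics);
the record schema stays tidy so inferential mixed-effects models can be
run externally on the same CSVs.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fit import compare_models, fit_cohort
from .models import EXP2_MODEL_IDS, MODELS, get_model
from .recovery import posterior_predictive
from .simulate import REALISTIC_PRIORS, generate_cohort, write_dataset
from .task import OFFER_LABELS, PHASES

logger = logging.getLogger("inequitylearn")

_REJECT = {"reject": 1, "accept": 0, 1: 1, 0: 0, True: 1, False: 0}


def _reject_indicator(records: pd.DataFrame) -> pd.Series:
    return records["action"].map(_REJECT).astype(float)


def rejection_rates(records: pd.DataFrame, phase: str) -> pd.DataFrame:
    """Per subject x offer type rejection rate in one phase.

    Cells a subject never saw are flagged missing (NaN rate, n_trials = 0)
    rather than zero, and are excluded from any condition-level mean.
    """
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}; expected one of {PHASES}")
    sub = records[records["phase"] == phase].copy()
    sub["reject"] = _reject_indicator(sub)
    cells = (
        sub.groupby(["subject", "offer_type"])["reject"]
        .agg(n_trials="count", n_rejected="sum")
        .reset_index()
    )
    # complete the subject x offer-type grid so absent cells surface as NaN
    subjects = sorted(sub["subject"].unique())
    grid = pd.MultiIndex.from_product(
        [subjects, OFFER_LABELS], names=["subject", "offer_type"]
    )
    full = cells.set_index(["subject", "offer_type"]).reindex(grid).reset_index()
    cond_map = sub.drop_duplicates("subject").set_index("subject")["condition"]
    full["condition"] = full["subject"].map(cond_map)
    full["n_trials"] = full["n_trials"].fillna(0).astype(int)
    full["n_rejected"] = full["n_rejected"].fillna(0).astype(int)
    full["rate"] = np.where(
        full["n_trials"] > 0, full["n_rejected"] / full["n_trials"].clip(lower=1), np.nan
    )
    full["phase"] = phase
    return full[["subject", "condition", "phase", "offer_type", "n_trials", "n_rejected", "rate"]]


@dataclass
class ContagionSummary:
    """Baseline-to-Transfer rejection-rate change (the contagion measure)."""

    per_subject: pd.DataFrame  # subject, condition, offer_type, baseline, transfer, delta
    by_condition: pd.DataFrame  # condition, offer_type, mean_delta, se_delta, n


def contagion_delta(records: pd.DataFrame) -> ContagionSummary:
    """Per-cell Transfer minus Baseline rejection rate, with condition means.

    Subjects missing either phase are excluded with a warning.
    """
    base = rejection_rates(records, "baseline").rename(columns={"rate": "baseline"})
    trans = rejection_rates(records, "transfer").rename(columns={"rate": "transfer"})
    have_base = set(base.loc[base["n_trials"] > 0, "subject"])
    have_trans = set(trans.loc[trans["n_trials"] > 0, "subject"])
    dropped = sorted((have_base ^ have_trans) | (set(records["subject"]) - (have_base & have_trans)))
    if dropped:
        warnings.warn(f"excluding {len(dropped)} subject(s) missing a phase: {dropped[:5]}...")
    merged = base.merge(
        trans[["subject", "offer_type", "transfer"]], on=["subject", "offer_type"], how="inner"
    )
    merged = merged[merged["subject"].isin(have_base & have_trans)]
    merged["delta"] = merged["transfer"] - merged["baseline"]
    per_subject = merged[["subject", "condition", "offer_type", "baseline", "transfer", "delta"]]
    by_condition = (
        per_subject.dropna(subset=["delta"])
        .groupby(["condition", "offer_type"])["delta"]
        .agg(mean_delta="mean", se_delta="sem", n="count")
        .reset_index()
    )
    return ContagionSummary(per_subject=per_subject, by_condition=by_condition)


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    xm, ym = x.mean(), y.mean()
    denom = ((x - xm) ** 2).sum()
    if denom == 0:
        return np.nan
    return float(((x - xm) * (y - ym)).sum() / denom)


def learning_trend(records: pd.DataFrame) -> pd.DataFrame:
    """Per subject x offer type least-squares slope of rejection over the
    within-type trial index during the Learning phase, with condition means.

    A simple descriptive trend (not the mixed-effects logistic model that a
    full inferential analysis would use). Cells with fewer than 2 trials
    are missing.
    """
    sub = records[records["phase"] == "learning"].copy()
    if sub.empty:
        raise ValueError("no learning-phase records")
    sub["reject"] = _reject_indicator(sub)
    sub = sub.sort_values(["subject", "trial"], kind="stable")
    sub["type_trial"] = sub.groupby(["subject", "offer_type"]).cumcount() + 1
    rows = []
    for (subj, cond, lab), grp in sub.groupby(["subject", "condition", "offer_type"]):
        slope = (
            _ols_slope(grp["type_trial"].to_numpy(float), grp["reject"].to_numpy(float))
            if len(grp) >= 2
            else np.nan
        )
        rows.append({"subject": subj, "condition": cond, "offer_type": lab, "slope": slope})
    per_subject = pd.DataFrame(rows)
    summary = (
        per_subject.dropna(subset=["slope"])
        .groupby(["condition", "offer_type"])["slope"]
        .agg(mean_slope="mean", se_slope="sem", n="count")
        .reset_index()
    )
    per_subject = per_subject.merge(summary, on=["condition", "offer_type"], how="left")
    return per_subject


def learning_trend_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Condition x offer type mean learning-phase slope with SE."""
    per = learning_trend(records)
    return per.drop_duplicates(["condition", "offer_type"])[
        ["condition", "offer_type", "mean_slope", "se_slope", "n"]
    ].reset_index(drop=True)


# ---------------------------------------------------------------------------
# pipeline runner

DEFAULT_CONFIG: dict = {
    "experiment": 1,
    "n_per_condition": 20,
    "generator_model": 6,
    "priors": "realistic",
    "candidate_models": None,  # None -> all (exp 1) or the exp-2 subset
    "n_starts": 25,
    "n_sims": 20,
    "seed": 0,
}


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """simulate -> fit -> compare -> posterior-predict -> report, to one directory.

    ``config`` may be a dict or a path to a YAML file with the keys of
    ``DEFAULT_CONFIG``. Returns the in-memory artifacts; all stage outputs
    are also written as CSV under ``out_dir`` together with the echoed
    config.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    cfg = {**DEFAULT_CONFIG, **config}
    if out_dir is None:
        out_dir = cfg.get("out", "pipeline_run")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    experiment = int(cfg["experiment"])
    seed = cfg["seed"]
    priors = cfg["priors"]
    if priors == "realistic":
        priors = REALISTIC_PRIORS
    elif priors == "default" or priors is None:
        priors = None
    candidates = cfg["candidate_models"]
    if candidates is None:
        candidates = sorted(MODELS) if experiment == 1 else list(EXP2_MODEL_IDS)

    def stage(name):
        logger.info("stage %s (t=%.1fs)", name, time.perf_counter() - t0)

    t0 = time.perf_counter()
    try:
        stage("simulate")
        dataset = generate_cohort(
            int(cfg["n_per_condition"]),
            experiment=experiment,
            model=get_model(cfg["generator_model"]),
            param_priors=priors,
            master_seed=seed,
        )
        write_dataset(dataset, out / "dataset")

        stage("fit")
        fits = fit_cohort(
            dataset.records, models=candidates, n_starts=int(cfg["n_starts"]), seed=seed
        )
        cond_map = dataset.records.drop_duplicates("subject").set_index("subject")["condition"]
        fits["condition"] = fits["subject"].map(cond_map)
        fits.to_csv(out / "fits.csv", index=False)

        stage("compare")
        table = compare_models(fits)
        table.table.to_csv(out / "model_comparison.csv")

        stage("posterior_predictive")
        best_fits = fits[fits["model_id"] == table.winner_id]
        curves = posterior_predictive(
            best_fits, n_sims=int(cfg["n_sims"]), experiment=experiment, seed=seed
        )
        curves.curves.to_csv(out / "predicted_curves.csv", index=False)
        curves.param_trajectories.to_csv(out / "param_trajectories.csv", index=False)

        stage("report")
        contagion = contagion_delta(dataset.records)
        contagion.by_condition.to_csv(out / "contagion_by_condition.csv", index=False)
        contagion.per_subject.to_csv(out / "contagion_per_subject.csv", index=False)
        trends = learning_trend_summary(dataset.records)
        trends.to_csv(out / "learning_trends.csv", index=False)
    except Exception as err:
        raise RuntimeError(f"pipeline failed: {err}") from err

    with open(out / "run_config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    logger.info("pipeline finished in %.1fs", time.perf_counter() - t0)
    return {
        "dataset": dataset,
        "fits": fits,
        "comparison": table,
        "curves": curves,
        "contagion": contagion,
        "trends": trends,
        "out_dir": out,
    }
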