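"""Synthetic cohorts: generative agents playing the full three-phase task.

An agent owns Fehr-Schmidt preferences (alpha_own, beta_own, tau_own) that
drive its Baseline choices, a learning model (one of the seven) that drives
its Learning-phase choices and updates from Teacher feedback, and a
contagion weight ``omega`` in [0, 1] that blends the learned Teacher
preferences into its Transfer-phase preferences:

    alpha_eff = (1 - omega) * alpha_own + omega * alpha_learned

(and likewise for beta). ``omega = 0`` is the no-contagion null: Transfer
behaviour is then distributionally identical to Baseline. The blend is a
generator-side construct that operationalizes preference contagion; for
learning models that do not carry explicit envy/guilt parameters, the
learned (alpha, beta) are obtained by least-squares inversion of the
model's final rejection-probability profile through the Fehr-Schmidt +
softmax map at the five nominal offers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit

from .models import ChoiceModel, get_model
from .models.primitives import fs_utility, softmax_reject_prob
from .task import (
    CONDITIONS,
    NOMINAL_RECEIVER_SHARE,
    OFFER_LABELS,
    TeacherProfile,
    TrialSpec,
    default_teacher_profile,
    make_schedule,
    teacher_preferred_action,
)

RECORD_COLUMNS = [
    "subject",
    "condition",
    "experiment",
    "phase",
    "trial",
    "offer_type",
    "receiver_share",
    "action",
    "teacher_action",
    "reward",
    "rating",
    "feedback_available",
    "rating_elicited",
]

SCHEMA_HEADER = "# inequitylearn cohort schema v1"


class SchemaError(ValueError):
    """A dataset file does not match the expected column schema."""


@dataclass
class GenerativeAgent:
    """Ground-truth description of one simulated participant."""

    alpha_own: float
    beta_own: float
    tau_own: float
    model: ChoiceModel
    learning_params: np.ndarray
    omega: float = 0.0

    def __post_init__(self):
        self.model = get_model(self.model)
        self.learning_params = self.model.check_params(np.asarray(self.learning_params, float))
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError(f"omega must lie in [0, 1], got {self.omega}")


def _fs_reject_prob(share: float, alpha: float, beta: float, tau: float) -> float:
    u_acc, u_rej = fs_utility(share, alpha, beta)
    return softmax_reject_prob(u_rej, u_acc, tau)


def _synthetic_rating(share: float, rng: np.random.Generator) -> int:
    """Decorative 1-7 fairness rating: affine in inequity, with noise."""
    raw = 7.0 - 6.0 / 50.0 * abs(share - 50.0) + rng.normal(0.0, 0.5)
    return int(min(max(round(raw), 1), 7))


def invert_fs_profile(
    p_reject: np.ndarray, tau: float, shares: np.ndarray | None = None
) -> tuple[float, float]:
    """Least-squares (alpha, beta) whose FS+softmax profile matches ``p_reject``.

    ``p_reject`` holds rejection probabilities at the five nominal offers
    (ordered 90:10 .. 10:90) unless ``shares`` overrides the grid.
    """
    if shares is None:
        shares = np.array([NOMINAL_RECEIVER_SHARE[lab] for lab in OFFER_LABELS], float)

    def resid(ab):
        a, b = ab
        u = shares - a * np.maximum(50.0 - shares, 0.0) - b * np.maximum(shares - 50.0, 0.0)
        return expit(-tau * u) - p_reject

    sol = least_squares(resid, x0=[1.0, 1.0], bounds=([0.0, 0.0], [10.0, 10.0]))
    return float(sol.x[0]), float(sol.x[1])


def learned_preferences(agent: GenerativeAgent, state) -> tuple[float, float]:
    """Read the (alpha, beta) the agent has attributed to the Teacher."""
    model, theta = agent.model, agent.learning_params
    if model.model_id == 6:
        return float(state["alpha"]), float(state["beta"])
    if model.model_id == 2:
        return float(theta[0]), float(theta[1])
    # generic route: invert the model's final rejection profile
    names = model.param_names
    tau = float(theta[names.index("tau")]) if "tau" in names else agent.tau_own
    probs = np.array(
        [
            model.predict_reject(theta, state, i, float(NOMINAL_RECEIVER_SHARE[lab]))
            for i, lab in enumerate(OFFER_LABELS)
        ]
    )
    return invert_fs_profile(probs, tau)


def _play_static_phase(
    schedule: list[TrialSpec],
    alpha: float,
    beta: float,
    tau: float,
    rng: np.random.Generator,
) -> list[dict]:
    rows = []
    for spec in schedule:
        s = spec.offer.receiver_share
        p = _fs_reject_prob(s, alpha, beta, tau)
        action = "reject" if rng.random() < p else "accept"
        rows.append(
            {
                "phase": spec.phase,
                "trial": spec.trial_index,
                "offer_type": spec.offer.offer_type.label,
                "receiver_share": s,
                "action": action,
                "teacher_action": np.nan,
                "reward": np.nan,
                "rating": float(_synthetic_rating(s, rng)) if spec.rating_elicited else np.nan,
                "feedback_available": spec.feedback_available,
                "rating_elicited": spec.rating_elicited,
            }
        )
    return rows


def play_learning_phase(
    model: ChoiceModel,
    theta: np.ndarray,
    teacher: TeacherProfile,
    schedule: list[TrialSpec],
    rng: np.random.Generator,
):
    """Simulate Learning-phase choices and feedback; returns (rows, final state)."""
    state = model.init_state(theta)
    type_to_idx = {lab: i for i, lab in enumerate(OFFER_LABELS)}
    rows = []
    for spec in schedule:
        lab = spec.offer.offer_type.label
        s = spec.offer.receiver_share
        k = type_to_idx[lab]
        p = model.predict_reject(theta, state, k, float(s))
        action = 1 if rng.random() < p else 0
        if spec.feedback_available:
            t_act = 1 if teacher_preferred_action(teacher, lab, rng) == "reject" else 0
            reward = float(action == t_act)
            model.update(theta, state, k, float(s), action, t_act)
        else:
            t_act, reward = None, np.nan
        rows.append(
            {
                "phase": "learning",
                "trial": spec.trial_index,
                "offer_type": lab,
                "receiver_share": s,
                "action": "reject" if action else "accept",
                "teacher_action": (
                    np.nan if t_act is None else ("reject" if t_act else "accept")
                ),
                "reward": reward,
                "rating": float(_synthetic_rating(s, rng)) if spec.rating_elicited else np.nan,
                "feedback_available": spec.feedback_available,
                "rating_elicited": spec.rating_elicited,
            }
        )
    return rows, state


def simulate_subject(
    agent: GenerativeAgent,
    condition: str,
    experiment: int = 1,
    seed: int | None = None,
    teacher: TeacherProfile | None = None,
    subject: str = "s0",
    phases: tuple[str, ...] = ("baseline", "learning", "transfer"),
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Play one subject through the task; returns (records, learned (alpha, beta))."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if experiment not in (1, 2):
        raise ValueError(f"unknown experiment {experiment!r}")
    if teacher is None:
        teacher = default_teacher_profile(condition)
    rng = np.random.default_rng(seed)
    all_rows: list[dict] = []
    learned = (agent.alpha_own, agent.beta_own)

    for phase in phases:
        schedule = make_schedule(experiment, phase, rng=rng)
        if phase == "learning":
            rows, state = play_learning_phase(
                agent.model, agent.learning_params, teacher, schedule, rng
            )
            learned = learned_preferences(agent, state)
        else:
            if phase == "baseline":
                a_eff, b_eff = agent.alpha_own, agent.beta_own
            else:  # transfer: blend own and learned preferences
                w = agent.omega
                a_eff = (1.0 - w) * agent.alpha_own + w * learned[0]
                b_eff = (1.0 - w) * agent.beta_own + w * learned[1]
            rows = _play_static_phase(schedule, a_eff, b_eff, agent.tau_own, rng)
        all_rows.extend(rows)

    df = pd.DataFrame(all_rows)
    df.insert(0, "subject", subject)
    df.insert(1, "condition", condition)
    df.insert(2, "experiment", experiment)
    return df[RECORD_COLUMNS], learned


# ---------------------------------------------------------------------------
# cohort generation

#: Default priors: each learning parameter's fitting box; own preferences
#: over the full envy/guilt boxes and the tau box; omega uniform.
def default_priors(model: ChoiceModel) -> dict[str, tuple[float, float]]:
    priors = {
        "alpha_own": (0.0, 10.0),
        "beta_own": (0.0, 10.0),
        "tau_own": (1e-4, 20.0),
        "omega": (0.0, 1.0),
    }
    for p in model.params:
        priors[p.name] = (p.lower, p.upper)
    return priors


#: Narrow preset reproducing the typical Western-sample baseline pattern
#: (envious but hardly guilty) with decisive choices and effective learning.
REALISTIC_PRIORS: dict[str, tuple[float, float]] = {
    "alpha_own": (1.0, 5.0),
    "beta_own": (0.0, 1.0),
    "tau_own": (0.05, 0.5),
    "omega": (0.5, 1.0),
    # preference-inference learning parameters
    "eta": (0.5, 2.0),
    "tau": (0.05, 0.3),
    "alpha0": (0.0, 2.0),
    "beta0": (0.0, 2.0),
}


def draw_agent(
    model: ChoiceModel,
    priors: dict[str, tuple[float, float]],
    rng: np.random.Generator,
) -> GenerativeAgent:
    """Draw one agent uniformly from per-parameter box priors."""

    def draw(name):
        lo, hi = priors[name]
        if lo > hi:
            raise ValueError(f"empty prior box for {name!r}: ({lo}, {hi})")
        return float(rng.uniform(lo, hi))

    theta = np.array([draw(p.name) for p in model.params])
    return GenerativeAgent(
        alpha_own=draw("alpha_own"),
        beta_own=draw("beta_own"),
        tau_own=draw("tau_own"),
        model=model,
        learning_params=theta,
        omega=draw("omega"),
    )


@dataclass
class CohortDataset:
    """Trial records plus the ground-truth parameter table that produced them."""

    records: pd.DataFrame
    truth: pd.DataFrame
    master_seed: int | None = None


def generate_cohort(
    n_per_condition: int,
    experiment: int = 1,
    model: ChoiceModel | int | str = 6,
    param_priors: dict[str, tuple[float, float]] | None = None,
    master_seed: int | None = None,
    teacher_profiles: dict[str, TeacherProfile] | None = None,
) -> CohortDataset:
    """Simulate a balanced two-condition cohort with known ground truth."""
    if n_per_condition < 0:
        raise ValueError("n_per_condition must be >= 0")
    model = get_model(model)
    priors = dict(default_priors(model))
    if param_priors:
        priors.update(param_priors)
    rng = np.random.default_rng(master_seed)

    records, truth_rows = [], []
    idx = 0
    for condition in CONDITIONS:
        teacher = (teacher_profiles or {}).get(condition) or default_teacher_profile(condition)
        for _ in range(n_per_condition):
            subj = f"s{idx:04d}"
            agent = draw_agent(model, priors, rng)
            subj_seed = int(np.random.SeedSequence([0 if master_seed is None else master_seed, idx]).generate_state(1)[0] % (2**31))
            df, learned = simulate_subject(
                agent, condition, experiment, seed=subj_seed, teacher=teacher, subject=subj
            )
            records.append(df)
            row = {
                "subject": subj,
                "condition": condition,
                "experiment": experiment,
                "model_id": model.model_id,
                "alpha_own": agent.alpha_own,
                "beta_own": agent.beta_own,
                "tau_own": agent.tau_own,
                "omega": agent.omega,
                "alpha_learned": learned[0],
                "beta_learned": learned[1],
            }
            row.update(dict(zip(model.param_names, agent.learning_params)))
            truth_rows.append(row)
            idx += 1

    if records:
        all_records = pd.concat(records, ignore_index=True)
    else:
        all_records = pd.DataFrame(columns=RECORD_COLUMNS)
    return CohortDataset(
        records=all_records, truth=pd.DataFrame(truth_rows), master_seed=master_seed
    )


# ---------------------------------------------------------------------------
# round-trip I/O


def write_dataset(dataset: CohortDataset, path: str | Path) -> Path:
    """Write trials.csv and ground_truth.csv under ``path`` (a directory)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    trials_file = path / "trials.csv"
    with open(trials_file, "w") as fh:
        fh.write(SCHEMA_HEADER + "\n")
        dataset.records.to_csv(fh, index=False)
    dataset.truth.to_csv(path / "ground_truth.csv", index=False)
    return path


def read_dataset(path: str | Path) -> CohortDataset:
    """Read a dataset written by :func:`write_dataset`; validates the schema."""
    path = Path(path)
    trials_file = path / "trials.csv"
    if not trials_file.exists():
        raise FileNotFoundError(trials_file)
    records = pd.read_csv(trials_file, comment="#")
    for col in RECORD_COLUMNS:
        if col not in records.columns:
            raise SchemaError(f"trials file missing required column {col!r}")
    records = records[RECORD_COLUMNS]
    truth_file = path / "ground_truth.csv"
    truth = pd.read_csv(truth_file) if truth_file.exists() else pd.DataFrame()
    return CohortDataset(records=records, truth=truth)
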