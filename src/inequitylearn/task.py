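"""Ultimatum-Game task protocol: offers, conditions, Teacher behaviour, schedules.

The task is a three-phase modified Ultimatum Game. In the Baseline and
Transfer phases the participant responds to offers as the Receiver; in the
Learning phase they choose on behalf of another Receiver (the "Teacher"),
whose preferred accept/reject response is revealed as feedback after each
choice. Offers are splits of 100 cents between a Proposer and the Receiver;
five nominal offer types span extreme disadvantageous inequity (90:10, the
Receiver gets 10) to extreme advantageous inequity (10:90). Every presented
offer is jittered by uniform integer noise on [-9, 9] so the nominal types
never overlap and the fair point stays inside the 50:50 band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Nominal offer types in Proposer:Receiver notation, ordered from extreme
#: disadvantageous to extreme advantageous inequity (for the Receiver).
OFFER_LABELS: tuple[str, ...] = ("90:10", "70:30", "50:50", "30:70", "10:90")

NOMINAL_RECEIVER_SHARE: dict[str, int] = {
    "90:10": 10,
    "70:30": 30,
    "50:50": 50,
    "30:70": 70,
    "10:90": 90,
}

PHASES: tuple[str, ...] = ("baseline", "learning", "transfer")

#: Half-width of the uniform integer jitter added to every presented offer.
OFFER_NOISE_HALF_WIDTH = 9

#: Fraction of trials on which a fairness rating is elicited (3 of every 5).
RATING_FRACTION = 0.6


def inequity_class(receiver_share_nominal: int) -> str:
    """Classify an offer by the Receiver's nominal share.

    ``Dis-I``: Receiver below the equal split; ``Adv-I``: above; ``Fair``: at it.
    """
    if receiver_share_nominal < 50:
        return "Dis-I"
    if receiver_share_nominal > 50:
        return "Adv-I"
    return "Fair"


@dataclass(frozen=True)
class OfferType:
    """One of the five nominal offer levels."""

    label: str

    def __post_init__(self) -> None:
        if self.label not in NOMINAL_RECEIVER_SHARE:
            raise ValueError(
                f"unknown offer type {self.label!r}; expected one of {OFFER_LABELS}"
            )

    @property
    def receiver_share_nominal(self) -> int:
        return NOMINAL_RECEIVER_SHARE[self.label]

    @property
    def proposer_share_nominal(self) -> int:
        return 100 - self.receiver_share_nominal

    @property
    def inequity_class(self) -> str:
        return inequity_class(self.receiver_share_nominal)


OFFER_TYPES: dict[str, OfferType] = {lab: OfferType(lab) for lab in OFFER_LABELS}


@dataclass(frozen=True)
class Offer:
    """A presented offer: nominal type plus the trial's integer jitter."""

    offer_type: OfferType
    noise: int

    def __post_init__(self) -> None:
        if not -OFFER_NOISE_HALF_WIDTH <= self.noise <= OFFER_NOISE_HALF_WIDTH:
            raise ValueError(f"offer noise {self.noise} outside ±{OFFER_NOISE_HALF_WIDTH}")

    @property
    def receiver_share(self) -> int:
        return self.offer_type.receiver_share_nominal + self.noise

    @property
    def proposer_share(self) -> int:
        # whatever is added to the Receiver is taken from the Proposer
        return 100 - self.receiver_share


CONDITIONS: tuple[str, ...] = ("Dis-I-Averse", "Adv-Dis-I-Averse")


def _check_condition(name: str) -> str:
    if name not in CONDITIONS:
        raise ValueError(f"unknown condition {name!r}; expected one of {CONDITIONS}")
    return name


@dataclass(frozen=True)
class TeacherProfile:
    """The Teacher's per-offer-type rejection preference and fairness ratings.

    The exact probabilities are configurable; the defaults encode strong but
    non-deterministic rejection (0.9) of the offer types the condition is
    averse to, and certain acceptance of fair offers and of every type the
    condition is not averse to.
    """

    condition: str
    reject_prob: Mapping[str, float]
    fairness_rating: Mapping[str, int]

    def __post_init__(self) -> None:
        _check_condition(self.condition)
        for lab, p in self.reject_prob.items():
            if lab not in NOMINAL_RECEIVER_SHARE:
                raise ValueError(f"unknown offer type {lab!r} in reject_prob")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"reject_prob[{lab!r}]={p} outside [0, 1]")
        for lab, r in self.fairness_rating.items():
            if not 1 <= int(r) <= 7:
                raise ValueError(f"fairness_rating[{lab!r}]={r} outside 1..7")


# Averse offer types are rejected with probability 0.9 (strong but not
# perfectly deterministic); fair offers and any type the condition is not
# averse to are always accepted.
_DEFAULT_REJECT_PROB = {
    "Dis-I-Averse": {"90:10": 0.9, "70:30": 0.9, "50:50": 0.0, "30:70": 0.0, "10:90": 0.0},
    "Adv-Dis-I-Averse": {"90:10": 0.9, "70:30": 0.9, "50:50": 0.0, "30:70": 0.9, "10:90": 0.9},
}
_DEFAULT_RATING = {
    "Dis-I-Averse": {"90:10": 2, "70:30": 2, "50:50": 6, "30:70": 6, "10:90": 6},
    "Adv-Dis-I-Averse": {"90:10": 2, "70:30": 2, "50:50": 6, "30:70": 2, "10:90": 2},
}


def default_teacher_profile(
    condition: str,
    reject_prob: Mapping[str, float] | None = None,
    fairness_rating: Mapping[str, int] | None = None,
) -> TeacherProfile:
    """Build the default Teacher for a condition, with optional overrides."""
    _check_condition(condition)
    rp = dict(_DEFAULT_REJECT_PROB[condition])
    fr = dict(_DEFAULT_RATING[condition])
    if reject_prob:
        rp.update(reject_prob)
    if fairness_rating:
        fr.update({k: int(v) for k, v in fairness_rating.items()})
    return TeacherProfile(condition=condition, reject_prob=rp, fairness_rating=fr)


def teacher_preferred_action(
    profile: TeacherProfile, offer_type: OfferType | str, rng: np.random.Generator
) -> str:
    """Sample the Teacher's preferred response for an offer type."""
    label = offer_type.label if isinstance(offer_type, OfferType) else offer_type
    if label not in profile.reject_prob:
        raise KeyError(f"offer type {label!r} missing from teacher profile")
    p = profile.reject_prob[label]
    return "reject" if rng.random() < p else "accept"


def teacher_rating(profile: TeacherProfile, offer_type: OfferType | str) -> int:
    """Look up the Teacher's (deterministic) 1-7 fairness rating."""
    label = offer_type.label if isinstance(offer_type, OfferType) else offer_type
    if label not in profile.fairness_rating:
        raise KeyError(f"offer type {label!r} missing from teacher profile")
    return int(profile.fairness_rating[label])


def apply_offer_noise(offer_type: OfferType | str, rng: np.random.Generator) -> Offer:
    """Jitter a nominal offer by an integer drawn uniformly from [-9, 9]."""
    ot = offer_type if isinstance(offer_type, OfferType) else OFFER_TYPES[offer_type]
    noise = int(rng.integers(-OFFER_NOISE_HALF_WIDTH, OFFER_NOISE_HALF_WIDTH + 1))
    return Offer(offer_type=ot, noise=noise)


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled trial."""

    experiment: int
    phase: str
    trial_index: int
    offer: Offer
    feedback_available: bool
    rating_elicited: bool


# Trials per offer type, per phase. Experiment 2 adds 25 moderate-offer
# learning trials and withholds feedback on the extreme offers.
_BASE_COUNTS = {lab: 5 for lab in OFFER_LABELS}
EXP1_LEARNING_COUNTS = {lab: 20 for lab in OFFER_LABELS}
EXP2_LEARNING_COUNTS = {"90:10": 20, "70:30": 45, "50:50": 20, "30:70": 45, "10:90": 20}
EXP2_NO_FEEDBACK_TYPES = frozenset({"90:10", "10:90"})


def make_schedule(
    experiment: int,
    phase: str,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    trial_counts: Mapping[str, int] | None = None,
    no_feedback_types: Iterable[str] | None = None,
    rating_fraction: float = RATING_FRACTION,
) -> list[TrialSpec]:
    """Build a fully randomized trial schedule for one phase.

    Baseline/Transfer: 5 trials of each offer type. Learning: 20 per type in
    Experiment 1; in Experiment 2, 45 of each moderate type (70:30, 30:70)
    and 20 of the rest, with no Teacher feedback on 90:10 and 10:90 trials.
    Ratings are elicited on a random 60% of trials within each offer type.
    The same seed reproduces the identical schedule.
    """
    if experiment not in (1, 2):
        raise ValueError(f"unknown experiment {experiment!r}; expected 1 or 2")
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}; expected one of {PHASES}")
    if rng is None:
        rng = np.random.default_rng(seed)

    if trial_counts is None:
        if phase in ("baseline", "transfer"):
            trial_counts = _BASE_COUNTS
        else:
            trial_counts = EXP1_LEARNING_COUNTS if experiment == 1 else EXP2_LEARNING_COUNTS
    if no_feedback_types is None:
        no_feedback_types = (
            EXP2_NO_FEEDBACK_TYPES if (experiment == 2 and phase == "learning") else frozenset()
        )
    no_feedback_types = frozenset(no_feedback_types)

    labels: list[str] = []
    rating_flags: dict[str, list[bool]] = {}
    for lab in OFFER_LABELS:
        n = int(trial_counts.get(lab, 0))
        labels.extend([lab] * n)
        n_rated = int(round(rating_fraction * n))
        flags = np.zeros(n, dtype=bool)
        flags[rng.choice(n, size=n_rated, replace=False)] = True
        rating_flags[lab] = list(flags)

    order = rng.permutation(len(labels))
    seen: dict[str, int] = {lab: 0 for lab in OFFER_LABELS}
    trials: list[TrialSpec] = []
    for t, i in enumerate(order):
        lab = labels[i]
        offer = apply_offer_noise(lab, rng)
        feedback = phase == "learning" and lab not in no_feedback_types
        rated = rating_flags[lab][seen[lab]]
        seen[lab] += 1
        trials.append(
            TrialSpec(
                experiment=experiment,
                phase=phase,
                trial_index=t,
                offer=offer,
                feedback_available=feedback,
                rating_elicited=bool(rated),
            )
        )
    return trials


def schedule_to_frame(trials: Sequence[TrialSpec]) -> pd.DataFrame:
    """Serialize a schedule to a tidy frame (one row per trial)."""
    return pd.DataFrame(
        {
            "experiment": [t.experiment for t in trials],
            "phase": [t.phase for t in trials],
            "trial": [t.trial_index for t in trials],
            "offer_type": [t.offer.offer_type.label for t in trials],
            "receiver_share": [t.offer.receiver_share for t in trials],
            "feedback_available": [t.feedback_available for t in trials],
            "rating_elicited": [t.rating_elicited for t in trials],
        }
    )
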