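"""The seven Learning-phase choice models.

Each model maps the trial's offer to a probability of rejecting, and (for
the learning models) updates its internal state from the Teacher's revealed
preference. Conventions shared by all models:

* actions are coded 1 = reject, 0 = accept;
* feedback reward is 1 when the learner's action matches the Teacher's
  preferred action, 0 otherwise;
* bin-indexed models (1, 3-5) key on the nominal offer type, the
  Fehr-Schmidt models (2, 6) evaluate utilities at the noisy receiver
  share, and the similarity model (7) keys on the noisy integer share;
* no-feedback trials yield predictions but never state updates.

Models:

1. Random choosing — a fixed rejection probability per offer type.
2. Static preference — fixed Fehr-Schmidt envy/guilt plus softmax.
3. Basic RL — delta-rule action values per offer type, one learning rate.
4. Offer-sensitive RL — as 3, with a learning rate per offer type.
5. RL with free initial values — as 3, with free initial rejection values.
6. Preference inference — trial-by-trial inference of the Teacher's envy
   and guilt parameters from the bounds implied by each observed choice.
7. Similarity RL — action values over every integer offer, with updates
   generalized across offers through a Gaussian similarity kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..task import OFFER_LABELS
from .primitives import (
    delta_update,
    fs_utility,
    pi_bound,
    similarity_learning_rate,
    softmax_reject_prob,
    vshape_initial_q,
)

N_TYPES = len(OFFER_LABELS)

# Default fitting box for the softmax inverse temperature: from effectively
# random choice to near-deterministic choice on a 0-100 utility scale. The
# model itself accepts any tau >= 0.
TAU_BOUNDS = (1e-4, 20.0)
# Kernel width box for the similarity model; the lower edge is kept strictly
# positive because the kernel is degenerate at sigma = 0.
SIGMA_BOUNDS = (1e-2, 200.0)

_TYPE_SUFFIX = [lab.replace(":", "_") for lab in OFFER_LABELS]


@dataclass(frozen=True)
class Param:
    """One free parameter: name, box bounds, and how random starts sample it."""

    name: str
    lower: float
    upper: float
    log_scale: bool = False


class ChoiceModel:
    """Base class: parameter metadata plus predict/update dynamics."""

    model_id: int
    name: str
    params: tuple[Param, ...]

    @property
    def k(self) -> int:
        return len(self.params)

    @property
    def param_names(self) -> list[str]:
        return [p.name for p in self.params]

    @property
    def bounds(self) -> np.ndarray:
        return np.array([(p.lower, p.upper) for p in self.params], dtype=float)

    @property
    def log_scale(self) -> np.ndarray:
        return np.array([p.log_scale for p in self.params], dtype=bool)

    def check_params(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.k,):
            raise ValueError(
                f"{self.name} expects {self.k} parameters, got shape {theta.shape}"
            )
        b = self.bounds
        if np.any(theta < b[:, 0]) or np.any(theta > b[:, 1]):
            raise ValueError(f"{self.name} parameters {theta} outside bounds")
        return theta

    def init_state(self, theta: np.ndarray):
        return None

    def predict_reject(self, theta, state, type_idx: int, share: float) -> float:
        raise NotImplementedError

    def update(self, theta, state, type_idx: int, share: float, action: int, teacher_action: int) -> None:
        """Consume one trial's feedback; mutates ``state`` in place."""
        # stateless models ignore feedback
        return None

    def __repr__(self) -> str:  # pragma: no cover
        return f"<{type(self).__name__} (model {self.model_id}, k={self.k})>"


class RandomChoice(ChoiceModel):
    """Model 1: reject each offer type with a fixed probability."""

    model_id = 1
    name = "random_choice"
    params = tuple(Param(f"p_{s}", 0.0, 1.0) for s in _TYPE_SUFFIX)

    def predict_reject(self, theta, state, type_idx, share):
        return float(theta[type_idx])


class StaticPreference(ChoiceModel):
    """Model 2: fixed Fehr-Schmidt preferences, softmax choice."""

    model_id = 2
    name = "static_preference"
    params = (
        Param("alpha", 0.0, 10.0),
        Param("beta", 0.0, 10.0),
        Param("tau", *TAU_BOUNDS, log_scale=True),
    )

    def predict_reject(self, theta, state, type_idx, share):
        u_acc, u_rej = fs_utility(share, theta[0], theta[1])
        return softmax_reject_prob(u_rej, u_acc, theta[2])


class _QTableRL(ChoiceModel):
    """Shared machinery for the per-offer-type delta-rule models (3-5)."""

    def _eta(self, theta, type_idx: int) -> float:
        raise NotImplementedError

    def _tau(self, theta) -> float:
        raise NotImplementedError

    def _q0_reject(self, theta) -> np.ndarray:
        return np.full(N_TYPES, 0.5)

    def init_state(self, theta):
        q = np.full((2, N_TYPES), 0.5)  # rows: [accept, reject]
        q[1, :] = self._q0_reject(theta)
        return {"q": q}

    def predict_reject(self, theta, state, type_idx, share):
        q = state["q"]
        return softmax_reject_prob(q[1, type_idx], q[0, type_idx], self._tau(theta))

    def update(self, theta, state, type_idx, share, action, teacher_action):
        reward = 1.0 if action == teacher_action else 0.0
        q = state["q"]
        q[action, type_idx] = delta_update(q[action, type_idx], self._eta(theta, type_idx), reward)


class BasicRL(_QTableRL):
    """Model 3: one learning rate, initial values fixed at 0.5."""

    model_id = 3
    name = "basic_rl"
    params = (Param("eta", 0.0, 1.0), Param("tau", *TAU_BOUNDS, log_scale=True))

    def _eta(self, theta, type_idx):
        return float(theta[0])

    def _tau(self, theta):
        return float(theta[1])


class OfferSensitiveRL(_QTableRL):
    """Model 4: a separate learning rate per offer type."""

    model_id = 4
    name = "offer_sensitive_rl"
    params = tuple(Param(f"eta_{s}", 0.0, 1.0) for s in _TYPE_SUFFIX) + (
        Param("tau", *TAU_BOUNDS, log_scale=True),
    )

    def _eta(self, theta, type_idx):
        return float(theta[type_idx])

    def _tau(self, theta):
        return float(theta[N_TYPES])


class FreeInitRL(_QTableRL):
    """Model 5: one learning rate, free initial rejection values per type."""

    model_id = 5
    name = "free_init_rl"
    params = (Param("eta", 0.0, 1.0), Param("tau", *TAU_BOUNDS, log_scale=True)) + tuple(
        Param(f"q0_{s}", 0.0, 1.0) for s in _TYPE_SUFFIX
    )

    def _eta(self, theta, type_idx):
        return float(theta[0])

    def _tau(self, theta):
        return float(theta[1])

    def _q0_reject(self, theta):
        return np.asarray(theta[2:], dtype=float).copy()


class PreferenceInference(ChoiceModel):
    """Model 6: infer the Teacher's envy/guilt from choice-implied bounds.

    The learner assumes the Teacher rejects exactly when the Fehr-Schmidt
    utility of accepting is negative. Each observed choice on an unfair
    offer therefore implies a bound on the relevant preference parameter
    (envy for disadvantageous offers, guilt for advantageous ones); the
    current estimate moves a fraction ``eta`` toward that bound whenever it
    violates it, and is otherwise left unchanged. Estimates are clipped to
    [0, 10] after every update; fair (share = 50) offers are uninformative.
    """

    model_id = 6
    name = "preference_inference"
    params = (
        Param("eta", 0.0, 5.0),
        Param("tau", *TAU_BOUNDS, log_scale=True),
        Param("alpha0", 0.0, 10.0),
        Param("beta0", 0.0, 10.0),
    )

    def init_state(self, theta):
        return {"alpha": float(theta[2]), "beta": float(theta[3])}

    def predict_reject(self, theta, state, type_idx, share):
        u_acc, u_rej = fs_utility(share, state["alpha"], state["beta"])
        return softmax_reject_prob(u_rej, u_acc, theta[1])

    def update(self, theta, state, type_idx, share, action, teacher_action):
        # the learner's own action is irrelevant: only the Teacher's
        # revealed preference constrains the inferred parameters
        if share == 50:
            return
        eta = float(theta[0])
        bound = pi_bound(share)
        key = "alpha" if share < 50 else "beta"
        current = state[key]
        rejected = teacher_action == 1
        if rejected and current <= bound:
            # rejection implies the parameter exceeds its lower bound
            current = current + eta * (bound - current)
        elif not rejected and current >= bound:
            # acceptance implies the parameter lies below its upper bound
            current = current + eta * (bound - current)
        state[key] = min(max(current, 0.0), 10.0)


class SimilarityRL(ChoiceModel):
    """Model 7: delta-rule values over every integer offer 1..100, with
    learning generalized across offers by a Gaussian similarity kernel.

    Initial rejection values follow a V-shape in the offer (slopes alpha,
    beta in [0, 3]), mimicking inequity-averse starting preferences;
    initial acceptance values are 0.5.
    """

    model_id = 7
    name = "similarity_rl"
    params = (
        Param("eta", 0.0, 1.0),
        Param("tau", *TAU_BOUNDS, log_scale=True),
        Param("sigma", *SIGMA_BOUNDS),
        Param("alpha", 0.0, 3.0),
        Param("beta", 0.0, 3.0),
    )

    #: initial acceptance value (the V-shape fixes only rejection values)
    Q0_ACCEPT = 0.5

    def init_state(self, theta):
        offers = np.arange(101, dtype=float)  # index = integer offer; 0 unused
        q = np.empty((2, 101))
        q[0, :] = self.Q0_ACCEPT
        q[1, :] = [vshape_initial_q(theta[3], theta[4], o) for o in offers]
        return {"q": q}

    def predict_reject(self, theta, state, type_idx, share):
        q = state["q"]
        s = int(share)
        return softmax_reject_prob(q[1, s], q[0, s], theta[1])

    def update(self, theta, state, type_idx, share, action, teacher_action):
        reward = 1.0 if action == teacher_action else 0.0
        eta, sigma = float(theta[0]), float(theta[2])
        q = state["q"]
        s = int(share)
        for o in range(1, 101):
            rate = similarity_learning_rate(eta, sigma, o - s)
            q[action, o] = delta_update(q[action, o], rate, reward)
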