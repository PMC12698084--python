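"""Choice models for Learning-phase behaviour, addressable by id or name."""

from __future__ import annotations

from .learners import (
    BasicRL,
    ChoiceModel,
    FreeInitRL,
    OfferSensitiveRL,
    Param,
    PreferenceInference,
    RandomChoice,
    SimilarityRL,
    StaticPreference,
)
from .primitives import (
    PROB_FLOOR,
    delta_update,
    fs_utility,
    pi_bound,
    similarity_learning_rate,
    softmax_reject_prob,
    vshape_initial_q,
)

#: Registry of the seven models, keyed by id.
MODELS: dict[int, ChoiceModel] = {
    m.model_id: m
    for m in (
        RandomChoice(),
        StaticPreference(),
        BasicRL(),
        OfferSensitiveRL(),
        FreeInitRL(),
        PreferenceInference(),
        SimilarityRL(),
    )
}

_BY_NAME = {m.name: m for m in MODELS.values()}

#: Candidate set retained for Experiment 2 (the simple per-type RL variants
#: are dropped from comparison there).
EXP2_MODEL_IDS: tuple[int, ...] = (1, 2, 5, 6, 7)


def get_model(key: int | str | ChoiceModel) -> ChoiceModel:
    """Look a model up by id (1-7), name, or pass an instance through."""
    if isinstance(key, ChoiceModel):
        return key
    if isinstance(key, str):
        if key in _BY_NAME:
            return _BY_NAME[key]
        raise KeyError(f"unknown model {key!r}; valid names: {sorted(_BY_NAME)}")
    key = int(key)
    if key in MODELS:
        return MODELS[key]
    raise KeyError(f"no model with id {key}; valid ids are 1-7")


__all__ = [
    "MODELS",
    "EXP2_MODEL_IDS",
    "get_model",
    "ChoiceModel",
    "Param",
    "RandomChoice",
    "StaticPreference",
    "BasicRL",
    "OfferSensitiveRL",
    "FreeInitRL",
    "PreferenceInference",
    "SimilarityRL",
    "fs_utility",
    "softmax_reject_prob",
    "pi_bound",
    "similarity_learning_rate",
    "vshape_initial_q",
    "delta_update",
    "PROB_FLOOR",
]
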