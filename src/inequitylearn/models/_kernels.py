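"""Compiled per-trial likelihood kernels for the stateful models (3-7).

These mirror the object API in ``learners`` exactly; the pure-Python
per-trial loop there is the reference implementation and the two routes are
held to 1e-10 agreement by the test suite. Shared conventions: actions and
teacher actions are coded 1 = reject / 0 = accept, teacher = -1 marks a
no-feedback trial (prediction only, no state update), and ``weight`` is 1.0
for trials whose choice enters the likelihood.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_FLOOR = 1e-12


@njit(cache=True)
def _logistic(x: float) -> float:
    if x >= 0.0:
        p = 1.0 / (1.0 + np.exp(-x))
    else:
        e = np.exp(x)
        p = e / (1.0 + e)
    if p < _FLOOR:
        p = _FLOOR
    elif p > 1.0 - _FLOOR:
        p = 1.0 - _FLOOR
    return p


@njit(cache=True)
def _nll_term(p_reject: float, action: int) -> float:
    pc = p_reject if action == 1 else 1.0 - p_reject
    if pc < _FLOOR:
        pc = _FLOOR
    return -np.log(pc)


@njit(cache=True)
def nll_qtable(
    etas: np.ndarray,  # per-offer-type learning rates (constant for model 3/5)
    tau: float,
    q0_reject: np.ndarray,
    type_idx: np.ndarray,
    action: np.ndarray,
    teacher: np.ndarray,
    weight: np.ndarray,
) -> float:
    n_types = q0_reject.shape[0]
    q = np.empty((2, n_types))
    q[0, :] = 0.5
    q[1, :] = q0_reject
    total = 0.0
    for t in range(type_idx.shape[0]):
        k = type_idx[t]
        a = action[t]
        p = _logistic(tau * (q[1, k] - q[0, k]))
        total += weight[t] * _nll_term(p, a)
        if teacher[t] >= 0:
            r = 1.0 if a == teacher[t] else 0.0
            q[a, k] += etas[k] * (r - q[a, k])
    return total


@njit(cache=True)
def nll_preference_inference(
    eta: float,
    tau: float,
    alpha0: float,
    beta0: float,
    share: np.ndarray,
    action: np.ndarray,
    teacher: np.ndarray,
    weight: np.ndarray,
) -> float:
    alpha = alpha0
    beta = beta0
    total = 0.0
    for t in range(share.shape[0]):
        s = share[t]
        dis = 50.0 - s if s < 50.0 else 0.0
        adv = s - 50.0 if s > 50.0 else 0.0
        u_acc = s - alpha * dis - beta * adv
        p = _logistic(-tau * u_acc)
        total += weight[t] * _nll_term(p, action[t])
        if teacher[t] >= 0 and s != 50.0:
            rejected = teacher[t] == 1
            if s < 50.0:
                bound = s / (50.0 - s)
                if (rejected and alpha <= bound) or ((not rejected) and alpha >= bound):
                    alpha += eta * (bound - alpha)
                    alpha = min(max(alpha, 0.0), 10.0)
            else:
                bound = s / (s - 50.0)
                if (rejected and beta <= bound) or ((not rejected) and beta >= bound):
                    beta += eta * (bound - beta)
                    beta = min(max(beta, 0.0), 10.0)
    return total


@njit(cache=True)
def nll_similarity(
    eta: float,
    tau: float,
    sigma: float,
    alpha: float,
    beta: float,
    q0_accept: float,
    share: np.ndarray,
    action: np.ndarray,
    teacher: np.ndarray,
    weight: np.ndarray,
) -> float:
    q = np.empty((2, 101))
    for o in range(101):
        q[0, o] = q0_accept
        v_dis = alpha / 50.0 * (50.0 - o)
        v_adv = beta / 50.0 * (o - 50.0)
        q[1, o] = v_dis if v_dis > v_adv else v_adv
    # Gaussian similarity weights by absolute offer distance
    w = np.empty(100)
    inv = 1.0 / (2.0 * sigma * sigma)
    for d in range(100):
        w[d] = np.exp(-(d * d) * inv)
    total = 0.0
    for t in range(share.shape[0]):
        s = int(share[t])
        a = action[t]
        p = _logistic(tau * (q[1, s] - q[0, s]))
        total += weight[t] * _nll_term(p, a)
        if teacher[t] >= 0:
            r = 1.0 if a == teacher[t] else 0.0
            for o in range(1, 101):
                d = o - s if o >= s else s - o
                rate = eta * w[d]
                q[a, o] += rate * (r - q[a, o])
    return total
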