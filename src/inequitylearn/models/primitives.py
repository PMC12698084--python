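"""Closed-form building blocks shared by the choice models.

All offer amounts are the Receiver's share in integer cents on a 0-100
scale; the fair point is 50. Utilities follow the Fehr-Schmidt inequity
aversion form with envy (alpha) weighting the disadvantageous gap and guilt
(beta) the advantageous gap.
"""

from __future__ import annotations

import math

FAIR_POINT = 50.0
PROB_FLOOR = 1e-12  # likelihood floor; guards log() at deterministic mispredictions


def fs_utility(receiver_share: float, alpha: float, beta: float) -> tuple[float, float]:
    """Fehr-Schmidt utilities (U_accept, U_reject) of an offer.

    U_accept = share - alpha*max(50 - share, 0) - beta*max(share - 50, 0);
    rejection yields nothing for both players, so U_reject = 0.
    """
    if alpha < 0 or beta < 0:
        raise ValueError(f"envy/guilt must be nonnegative, got alpha={alpha}, beta={beta}")
    dis_gap = max(FAIR_POINT - receiver_share, 0.0)
    adv_gap = max(receiver_share - FAIR_POINT, 0.0)
    u_accept = receiver_share - alpha * dis_gap - beta * adv_gap
    return u_accept, 0.0


def softmax_reject_prob(u_reject: float, u_accept: float, tau: float) -> float:
    """Softmax probability of rejecting, with inverse temperature ``tau``.

    Computed in the numerically stable logistic form; as tau -> 0 both
    actions are chosen with equal probability, and the result is floored
    away from exactly 0 or 1.
    """
    if not (math.isfinite(u_reject) and math.isfinite(u_accept) and math.isfinite(tau)):
        raise ValueError("softmax inputs must be finite")
    if tau < 0:
        raise ValueError(f"inverse temperature must be nonnegative, got {tau}")
    x = tau * (u_reject - u_accept)
    if x >= 0:
        p = 1.0 / (1.0 + math.exp(-x))
    else:
        e = math.exp(x)
        p = e / (1.0 + e)
    return min(max(p, PROB_FLOOR), 1.0 - PROB_FLOOR)


def pi_bound(receiver_share: float, side: str = "lower") -> float:
    """Bound on the Teacher's envy/guilt implied by one accept/reject choice.

    For a disadvantageous offer (share < 50), U_accept < 0 iff
    alpha > share/(50 - share): a rejection implies that lower bound on envy
    and an acceptance the same expression as an upper bound. For an
    advantageous offer (share > 50) the analogous guilt bound is
    share/(share - 50). The numeric value is the same for either side; which
    bound it is depends on the observed action.
    """
    if side not in ("lower", "upper"):
        raise ValueError(f"side must be 'lower' or 'upper', got {side!r}")
    if receiver_share == FAIR_POINT:
        raise ZeroDivisionError("preference bound undefined at the fair split (share = 50)")
    if receiver_share < FAIR_POINT:
        return receiver_share / (FAIR_POINT - receiver_share)
    return receiver_share / (receiver_share - FAIR_POINT)


def similarity_learning_rate(eta: float, sigma: float, delta: float) -> float:
    """Gaussian-kernel learning rate for generalization across offers.

    eta * exp(-delta^2 / (2 sigma^2)): equals eta at delta = 0 and decays
    with the distance between the experienced and the to-be-updated offer.
    """
    if sigma <= 0:
        raise ValueError(f"kernel width must be positive, got sigma={sigma}")
    return eta * math.exp(-(delta * delta) / (2.0 * sigma * sigma))


def vshape_initial_q(alpha: float, beta: float, receiver_share: float) -> float:
    """V-shaped initial rejection value, zero at the fair split.

    max(alpha/50*(50 - share), beta/50*(share - 50)); slopes constrained to
    [0, 3].
    """
    if not (0.0 <= alpha <= 3.0 and 0.0 <= beta <= 3.0):
        raise ValueError(f"V-shape slopes must lie in [0, 3], got alpha={alpha}, beta={beta}")
    return max(
        alpha / FAIR_POINT * (FAIR_POINT - receiver_share),
        beta / FAIR_POINT * (receiver_share - FAIR_POINT),
    )


def delta_update(q: float, eta: float, reward: float) -> float:
    """One delta-rule step: Q + eta * (R - Q)."""
    return q + eta * (reward - q)
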