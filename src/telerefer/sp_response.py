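"""Specialist congestion, quality cost, and the optimal service-rate response.

The specialist is modelled as an M/M/1 queue with arrival rate ``lam`` and
service rate ``mu``; the expected wait is ``1/(mu - lam)``.  The per-patient
quality cost combines delay cost and inadequate-care cost,

    QC(lam, mu) = beta / (mu - lam) + alpha * mu,

and the profit-maximising specialist (whose profit increases in arrivals)
picks the service rate that minimises QC, which satisfies the first-order
condition ``beta / (mu - lam)^2 = alpha``, i.e. ``mu* = lam + sqrt(beta/alpha)``.
A notable consequence is that the equilibrium wait ``sqrt(alpha/beta)`` does
not depend on the arrival rate: extra demand is absorbed entirely by working
faster, degrading care quality (the ``alpha*mu`` term) instead of lengthening
the queue.
"""

from __future__ import annotations

import math


class QueueInstabilityError(ValueError):
    """Raised when mu <= lam (the M/M/1 queue has no stationary regime)."""


def _check_stable(lam: float, mu: float) -> None:
    if lam < 0:
        raise ValueError(f"arrival rate must be nonnegative, got {lam}")
    if mu <= lam:
        raise QueueInstabilityError(
            f"service rate mu={mu} must exceed arrival rate lam={lam}"
        )


def waiting_time(lam: float, mu: float) -> float:
    """Expected M/M/1 waiting time 1/(mu - lam)."""
    _check_stable(lam, mu)
    return 1.0 / (mu - lam)


def quality_cost(lam: float, mu: float, alpha: float, beta: float) -> float:
    """Per-patient quality cost beta/(mu - lam) + alpha*mu."""
    _check_stable(lam, mu)
    return beta / (mu - lam) + alpha * mu


def optimal_service_rate(lam: float, alpha: float, beta: float) -> float:
    """The specialist's best-response service rate mu* = lam + sqrt(beta/alpha).

    Solves the first-order condition beta/(mu - lam)^2 = alpha of quality-cost
    minimisation; the implied wait sqrt(alpha/beta) is independent of lam.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError(f"alpha and beta must be positive, got alpha={alpha}, beta={beta}")
    if lam < 0:
        raise ValueError(f"arrival rate must be nonnegative, got {lam}")
    mu = lam + math.sqrt(beta / alpha)
    # FOC residual check: guards against degenerate float inputs.
    residual = abs(beta / (mu - lam) ** 2 - alpha)
    if residual > 1e-10 * max(1.0, alpha):
        raise ArithmeticError(f"FOC residual {residual} too large at mu={mu}")
    return mu


def equilibrium_quality_cost(lam: float, alpha: float, beta: float) -> float:
    """Quality cost at the best-response service rate: 2*sqrt(alpha*beta) + alpha*lam.

    Affine and increasing in the arrival rate with slope alpha — more demand
    means faster, lower-quality service.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError(f"alpha and beta must be positive, got alpha={alpha}, beta={beta}")
    if lam < 0:
        raise ValueError(f"arrival rate must be nonnegative, got {lam}")
    return 2.0 * math.sqrt(alpha * beta) + alpha * lam
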