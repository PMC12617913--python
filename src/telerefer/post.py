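"""Post-telemedicine equilibrium: tele cutoff, scenario classification, mixed strategies.

Telemedicine adds two paths: a referred patient can be treated remotely by the
specialist with the GP assisting (the GP collects the tele-reward ``gamma``
per assisted encounter), and a patient may even pick telemedicine for the
first visit.  The remote utility

    Us2 = Rt - (1 - qt) * Ps - QC

carries no travel cost, so it beats the in-person utility ``Us1`` exactly
beyond the tele cutoff ``d_tilde = [Rs - Rt + (qs - qt) * Ps] / Ct``.

Two market shapes arise.  In *scenario 1* (``d_hat <= d_tilde``) nobody
tele-visits first: near patients go to the specialist in person, middle ones
GP-first with in-person referral, far ones GP-first with tele referral.  In
*scenario 2* (``d_hat > d_tilde``) patients beyond ``d_tilde`` split between
direct telemedicine and GP-first; the split mass ``lam_tele`` is pinned down
by a congestion-mediated indifference condition — extra tele-first demand
raises the specialist's arrival rate, hence (through the service-rate
response) the quality cost, until the remote utility falls to the GP-first
continuation value.  The relation between tele-first mass and quality cost is
affine, so the indifference equation solves in closed form and is clamped to
``[0, dmax - d_tilde]`` with a strict-preference check at the boundaries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from ._optim import maximize_on_interval
from .params import ModelParams, ParamValidationError
from .pre import (K_MIN, DegenerateReferralError, ModelInconsistencyError,
                  _cutoff_raw, _gp_base_utility)
from .sp_response import equilibrium_quality_cost, optimal_service_rate

log = logging.getLogger(__name__)


class ScenarioMismatchError(RuntimeError):
    """The requested scenario's segmentation is inconsistent at the solved state."""


@dataclass
class PostEquilibrium:
    """Endogenous outcome of one post-telemedicine solve at referral level ``k``."""

    k: float
    d_tilde: float        # in-person vs telemedicine cutoff (parameter-only)
    d_hat: float          # direct-SP vs GP-first cutoff (scenario 1 structure)
    lam_tele: float       # mass choosing telemedicine for the first visit (scenario 2)
    lam_s: float
    lam_g: float          # GP first-visit mass
    mu: float
    qc: float
    pi_g: float
    scenario: int         # 1 | 2
    clamped: bool = False
    diagnostics: dict = field(default_factory=dict)


def tele_cutoff(p: ModelParams) -> float:
    """Farthest distance preferring the specialist in person over telemedicine.

    ``d_tilde = max(0, [Rs - Rt + (qs - qt) * Ps] / Ct)``; independent of the
    referral level and of congestion (the quality cost cancels between Us1 and
    Us2 because the specialist serves both channels identically).
    """
    return max(0.0, (p.Rs - p.Rt + (p.qs - p.qt) * p.Ps) / p.Ct)


def utilities_post(k: float, d: float, qc: float,
                   p: ModelParams) -> tuple[float, float, float, float]:
    """Expected utilities (Us1, Us2, Ug1, Ug2) of the four post-tele paths.

    Us1/Us2: direct specialist in person / via telemedicine.  Ug1/Ug2: GP
    first with in-person / telemedicine referral continuation.
    """
    if not 0.0 < k <= 1.0:
        raise ParamValidationError(f"k must lie in (0, 1], got {k}")
    us1 = p.Rs - (1.0 - p.qs) * p.Ps - qc - p.Ct * d
    us2 = p.Rt - (1.0 - p.qt) * p.Ps - qc
    F = p.success().F(k)
    base = _gp_base_utility(k, p)
    ug1 = base + (1.0 - F) * us1
    ug2 = base + (1.0 - F) * us2
    return us1, us2, ug1, ug2


def indifference_target(k: float, p: ModelParams) -> float:
    """The remote utility level at which direct-tele and GP-first tie.

    Setting Ug2 = Us2 and solving for Us2 gives
    ``Rg - [k (1-qg) Pg + m (k - F(k))] / F(k)`` — decreasing in the
    mistreatment cost and equal to ``Rg`` when the GP visit is free of fees
    and risk.
    """
    F = p.success().F(k)
    if F <= 0.0:
        raise DegenerateReferralError(f"F(k)={F} at k={k}")
    return p.Rg - (k * (1.0 - p.qg) * p.Pg + p.m * (k - F)) / F


def solve_scenario1(k: float, p: ModelParams, strict: bool = True) -> PostEquilibrium:
    """Scenario-1 equilibrium at fixed ``k``: no first-visit telemedicine.

    The specialist absorbs everyone except the GP-cured fraction,
    ``lam_s = dmax - (dmax - d_hat) F(k)``, and the cutoff system is the same
    linear fixed point as under full coverage.  Raises (or flags, with
    ``strict=False``) a scenario mismatch when the solved ``d_hat`` exceeds
    the tele cutoff.
    """
    F = p.success().F(k)
    if F <= 0.0:
        raise DegenerateReferralError(f"F(k)={F} at k={k}")
    s = 2.0 * math.sqrt(p.alpha * p.beta)
    rhs = _cutoff_raw(k, 0.0, p) - (s + p.alpha * p.dmax * (1.0 - F)) / p.Ct
    d_hat = rhs / (1.0 + p.alpha * F / p.Ct)
    clamped = not (0.0 <= d_hat <= p.dmax)
    d_hat = min(max(d_hat, 0.0), p.dmax)
    lam_s = p.dmax - (p.dmax - d_hat) * F
    qc = equilibrium_quality_cost(lam_s, p.alpha, p.beta)
    mu = optimal_service_rate(lam_s, p.alpha, p.beta)
    d_tilde = tele_cutoff(p)
    consistent = d_hat <= d_tilde + 1e-12
    if strict and not consistent:
        raise ScenarioMismatchError(
            f"scenario 1 inconsistent: d_hat={d_hat} > d_tilde={d_tilde}")
    state = PostEquilibrium(
        k=k, d_tilde=d_tilde, d_hat=d_hat, lam_tele=0.0, lam_s=lam_s,
        lam_g=p.dmax - d_hat, mu=mu, qc=qc, pi_g=0.0, scenario=1, clamped=clamped,
        diagnostics={"scenario_consistent": bool(consistent),
                     "cutoff_residual": 0.0 if clamped else abs(d_hat - _cutoff_raw(k, qc, p))})
    state.pi_g = gp_profit_post(k, state, p)
    return state


def solve_scenario2(k: float, p: ModelParams) -> PostEquilibrium:
    """Scenario-2 equilibrium at fixed ``k``: mixed tele-first strategies.

    Solves ``Us2(lam_s) = indifference_target(k)`` through the affine chain
    lam_tele -> lam_s -> qc -> Us2, clamps to ``[0, dmax - d_tilde]``, and at
    a clamped boundary verifies that the strict preference points outward
    (toward the boundary), so no interior deviation is profitable.
    """
    F = p.success().F(k)
    if F <= 0.0:
        raise DegenerateReferralError(f"F(k)={F} at k={k}")
    d_tilde = tele_cutoff(p)
    cap = p.dmax - d_tilde
    target = indifference_target(k, p)
    s = 2.0 * math.sqrt(p.alpha * p.beta)
    # Us2 = Rt - (1-qt)Ps - qc = target  =>  required qc and arrival rate
    qc_req = p.Rt - (1.0 - p.qt) * p.Ps - target
    lam_req = (qc_req - s) / p.alpha
    lam_tele_raw = (lam_req - p.dmax + (p.dmax - d_tilde) * F) / F
    lam_tele = min(max(lam_tele_raw, 0.0), max(cap, 0.0))
    clamped = lam_tele != lam_tele_raw
    lam_s = p.dmax - (p.dmax - d_tilde - lam_tele) * F
    qc = equilibrium_quality_cost(lam_s, p.alpha, p.beta)
    mu = optimal_service_rate(lam_s, p.alpha, p.beta)
    us2 = p.Rt - (1.0 - p.qt) * p.Ps - qc
    if clamped:
        # boundary consistency: at lam_tele=0 GP-first must be weakly preferred,
        # at lam_tele=cap direct tele must be weakly preferred
        if lam_tele == 0.0 and us2 > target + 1e-9:
            raise ModelInconsistencyError(
                f"lam_tele clamped to 0 but direct tele strictly preferred (Us2={us2} > {target})")
        if lam_tele == cap and us2 < target - 1e-9:
            raise ModelInconsistencyError(
                f"lam_tele clamped to cap but GP-first strictly preferred (Us2={us2} < {target})")
    d_hat_implied = _cutoff_raw(k, qc, p)
    state = PostEquilibrium(
        k=k, d_tilde=d_tilde, d_hat=min(max(d_hat_implied, 0.0), p.dmax),
        lam_tele=lam_tele, lam_s=lam_s, lam_g=p.dmax - d_tilde - lam_tele,
        mu=mu, qc=qc, pi_g=0.0, scenario=2, clamped=clamped,
        diagnostics={"indifference_residual": 0.0 if clamped else abs(us2 - target),
                     "d_hat_implied": d_hat_implied,
                     "scenario_consistent": bool(d_hat_implied > d_tilde - 1e-12)})
    state.pi_g = gp_profit_post(k, state, p)
    return state


def gp_profit_post(k: float, state: PostEquilibrium, p: ModelParams) -> float:
    """GP profit with the tele-reward term.

    Scenario 1: treatment margin on the GP-first mass plus ``gamma`` per
    tele-referred encounter beyond the tele cutoff.  Scenario 2: the GP-first
    mass shrinks by the tele-first defectors, but the GP collects ``gamma``
    for assisting them as well.
    """
    F = p.success().F(k)
    margin = (p.Pg - p.Cg) * k - p.m * (k - F)
    if state.scenario == 1:
        dt = min(state.d_tilde, p.dmax)   # no tele-assisted encounters beyond the market
        return (p.dmax - state.d_hat) * margin + p.gamma * (p.dmax - dt) * (1.0 - F)
    gp_mass = p.dmax - state.d_tilde - state.lam_tele
    return gp_mass * margin + p.gamma * (state.lam_tele + gp_mass * (1.0 - F))


def solve_post_at_k(k: float, p: ModelParams) -> PostEquilibrium:
    """The consistent-scenario equilibrium at fixed ``k`` (scenario 1 tried first)."""
    state = solve_scenario1(k, p, strict=False)
    if state.diagnostics["scenario_consistent"]:
        return state
    return solve_scenario2(k, p)


def solve_post_equilibrium(p: ModelParams, k_min: float = K_MIN,
                           grid_n: int = 2001, xatol: float = 1e-7) -> PostEquilibrium:
    """Post-telemedicine equilibrium at the GP's optimal referral level.

    For each candidate ``k`` the consistent scenario is solved (the two are
    exclusive because ``d_hat`` moves continuously through ``d_tilde``); the
    GP profit is then maximized over ``k``.  The returned state records a
    patient best-response audit on a 101-point distance grid.
    """
    k_star, _, info = maximize_on_interval(lambda k: solve_post_at_k(k, p).pi_g,
                                           k_min, 1.0, grid_n=grid_n, xatol=xatol)
    state = solve_post_at_k(k_star, p)
    gain = best_response_gain_post(state, p)
    state.diagnostics["max_deviation_gain"] = gain
    state.diagnostics["unimodal"] = info.get("unimodal", True)
    if gain > 1e-6:
        log.warning("patient best-response audit found a %.3g-utility deviation", gain)
    return state


def best_response_gain_post(state: PostEquilibrium, p: ModelParams, n: int = 101) -> float:
    """Max utility a patient could gain by deviating from the assigned path.

    Audits the equilibrium segmentation on an ``n``-point distance grid with
    the aggregate quality cost held at its equilibrium value.  The GP-first
    option lets the referred patient pick the better referral channel.
    """
    k, qc = state.k, state.qc
    F = p.success().F(k)
    base = _gp_base_utility(k, p)
    worst = 0.0
    for i in range(n):
        d = (i + 0.5) * p.dmax / n
        us1, us2, _, _ = utilities_post(k, d, qc, p)
        gp_first = base + (1.0 - F) * max(us1, us2)
        best = max(us1, us2, gp_first)
        if state.scenario == 1:
            if d <= state.d_hat:
                assigned = us1
            elif d <= state.d_tilde:
                assigned = base + (1.0 - F) * us1
            else:
                assigned = base + (1.0 - F) * us2
        else:
            if d <= state.d_tilde:
                assigned = us1
            elif 0.0 < state.lam_tele < p.dmax - state.d_tilde:
                assigned = max(us2, base + (1.0 - F) * us2)  # mixed: both played
            elif state.lam_tele == 0.0:
                assigned = base + (1.0 - F) * us2
            else:
                assigned = us2
        worst = max(worst, best - assigned)
    return worst
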