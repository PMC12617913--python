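"""Pre-telemedicine equilibrium: patient segmentation, SP demand, GP referral choice.

Without telemedicine a patient at distance ``d`` compares two paths:

* direct specialist visit, with utility
  ``Us = Rs - (1-qs)*Ps - QC - Ct*d``;
* GP first, with utility
  ``Ug = F(k)*Rg - k*(1-qg)*Pg - m*(k - F(k)) + (1 - F(k))*Us``
  (the GP cures a fraction ``F(k)``, charges for every treatment attempt,
  exposes the patient to mistreatment risk ``k - F(k)``, and refers the rest).

Because ``Us`` falls with distance while the GP detour dilutes the travel
burden by the factor ``1 - F(k)``, nearby patients go straight to the
specialist and distant ones see the GP first; the indifference cutoff is
``d_hat``.  Under *full coverage* every patient reaches care; under *partial
coverage* the specialist's utility turns negative beyond the give-up distance
``d_o`` (where ``Us = 0``) and referred patients past it abandon treatment.

The specialist's best-response service rate (quality-cost FOC) makes the
equilibrium quality cost affine in its arrival rate, so each regime reduces
to a small linear system in the cutoffs; a damped fixed-point iteration is
kept as an internal cross-check and as a fallback when a cutoff clamps.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable

from ._optim import maximize_on_interval
from .params import ModelParams, ParamValidationError
from .sp_response import equilibrium_quality_cost, optimal_service_rate

log = logging.getLogger(__name__)

K_MIN = 1e-4  # smallest admissible referral level; Eq-3-style cutoffs divide by F(k)


class DegenerateReferralError(ValueError):
    """Raised when F(k) = 0 makes the GP-first path undefined."""


class RegimeMismatchError(RuntimeError):
    """The requested coverage regime is inconsistent at the solved state."""


class ModelInconsistencyError(RuntimeError):
    """Neither coverage regime passes its post-solve consistency check."""


@dataclass
class PreEquilibrium:
    """Endogenous outcome of one pre-telemedicine solve at referral level ``k``."""

    k: float
    d_hat: float          # direct-SP vs GP-first cutoff
    d_o: float            # farthest distance willing to visit SP (= dmax when full)
    lam_s: float          # SP arrival mass
    lam_g: float          # GP arrival mass (includes give-up patients under partial)
    mu: float
    qc: float
    pi_g: float
    regime: str           # "full" | "partial"
    clamped: bool = False
    diagnostics: dict = field(default_factory=dict)


def utilities_pre(k: float, d: float, qc: float, p: ModelParams) -> tuple[float, float]:
    """Expected utilities (Us, Ug) of direct-SP vs GP-first at distance ``d``."""
    if not 0.0 < k <= 1.0:
        raise ParamValidationError(f"k must lie in (0, 1], got {k}")
    if qc < 0:
        raise ParamValidationError(f"quality cost must be nonnegative, got {qc}")
    F = p.success().F(k)
    us = p.Rs - (1.0 - p.qs) * p.Ps - qc - p.Ct * d
    ug = F * p.Rg - k * (1.0 - p.qg) * p.Pg - p.m * (k - F) + (1.0 - F) * us
    return us, ug


def _gp_base_utility(k: float, p: ModelParams) -> float:
    # utility components of a GP visit that do not depend on the referral outcome
    F = p.success().F(k)
    return F * p.Rg - k * (1.0 - p.qg) * p.Pg - p.m * (k - F)


def _cutoff_raw(k: float, qc: float, p: ModelParams) -> float:
    F = p.success().F(k)
    if F <= 0.0:
        raise DegenerateReferralError(f"F(k)={F} at k={k}: GP-first path degenerate")
    return ((p.m + (1.0 - p.qg) * p.Pg) * k / (p.Ct * F)
            + (p.Rs - p.Rg - p.m - (1.0 - p.qs) * p.Ps - qc) / p.Ct)


def cutoff_direct_vs_gp(k: float, qc: float, p: ModelParams,
                        upper: float | None = None) -> float:
    """Indifference cutoff between direct-SP and GP-first, clamped to [0, upper]."""
    d_hat = _cutoff_raw(k, qc, p)
    hi = p.dmax if upper is None else upper
    return min(max(d_hat, 0.0), hi)


def _finish_state(k: float, d_hat: float, d_o: float, lam_s: float, p: ModelParams,
                  regime: str, clamped: bool, diagnostics: dict) -> PreEquilibrium:
    qc = equilibrium_quality_cost(lam_s, p.alpha, p.beta)
    mu = optimal_service_rate(lam_s, p.alpha, p.beta)
    lam_g = p.dmax - d_hat
    pi_g = gp_profit_pre(k, d_hat, p)
    return PreEquilibrium(k=k, d_hat=d_hat, d_o=d_o, lam_s=lam_s, lam_g=lam_g,
                          mu=mu, qc=qc, pi_g=pi_g, regime=regime,
                          clamped=clamped, diagnostics=diagnostics)


def solve_full_coverage(k: float, p: ModelParams) -> PreEquilibrium:
    """Full-coverage equilibrium at fixed ``k``: everyone within ``dmax`` seeks care.

    Solves the linear fixed point of (cutoff, arrival rate, quality cost):
    ``lam_s = d_hat + (dmax - d_hat)(1 - F(k))`` with
    ``qc = 2 sqrt(alpha beta) + alpha lam_s``.
    """
    F = p.success().F(k)
    if F <= 0.0:
        raise DegenerateReferralError(f"F(k)={F} at k={k}")
    s = 2.0 * math.sqrt(p.alpha * p.beta)
    # d_hat*(1 + alpha*F/Ct) = cutoff_raw(qc=0) - (s + alpha*dmax*(1-F))/Ct
    rhs = _cutoff_raw(k, 0.0, p) - (s + p.alpha * p.dmax * (1.0 - F)) / p.Ct
    d_hat = rhs / (1.0 + p.alpha * F / p.Ct)
    clamped = not (0.0 <= d_hat <= p.dmax)
    d_hat = min(max(d_hat, 0.0), p.dmax)
    lam_s = d_hat + (p.dmax - d_hat) * (1.0 - F)
    qc = equilibrium_quality_cost(lam_s, p.alpha, p.beta)
    resid = 0.0 if clamped else abs(d_hat - _cutoff_raw(k, qc, p))
    diag = {"method": "linear", "cutoff_residual": resid,
            "us_at_dmax": p.Rs - (1.0 - p.qs) * p.Ps - qc - p.Ct * p.dmax}
    return _finish_state(k, d_hat, p.dmax, lam_s, p, "full", clamped, diag)


def solve_partial_coverage(k: float, p: ModelParams, strict: bool = True) -> PreEquilibrium:
    """Partial-coverage equilibrium at fixed ``k``: distant patients give up.

    Jointly solves the cutoff ``d_hat``, the give-up distance ``d_o`` (where
    ``Us = 0``) and the SP arrival rate; the interior case is a linear solve in
    the equilibrium quality cost.  With ``strict`` a solved ``d_o >= dmax``
    raises :class:`RegimeMismatchError` (the market is actually fully covered);
    otherwise the state is returned with ``d_o`` clamped and flagged, which
    keeps the GP profit function continuous during referral optimisation.
    """
    F = p.success().F(k)
    if F <= 0.0:
        raise DegenerateReferralError(f"F(k)={F} at k={k}")
    s = 2.0 * math.sqrt(p.alpha * p.beta)
    k1 = _cutoff_raw(k, 0.0, p)                       # d_hat = k1 - qc/Ct
    k2 = (p.Rs - (1.0 - p.qs) * p.Ps) / p.Ct          # d_o   = k2 - qc/Ct
    # lam_s = F*d_hat + (1-F)*d_o  =>  qc*(1 + alpha/Ct) = s + alpha*(F*k1 + (1-F)*k2)
    qc = (s + p.alpha * (F * k1 + (1.0 - F) * k2)) / (1.0 + p.alpha / p.Ct)
    d_hat = k1 - qc / p.Ct
    d_o = k2 - qc / p.Ct
    clamped = False
    used_iteration = False
    if not (0.0 <= d_hat <= d_o and 0.0 <= d_o <= p.dmax):
        d_hat, d_o, clamped = _iterate_partial(k, p)
        used_iteration = True
    if d_o >= p.dmax - 1e-12:
        if strict:
            raise RegimeMismatchError(
                f"solved give-up distance d_o={d_o} reaches dmax={p.dmax}; use full coverage")
        d_o = p.dmax
        clamped = True
    lam_s = d_hat + (d_o - d_hat) * (1.0 - F)
    qc = equilibrium_quality_cost(lam_s, p.alpha, p.beta)
    us_at_do = p.Rs - (1.0 - p.qs) * p.Ps - qc - p.Ct * d_o
    diag = {"method": "iterative" if used_iteration else "linear",
            "us_at_do": us_at_do,
            "cutoff_residual": 0.0 if clamped else abs(d_hat - _cutoff_raw(k, qc, p))}
    return _finish_state(k, d_hat, d_o, lam_s, p, "partial", clamped, diag)


def _iterate_partial(k: float, p: ModelParams, relax: float = 0.5,
                     tol: float = 1e-12, max_iter: int = 100_000) -> tuple[float, float, bool]:
    """Damped fixed-point iteration on (d_hat, d_o) with boundary clamping."""
    F = p.success().F(k)
    d_hat, d_o = p.dmax / 2.0, p.dmax / 2.0
    clamped = False
    for _ in range(max_iter):
        lam_s = d_hat + (d_o - d_hat) * (1.0 - F)
        qc = equilibrium_quality_cost(lam_s, p.alpha, p.beta)
        d_o_new = min(max((p.Rs - (1.0 - p.qs) * p.Ps - qc) / p.Ct, 0.0), p.dmax)
        d_hat_new = min(max(_cutoff_raw(k, qc, p), 0.0), d_o_new)
        d_hat_next = d_hat + relax * (d_hat_new - d_hat)
        d_o_next = d_o + relax * (d_o_new - d_o)
        if abs(d_hat_next - d_hat) < tol and abs(d_o_next - d_o) < tol:
            raw_hat = _cutoff_raw(k, qc, p)
            raw_o = (p.Rs - (1.0 - p.qs) * p.Ps - qc) / p.Ct
            clamped = (raw_hat < -1e-9 or raw_hat > d_o_new + 1e-9
                       or raw_o < -1e-9 or raw_o > p.dmax + 1e-9)
            return d_hat_next, d_o_next, clamped
        d_hat, d_o = d_hat_next, d_o_next
    raise ModelInconsistencyError("partial-coverage fixed point failed to converge")


def gp_profit_pre(k: float, d_hat: float, p: ModelParams) -> float:
    """GP profit ``(dmax - d_hat) * [(Pg - Cg)k - m(k - F(k))]``.

    The GP arrival mass is ``dmax - d_hat`` in both regimes: give-up patients
    still visit the GP first.
    """
    if not 0.0 <= k <= 1.0:
        raise ParamValidationError(f"k must lie in [0, 1], got {k}")
    F = p.success().F(k)
    return (p.dmax - d_hat) * ((p.Pg - p.Cg) * k - p.m * (k - F))


def optimize_gp_referral(p: ModelParams,
                         solver: Callable[[float, ModelParams], PreEquilibrium],
                         k_min: float = K_MIN, grid_n: int = 2001,
                         xatol: float = 1e-7) -> float:
    """The GP's optimal referral level under a given regime solver.

    Maximizes the solved GP profit over ``k`` in [k_min, 1] by grid search with
    golden-section refinement; ties break toward the smallest maximizer (the
    least gatekeeping distortion).  A non-unimodal profile triggers a logged
    warning and falls back to the global grid argmax.
    """
    k_star, _, _ = maximize_on_interval(lambda k: solver(k, p).pi_g, k_min, 1.0,
                                        grid_n=grid_n, xatol=xatol)
    return k_star


def best_response_gain_pre(state: PreEquilibrium, p: ModelParams, n: int = 101) -> float:
    """Max utility a patient could gain by deviating from the assigned path.

    Audits the pre-telemedicine segmentation on an ``n``-point distance grid
    with the quality cost held at its equilibrium value.  The GP-first option
    includes the referred patient's choice to give up when the specialist
    continuation is negative.
    """
    k, qc = state.k, state.qc
    F = p.success().F(k)
    base = _gp_base_utility(k, p)
    worst = 0.0
    for i in range(n):
        d = (i + 0.5) * p.dmax / n
        us, _ = utilities_pre(k, d, qc, p)
        gp_first = base + (1.0 - F) * max(us, 0.0)
        best = max(us, gp_first)
        if d <= state.d_hat:
            assigned = us
        elif d <= state.d_o:
            assigned = base + (1.0 - F) * us
        else:
            assigned = base
        worst = max(worst, best - assigned)
    return worst


def solve_pre_equilibrium(p: ModelParams, coverage: str = "auto") -> PreEquilibrium:
    """Full pre-telemedicine equilibrium: optimal ``k`` plus regime selection.

    Tries full coverage first; if the marginal patient at ``dmax`` would get
    negative utility from the specialist at the solved state, re-solves and
    re-optimizes under partial coverage.  ``coverage`` may force a regime (the
    consistency check is still run and reported in the diagnostics).
    """
    if coverage not in ("auto", "full", "partial"):
        raise ValueError(f"coverage must be auto|full|partial, got {coverage!r}")

    full_state = None
    if coverage in ("auto", "full"):
        k_full = optimize_gp_referral(p, solve_full_coverage)
        full_state = solve_full_coverage(k_full, p)
        full_ok = full_state.diagnostics["us_at_dmax"] >= -1e-12
        full_state.diagnostics["regime_consistent"] = bool(full_ok)
        if coverage == "full":
            if not full_ok:
                log.warning("forced full coverage is inconsistent: Us(dmax)=%.6g",
                            full_state.diagnostics["us_at_dmax"])
            return full_state
        if full_ok:
            return full_state

    def partial_solver(k: float, q: ModelParams) -> PreEquilibrium:
        return solve_partial_coverage(k, q, strict=False)

    k_part = optimize_gp_referral(p, partial_solver)
    part_state = solve_partial_coverage(k_part, p, strict=False)
    part_ok = part_state.d_o < p.dmax - 1e-12
    part_state.diagnostics["regime_consistent"] = bool(part_ok)
    if coverage == "partial":
        if not part_ok:
            log.warning("forced partial coverage is inconsistent: d_o=%.6g >= dmax=%.6g",
                        part_state.d_o, p.dmax)
        return part_state
    if part_ok:
        return part_state
    raise ModelInconsistencyError(
        "neither coverage regime is self-consistent: "
        f"full Us(dmax)={full_state.diagnostics['us_at_dmax']:.6g}, "
        f"partial d_o={part_state.d_o:.6g} vs dmax={p.dmax:.6g}")
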