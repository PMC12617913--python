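"""Independent verification: brute-force optimizers, damped iteration, agent simulation.

These deliberately avoid the analytic linear solves in :mod:`telerefer.pre`
and :mod:`telerefer.post`: the fixed points are re-found by damped iteration
or bisection straight from the model primitives, and the patient continuum is
replaced by a finite population of agents running sequential (Gauss–Seidel)
best-response dynamics.  Agreement between the routes is what the test suite
checks; nothing here is used by the solvers themselves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .params import ModelParams
from .post import tele_cutoff

__all__ = ["brute_force_gp_optimum", "iterate_pre", "iterate_post",
           "agent_best_response", "AgentEquilibrium"]


def brute_force_gp_optimum(p: ModelParams, solver: Callable[[float, ModelParams], object],
                           grid_n: int = 2001, k_min: float = 1e-4) -> tuple[float, bool]:
    """Grid argmax of GP profit and a unimodality flag for the sampled profile.

    ``solver(k, p)`` must return a state exposing ``pi_g``.  Plateaus within
    1e-9 are ignored when counting local maxima.
    """
    ks = np.linspace(k_min, 1.0, grid_n)
    vals = np.array([solver(float(k), p).pi_g for k in ks])
    dv = np.diff(vals)
    sign = np.where(dv > 1e-9, 1, np.where(dv < -1e-9, -1, 0))
    sign = sign[sign != 0]
    if len(sign) == 0:
        unimodal = True
    else:
        switches = int(np.sum((sign[:-1] > 0) & (sign[1:] < 0)))
        n_max = switches + (1 if sign[0] < 0 else 0) + (1 if sign[-1] > 0 else 0)
        unimodal = max(1, n_max) <= 1
    return float(ks[int(np.argmax(vals))]), unimodal


def _qc(lam: float, p: ModelParams) -> float:
    return 2.0 * math.sqrt(p.alpha * p.beta) + p.alpha * lam


def iterate_pre(k: float, p: ModelParams, relax: float = 0.5,
                tol: float = 1e-12, max_iter: int = 100_000) -> dict:
    """Pre-telemedicine cutoffs by damped fixed-point iteration from the primitives.

    Iterates (d_hat, d_o) under the indifference and zero-utility conditions
    with the service-rate response substituted; the regime label follows from
    whether the give-up distance reaches ``dmax``.
    """
    F = p.success().F(k)
    d_hat, d_o = p.dmax / 2.0, p.dmax
    for _ in range(max_iter):
        lam_s = d_hat + (d_o - d_hat) * (1.0 - F)
        qc = _qc(lam_s, p)
        raw_hat = ((p.m + (1.0 - p.qg) * p.Pg) * k / (p.Ct * F)
                   + (p.Rs - p.Rg - p.m - (1.0 - p.qs) * p.Ps - qc) / p.Ct)
        raw_o = (p.Rs - (1.0 - p.qs) * p.Ps - qc) / p.Ct
        d_o_new = min(max(raw_o, 0.0), p.dmax)
        d_hat_new = min(max(raw_hat, 0.0), d_o_new)
        nxt_hat = d_hat + relax * (d_hat_new - d_hat)
        nxt_o = d_o + relax * (d_o_new - d_o)
        if abs(nxt_hat - d_hat) < tol and abs(nxt_o - d_o) < tol:
            d_hat, d_o = nxt_hat, nxt_o
            break
        d_hat, d_o = nxt_hat, nxt_o
    lam_s = d_hat + (d_o - d_hat) * (1.0 - F)
    regime = "full" if d_o >= p.dmax - 1e-9 else "partial"
    return {"d_hat": d_hat, "d_o": d_o, "lam_s": lam_s, "regime": regime,
            "qc": _qc(lam_s, p)}


def iterate_post(k: float, p: ModelParams, relax: float = 0.5,
                 tol: float = 1e-12, max_iter: int = 100_000) -> dict:
    """Post-telemedicine outcome by damped iteration (scenario 1) or bisection.

    Scenario 1 iterates the cutoff; when the converged cutoff exceeds the tele
    cutoff, the tele-first mass is found by bisection on the sign of
    ``Us2 - (GP-first continuation target)``, which is monotone because extra
    tele demand raises congestion.
    """
    F = p.success().F(k)
    d_tilde = tele_cutoff(p)
    # scenario 1 trial: iterate d_hat under lam_s = dmax - (dmax - d_hat) F
    d_hat = p.dmax / 2.0
    for _ in range(max_iter):
        lam_s = p.dmax - (p.dmax - d_hat) * F
        qc = _qc(lam_s, p)
        raw = ((p.m + (1.0 - p.qg) * p.Pg) * k / (p.Ct * F)
               + (p.Rs - p.Rg - p.m - (1.0 - p.qs) * p.Ps - qc) / p.Ct)
        new = min(max(raw, 0.0), p.dmax)
        nxt = d_hat + relax * (new - d_hat)
        if abs(nxt - d_hat) < tol:
            d_hat = nxt
            break
        d_hat = nxt
    if d_hat <= d_tilde + 1e-9:
        lam_s = p.dmax - (p.dmax - d_hat) * F
        return {"scenario": 1, "d_hat": d_hat, "lam_tele": 0.0,
                "lam_s": lam_s, "qc": _qc(lam_s, p)}

    # scenario 2: bisection on lam_tele in [0, dmax - d_tilde]
    target = p.Rg - (k * (1.0 - p.qg) * p.Pg + p.m * (k - F)) / F

    def excess(lam_tele: float) -> float:
        lam_s = p.dmax - (p.dmax - d_tilde - lam_tele) * F
        us2 = p.Rt - (1.0 - p.qt) * p.Ps - _qc(lam_s, p)
        return us2 - target

    lo, hi = 0.0, p.dmax - d_tilde
    if excess(lo) <= 0.0:
        lam_tele = 0.0
    elif excess(hi) >= 0.0:
        lam_tele = hi
    else:
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if excess(mid) > 0.0:
                lo = mid
            else:
                hi = mid
        lam_tele = 0.5 * (lo + hi)
    lam_s = p.dmax - (p.dmax - d_tilde - lam_tele) * F
    return {"scenario": 2, "d_hat": d_tilde, "lam_tele": lam_tele,
            "lam_s": lam_s, "qc": _qc(lam_s, p)}


@dataclass
class AgentEquilibrium:
    """Empirical outcome of agent best-response dynamics."""

    mode: str
    regime: str | None      # pre mode: full | partial
    scenario: int | None    # post mode: 1 | 2
    d_hat: float            # mass of direct in-person visitors (contiguous from 0)
    d_o: float | None       # pre mode: empirical give-up boundary
    lam_tele: float | None  # post mode: empirical tele-first mass
    lam_s: float
    lam_g: float
    converged: bool
    sweeps: int


def agent_best_response(p: ModelParams, mode: str, k: float, N: int = 10_000,
                        max_rounds: int = 200) -> AgentEquilibrium:
    """Sequential best-response dynamics over ``N`` agents at fixed referral level.

    Agents sit at ``d_i = (i - 0.5) dmax / N``, each carrying mass ``dmax/N``
    and the population complexity distribution in expectation (cure fraction
    ``F(k)``).  One sweep updates every agent in turn against the current
    aggregate arrival rate, with the specialist's service rate re-set by the
    quality-cost FOC after every switch.  Sequential updating moves the
    aggregate one agent mass at a time, so the dynamics settle to within one
    agent of the continuum fixed point; convergence is declared when a sweep
    flips at most a few agents (the marginal, indifferent ones may dither).
    """
    if mode not in ("pre", "post"):
        raise ValueError(f"mode must be 'pre' or 'post', got {mode!r}")
    if N < 1000:
        raise ValueError(f"need at least 1000 agents for a stable estimate, got {N}")
    F = p.success().F(k)
    base = F * p.Rg - k * (1.0 - p.qg) * p.Pg - p.m * (k - F)
    mass = p.dmax / N
    d = (np.arange(N) + 0.5) * mass
    s_const = 2.0 * math.sqrt(p.alpha * p.beta)
    us_net0 = p.Rs - (1.0 - p.qs) * p.Ps          # in-person, before qc and travel
    ut_net0 = p.Rt - (1.0 - p.qt) * p.Ps          # telemedicine, before qc
    d_tilde = tele_cutoff(p) if mode == "post" else None

    # choice codes — pre: 0 direct-SP, 1 GP-then-comply, 2 GP-then-giveup
    #              post: 0 direct in person, 1 direct tele, 2 GP first
    if mode == "pre":
        # pre paths: direct-SP, GP-then-comply, GP-then-giveup
        contrib = (1.0, 1.0 - F, 0.0)
    else:
        # post paths: direct in person, direct tele, GP first (referred to best channel)
        contrib = (1.0, 1.0, 1.0 - F)
    choice = np.full(N, 2, dtype=np.int64)  # start everyone at the GP
    lam_s = float(np.sum([contrib[int(c)] for c in choice]) * mass)

    converged = False
    sweeps = 0
    for sweeps in range(1, max_rounds + 1):
        flips = 0
        for i in range(N):
            qc = s_const + p.alpha * lam_s
            if mode == "pre":
                us = us_net0 - qc - p.Ct * d[i]
                utils = (us, base + (1.0 - F) * us, base)
            else:
                us1 = us_net0 - qc - p.Ct * d[i]
                us2 = ut_net0 - qc
                utils = (us1, us2, base + (1.0 - F) * max(us1, us2))
            cur = int(choice[i])
            best = max(utils)
            # hysteresis: a marginal agent within a hair of the best stays put,
            # otherwise the indifferent agent at the cutoff dithers forever
            if utils[cur] >= best - 1e-12:
                new = cur
            else:
                new = int(utils.index(best))
            if new != cur:
                lam_s += (contrib[new] - contrib[cur]) * mass
                choice[i] = new
                flips += 1
        if flips <= 3:
            converged = True
            break

    lam_s = float(np.sum([contrib[int(c)] for c in choice]) * mass)
    if mode == "pre":
        direct = float(np.sum(choice == 0) * mass)
        comply = float(np.sum(choice == 1) * mass)
        d_o = direct + comply
        regime = "full" if d_o >= p.dmax - 2.5 * mass else "partial"
        return AgentEquilibrium(mode="pre", regime=regime, scenario=None,
                                d_hat=direct, d_o=d_o, lam_tele=None,
                                lam_s=lam_s, lam_g=p.dmax - direct,
                                converged=converged, sweeps=sweeps)
    direct_in = float(np.sum(choice == 0) * mass)
    lam_tele = float(np.sum(choice == 1) * mass)
    scenario = 2 if lam_tele > 2.5 * mass else 1
    return AgentEquilibrium(mode="post", regime=None, scenario=scenario,
                            d_hat=direct_in, d_o=None, lam_tele=lam_tele,
                            lam_s=lam_s, lam_g=float(np.sum(choice == 2) * mass),
                            converged=converged, sweeps=sweeps)
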