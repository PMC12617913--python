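"""Segment accounting, average quality cost, and total social welfare.

Welfare is counted in resources: treatment rewards minus production costs
(GP treatment ``Cg k`` per GP visitor, SP time cost ``Cs/mu`` per arrival),
travel, mistreatment, and the congestion/quality cost at the specialist.
Prices, reimbursements and the tele-reward are transfers between patients,
providers and the government and net out of welfare; an explicit audit
(:func:`transfer_audit`) recomputes welfare from realized patient utilities
plus provider profits plus government outlays and must agree to float
precision.

The average quality cost ``phi`` is the total quality cost — GP mistreatment
``lam_g m (k - F)`` plus SP quality cost ``lam_s QC`` — divided by the number
of cured patients ``lam_g F + lam_s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

from .params import ModelParams
from .post import PostEquilibrium
from .pre import PreEquilibrium

State = Union[PreEquilibrium, PostEquilibrium]


class AccountingError(RuntimeError):
    """Segment masses do not reproduce the solved state's aggregates."""


@dataclass(frozen=True)
class Segment:
    """One patient segment: a path label, its distance interval, and its mass.

    ``lo``/``hi`` bound the distance interval; for the scenario-2 tele region
    the direct-tele and GP-then-tele segments share an interval with split
    masses.  Per-patient expected reward, total travel cost, and the in-person
    vs telemedicine specialist arrivals the segment generates are precomputed.
    """

    label: str            # direct-in-person | gp-then-inperson | gp-then-tele
                          # | direct-tele | gp-then-giveup
    lo: float
    hi: float
    mass: float
    reward: float         # per-patient expected reward
    travel: float         # total travel cost of the segment
    gp_mass: float        # mass that visits a GP first
    sp_inperson: float    # in-person specialist arrivals generated
    sp_tele: float        # telemedicine specialist arrivals generated


def _travel_integral(ct: float, lo: float, hi: float) -> float:
    # uniform density 1 on [lo, hi]: total travel cost = Ct * (hi^2 - lo^2) / 2
    return ct * (hi * hi - lo * lo) / 2.0


def segment_table(state: State, p: ModelParams) -> list[Segment]:
    """Decompose the market into path segments consistent with the solved state."""
    F = p.success().F(state.k)
    segs: list[Segment] = []

    def add(label: str, lo: float, hi: float, mass: float) -> None:
        if mass < -1e-12:
            raise AccountingError(f"negative mass {mass} for segment {label}")
        mass = max(mass, 0.0)
        if label == "direct-in-person":
            segs.append(Segment(label, lo, hi, mass, p.Rs,
                                _travel_integral(p.Ct, lo, hi), 0.0, mass, 0.0))
        elif label == "gp-then-inperson":
            segs.append(Segment(label, lo, hi, mass, F * p.Rg + (1 - F) * p.Rs,
                                (1 - F) * _travel_integral(p.Ct, lo, hi),
                                mass, (1 - F) * mass, 0.0))
        elif label == "gp-then-tele":
            segs.append(Segment(label, lo, hi, mass, F * p.Rg + (1 - F) * p.Rt,
                                0.0, mass, 0.0, (1 - F) * mass))
        elif label == "direct-tele":
            segs.append(Segment(label, lo, hi, mass, p.Rt, 0.0, 0.0, 0.0, mass))
        elif label == "gp-then-giveup":
            segs.append(Segment(label, lo, hi, mass, F * p.Rg, 0.0, mass, 0.0, 0.0))
        else:  # pragma: no cover
            raise ValueError(label)

    if isinstance(state, PreEquilibrium):
        add("direct-in-person", 0.0, state.d_hat, state.d_hat)
        if state.regime == "full":
            add("gp-then-inperson", state.d_hat, p.dmax, p.dmax - state.d_hat)
        else:
            add("gp-then-inperson", state.d_hat, state.d_o, state.d_o - state.d_hat)
            add("gp-then-giveup", state.d_o, p.dmax, p.dmax - state.d_o)
    else:
        if state.scenario == 1:
            dt = min(state.d_tilde, p.dmax)   # tele segment empty when unattractive
            add("direct-in-person", 0.0, state.d_hat, state.d_hat)
            add("gp-then-inperson", state.d_hat, dt, dt - state.d_hat)
            add("gp-then-tele", dt, p.dmax, p.dmax - dt)
        else:
            add("direct-in-person", 0.0, state.d_tilde, state.d_tilde)
            add("direct-tele", state.d_tilde, p.dmax, state.lam_tele)
            add("gp-then-tele", state.d_tilde, p.dmax,
                p.dmax - state.d_tilde - state.lam_tele)

    total = sum(s.mass for s in segs)
    if abs(total - p.dmax) > 1e-9 * max(1.0, p.dmax):
        raise AccountingError(f"segment masses sum to {total}, expected dmax={p.dmax}")
    lam_s = sum(s.sp_inperson + s.sp_tele for s in segs)
    if abs(lam_s - state.lam_s) > 1e-9 * max(1.0, p.dmax):
        raise AccountingError(f"segment SP arrivals {lam_s} != state lam_s {state.lam_s}")
    return segs


def average_quality_cost(state: State, p: ModelParams) -> float:
    """Average quality cost per cured patient (phi)."""
    F = p.success().F(state.k)
    cured = state.lam_g * F + state.lam_s
    if cured <= 0.0:
        raise AccountingError("no cured patients: average quality cost undefined")
    total_qc = state.lam_g * p.m * (state.k - F) + state.lam_s * state.qc
    return total_qc / cured


@dataclass
class WelfareReport:
    phi: float
    tsw: float
    cured_mass: float
    components: dict = field(default_factory=dict)

    def as_record(self) -> dict:
        """Flat mapping for CSV export."""
        rec = {"phi": self.phi, "tsw": self.tsw, "cured_mass": self.cured_mass}
        rec.update({f"component_{k}": v for k, v in self.components.items()})
        return rec


def total_social_welfare(state: State, p: ModelParams) -> WelfareReport:
    """Total social welfare: rewards minus resource costs, with a component breakdown.

    Components: ``rewards`` (expected cure rewards over all segments),
    ``travel``, ``mistreatment`` (m(k-F) per GP visitor), ``gp_production``
    (Cg k per GP visitor), ``sp_production`` (Cs/mu per SP arrival) and
    ``quality`` (QC per SP arrival).  Transfers (prices, reimbursements,
    tele-reward) net out by construction.
    """
    segs = segment_table(state, p)
    F = p.success().F(state.k)
    rewards = sum(s.mass * s.reward for s in segs)
    travel = sum(s.travel for s in segs)
    gp_mass = sum(s.gp_mass for s in segs)
    lam_s = sum(s.sp_inperson + s.sp_tele for s in segs)
    mistreat = p.m * (state.k - F) * gp_mass
    gp_prod = p.Cg * state.k * gp_mass
    sp_prod = (p.Cs / state.mu) * lam_s
    quality = state.qc * lam_s
    tsw = rewards - travel - mistreat - gp_prod - sp_prod - quality
    cured = gp_mass * F + lam_s
    phi = average_quality_cost(state, p) if cured > 0 else float("nan")
    return WelfareReport(
        phi=phi, tsw=tsw, cured_mass=cured,
        components={"rewards": rewards, "travel": travel, "mistreatment": mistreat,
                    "gp_production": gp_prod, "sp_production": sp_prod,
                    "quality": quality})


def transfer_audit(state: State, p: ModelParams) -> tuple[float, float]:
    """Recompute TSW from utilities + profits + government outlays.

    Returns ``(tsw_components, tsw_transfer)``.  The transfer route sums
    realized patient-path utilities, GP profit, SP profit
    ``(Ps - Cs/mu) lam_s``, and the government's reimbursement and tele-reward
    outlays.  The GP's objective internalizes the mistreatment penalty that
    patients also bear, so one ``m(k-F)`` per GP visitor is added back: it is
    a single resource loss, not two.
    """
    segs = segment_table(state, p)
    F = p.success().F(state.k)
    k = state.k
    qc = state.qc
    base = (F * p.Rg - k * (1.0 - p.qg) * p.Pg - p.m * (k - F))
    us_net = p.Rs - (1.0 - p.qs) * p.Ps - qc      # in-person SP utility before travel
    ut_net = p.Rt - (1.0 - p.qt) * p.Ps - qc      # telemedicine utility

    utilities = 0.0
    for s in segs:
        if s.label == "direct-in-person":
            utilities += s.mass * us_net - s.travel
        elif s.label == "gp-then-inperson":
            utilities += s.mass * base + (1.0 - F) * s.mass * us_net - s.travel
        elif s.label == "gp-then-tele":
            utilities += s.mass * (base + (1.0 - F) * ut_net)
        elif s.label == "direct-tele":
            utilities += s.mass * ut_net
        elif s.label == "gp-then-giveup":
            utilities += s.mass * base

    gp_mass = sum(s.gp_mass for s in segs)
    sp_inperson = sum(s.sp_inperson for s in segs)
    sp_tele = sum(s.sp_tele for s in segs)
    lam_s = sp_inperson + sp_tele

    pi_g = state.pi_g
    pi_s = (p.Ps - p.Cs / state.mu) * lam_s
    gamma_outlay = p.gamma * sp_tele if isinstance(state, PostEquilibrium) else 0.0
    government = -(p.qg * p.Pg * k * gp_mass + p.qs * p.Ps * sp_inperson
                   + p.qt * p.Ps * sp_tele + gamma_outlay)
    correction = p.m * (k - F) * gp_mass

    tsw_transfer = utilities + pi_g + pi_s + government + correction
    tsw_components = total_social_welfare(state, p).tsw
    return tsw_components, tsw_transfer
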