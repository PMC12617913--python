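"""Exogenous model parameters and the treatment-success function family.

The model describes a two-tier (gatekeeper) healthcare market: a continuum of
patients of total mass ``dmax``, uniformly distributed at distance
``d ∈ [0, dmax]`` from a single specialist provider (SP), choose between
visiting a general practitioner (GP) first or going to the SP directly
(in person or, once available, via telemedicine).  Patient case complexity
``x ∈ [0, 1]`` is handled in expectation through a success function ``f``:
the probability that a GP cures a patient of complexity ``x``.  The GP treats
every patient with complexity at or below the referral level ``k`` and refers
the rest, so the cured fraction among GP visitors is ``F(k) = ∫₀ᵏ f(x) dx``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Callable, Mapping

from pydantic import BaseModel, ConfigDict, ValidationError, model_validator


class ParamValidationError(ValueError):
    """A parameter set violates one of the model's ordering or sign constraints."""


@dataclass(frozen=True)
class SuccessFunction:
    """The pair (f, F): per-complexity cure probability and its running integral.

    ``f`` must be strictly decreasing on [0, 1] with values in [0, 1];
    ``F(k) = ∫₀ᵏ f(x) dx`` is then increasing, concave, and satisfies
    ``F(k) ≤ k`` (the cured fraction can never exceed the treated fraction).
    """

    f: Callable[[float], float]
    F: Callable[[float], float]
    family: str = "linear"
    p: float = 1.0

    def __call__(self, k: float) -> tuple[float, float]:
        return success_eval(self, k)


def _power_family(p: float) -> SuccessFunction:
    # f(x) = (1-x)^p  =>  F(k) = (1 - (1-k)^(p+1)) / (p+1); p=1 is the linear default.
    if p <= 0:
        raise ParamValidationError(f"success-function exponent p must be > 0, got {p}")

    def f(x: float) -> float:
        return (1.0 - x) ** p

    def F(k: float) -> float:
        return (1.0 - (1.0 - k) ** (p + 1.0)) / (p + 1.0)

    family = "linear" if p == 1.0 else "power"
    return SuccessFunction(f=f, F=F, family=family, p=p)


def make_success_function(form: Mapping[str, Any] | None = None) -> SuccessFunction:
    """Build a success function from a ``{"family": ..., "p": ...}`` mapping.

    Supported families: ``linear`` (f(x) = 1 - x) and ``power``
    (f(x) = (1 - x)^p, p > 0).
    """
    if form is None:
        return _power_family(1.0)
    family = form.get("family", "linear")
    if family == "linear":
        return _power_family(1.0)
    if family == "power":
        return _power_family(float(form.get("p", 1.0)))
    raise ParamValidationError(f"unknown success-function family: {family!r}")


def success_eval(sf: SuccessFunction, k: float) -> tuple[float, float]:
    """Evaluate (f(k), F(k)) at referral level ``k`` ∈ [0, 1]."""
    if not 0.0 <= k <= 1.0:
        raise ParamValidationError(f"referral level k must lie in [0, 1], got {k}")
    return float(sf.f(k)), float(sf.F(k))


class ModelParams(BaseModel):
    """All exogenous scalars of the referral-market model.

    Rewards ``Rs > Rt > Rg`` order the cure reward at the SP in person, the SP
    via telemedicine, and the GP.  Reimbursement rates ``qg > qt > qs`` (all in
    [0, 1]) encode the policy tilt toward gatekeeping and telemedicine.
    ``Pg < Ps`` are service prices; ``Cg`` the GP's unit treatment cost, ``Cs``
    the SP's cost per unit time, ``m`` the patient-borne mistreatment cost of a
    failed GP attempt, ``alpha``/``beta`` the inadequate-care and delay cost
    coefficients in the SP quality cost, ``Ct`` the travel cost per unit
    distance, ``gamma`` the GP tele-reward per assisted encounter, and ``dmax``
    the SP's service range (equal to total patient mass).
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    Rg: float
    Rs: float
    Rt: float
    Pg: float
    Ps: float
    qg: float
    qs: float
    qt: float
    Cg: float
    Cs: float
    m: float
    alpha: float
    beta: float
    Ct: float
    gamma: float
    dmax: float
    success_form: dict = {"family": "linear", "p": 1.0}

    @model_validator(mode="after")
    def _check_orderings(self) -> "ModelParams":
        if not (self.Rs > self.Rt > self.Rg):
            raise ParamValidationError(
                f"rewards must satisfy Rs > Rt > Rg, got Rs={self.Rs}, Rt={self.Rt}, Rg={self.Rg}"
            )
        if not (self.qg > self.qt > self.qs):
            raise ParamValidationError(
                f"reimbursement rates must satisfy qg > qt > qs, got qg={self.qg}, qt={self.qt}, qs={self.qs}"
            )
        for name in ("qg", "qs", "qt"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParamValidationError(f"{name} must lie in [0, 1], got {v}")
        if not self.Pg < self.Ps:
            raise ParamValidationError(
                f"prices must satisfy Pg < Ps, got Pg={self.Pg}, Ps={self.Ps}"
            )
        for name in ("Pg", "Ps", "Cg", "Cs", "m", "alpha", "beta", "Ct", "gamma", "dmax"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0.0):
                raise ParamValidationError(f"{name} must be strictly positive, got {v}")
        make_success_function(self.success_form)  # validates the family spec
        return self

    def success(self) -> SuccessFunction:
        """The success function (f, F) configured by ``success_form``."""
        return make_success_function(self.success_form)

    def replace(self, **overrides: Any) -> "ModelParams":
        """A copy with some fields overridden (re-validated)."""
        return ModelParams(**{**self.model_dump(), **overrides})


def validate_params(raw: Mapping[str, Any]) -> ModelParams:
    """Validate a flat parameter mapping into a :class:`ModelParams`.

    Raises :class:`ParamValidationError` naming the violated constraint (or
    pydantic's ValidationError for missing/non-numeric fields); never silently
    reorders or coerces an inconsistent set.
    """
    try:
        return ModelParams(**dict(raw))
    except ValidationError as exc:
        for err in exc.errors():
            cause = err.get("ctx", {}).get("error")
            if isinstance(cause, ParamValidationError):
                raise ParamValidationError(str(cause)) from exc
        raise
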