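"""Shared fixtures: worked-example parameter sets and random draws from the study box."""

from __future__ import annotations

import numpy as np
import pytest

from telerefer import ModelParams
from telerefer.experiments import PARAM_RANGES

#: the worked-example parameter set (lower end of every documented range)
EXAMPLE = dict(Rg=10.0, Rs=20.0, Rt=15.0, Pg=10.0, Ps=15.0,
               qg=0.9, qs=0.8, qt=0.85, Cg=4.0, Cs=6.0, m=10.0,
               alpha=2.0, beta=2.0, Ct=6.0, gamma=2.0)


@pytest.fixture
def ex_params() -> ModelParams:
    """Worked-example parameters on a small (full-coverage) market."""
    return ModelParams(dmax=1.0, **EXAMPLE)


@pytest.fixture
def ex_params3() -> ModelParams:
    """Worked-example parameters on a large (partial-coverage) market."""
    return ModelParams(dmax=3.0, **EXAMPLE)


def draw_params(rng: np.random.Generator, dmax: float) -> ModelParams:
    """One uniform draw from the documented parameter box (rewards/rates fixed)."""
    draw = {name: float(rng.uniform(lo, hi)) for name, (lo, hi) in PARAM_RANGES.items()}
    return ModelParams(Rg=10.0, Rs=20.0, Rt=15.0, qg=0.9, qs=0.8, qt=0.85,
                       dmax=dmax, **draw)
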