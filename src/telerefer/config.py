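"""Run configuration: YAML/JSON loading, defaults, and result serialization."""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from .experiments import (MIDPOINT_BASELINE, PARTIAL_DMAX, compare_pre_post,
                          records_to_frame, sensitivity_suite, sweep)
from .params import ModelParams, validate_params
from .post import solve_post_equilibrium
from .pre import solve_pre_equilibrium
from .welfare import total_social_welfare

log = logging.getLogger(__name__)


class RunBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    mode: Literal["solve", "compare", "sweep", "sensitivity", "validate"] = "compare"
    sweep_param: str | None = None
    grid: str | None = None          # "start:stop:count"
    coverage: Literal["auto", "full", "partial"] = "auto"
    out_dir: str = "results"
    seed: int = 0                    # used only by randomized oracle utilities
    verbosity: str = "INFO"

    @field_validator("grid")
    @classmethod
    def _check_grid(cls, v: str | None) -> str | None:
        if v is not None:
            parse_grid(v)
        return v


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    params: dict = {}
    run: RunBlock = RunBlock()

    def model_params(self) -> ModelParams:
        """Validated parameters: documented baseline midpoints plus overrides."""
        merged = {**MIDPOINT_BASELINE, "dmax": PARTIAL_DMAX, **self.params}
        return validate_params(merged)


def parse_grid(spec: str) -> np.ndarray:
    """Parse a ``start:stop:count`` grid spec into a linspace."""
    parts = spec.split(":")
    if len(parts) != 3:
        raise ValueError(
            f"run.grid: expected 'start:stop:count' with three fields, got {spec!r}")
    try:
        start, stop, count = float(parts[0]), float(parts[1]), int(parts[2])
    except ValueError as exc:
        raise ValueError(f"run.grid: non-numeric field in {spec!r}: {exc}") from exc
    if count < 1:
        raise ValueError(f"run.grid: count must be >= 1, got {count}")
    return np.linspace(start, stop, count)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    return RunConfig(**data)


def state_to_dict(state) -> dict:
    """Flat, JSON-serializable mapping of an equilibrium state."""
    d = dataclasses.asdict(state)
    d["diagnostics"] = {k: (bool(v) if isinstance(v, (bool, np.bool_)) else float(v)
                            if isinstance(v, (int, float, np.floating)) else v)
                        for k, v in d.get("diagnostics", {}).items()}
    return d


def run(config: RunConfig) -> int:
    """Execute one configured run; writes CSV/JSON artifacts, returns exit status."""
    logging.basicConfig(level=getattr(logging, config.run.verbosity.upper(), logging.INFO))
    out = Path(config.run.out_dir)
    mode = config.run.mode
    try:
        p = config.model_params()
    except Exception as exc:
        log.error("parameter validation failed: %s", exc)
        return 2
    if mode == "validate":
        print("parameters valid:", json.dumps(p.model_dump(), indent=2, sort_keys=True))
        return 0

    out.mkdir(parents=True, exist_ok=True)
    try:
        if mode == "solve":
            pre = solve_pre_equilibrium(p, coverage=config.run.coverage)
            post = solve_post_equilibrium(p)
            summary = {
                "params": p.model_dump(),
                "pre": state_to_dict(pre),
                "post": state_to_dict(post),
                "welfare_pre": total_social_welfare(pre, p).as_record(),
                "welfare_post": total_social_welfare(post, p).as_record(),
            }
            (out / "solution.json").write_text(json.dumps(summary, indent=2))
            print(f"wrote {out / 'solution.json'} "
                  f"(regime={pre.regime}, scenario={post.scenario})")
        elif mode == "compare":
            rec = compare_pre_post(p)
            frame = records_to_frame([rec])
            frame.to_csv(out / "compare.csv", index=False, float_format="%.12g")
            (out / "compare.json").write_text(json.dumps(rec.as_record(), indent=2))
            print(frame.to_string(index=False))
        elif mode == "sweep":
            if not config.run.sweep_param or not config.run.grid:
                log.error("mode=sweep requires run.sweep_param and run.grid")
                return 2
            records = sweep(p, config.run.sweep_param, parse_grid(config.run.grid))
            frame = records_to_frame(records)
            frame.to_csv(out / "sweep.csv", index=False, float_format="%.12g")
            print(f"wrote {out / 'sweep.csv'} ({len(frame)} rows)")
        elif mode == "sensitivity":
            from .experiments import PARAM_RANGES
            grids = {name: np.linspace(*PARAM_RANGES[name], 5)
                     for name in ("m", "beta", "Cs", "alpha")}
            report = sensitivity_suite(p, grids)
            (out / "sensitivity.json").write_text(json.dumps(report, indent=2))
            uniform = {k: v["uniform"] for k, v in report.items()}
            print("sign patterns uniform:", uniform)
    except Exception as exc:  # noqa: BLE001 — CLI boundary
        log.error("run failed: %s", exc)
        return 1
    return 0
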