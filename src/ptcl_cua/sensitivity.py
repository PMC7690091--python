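"""One-way deterministic sensitivity analysis and tornado ordering.

Each scenario perturbs one model input (or one coherent group of inputs)
to a low and a high value, reruns the entire pipeline with everything else
at base case, and records the resulting ICER per QALY. Scenarios follow
the published analysis: extrapolation-family swaps per arm, 95% CI bounds
on the four response-state utilities (CI half-widths are configuration —
the source CIs are not public — defaulting to ±10% of the point
estimates), transplant success rate ±10%, a 20% comparator-chemotherapy
dose reduction with proportional cost change, and 10- vs 30-year horizons.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .pipeline import BaseCase
from .synthetic_data import ModelParameters

__all__ = ["Scenario", "build_scenarios", "run_one_way", "tornado_order"]


@dataclass
class Scenario:
    """One perturbation: named parameter paths with low/high values.

    ``kind`` selects the mechanics: ``param`` rewrites dotted paths into a
    parameter copy; ``horizon`` swaps the simulation horizon (years);
    ``distribution`` re-runs with each alternative converged survival
    family per arm and reports the extreme ICERs across those swaps."""

    name: str
    kind: str = "param"
    paths: tuple = ()
    low: tuple = ()
    high: tuple = ()
    scope: str = ""

    def __post_init__(self):
        if self.kind == "param" and not (
            len(self.paths) == len(self.low) == len(self.high)
        ):
            raise ValueError(f"scenario {self.name}: paths/low/high length mismatch")


def _set_path(params: ModelParameters, path: str, value: float) -> None:
    parts = path.split(".")
    obj = params
    for part in parts[:-1]:
        obj = obj[part] if isinstance(obj, dict) else getattr(obj, part)
    if isinstance(obj, dict):
        if parts[-1] not in obj:
            raise KeyError(f"unknown parameter path {path!r}")
        obj[parts[-1]] = value
    else:
        if not hasattr(obj, parts[-1]):
            raise AttributeError(f"unknown parameter path {path!r}")
        setattr(obj, parts[-1], value)


def _get_path(params: ModelParameters, path: str) -> float:
    parts = path.split(".")
    obj = params
    for part in parts:
        obj = obj[part] if isinstance(obj, dict) else getattr(obj, part)
    return obj


def build_scenarios(
    params: ModelParameters,
    utility_ci: Optional[dict] = None,
    sct_success_rel: float = 0.10,
    dose_reduction: float = 0.20,
    horizons: tuple = (10.0, 30.0),
) -> list:
    """The base-case scenario battery.

    ``utility_ci`` maps response state to (low, high); absent entries fall
    back to ±10% of the point estimate (capped at utility 1.0)."""
    utility_ci = utility_ci or {}
    scenarios = [Scenario(name="os_distribution", kind="distribution", scope="both arms")]
    for resp in ("CR", "PR", "SD", "PD"):
        base = params.utilities[resp]
        lo, hi = utility_ci.get(resp, (0.9 * base, min(1.1 * base, 1.0)))
        scenarios.append(
            Scenario(
                name=f"utility_{resp}",
                paths=(f"utilities.{resp}",),
                low=(lo,),
                high=(hi,),
                scope="both arms",
            )
        )
    s = params.sct_success
    scenarios.append(
        Scenario(
            name="sct_success_rate",
            paths=("sct_success",),
            low=(s * (1.0 - sct_success_rel),),
            high=(s * (1.0 + sct_success_rel),),
            scope="both arms",
        )
    )
    cc_init = params.medication_weekly["cc_initial"]
    cc_sub = params.medication_weekly["cc_subsequent"]
    scenarios.append(
        Scenario(
            name="comparator_dose",
            paths=("medication_weekly.cc_initial", "medication_weekly.cc_subsequent"),
            low=((1.0 - dose_reduction) * cc_init, (1.0 - dose_reduction) * cc_sub),
            high=(cc_init, cc_sub),
            scope="chemotherapy medication, both arms' CC phases",
        )
    )
    scenarios.append(
        Scenario(
            name="time_horizon",
            kind="horizon",
            low=(min(horizons),),
            high=(max(horizons),),
            scope="both arms",
        )
    )
    return scenarios


def _icer(base: BaseCase, params=None, fits=None) -> float:
    _, _, inc = base.run(params=params, fits=fits)
    return np.nan if inc.icer_per_qaly is None else float(inc.icer_per_qaly)


def run_one_way(scenarios, base: BaseCase) -> pd.DataFrame:
    """Rerun the pipeline at every scenario bound.

    Returns a DataFrame with scenario name, low/high ICER per QALY and a
    JSON provenance column recording the exact perturbed values. A failing
    scenario is recorded with NaNs and its error message; it does not
    abort the batch. The stored base configuration is never mutated."""
    rows = []
    for sc in scenarios:
        detail: dict = {"kind": sc.kind, "scope": sc.scope}
        try:
            if sc.kind == "param":
                vals = {}
                icers = []
                for bound, values in (("low", sc.low), ("high", sc.high)):
                    p = base.params.copy()
                    for path, v in zip(sc.paths, values):
                        _set_path(p, path, v)
                    vals[bound] = dict(zip(sc.paths, values))
                    icers.append(_icer(base, params=p))
                detail["values"] = vals
                lo, hi = icers
            elif sc.kind == "horizon":
                icers = []
                for years in (sc.low[0], sc.high[0]):
                    p = base.params.copy()
                    p.horizon_years = float(years)
                    icers.append(_icer(base, params=p))
                detail["values"] = {"low": sc.low[0], "high": sc.high[0]}
                lo, hi = icers
            elif sc.kind == "distribution":
                # full cartesian grid over every converged family per arm
                ev = base.evidence or {}
                cand = {
                    arm: (
                        {f.family: f for f in ev[arm].fits if f.converged}
                        if arm in ev
                        else {base.fits[arm].family: base.fits[arm]}
                    )
                    for arm in ("pralatrexate", "cc")
                }
                grid = {}
                for fam_p, fit_p in cand["pralatrexate"].items():
                    for fam_c, fit_c in cand["cc"].items():
                        grid[f"{fam_p}|{fam_c}"] = _icer(
                            base, fits={"pralatrexate": fit_p, "cc": fit_c}
                        )
                finite = {k: v for k, v in grid.items() if np.isfinite(v)}
                if not finite:
                    raise RuntimeError("no finite ICER in the distribution grid")
                lo = min(finite.values())
                hi = max(finite.values())
                detail["values"] = finite
            else:
                raise ValueError(f"unknown scenario kind {sc.kind!r}")
            rows.append((sc.name, lo, hi, json.dumps(detail)))
        except Exception as exc:  # per-scenario failure, batch continues
            detail["error"] = str(exc)
            rows.append((sc.name, np.nan, np.nan, json.dumps(detail)))
    return pd.DataFrame(rows, columns=["scenario", "icer_low", "icer_high", "detail"])


def tornado_order(table: pd.DataFrame) -> pd.DataFrame:
    """Sort scenarios by ICER range (|high - low|) descending.

    Equal ranges keep their input order (stable sort). The returned frame
    adds the range column and is ready for CSV/JSON export."""
    if table.empty:
        raise ValueError("empty sensitivity table")
    out = table.copy()
    out["range"] = (out["icer_high"] - out["icer_low"]).abs()
    out = out.sort_values("range", ascending=False, kind="stable").reset_index(drop=True)
    return out


def tornado_json(table: pd.DataFrame) -> list:
    """Plot-ready payload: one record per bar, widest first."""
    ordered = tornado_order(table)
    return [
        {
            "scenario": r.scenario,
            "icer_low": None if pd.isna(r.icer_low) else r.icer_low,
            "icer_high": None if pd.isna(r.icer_high) else r.icer_high,
            "range": None if pd.isna(r.range) else r.range,
        }
        for r in ordered.itertuples()
    ]
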