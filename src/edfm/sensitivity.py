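"""One-at-a-time sensitivity analysis with the normalized sensitivity
coefficient S = (dOutput/Output_base) / (dParameter/Parameter_base).

Each parameter is perturbed relative to its baseline (default +/-20 %)
while all seeds stay fixed, the season is re-run, and both one-sided
coefficients plus their mean are reported. Since S is
direction-dependent for nonlinear responses, the mean of the two
one-sided coefficients is the headline number; the table is sorted by
its magnitude.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import SimulationConfig, run_season
from .errors import InvalidArgumentError
from .synthdata import EnvironmentDay

__all__ = [
    "PARAMETER_PATHS",
    "SensitivitySpec",
    "normalized_sensitivity",
    "run_oat",
    "season_metric",
]

# dotted attribute paths into SimulationConfig for the named parameters
PARAMETER_PATHS = {
    "psi_root": "water.psi_root",
    "gamma": "water.gamma",
    "k": "plant.leaf_k",
    "t_base": "phenology.t_base",
    "lue": "lue.lue",
    "beta": "lue.beta",
    "sla": "sla_cm2_per_g",
}


def normalized_sensitivity(
    out_base: float, out_pert: float, p_base: float, p_pert: float
) -> float:
    """S = ((out_pert - out_base)/out_base) / ((p_pert - p_base)/p_base)."""
    if out_base == 0:
        raise InvalidArgumentError("undefined sensitivity: baseline output is zero")
    if p_base == 0 or p_pert == p_base:
        raise InvalidArgumentError("parameter baseline must be nonzero and perturbed")
    return ((out_pert - out_base) / out_base) / ((p_pert - p_base) / p_base)


def _resolve(config: SimulationConfig, name: str) -> tuple[object, str]:
    path = PARAMETER_PATHS.get(name, name)
    obj = config
    parts = path.split(".")
    for part in parts[:-1]:
        obj = getattr(obj, part)
    if not hasattr(obj, parts[-1]):
        raise InvalidArgumentError(f"unknown parameter {name!r}")
    return obj, parts[-1]


def _with_value(config: SimulationConfig, name: str, value: float) -> SimulationConfig:
    cfg = copy.deepcopy(config)
    obj, attr = _resolve(cfg, name)
    setattr(obj, attr, value)
    # re-validate the touched parameter group
    post = getattr(obj, "__post_init__", None)
    if post is not None:
        post()
    return cfg


def season_metric(
    config: SimulationConfig, weather: list[EnvironmentDay], metric: str
) -> float:
    """Run the engine and read the output metric at the silking stage.

    Silking is operationalized as the first day PDT crosses
    ``config.silking_pdt`` (the season's last day if it never does).
    """
    result = run_season(config, weather)
    tr = result.traits
    crossed = tr.index[tr["pdt"] >= config.silking_pdt]
    row = tr.loc[crossed[0]] if len(crossed) else tr.iloc[-1]
    if metric == "lai_at_silking":
        return float(row["lai"])
    if metric == "height_at_silking":
        return float(row["height_cm"])
    raise InvalidArgumentError(f"unknown metric {metric!r}")


@dataclass
class SensitivitySpec:
    """One-at-a-time analysis specification."""

    parameters: list[str]
    config: SimulationConfig
    weather: list[EnvironmentDay]
    relative_perturbation: float = 0.20
    metric: str = "lai_at_silking"
    extra_baselines: dict[str, float] = field(default_factory=dict)


def run_oat(spec: SensitivitySpec) -> pd.DataFrame:
    """Run the baseline and all perturbed seasons; tabulate S per parameter.

    Every run shares the baseline's seeds, so differences are purely
    parametric. Columns: baseline value, outputs, S_plus, S_minus,
    S_mean; rows sorted by |S_mean| descending.
    """
    out_base = season_metric(spec.config, spec.weather, spec.metric)
    if out_base == 0:
        raise InvalidArgumentError("baseline scenario produced zero output metric")
    rows = []
    for name in spec.parameters:
        obj, attr = _resolve(spec.config, name)
        p_base = float(getattr(obj, attr))
        if p_base == 0:
            raise InvalidArgumentError(
                f"parameter {name!r} has zero baseline; relative perturbation undefined"
            )
        outs = {}
        for sign in (+1, -1):
            p_pert = p_base * (1 + sign * spec.relative_perturbation)
            cfg = _with_value(spec.config, name, p_pert)
            outs[sign] = season_metric(cfg, spec.weather, spec.metric)
        s_plus = normalized_sensitivity(
            out_base, outs[+1], p_base, p_base * (1 + spec.relative_perturbation)
        )
        s_minus = normalized_sensitivity(
            out_base, outs[-1], p_base, p_base * (1 - spec.relative_perturbation)
        )
        rows.append(
            {
                "parameter": name,
                "baseline": p_base,
                "output_baseline": out_base,
                "output_plus": outs[+1],
                "output_minus": outs[-1],
                "S_plus": s_plus,
                "S_minus": s_minus,
                "S_mean": 0.5 * (s_plus + s_minus),
            }
        )
    table = pd.DataFrame(rows)
    return table.reindex(
        table["S_mean"].abs().sort_values(ascending=False).index
    ).reset_index(drop=True)
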