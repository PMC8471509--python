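"""One-at-a-time (OAT) sensitivity sweeps.

The two inputs that are hardest to pin down in a real workplace are the
LEV efficacy (entering the emission rate as the retained fraction
``LC_LEV``) and the inter-zonal NF<->FF air flow ``beta``.  An OAT sweep
re-solves the model for each value of one parameter while everything
else stays at its base value, yielding a tidy table of concentrations
(and, when measurements are supplied, modelled/measured ratios).

A ``beta`` sweep updates ``beta_i = beta + q_lev_nf`` consistently: the
LEV-induced FF->NF draw is a property of the exhaust, not of the room
air movement being varied.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from .boxmodels import Scenario, one_box_steady_state, two_box_steady_state
from .dustiness import EmissionSpec, retained_from_reduction_pct

__all__ = ["OatGrid", "run_oat", "default_grids", "LEV_PARAM", "BETA_PARAM"]

LEV_PARAM = "lc_lev_reduction_pct"
BETA_PARAM = "beta_m3_min"


@dataclass(frozen=True)
class OatGrid:
    """Ordered sweep values for one parameter.

    ``parameter`` is ``"lc_lev_reduction_pct"`` (percent reduction, in
    [0, 100]) or ``"beta_m3_min"`` (m^3 min^-1, positive).  ``base`` marks
    the value used when the parameter is *not* being swept; ``most_likely``
    is informational.
    """

    parameter: str
    values: tuple[float, ...]
    base: float | None = None
    most_likely: float | None = None

    def __post_init__(self) -> None:
        if self.parameter not in (LEV_PARAM, BETA_PARAM):
            raise ValueError(f"unknown OAT parameter {self.parameter!r}")
        vals = tuple(float(v) for v in self.values)
        if not vals:
            raise ValueError("grid must contain at least one value")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("grid values must be strictly increasing")
        object.__setattr__(self, "values", vals)

    def is_valid_value(self, value: float) -> bool:
        if self.parameter == LEV_PARAM:
            return 0.0 <= value <= 100.0
        return value > 0.0


def default_grids() -> tuple[OatGrid, OatGrid]:
    """The conventional sweep ranges for LEV efficacy and beta.

    LEV reductions of 50/70/80/90% span the efficacies reported for fixed
    capturing hoods, with 70% as the base setting; beta values
    0.25-10 m^3 min^-1 span literature inter-zonal flows, with
    5 m^3 min^-1 the most likely value.
    """
    lev = OatGrid(LEV_PARAM, (50.0, 70.0, 80.0, 90.0), base=70.0)
    beta = OatGrid(
        BETA_PARAM, (0.25, 0.5, 1.0, 2.5, 5.0, 10.0), base=5.0, most_likely=5.0
    )
    return lev, beta


def _solve(model: str, spec: EmissionSpec, scenario: Scenario):
    """(compartment, concentration) steady-state pairs for one model."""
    s = spec.base_rate
    if model == "one_box":
        return [("room", one_box_steady_state(s, scenario).c_room)]
    if model == "two_box":
        ss = two_box_steady_state(s, scenario)
        return [("nf", ss.c_nf), ("ff", ss.c_ff)]
    raise ValueError(f"unknown model {model!r}")


def run_oat(
    grid: OatGrid,
    spec: EmissionSpec,
    scenario: Scenario,
    models: Sequence[str] = ("one_box", "two_box"),
    measured: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Steady-state concentrations across one OAT grid.

    Returns a long table with one row per (grid value, model,
    compartment): columns ``parameter, value, model, compartment,
    concentration_mg_m3, ratio, error``.  ``measured`` maps compartment
    names (``room``/``nf``/``ff``) to measured concentrations; when given,
    the modelled/measured ratio is filled in.  An invalid grid value
    yields a row with the ``error`` column set and the sweep continues.

    Every row's metadata reflects exactly one changed parameter: the
    scenario (and emission spec) are otherwise reused as passed in.
    """
    rows = []
    for value in grid.values:
        if not grid.is_valid_value(value):
            rows.append(
                {
                    "parameter": grid.parameter,
                    "value": value,
                    "model": None,
                    "compartment": None,
                    "concentration_mg_m3": None,
                    "ratio": None,
                    "error": f"invalid value {value} for {grid.parameter}",
                }
            )
            continue
        if grid.parameter == LEV_PARAM:
            spec_v, scen_v = spec.with_lev_reduction_pct(value), scenario
        else:
            spec_v, scen_v = spec, replace(scenario, beta=value)
        for model in models:
            for compartment, conc in _solve(model, spec_v, scen_v):
                meas = (measured or {}).get(compartment)
                rows.append(
                    {
                        "parameter": grid.parameter,
                        "value": value,
                        "model": model,
                        "compartment": compartment,
                        "concentration_mg_m3": conc,
                        "ratio": None if not meas else conc / meas,
                        "error": None,
                    }
                )
    return pd.DataFrame(rows)
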