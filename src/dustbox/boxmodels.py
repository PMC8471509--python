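"""One- and two-box well-mixed mass-balance models.

Both models treat airborne dust as instantaneously mixed within each
compartment, with removal only by ventilation (no deposition or
coagulation).  Concentrations are in mg m^-3, flows in m^3 min^-1,
volumes in m^3 and time in minutes.

One-box (whole room, volume V, total ventilation Q = Q_GV + Q_LEV):

    V dC/dt = S + Q*C0 - Q*C

Two-box (near field NF of volume V_NF around the source, far field FF
with V_FF = V - V_NF, inter-zonal flow beta, and beta_i = beta + Q_LEV,NF
where Q_LEV,NF is the extra FF->NF draw created by the local exhaust):

    V_NF dC_NF/dt = S + beta_i*C_FF - beta_i*C_NF
    V_FF dC_FF/dt = (Q_GV + Q_LEV)*C0 + beta*C_NF - beta_i*C_FF - Q_GV*C_FF

The equations are implemented literally: the NF loses ``beta_i*C_NF`` while
the FF regains only ``beta*C_NF`` (the difference is removed by the LEV),
so the room-level air balance is open whenever the room exhaust flow Q_LEV
differs from Q_LEV,NF.  :func:`air_balance_report` surfaces, but does not
alter, that imbalance.

Transients are solved exactly on each constant-source segment: scalar
exponential relaxation for the one box, eigen-decomposition of the 2x2
system matrix (matrix-exponential fallback for near-repeated eigenvalues)
for the two boxes.  A numerical integrator is available as an independent
cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .dustiness import EmissionSpec, emission_rate

__all__ = [
    "Scenario",
    "ConcentrationSeries",
    "SteadyState",
    "ach_from_flows",
    "flows_from_ach",
    "one_box_steady_state",
    "two_box_steady_state",
    "solve_one_box",
    "solve_two_box",
    "time_weighted_average",
    "air_balance_report",
    "read_scenario_yaml",
    "write_scenario_yaml",
]


@dataclass(frozen=True)
class Scenario:
    """Room geometry, ventilation flows and background for a modelled task.

    Attributes
    ----------
    v : float
        Total room volume, m^3.
    v_nf : float
        Near-field volume, m^3 (two-box model only); the far field gets
        the remainder ``v - v_nf``.
    q_gv : float
        General (natural) ventilation flow, m^3 min^-1.
    q_lev : float
        Room exhaust flow of the local exhaust ventilation, m^3 min^-1.
    q_lev_nf : float
        FF->NF flow attributed to the LEV, m^3 min^-1; enters the model
        only through ``beta_i = beta + q_lev_nf``.
    beta : float
        Inter-zonal NF<->FF air flow, m^3 min^-1.
    c0 : float
        Incoming / background concentration, mg m^-3.
    """

    name: str
    v: float
    q_gv: float
    q_lev: float
    v_nf: float = 8.0
    q_lev_nf: float = 0.0
    beta: float = 5.0
    c0: float = 0.0

    def __post_init__(self) -> None:
        if self.v <= 0 or self.v_nf <= 0:
            raise ValueError("volumes must be positive")
        if self.v_nf >= self.v:
            raise ValueError("near-field volume must be smaller than the room volume")
        for name in ("q_gv", "q_lev", "q_lev_nf", "beta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.c0 < 0:
            raise ValueError("background concentration must be non-negative")

    @property
    def v_ff(self) -> float:
        return self.v - self.v_nf

    @property
    def q_total(self) -> float:
        return self.q_gv + self.q_lev

    @property
    def beta_i(self) -> float:
        return self.beta + self.q_lev_nf

    @property
    def ach(self) -> float:
        """Air changes per hour implied by the total ventilation flow."""
        return ach_from_flows(self.q_gv, self.q_lev, self.v)

    # -- serialisation with explicit unit suffixes ---------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "v_m3": self.v,
            "v_nf_m3": self.v_nf,
            "q_gv_m3_per_min": self.q_gv,
            "q_lev_m3_per_min": self.q_lev,
            "q_lev_nf_m3_per_min": self.q_lev_nf,
            "beta_m3_per_min": self.beta,
            "c0_mg_per_m3": self.c0,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Scenario":
        return cls(
            name=data["name"],
            v=float(data["v_m3"]),
            v_nf=float(data.get("v_nf_m3", 8.0)),
            q_gv=float(data["q_gv_m3_per_min"]),
            q_lev=float(data["q_lev_m3_per_min"]),
            q_lev_nf=float(data.get("q_lev_nf_m3_per_min", 0.0)),
            beta=float(data.get("beta_m3_per_min", 5.0)),
            c0=float(data.get("c0_mg_per_m3", 0.0)),
        )


def read_scenario_yaml(path) -> dict[str, Scenario]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {key: Scenario.from_dict(val) for key, val in raw.items()}


def write_scenario_yaml(scenarios: dict[str, Scenario], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({k: s.to_dict() for k, s in scenarios.items()}, fh, sort_keys=False)


@dataclass(frozen=True)
class SteadyState:
    """Long-time concentrations, mg m^-3 (``c_ff`` is None for one box)."""

    c_room: float | None = None
    c_nf: float | None = None
    c_ff: float | None = None


@dataclass
class ConcentrationSeries:
    """Timestamped concentrations for one or two compartments.

    ``values`` has one column per compartment, matching ``columns``
    (``["c_room_mg_m3"]`` for the one-box model, ``["c_nf_mg_m3",
    "c_ff_mg_m3"]`` for the two-box model).  Times are minutes, strictly
    increasing.
    """

    times: np.ndarray
    values: np.ndarray
    columns: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != self.times.size:
            self.values = self.values.T
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be a strictly increasing 1-D array")
        if self.values.shape != (self.times.size, len(self.columns)):
            raise ValueError("values shape does not match times/columns")
        if np.any(self.values < -1e-12):
            raise ValueError("concentrations must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=list(self.columns))
        frame.insert(0, "time_min", self.times)
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.columns.index(name)]


def ach_from_flows(q_gv: float, q_lev: float, v: float) -> float:
    """Air changes per hour from ventilation flows (m^3 min^-1) and volume."""
    if v <= 0:
        raise ValueError("volume must be positive")
    return 60.0 * (q_gv + q_lev) / v


def flows_from_ach(ach: float, v: float) -> float:
    """Total ventilation flow (m^3 min^-1) implied by an ACH (h^-1)."""
    if v <= 0:
        raise ValueError("volume must be positive")
    return ach * v / 60.0


def one_box_steady_state(s: float, scenario: Scenario) -> SteadyState:
    """Equilibrium of the one-box balance: C = (S + Q*C0) / Q."""
    q = scenario.q_total
    if q <= 0:
        raise ValueError("no steady state: total ventilation flow is zero")
    return SteadyState(c_room=(s + q * scenario.c0) / q)


def two_box_steady_state(s: float, scenario: Scenario) -> SteadyState:
    """Equilibrium of the two-box balance.

    C_FF = [beta*S/beta_i + (Q_GV + Q_LEV)*C0] / (beta_i + Q_GV - beta)
    C_NF = C_FF + S / beta_i

    The FF denominator equals ``q_lev_nf + q_gv`` because
    ``beta_i - beta = q_lev_nf``.
    """
    beta_i = scenario.beta_i
    if beta_i <= 0:
        raise ValueError("beta_i must be positive for a steady state")
    denom = beta_i + scenario.q_gv - scenario.beta
    if denom <= 0:
        raise ValueError("unphysical flow set: q_lev_nf + q_gv must be positive")
    c_ff = (scenario.beta * s / beta_i + scenario.q_total * scenario.c0) / denom
    return SteadyState(c_nf=c_ff + s / beta_i, c_ff=c_ff)


def _segment_edges(spec: EmissionSpec, t0: float, t1: float) -> np.ndarray:
    """Times in [t0, t1] where the (piecewise-constant) source switches."""
    edges = {t0, t1}
    for start, end in spec.schedule:
        for e in (start, end):
            if t0 < e < t1:
                edges.add(e)
    return np.array(sorted(edges))


def solve_one_box(
    spec: EmissionSpec,
    scenario: Scenario,
    t_grid: Sequence[float],
    c_init: float | None = None,
) -> ConcentrationSeries:
    """Exact piecewise-analytic one-box transient on the requested grid.

    On every segment of constant source S the solution relaxes
    exponentially towards the segment steady state with time constant
    V/Q.  The default initial condition is the background ``scenario.c0``.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size == 0 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be a non-empty strictly increasing 1-D array")
    if np.any(t < 0):
        raise ValueError("t_grid times must be non-negative")
    c = scenario.c0 if c_init is None else float(c_init)
    if c < 0:
        raise ValueError("initial concentration must be non-negative")
    q, v = scenario.q_total, scenario.v

    out = np.empty_like(t)
    edges = _segment_edges(spec, t[0], t[-1])
    for left, right in zip(edges[:-1], edges[1:]):
        s = emission_rate(spec, (left + right) / 2.0)
        mask = (t >= left) & (t <= right)
        dt = t[mask] - left
        if q > 0:
            c_ss = (s + q * scenario.c0) / q
            out[mask] = c_ss + (c - c_ss) * np.exp(-q * dt / v)
            c = c_ss + (c - c_ss) * math.exp(-q * (right - left) / v)
        else:  # pure accumulation, no ventilation exchange
            out[mask] = c + s * dt / v
            c = c + s * (right - left) / v
    return ConcentrationSeries(
        times=t,
        values=out[:, None],
        columns=("c_room_mg_m3",),
        meta={"model": "one_box", "scenario": scenario.name},
    )


def _two_box_system(s: float, scenario: Scenario) -> tuple[np.ndarray, np.ndarray]:
    """System matrix A and forcing b of d[C_NF, C_FF]/dt = A C + b."""
    beta, beta_i = scenario.beta, scenario.beta_i
    v_nf, v_ff = scenario.v_nf, scenario.v_ff
    a = np.array(
        [
            [-beta_i / v_nf, beta_i / v_nf],
            [beta / v_ff, -(beta_i + scenario.q_gv) / v_ff],
        ]
    )
    b = np.array([s / v_nf, scenario.q_total * scenario.c0 / v_ff])
    return a, b


def _propagate_two_box(
    a: np.ndarray, b: np.ndarray, c_start: np.ndarray, dt: np.ndarray
) -> np.ndarray:
    """Exact solution C(dt) = C_p + exp(A dt) (C_start - C_p) for each dt."""
    c_p = np.linalg.solve(a, -b)
    dev = c_start - c_p
    lam, vec = np.linalg.eig(a)
    if np.all(np.isreal(lam)) and abs(lam[0] - lam[1]) > 1e-9 * max(1.0, abs(lam[0])):
        lam = lam.real
        vec = vec.real
        coeff = np.linalg.solve(vec, dev)
        modes = coeff[None, :] * np.exp(np.outer(dt, lam))
        return c_p[None, :] + modes @ vec.T
    # (near-)repeated or complex eigenvalues: matrix exponential per point
    return np.stack([c_p + expm(a * float(d)) @ dev for d in np.atleast_1d(dt)])


def solve_two_box(
    spec: EmissionSpec,
    scenario: Scenario,
    t_grid: Sequence[float],
    c_init_nf: float | None = None,
    c_init_ff: float | None = None,
    method: str = "analytic",
    rtol: float = 1e-8,
) -> ConcentrationSeries:
    """Two-box transient on the requested grid.

    ``method="analytic"`` (default) solves each constant-source segment in
    closed form; ``method="numeric"`` integrates the same segments with an
    adaptive Runge-Kutta scheme at relative tolerance ``rtol`` and serves
    as an independent cross-check.
    """
    if method not in ("analytic", "numeric"):
        raise ValueError("method must be 'analytic' or 'numeric'")
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size == 0 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be a non-empty strictly increasing 1-D array")
    if np.any(t < 0):
        raise ValueError("t_grid times must be non-negative")
    if scenario.beta_i <= 0:
        raise ValueError("beta_i must be positive")
    c = np.array(
        [
            scenario.c0 if c_init_nf is None else float(c_init_nf),
            scenario.c0 if c_init_ff is None else float(c_init_ff),
        ]
    )
    if np.any(c < 0):
        raise ValueError("initial concentrations must be non-negative")

    out = np.empty((t.size, 2))
    edges = _segment_edges(spec, t[0], t[-1])
    for left, right in zip(edges[:-1], edges[1:]):
        s = emission_rate(spec, (left + right) / 2.0)
        a, b = _two_box_system(s, scenario)
        mask = (t >= left) & (t <= right)
        dt = t[mask] - left
        if method == "analytic":
            out[mask] = _propagate_two_box(a, b, c, dt)
            c = _propagate_two_box(a, b, c, np.array([right - left]))[0]
        else:
            t_eval = np.union1d(dt + left, [right])
            sol = solve_ivp(
                lambda _, y: a @ y + b,
                (left, right),
                c,
                t_eval=t_eval,
                rtol=rtol,
                atol=1e-12,
                method="LSODA",
            )
            if not sol.success:
                raise RuntimeError(f"numerical integration failed: {sol.message}")
            lookup = {tt: sol.y[:, k] for k, tt in enumerate(sol.t)}
            out[mask] = np.array([lookup[tt] for tt in dt + left])
            c = sol.y[:, -1]
    out = np.clip(out, 0.0, None)
    return ConcentrationSeries(
        times=t,
        values=out,
        columns=("c_nf_mg_m3", "c_ff_mg_m3"),
        meta={"model": "two_box", "scenario": scenario.name, "method": method},
    )


def time_weighted_average(
    series: ConcentrationSeries, window: tuple[float, float] | None = None
) -> dict[str, float]:
    """Trapezoidal time average of each compartment over ``window``.

    ``window`` defaults to the full series span and must lie within it;
    endpoint values are linearly interpolated.
    """
    t0, t1 = (series.times[0], series.times[-1]) if window is None else window
    if not (series.times[0] <= t0 < t1 <= series.times[-1]):
        raise ValueError("window must be a non-empty interval within the series span")
    inner = series.times[(series.times > t0) & (series.times < t1)]
    grid = np.concatenate(([t0], inner, [t1]))
    out = {}
    for j, name in enumerate(series.columns):
        vals = np.interp(grid, series.times, series.values[:, j])
        out[name] = float(np.trapezoid(vals, grid) / (t1 - t0))
    return out


def air_balance_report(scenario: Scenario) -> dict:
    """Volumetric in/out flows per compartment under the literal equations.

    The NF always balances (``beta_i`` in, ``beta_i`` out).  The FF gains
    the makeup flow ``q_gv + q_lev`` plus ``beta`` from the NF and loses
    ``beta_i`` to the NF plus ``q_gv`` out of the room, so its balance is
    open by ``q_lev - q_lev_nf``; a non-zero imbalance is flagged as a
    warning but the scenario is never altered.
    """
    nf_in = nf_out = scenario.beta_i
    ff_in = scenario.q_total + scenario.beta
    ff_out = scenario.beta_i + scenario.q_gv
    imbalance = scenario.q_lev - scenario.q_lev_nf
    return {
        "scenario": scenario.name,
        "nf_inflow_m3_per_min": nf_in,
        "nf_outflow_m3_per_min": nf_out,
        "ff_inflow_m3_per_min": ff_in,
        "ff_outflow_m3_per_min": ff_out,
        "imbalance_m3_per_min": imbalance,
        "balanced": math.isclose(imbalance, 0.0, abs_tol=1e-12),
        "warning": (
            None
            if math.isclose(imbalance, 0.0, abs_tol=1e-12)
            else (
                "room exhaust flow q_lev differs from the FF->NF LEV draw "
                f"q_lev_nf by {imbalance:g} m^3/min; the literal two-box "
                "equations leave this air unaccounted for"
            )
        ),
    }
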