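"""Synthetic worker-area monitoring campaigns.

No raw time series from the original monitoring campaign are available,
so end-to-end behaviour is exercised on synthetic data with the
statistical structure the analysis assumes: a box-model "truth" series
at 1-minute resolution, perturbed per time step by multiplicative
lognormal noise (occupational concentrations are conventionally
lognormal) and an additive background level, then reduced to task
averages exactly as real stationary measurements would be.

The generator also supports the inverse exercise: recovering the
inter-zonal flow ``beta`` (or the source strength ``S``) from noisy
NF/FF concentration pairs, which probes how much information the
NF-FF contrast ``C_NF - C_FF = S / beta_i`` actually carries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import optimize

from .boxmodels import (
    ConcentrationSeries,
    Scenario,
    solve_one_box,
    solve_two_box,
    time_weighted_average,
    two_box_steady_state,
)
from .dustiness import EmissionSpec
from .evaluation import PairedObservation

__all__ = [
    "NoiseModel",
    "SyntheticCampaign",
    "generate_campaign",
    "recover_beta",
    "recover_source",
]


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description for synthetic monitoring.

    ``gsd`` is the geometric standard deviation of the multiplicative
    lognormal error applied to each 1-minute concentration (1 = no
    noise); ``background_level``/``background_sd`` describe an additive
    normal background in mg m^-3, truncated at zero.
    """

    gsd: float = 1.5
    background_level: float = 0.0
    background_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gsd < 1.0:
            raise ValueError("gsd must be >= 1")
        if self.background_level < 0 or self.background_sd < 0:
            raise ValueError("background parameters must be non-negative")


@dataclass(frozen=True)
class SyntheticCampaign:
    """A replicated synthetic monitoring campaign for one task.

    The truth series comes from the requested box model under
    ``scenario``/``emission``; replicates differ only through the seeded
    noise stream.  ``task_duration_min`` sets the averaging window
    (and the span of the generated series), sampled at ``dt_min``.
    """

    scenario: Scenario
    emission: EmissionSpec
    noise: NoiseModel = NoiseModel()
    n_replicates: int = 3
    task_duration_min: float = 120.0
    model: str = "two_box"
    dt_min: float = 1.0

    def __post_init__(self) -> None:
        if self.model not in ("one_box", "two_box"):
            raise ValueError("model must be 'one_box' or 'two_box'")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.task_duration_min <= 0 or self.dt_min <= 0:
            raise ValueError("durations must be positive")


def generate_campaign(
    campaign: SyntheticCampaign,
) -> tuple[list[ConcentrationSeries], list[PairedObservation], dict]:
    """Simulate a campaign of noisy replicate measurements.

    Returns ``(series, observations, truth)`` where ``series`` holds one
    noisy ConcentrationSeries per replicate, ``observations`` pairs each
    replicate's noisy task average with the noiseless truth average
    (truth as "modelled", noisy as "measured"), and ``truth`` records the
    generating series, task averages and parameters.  Fully reproducible
    from ``campaign.noise.seed``.
    """
    rng = np.random.default_rng(campaign.noise.seed)
    t = np.arange(
        0.0, campaign.task_duration_min + campaign.dt_min / 2, campaign.dt_min
    )
    if campaign.model == "one_box":
        truth = solve_one_box(campaign.emission, campaign.scenario, t)
    else:
        truth = solve_two_box(campaign.emission, campaign.scenario, t)
    truth_avg = time_weighted_average(truth)

    sigma = math.log(campaign.noise.gsd)
    series_out: list[ConcentrationSeries] = []
    observations: list[PairedObservation] = []
    for rep in range(campaign.n_replicates):
        noisy = truth.values.copy()
        if sigma > 0:
            noisy = noisy * rng.lognormal(0.0, sigma, size=noisy.shape)
        if campaign.noise.background_level > 0 or campaign.noise.background_sd > 0:
            background = rng.normal(
                campaign.noise.background_level,
                campaign.noise.background_sd,
                size=noisy.shape,
            )
            noisy = noisy + np.clip(background, 0.0, None)
        series = ConcentrationSeries(
            times=t,
            values=noisy,
            columns=truth.columns,
            meta={
                **truth.meta,
                "replicate": f"R{rep + 1}",
                "seed": campaign.noise.seed,
                "gsd": campaign.noise.gsd,
            },
        )
        series_out.append(series)
        noisy_avg = time_weighted_average(series)
        for column in truth.columns:
            compartment = column.replace("c_", "").replace("_mg_m3", "")
            observations.append(
                PairedObservation(
                    material=campaign.emission.dustiness.material,
                    replicate=f"R{rep + 1}",
                    filling_line=campaign.scenario.name,
                    model=f"{campaign.model}:{compartment}",
                    di_method=campaign.emission.dustiness.method,
                    fraction=campaign.emission.fraction,
                    modelled=truth_avg[column],
                    measured=noisy_avg[column],
                )
            )
    truth_record = {
        "series": truth,
        "task_average": truth_avg,
        "emission_rate_mg_min": campaign.emission.base_rate,
        "scenario": campaign.scenario,
        "seed": campaign.noise.seed,
    }
    return series_out, observations, truth_record


def _beta_objective(
    beta: float, obs_nf: np.ndarray, obs_ff: np.ndarray, scenario: Scenario, s: float
) -> float:
    ss = two_box_steady_state(s, replace(scenario, beta=beta))
    return float(
        np.sum((np.log(obs_nf) - math.log(ss.c_nf)) ** 2)
        + np.sum((np.log(obs_ff) - math.log(ss.c_ff)) ** 2)
    )


def recover_beta(
    obs_nf: Sequence[float],
    obs_ff: Sequence[float],
    scenario: Scenario,
    s: float,
    grid: Sequence[float] | None = None,
    refine: bool = True,
) -> tuple[float, float]:
    """Least-squares estimate of beta from NF/FF concentration pairs.

    ``obs_nf``/``obs_ff`` are post-transient (steady-state-window)
    concentrations, e.g. replicate task averages; the source strength
    ``s`` and all other scenario parameters are taken as known.  The fit
    minimises squared log-concentration residuals over a log-spaced grid
    (default 0.05-100 m^3 min^-1) with optional local refinement.

    Returns ``(beta_estimate, objective_value)``.
    """
    if s <= 0:
        raise ValueError("beta is not identifiable without an active source (S > 0)")
    obs_nf = np.asarray(obs_nf, dtype=float)
    obs_ff = np.asarray(obs_ff, dtype=float)
    if obs_nf.size == 0 or obs_nf.shape != obs_ff.shape:
        raise ValueError("need matching, non-empty NF and FF observation arrays")
    if np.any(obs_nf <= 0) or np.any(obs_ff <= 0):
        raise ValueError("observed concentrations must be positive")
    grid = np.asarray(
        np.geomspace(0.05, 100.0, 60) if grid is None else grid, dtype=float
    )
    objectives = [_beta_objective(b, obs_nf, obs_ff, scenario, s) for b in grid]
    k = int(np.argmin(objectives))
    best, best_obj = float(grid[k]), float(objectives[k])
    if refine:
        lo = float(grid[max(k - 1, 0)])
        hi = float(grid[min(k + 1, grid.size - 1)])
        if lo < hi:
            res = optimize.minimize_scalar(
                _beta_objective,
                bounds=(lo, hi),
                args=(obs_nf, obs_ff, scenario, s),
                method="bounded",
                options={"xatol": 1e-10},
            )
            if res.fun <= best_obj:
                best, best_obj = float(res.x), float(res.fun)
    return best, best_obj


def recover_source(
    observed: Sequence[float],
    model_at_unit_source: Sequence[float],
) -> float:
    """Source strength S from observations and the model response to S=1.

    With zero background the box models are linear in S, so the
    least-squares estimate in log space is the geometric mean of the
    observed/unit-response ratios.
    """
    observed = np.asarray(observed, dtype=float)
    unit = np.asarray(model_at_unit_source, dtype=float)
    if observed.size == 0 or observed.shape != unit.shape:
        raise ValueError("need matching, non-empty observation and response arrays")
    if np.any(observed <= 0) or np.any(unit <= 0):
        raise ValueError("concentrations must be positive")
    return float(np.exp(np.mean(np.log(observed) - np.log(unit))))
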