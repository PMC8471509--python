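"""Model-performance metrics for paired modelled/measured concentrations.

Model skill is judged on the ratio of modelled to measured task-average
concentration, binned into the benchmark bands conventional in exposure
modelling:

* under-estimation       ratio < 0.5
* accurate estimation    0.5 <= ratio <= 2
* slight over-estimation 2 < ratio <= 5
* high over-estimation   ratio > 5

plus the mean absolute error (MAE), the squared Pearson correlation
(R^2), the Spearman rank correlation, and the fraction of cases where the
measurement exceeds the model (a screening model should rarely
under-predict).

Band edges are inclusive at their upper bound, and classification can be
performed on ratios rounded to a stated printed precision: published
evaluation tables round to one decimal, so a raw ratio of 5.03 that was
printed as 5.0 belongs to the "slight over-estimation" group when
reproducing published counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "BANDS",
    "PairedObservation",
    "EvaluationSummary",
    "ratio",
    "classify",
    "summarize",
]

BANDS = ("under", "accurate", "slight_over", "high_over")


@dataclass(frozen=True)
class PairedObservation:
    """One modelled/measured pair for a single replicate task.

    ``measured_no_events`` optionally holds the measurement with
    concentration spikes from recorded incidents (e.g. broken bags)
    removed; ``printed_ratio`` carries a published rounded ratio when the
    pair was transcribed from a report table.
    """

    material: str
    replicate: str
    filling_line: str
    model: str
    di_method: str
    fraction: str
    modelled: float
    measured: float
    measured_no_events: float | None = None
    printed_ratio: float | None = None
    printed_ratio_no_events: float | None = None

    def __post_init__(self) -> None:
        if self.modelled < 0:
            raise ValueError("modelled concentration must be non-negative")
        if self.measured <= 0:
            raise ValueError("measured concentration must be positive")
        if self.measured_no_events is not None and self.measured_no_events <= 0:
            raise ValueError("event-excluded measurement must be positive")


def ratio(
    obs: PairedObservation,
    use_printed: bool = False,
    exclude_events: bool = False,
) -> float:
    """Modelled/measured concentration ratio for one observation.

    ``use_printed`` returns the published rounded ratio when available;
    ``exclude_events`` divides by the event-excluded measurement instead
    (falling back to the raw measurement when no such value exists).
    """
    if use_printed:
        printed = (
            obs.printed_ratio_no_events
            if exclude_events and obs.printed_ratio_no_events is not None
            else obs.printed_ratio
        )
        if printed is not None:
            return printed
    measured = obs.measured
    if exclude_events and obs.measured_no_events is not None:
        measured = obs.measured_no_events
    if measured <= 0:
        raise ValueError("measured concentration must be positive")
    return obs.modelled / measured


def classify(r: float, precision_decimals: int | None = None) -> str:
    """Benchmark band of a modelled/measured ratio.

    Upper edges are inclusive: under < 0.5 <= accurate <= 2 < slight_over
    <= 5 < high_over.  When ``precision_decimals`` is given the ratio is
    rounded first, matching classification of values printed at that
    precision.
    """
    if r <= 0:
        raise ValueError(f"ratio must be positive, got {r}")
    if precision_decimals is not None:
        r = round(r, precision_decimals)
    if r < 0.5:
        return "under"
    if r <= 2:
        return "accurate"
    if r <= 5:
        return "slight_over"
    return "high_over"


@dataclass(frozen=True)
class EvaluationSummary:
    """Aggregate performance metrics over a set of paired observations.

    Percentages are on the 0-100 scale.  ``pct_within_05_5`` combines the
    accurate and slight-over-estimation bands (ratio in [0.5, 5]), the
    usual headline for screening-level model skill.  Correlations are
    ``None`` when fewer than two pairs are available.
    """

    n: int
    pct_under: float
    pct_accurate: float
    pct_slight_over: float
    pct_high_over: float
    pct_within_05_5: float
    mae: float
    r_squared: float | None
    spearman_rho: float | None
    pct_measured_exceeds_modelled: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def summarize(
    observations: Sequence[PairedObservation],
    use_printed: bool = False,
    exclude_events: bool = False,
    ratio_decimals: int | None = 1,
    modelled_scale: float = 1.0,
) -> EvaluationSummary:
    """Band percentages, MAE, correlations and exceedance for a stratum.

    ``ratio_decimals`` controls the rounding applied before band
    classification (default one decimal, the printed precision of
    published evaluation tables; pass ``None`` to classify raw ratios).
    ``modelled_scale`` multiplies every modelled value first — useful for
    re-evaluating a stratum under a rescaled handling factor without
    rebuilding the observations.
    """
    if not observations:
        raise ValueError("no observations supplied")
    modelled = np.array([o.modelled * modelled_scale for o in observations])
    measured = np.array(
        [
            o.measured_no_events
            if exclude_events and o.measured_no_events is not None
            else o.measured
            for o in observations
        ]
    )
    if use_printed:
        ratios = np.array(
            [
                ratio(o, use_printed=True, exclude_events=exclude_events)
                * modelled_scale
                for o in observations
            ]
        )
    else:
        ratios = modelled / measured
    bands = [classify(r, ratio_decimals) for r in ratios]
    n = len(observations)
    pct = {band: 100.0 * bands.count(band) / n for band in BANDS}

    mae = float(np.mean(np.abs(modelled - measured)))
    if n >= 2 and np.std(modelled) > 0 and np.std(measured) > 0:
        r_squared = float(stats.pearsonr(modelled, measured).statistic ** 2)
        spearman = float(stats.spearmanr(modelled, measured).statistic)
    else:
        r_squared = spearman = None
    return EvaluationSummary(
        n=n,
        pct_under=pct["under"],
        pct_accurate=pct["accurate"],
        pct_slight_over=pct["slight_over"],
        pct_high_over=pct["high_over"],
        pct_within_05_5=pct["accurate"] + pct["slight_over"],
        mae=mae,
        r_squared=r_squared,
        spearman_rho=spearman,
        pct_measured_exceeds_modelled=float(100.0 * np.mean(measured > modelled)),
    )
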