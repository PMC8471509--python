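"""Emission-source characterisation from dustiness data.

The tendency of a powder to release airborne dust is quantified by its
dustiness index (DI, mg of aerosolised dust per kg of powder handled),
determined with one of the EN 15051 laboratory methods: the continuous
drop (CD) test, which pours material through a vertical column, or the
rotating drum (RD) test, which tumbles it.  A process-specific emission
rate is obtained by scaling the DI with the mass throughput of the
process, a dimensionless handling-energy factor ``H`` that links the
mechanical energy of the real process to that of the dustiness test, and
local-control factors for enclosure of the receiving bag and for local
exhaust ventilation (LEV):

    S(t) = DI * H * dM/dt * LC_bag * LC_LEV        [mg min^-1]

with DI in mg kg^-1 and dM/dt in kg min^-1.  Local controls are stored as
*retained* fractions (1 - efficacy); user-facing helpers convert from the
"percent reduction" convention once, at the boundary.

The module also provides the CD/RD method-comparison statistics used to
rescale ``H`` when a dustiness method systematically over-drives the
emission estimate for a given particle-size fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FRACTIONS",
    "METHODS",
    "ALWAYS_ACTIVE",
    "DustinessRecord",
    "EmissionSpec",
    "DiRatioStats",
    "retained_from_reduction_pct",
    "reduction_pct_from_retained",
    "emission_rate",
    "di_ratio_stats",
    "corrected_h",
    "records_to_frame",
    "records_from_frame",
    "read_dustiness_csv",
    "write_dustiness_csv",
]

FRACTIONS = ("inhalable", "respirable")
METHODS = ("CD", "RD")
EN15051_CLASSES = ("very_low", "low", "medium", "high")

#: Schedule meaning "source active at all times".
ALWAYS_ACTIVE = ((0.0, math.inf),)


def retained_from_reduction_pct(pct: float) -> float:
    """Convert a percent-reduction efficacy to a retained fraction.

    A local control reported as "70% reduction" lets 30% of the emission
    through, so ``retained_from_reduction_pct(70) == 0.3``.
    """
    if not 0.0 <= pct <= 100.0:
        raise ValueError(f"reduction percentage must be in [0, 100], got {pct}")
    return 1.0 - pct / 100.0


def reduction_pct_from_retained(retained: float) -> float:
    """Inverse of :func:`retained_from_reduction_pct`."""
    if not 0.0 <= retained <= 1.0:
        raise ValueError(f"retained fraction must be in [0, 1], got {retained}")
    return 100.0 * (1.0 - retained)


@dataclass(frozen=True)
class DustinessRecord:
    """Dustiness of one material under one EN 15051 test method.

    Parameters
    ----------
    material : str
        Material name, used to match CD and RD records.
    method : {"CD", "RD"}
        Continuous drop or rotating drum test.
    w_inhalable, w_respirable : float
        Dustiness index of the inhalable / respirable fraction, mg kg^-1.
        The respirable aerosol is a sub-fraction of the inhalable one, so
        ``w_inhalable >= w_respirable`` is enforced.
    sd_inhalable, sd_respirable : float, optional
        Arithmetic standard deviations of the test replicates.
    en15051_class_inhalable, en15051_class_respirable : str, optional
        Categorical EN 15051 dustiness ranking
        (very_low / low / medium / high).
    """

    material: str
    method: str
    w_inhalable: float
    w_respirable: float
    sd_inhalable: float | None = None
    sd_respirable: float | None = None
    en15051_class_inhalable: str | None = None
    en15051_class_respirable: str | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.w_inhalable < 0 or self.w_respirable < 0:
            raise ValueError("dustiness indices must be non-negative")
        if self.w_inhalable < self.w_respirable:
            raise ValueError(
                f"{self.material} ({self.method}): inhalable DI "
                f"{self.w_inhalable} < respirable DI {self.w_respirable}"
            )
        for cls in (self.en15051_class_inhalable, self.en15051_class_respirable):
            if cls is not None and cls not in EN15051_CLASSES:
                raise ValueError(f"unknown EN 15051 class {cls!r}")

    def di(self, fraction: str) -> float:
        """Dustiness index (mg kg^-1) for the requested size fraction."""
        if fraction == "inhalable":
            return self.w_inhalable
        if fraction == "respirable":
            return self.w_respirable
        raise ValueError(f"fraction must be one of {FRACTIONS}, got {fraction!r}")


def _validate_schedule(schedule: Sequence[tuple[float, float]]) -> tuple[tuple[float, float], ...]:
    out = tuple((float(a), float(b)) for a, b in schedule)
    prev_end = -math.inf
    for start, end in out:
        if not start < end:
            raise ValueError(f"schedule interval ({start}, {end}) must have start < end")
        if start < prev_end:
            raise ValueError("schedule intervals must be sorted and non-overlapping")
        prev_end = end
    return out


@dataclass(frozen=True)
class EmissionSpec:
    """Everything needed to evaluate the emission rate S(t).

    ``schedule`` is an ordered, non-overlapping list of ``(start, end)``
    activity intervals in minutes; the source is on during ``[start, end)``
    and off elsewhere.  The default schedule is always-on.
    """

    dustiness: DustinessRecord
    fraction: str
    h: float
    mass_flow_kg_min: float
    lc_bag_retained: float
    lc_lev_retained: float
    schedule: tuple[tuple[float, float], ...] = ALWAYS_ACTIVE

    def __post_init__(self) -> None:
        if self.fraction not in FRACTIONS:
            raise ValueError(f"fraction must be one of {FRACTIONS}, got {self.fraction!r}")
        if self.h < 0:
            raise ValueError("handling factor H must be non-negative")
        if self.mass_flow_kg_min < 0:
            raise ValueError("mass flow must be non-negative")
        for name, value in (
            ("lc_bag_retained", self.lc_bag_retained),
            ("lc_lev_retained", self.lc_lev_retained),
        ):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        object.__setattr__(self, "schedule", _validate_schedule(self.schedule))

    @property
    def base_rate(self) -> float:
        """Emission rate while the source is active, mg min^-1."""
        return (
            self.dustiness.di(self.fraction)
            * self.h
            * self.mass_flow_kg_min
            * self.lc_bag_retained
            * self.lc_lev_retained
        )

    def active_at(self, t: float) -> bool:
        return any(start <= t < end for start, end in self.schedule)

    def with_lev_reduction_pct(self, pct: float) -> "EmissionSpec":
        """Copy of this spec with the LEV efficacy set from a percent reduction."""
        return EmissionSpec(
            dustiness=self.dustiness,
            fraction=self.fraction,
            h=self.h,
            mass_flow_kg_min=self.mass_flow_kg_min,
            lc_bag_retained=self.lc_bag_retained,
            lc_lev_retained=retained_from_reduction_pct(pct),
            schedule=self.schedule,
        )


def emission_rate(spec: EmissionSpec, t: float | np.ndarray) -> float | np.ndarray:
    """Source strength S(t) in mg min^-1.

    Returns ``DI * H * dM/dt * LC_bag * LC_LEV`` while ``t`` lies inside an
    active schedule interval and 0 otherwise.  Accepts a scalar time or an
    array of times (minutes); negative times are rejected.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    base = spec.base_rate
    active = np.zeros(t_arr.shape, dtype=bool)
    for start, end in spec.schedule:
        active |= (t_arr >= start) & (t_arr < end)
    out = np.where(active, base, 0.0)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


@dataclass(frozen=True)
class DiRatioStats:
    """Per-material CD/RD dustiness-index ratios and their summary."""

    fraction: str
    per_material_ratio: tuple[tuple[str, float], ...]
    mean: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if not self.min <= self.mean <= self.max:
            raise ValueError("inconsistent ratio summary (min <= mean <= max violated)")


def di_ratio_stats(
    records_cd: Iterable[DustinessRecord],
    records_rd: Iterable[DustinessRecord],
    fraction: str,
) -> DiRatioStats:
    """CD/RD dustiness-index ratio per material, with mean / min / max.

    The two record lists must cover the same materials (matched by name).
    The mean is the arithmetic mean of the per-material ratios.  A zero RD
    index makes the ratio undefined and is reported per material.
    """
    if fraction not in FRACTIONS:
        raise ValueError(f"fraction must be one of {FRACTIONS}, got {fraction!r}")
    cd = {r.material: r for r in records_cd}
    rd = {r.material: r for r in records_rd}
    if set(cd) != set(rd):
        only_cd = sorted(set(cd) - set(rd))
        only_rd = sorted(set(rd) - set(cd))
        raise ValueError(
            f"material sets differ: only in CD {only_cd}, only in RD {only_rd}"
        )
    if not cd:
        raise ValueError("no materials supplied")
    ratios = []
    for material in cd:
        num = cd[material].di(fraction)
        den = rd[material].di(fraction)
        if den == 0:
            raise ZeroDivisionError(f"zero RD dustiness index for {material!r}")
        ratios.append((material, num / den))
    values = [v for _, v in ratios]
    return DiRatioStats(
        fraction=fraction,
        per_material_ratio=tuple(ratios),
        mean=float(np.mean(values)),
        min=float(np.min(values)),
        max=float(np.max(values)),
    )


def corrected_h(h_original: float, ratio_mean: float, rounding_decimals: int = 2) -> float:
    """Rescale a handling factor by the mean CD/RD dustiness ratio.

    When one test method yields systematically larger indices than another
    (factor ``ratio_mean``), an H calibrated for the second method must be
    divided by that factor to give comparable emission estimates.
    """
    if ratio_mean <= 0:
        raise ValueError(f"ratio_mean must be positive, got {ratio_mean}")
    return round(h_original / ratio_mean, rounding_decimals)


# ---------------------------------------------------------------------------
# CSV interchange (long format: one row per material x method x fraction)

_CSV_COLUMNS = ["material", "method", "fraction", "di_mg_per_kg", "sd", "en15051_class"]


def records_to_frame(records: Iterable[DustinessRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append((r.material, r.method, "inhalable", r.w_inhalable,
                     r.sd_inhalable, r.en15051_class_inhalable))
        rows.append((r.material, r.method, "respirable", r.w_respirable,
                     r.sd_respirable, r.en15051_class_respirable))
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def records_from_frame(frame: pd.DataFrame) -> list[DustinessRecord]:
    missing = set(_CSV_COLUMNS[:4]) - set(frame.columns)
    if missing:
        raise ValueError(f"dustiness table missing columns: {sorted(missing)}")
    records = []
    for (material, method), grp in frame.groupby(["material", "method"], sort=False):
        by_fraction = {row.fraction: row for row in grp.itertuples()}
        if set(by_fraction) != set(FRACTIONS):
            raise ValueError(
                f"{material} ({method}): need exactly one row per fraction {FRACTIONS}"
            )
        inh, resp = by_fraction["inhalable"], by_fraction["respirable"]

        def _opt(value):
            return None if value is None or (isinstance(value, float) and math.isnan(value)) else value

        records.append(
            DustinessRecord(
                material=material,
                method=method,
                w_inhalable=float(inh.di_mg_per_kg),
                w_respirable=float(resp.di_mg_per_kg),
                sd_inhalable=_opt(getattr(inh, "sd", None)),
                sd_respirable=_opt(getattr(resp, "sd", None)),
                en15051_class_inhalable=_opt(getattr(inh, "en15051_class", None)),
                en15051_class_respirable=_opt(getattr(resp, "en15051_class", None)),
            )
        )
    return records


def read_dustiness_csv(path) -> list[DustinessRecord]:
    return records_from_frame(pd.read_csv(path))


def write_dustiness_csv(records: Iterable[DustinessRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)
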