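"""Packaged reference tables: dustiness indices, emission parameters,
paired modelled/measured concentrations and scenario defaults.

Seven ceramic raw materials (two clays, two kaolins, two feldspars, one
quartz) were dustiness-tested with both EN 15051 methods, and their
bagging was monitored on three filling lines (L, M, H) with increasing
mitigation levels, yielding fifteen replicate filling tasks.  The tables
here carry those published inputs and results as plain CSV/YAML under
``dustbox/data`` so that every reproduction computation can run offline
from in-package data alone.

``load_fixtures`` validates shape and internal consistency on load;
``verify_ratios`` recomputes every published modelled/measured ratio from
its concentration pair and reports any discrepancy beyond what rounding
of the printed values can explain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .boxmodels import Scenario, read_scenario_yaml
from .dustiness import (
    DustinessRecord,
    EmissionSpec,
    records_from_frame,
    retained_from_reduction_pct,
)
from .evaluation import PairedObservation, classify

__all__ = ["FixtureBundle", "load_fixtures", "verify_ratios"]

MATERIALS = (
    "Clay 1", "Clay 2", "Kaolin 1", "Feldspar 1", "Quartz 1",
    "Feldspar 2", "Kaolin 2",
)
_REPLICATES = {"Clay 1": 3}  # every other material has 2 replicate tasks
N_CASES = 15

# Published table cells whose printed ratio does not reconcile with the
# printed concentration pair even allowing for rounding: the respirable
# CD rows for Feldspar 2 R2 print the same ratio for the with- and
# without-events variants although the measured value changes
# (0.29 -> 0.26 mg m^-3). verify_ratios still reports these; load_fixtures
# does not treat them as corruption.
KNOWN_INCONSISTENT = {
    ("respirable", "one_box", "CD", "Feldspar 2", "R2", "no_events"),
    ("respirable", "two_box", "CD", "Feldspar 2", "R2", "no_events"),
}
STRATA = [
    (fraction, model, method)
    for fraction in ("inhalable", "respirable")
    for model in ("one_box", "two_box")
    for method in ("CD", "RD")
]


@dataclass(frozen=True)
class FixtureBundle:
    """Validated reference tables plus typed accessors."""

    dustiness: pd.DataFrame
    emission: pd.DataFrame
    observations: pd.DataFrame
    scenarios: dict[str, Scenario]

    # -- typed accessors -----------------------------------------------------

    def dustiness_records(self, method: str | None = None) -> list[DustinessRecord]:
        frame = self.dustiness
        if method is not None:
            frame = frame[frame.method == method]
        return records_from_frame(frame)

    def di(self, material: str, method: str, fraction: str) -> float:
        sel = self.dustiness.query(
            "material == @material and method == @method and fraction == @fraction"
        )
        if len(sel) != 1:
            raise KeyError((material, method, fraction))
        return float(sel.di_mg_per_kg.iloc[0])

    def emission_spec(
        self,
        material: str,
        method: str,
        fraction: str,
        lev_reduction_pct: float = 70.0,
        dm_dt_kg_min: float | None = None,
    ) -> EmissionSpec:
        """Emission spec for one material/method/fraction combination.

        ``dm_dt_kg_min`` must be given for line H materials, whose mass
        flow is only known as a 100-250 kg/min range; for the other lines
        it defaults to the tabulated value.
        """
        row = self.emission[self.emission.material == material]
        if row.empty:
            raise KeyError(material)
        row = row.iloc[0]
        lo, hi = float(row.dm_dt_min_kg_per_min), float(row.dm_dt_max_kg_per_min)
        if dm_dt_kg_min is None:
            if lo != hi:
                raise ValueError(
                    f"{material}: mass flow is a range {lo}-{hi} kg/min; "
                    "pass dm_dt_kg_min explicitly"
                )
            dm_dt_kg_min = lo
        elif not lo <= dm_dt_kg_min <= hi:
            raise ValueError(
                f"{material}: dm_dt {dm_dt_kg_min} outside tabulated range [{lo}, {hi}]"
            )
        records = {r.material: r for r in self.dustiness_records(method)}
        return EmissionSpec(
            dustiness=records[material],
            fraction=fraction,
            h=float(row.h_factor),
            mass_flow_kg_min=dm_dt_kg_min,
            lc_bag_retained=float(row.lc_bag_retained),
            lc_lev_retained=retained_from_reduction_pct(lev_reduction_pct),
        )

    def paired_observations(
        self, fraction: str, model: str, di_method: str
    ) -> list[PairedObservation]:
        sel = self.observations.query(
            "fraction == @fraction and model == @model and di_method == @di_method"
        )
        out = []
        for row in sel.itertuples():
            out.append(
                PairedObservation(
                    material=row.material,
                    replicate=row.replicate,
                    filling_line=row.filling_line,
                    model=row.model,
                    di_method=row.di_method,
                    fraction=row.fraction,
                    modelled=float(row.modelled_mg_m3),
                    measured=float(row.measured_mg_m3),
                    measured_no_events=_opt(row.measured_no_events_mg_m3),
                    printed_ratio=_opt(row.printed_ratio),
                    printed_ratio_no_events=_opt(row.printed_ratio_no_events),
                )
            )
        return out


def _opt(value) -> float | None:
    return None if value is None or (isinstance(value, float) and math.isnan(value)) else float(value)


def _data_path(name: str):
    return resources.files("dustbox.data").joinpath(name)


def load_fixtures() -> FixtureBundle:
    """Load and validate the packaged reference tables.

    Raises ``ValueError`` enumerating the offending cells when a shape or
    consistency check fails.
    """
    dustiness = pd.read_csv(_data_path("dustiness.csv"))
    emission = pd.read_csv(_data_path("emission_params.csv"))
    observations = pd.read_csv(_data_path("observations.csv"))
    with resources.as_file(_data_path("scenarios.yaml")) as path:
        scenarios = read_scenario_yaml(path)
    bundle = FixtureBundle(dustiness, emission, observations, scenarios)

    problems: list[str] = []
    if set(dustiness.material) != set(MATERIALS):
        problems.append(f"dustiness materials {sorted(set(dustiness.material))}")
    if len(dustiness) != len(MATERIALS) * 2 * 2:
        problems.append(f"dustiness has {len(dustiness)} rows, expected 28")
    # respirable DI may not exceed inhalable DI for the same material/method
    wide = dustiness.pivot_table(
        index=["material", "method"], columns="fraction", values="di_mg_per_kg"
    )
    bad = wide[wide.respirable > wide.inhalable]
    problems += [f"respirable > inhalable DI for {idx}" for idx in bad.index]

    if set(emission.material) != set(MATERIALS):
        problems.append("emission parameter table does not cover all materials")

    for fraction, model, method in STRATA:
        sel = observations.query(
            "fraction == @fraction and model == @model and di_method == @method"
        )
        if len(sel) != N_CASES:
            problems.append(
                f"{fraction}/{model}/{method}: {len(sel)} cases, expected {N_CASES}"
            )
        counts = sel.groupby("material").size()
        for material in MATERIALS:
            expect = _REPLICATES.get(material, 2)
            if counts.get(material, 0) != expect:
                problems.append(
                    f"{fraction}/{model}/{method}: {material} has "
                    f"{counts.get(material, 0)} replicates, expected {expect}"
                )

    if set(scenarios) != {"L", "M", "H"}:
        problems.append(f"scenarios {sorted(scenarios)}, expected L/M/H")

    report = verify_ratios(bundle)
    for row in report[~report.consistent].itertuples():
        key = (row.fraction, row.model, row.di_method, row.material,
               row.replicate, row.variant)
        if key in KNOWN_INCONSISTENT:
            continue
        problems.append(
            f"printed ratio inconsistent for {row.fraction}/{row.model}/"
            f"{row.di_method} {row.material} {row.replicate}: printed "
            f"{row.printed} vs recomputed {row.recomputed:.3g}"
        )
    if problems:
        raise ValueError("fixture validation failed:\n  " + "\n  ".join(problems))
    return bundle


def _ulp(value: float) -> float:
    """One unit in the last printed decimal place of a table value."""
    text = f"{value:g}"
    if "." in text:
        return 10.0 ** -len(text.split(".")[1])
    return 1.0


def _ratio_tolerance(printed: float, modelled: float, measured: float) -> float:
    """Allowed |printed - recomputed| given rounding of all three numbers.

    The recomputation divides two values that were themselves rounded for
    printing, so the tolerance propagates half an ulp of each operand in
    relative terms and adds one ulp of the printed ratio.
    """
    rel = 0.02 + 0.5 * _ulp(modelled) / modelled + 0.5 * _ulp(measured) / measured
    return rel * (modelled / measured) + _ulp(printed)


def verify_ratios(bundle: FixtureBundle) -> pd.DataFrame:
    """Recompute every published ratio from its concentration pair.

    Returns one row per printed ratio (including the event-excluded
    variants) with the recomputed value, whether it is consistent with
    the printed one given printing precision, and whether the case sits
    on a benchmark band edge (classification of the raw ratio differs
    from that of the ratio rounded to the printed precision).
    """
    rows = []
    for row in bundle.observations.itertuples():
        for printed, measured, variant in (
            (_opt(row.printed_ratio), float(row.measured_mg_m3), "with_events"),
            (
                _opt(row.printed_ratio_no_events),
                _opt(row.measured_no_events_mg_m3),
                "no_events",
            ),
        ):
            if printed is None or measured is None:
                continue
            modelled = float(row.modelled_mg_m3)
            recomputed = modelled / measured
            tol = _ratio_tolerance(printed, modelled, measured)
            rows.append(
                {
                    "fraction": row.fraction,
                    "model": row.model,
                    "di_method": row.di_method,
                    "material": row.material,
                    "replicate": row.replicate,
                    "variant": variant,
                    "printed": printed,
                    "recomputed": recomputed,
                    "tolerance": tol,
                    "consistent": abs(printed - recomputed) <= tol,
                    "band_edge": classify(recomputed, None) != classify(recomputed, 1),
                }
            )
    return pd.DataFrame(rows)
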