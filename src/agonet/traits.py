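"""Performance and feeding-behaviour traits per animal.

Growth traits come from a within-animal ordinary least squares regression
of body weight (kg) on age (days): the slope is the average daily gain
(ADG, kg/day) and the fitted line evaluated at 180 days gives the adjusted
body weight (BW). Back-fat thickness (BF, mm) is adjusted to 180 days the
same way. The feed conversion ratio is FCR = ADC / ADG with ADC the
average daily feed consumption (kg/day).

Feeding-behaviour traits are derived from electronic-feeder visit logs,
first per day, then averaged over days with visits:

* FR   — feeding rate, daily intake / daily trough time (g/min);
* OT   — occupation time, total minutes at the trough per day;
* FF   — feeding frequency, visits per day;
* FInt — mean interval between consecutive visit start times (minutes),
         averaged over days with at least two visits.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "fit_growth",
    "adjust_backfat",
    "feed_conversion",
    "feeding_behaviour",
    "trait_table",
    "TRAIT_COLUMNS",
]

#: Trait column order of the per-animal trait table.
TRAIT_COLUMNS = ("ADC", "FCR", "BF", "BW", "ADG", "FR", "OT", "FF", "FInt")

ADJUST_AGE = 180.0  # days; slaughter-age reference for BW and BF


def _ols_line(ages: Sequence[float], values: Sequence[float]) -> tuple[float, float]:
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    if ages.size < 2 or values.size != ages.size:
        raise ValueError("need >= 2 paired records")
    if np.unique(ages).size < 2:
        raise ValueError("all ages identical: regression undefined")
    slope, intercept = np.polyfit(ages, values, 1)
    return float(slope), float(intercept)


def fit_growth(ages: Sequence[float], weights: Sequence[float]) -> tuple[float, float]:
    """OLS of weight on age -> (ADG kg/day, BW kg adjusted to 180 d)."""
    slope, intercept = _ols_line(ages, weights)
    return slope, intercept + ADJUST_AGE * slope


def adjust_backfat(ages: Sequence[float], thickness: Sequence[float]) -> float:
    """OLS of back-fat (mm) on age, evaluated at 180 days."""
    slope, intercept = _ols_line(ages, thickness)
    return intercept + ADJUST_AGE * slope


def feed_conversion(adc: float, adg: float) -> float:
    """FCR = ADC / ADG (kg feed per kg gain); requires positive gain."""
    if adg <= 0:
        raise ValueError(f"non-positive ADG ({adg}): FCR undefined")
    return adc / adg


def feeding_behaviour(visits: pd.DataFrame) -> dict[str, float]:
    """Feeding-behaviour traits for one animal's feeder visits.

    ``visits`` needs columns ``day`` (calendar day key), ``start_min``
    (visit start, minutes since midnight), ``duration_min`` and
    ``intake_g``. Traits are computed per day and averaged across days
    with at least one visit; FInt across days with at least two. A day
    with zero total trough time is excluded from FR with a warning.

    Returns FR (g/min), OT (min/day), FF (visits/day), FInt (min) and ADC
    (kg/day). FInt is NaN when no day has two visits.
    """
    if visits.empty:
        raise ValueError("no feeder visits for this animal")
    fr_days: list[float] = []
    ot_days: list[float] = []
    ff_days: list[float] = []
    fint_days: list[float] = []
    adc_days: list[float] = []
    for day, grp in visits.groupby("day", sort=True):
        dur = float(grp["duration_min"].sum())
        intake = float(grp["intake_g"].sum())
        ot_days.append(dur)
        ff_days.append(len(grp))
        adc_days.append(intake)
        if dur > 0:
            fr_days.append(intake / dur)
        else:
            warnings.warn(
                f"day {day!r}: zero total trough time, excluded from FR",
                stacklevel=2,
            )
        if len(grp) >= 2:
            starts = np.sort(grp["start_min"].to_numpy(dtype=float))
            fint_days.append(float(np.mean(np.diff(starts))))
    return {
        "FR": float(np.mean(fr_days)) if fr_days else float("nan"),
        "OT": float(np.mean(ot_days)),
        "FF": float(np.mean(ff_days)),
        "FInt": float(np.mean(fint_days)) if fint_days else float("nan"),
        "ADC": float(np.mean(adc_days)) / 1000.0,
    }


def trait_table(
    weights: pd.DataFrame,
    backfat: pd.DataFrame,
    feeder: pd.DataFrame,
) -> pd.DataFrame:
    """Derive the full per-animal trait table from the three raw inputs.

    ``weights``: animal, age_days, weight_kg; ``backfat``: animal,
    age_days, backfat_mm; ``feeder``: animal, day, start_min,
    duration_min, intake_g. Animals missing a data source get NaN for the
    affected traits; animals with non-positive ADG are flagged and their
    FCR left NaN.
    """
    rows: dict[str, dict[str, float]] = {}
    for animal, grp in weights.groupby("animal"):
        adg, bw = fit_growth(grp["age_days"], grp["weight_kg"])
        rows.setdefault(str(animal), {})["ADG"] = adg
        rows[str(animal)]["BW"] = bw
    for animal, grp in backfat.groupby("animal"):
        rows.setdefault(str(animal), {})["BF"] = adjust_backfat(
            grp["age_days"], grp["backfat_mm"]
        )
    # Daily aggregation is done in one vectorized pass; per (animal, day)
    # the mean gap between sorted visit starts telescopes to
    # (max - min) / (count - 1), so no per-day loop is needed. This path
    # matches feeding_behaviour() exactly.
    if not feeder.empty:
        daily = feeder.groupby(["animal", "day"], sort=True).agg(
            dur=("duration_min", "sum"),
            intake=("intake_g", "sum"),
            k=("start_min", "size"),
            smin=("start_min", "min"),
            smax=("start_min", "max"),
        )
        zero_dur = daily["dur"] <= 0
        if zero_dur.any():
            warnings.warn(
                f"{int(zero_dur.sum())} animal-day(s) with zero trough time "
                "excluded from FR",
                stacklevel=2,
            )
        daily["fr"] = np.where(zero_dur, np.nan, daily["intake"] / daily["dur"])
        daily["fint"] = np.where(
            daily["k"] >= 2, (daily["smax"] - daily["smin"]) / (daily["k"] - 1),
            np.nan,
        )
        per_animal = daily.groupby("animal").agg(
            FR=("fr", "mean"),
            OT=("dur", "mean"),
            FF=("k", "mean"),
            FInt=("fint", "mean"),
            ADC=("intake", "mean"),
        )
        per_animal["ADC"] /= 1000.0
        per_animal["FF"] = per_animal["FF"].astype(float)
        for animal, row in per_animal.iterrows():
            rows.setdefault(str(animal), {}).update(row.to_dict())

    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "animal_id"
    frame["flagged"] = False
    fcr = []
    for _, row in frame.iterrows():
        adc, adg = row.get("ADC", np.nan), row.get("ADG", np.nan)
        if np.isnan(adc) or np.isnan(adg):
            fcr.append(np.nan)
        elif adg <= 0:
            fcr.append(np.nan)
        else:
            fcr.append(feed_conversion(adc, adg))
    frame["FCR"] = fcr
    frame.loc[frame.get("ADG", pd.Series(dtype=float)) <= 0, "flagged"] = True
    cols = [c for c in TRAIT_COLUMNS if c in frame.columns] + ["flagged"]
    return frame[cols].sort_index()
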