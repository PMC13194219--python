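"""Calibration, emission-rate normalization, and background separation.

Component areas (summed deconvoluted ion intensities) are converted to mass
via ordinary-least-squares calibration lines built from 2–8 spiked levels;
terpenoids without their own standard are tentatively quantified through a
structurally related surrogate's curve.  Amounts are then normalized to the
sampled bark area and sampling duration, giving emission rates in either
ng dm⁻² h⁻¹ (calibrated) or component area ×10⁶ dm⁻² h⁻¹ (uncalibrated).
Ambient "background" samples separate trunk volatiles from ubiquitous air
contaminants.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .study import SampleRecord

__all__ = [
    "CalibrationCurve",
    "UNIT_AREA",
    "UNIT_NG",
    "AREA_UNIT_SCALE",
    "fit_calibration",
    "area_to_mass",
    "to_emission_rate",
    "surrogate_quantify",
    "background_filter",
    "build_emission_table",
    "load_calibration",
]

UNIT_NG = "ng_per_dm2_h"
UNIT_AREA = "area_per_dm2_h"
#: Area-based rates are expressed in units of 1e6 counts dm^-2 h^-1.
AREA_UNIT_SCALE = 1e6


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS line area = slope·mass + intercept for one compound.

    ``surrogate_for`` lists compounds tentatively quantified via this curve;
    ``tentative`` is set on the copy handed to such a compound.
    """

    compound: str
    slope: float
    intercept: float
    r_squared: float
    levels: tuple[tuple[float, float], ...]
    surrogate_for: tuple[str, ...] = ()
    tentative: bool = False

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValueError(f"{self.compound}: need >= 2 calibration levels")
        if not self.slope > 0:
            raise ValueError(f"{self.compound}: calibration slope must be > 0")


def fit_calibration(compound: str, levels) -> CalibrationCurve:
    """Fit an ordinary-least-squares calibration line to (mass_ng, area) levels.

    The intercept is kept free (it absorbs the adsorbent blank).  Requires at
    least two distinct mass levels.
    """
    levels = tuple((float(m), float(a)) for m, a in levels)
    if len(levels) < 2:
        raise ValueError("need at least 2 calibration levels")
    mass = np.array([m for m, _ in levels])
    area = np.array([a for _, a in levels])
    if np.ptp(mass) == 0:
        raise ValueError("calibration masses have zero variance")
    # closed-form OLS; r^2 = 1 exactly for collinear levels
    mx, my = mass.mean(), area.mean()
    sxx = np.sum((mass - mx) ** 2)
    sxy = np.sum((mass - mx) * (area - my))
    slope = sxy / sxx
    intercept = my - slope * mx
    resid = area - (slope * mass + intercept)
    sst = np.sum((area - my) ** 2)
    r2 = 1.0 if sst == 0 else 1.0 - float(np.sum(resid**2)) / float(sst)
    return CalibrationCurve(
        compound=compound,
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r2),
        levels=levels,
    )


def area_to_mass(area: float, curve: CalibrationCurve) -> tuple[float, bool]:
    """Back-calculate mass (ng) from a component area.

    Returns ``(mass, below_calibration)``: a negative back-calculated mass
    (area below the intercept) is floored at 0 ng and flagged rather than
    rejected — low-level detections below the lowest level are expected.
    """
    mass = (area - curve.intercept) / curve.slope
    if mass < 0:
        return 0.0, True
    return float(mass), False


def to_emission_rate(amount: float, sample: SampleRecord, kind: str = UNIT_NG) -> float:
    """Normalize an amount to bark area and sampling time.

    ``kind=UNIT_NG``: *amount* in ng, rate in ng dm⁻² h⁻¹.
    ``kind=UNIT_AREA``: *amount* in raw counts, rate in ×10⁶ counts dm⁻² h⁻¹.
    Background samples carry no bark area and cannot be normalized.
    """
    if sample.is_background:
        raise ValueError(
            f"sample {sample.sample_id} is a background measurement; "
            "backgrounds are not area-normalized"
        )
    rate = amount / (sample.bark_area_dm2 * sample.duration_h)
    if kind == UNIT_AREA:
        rate /= AREA_UNIT_SCALE
    elif kind != UNIT_NG:
        raise ValueError(f"unknown rate kind {kind!r}")
    return rate


def surrogate_quantify(
    compound: str,
    curves: dict[str, CalibrationCurve],
    mapping: dict[str, str],
) -> CalibrationCurve | None:
    """Resolve the calibration curve used to quantify *compound*.

    A compound with its own curve uses it directly.  A compound mapped to a
    structurally related surrogate gets the surrogate's curve tagged
    tentative.  A compound with neither stays in area units (returns None).
    """
    if compound in curves:
        return curves[compound]
    surrogate = mapping.get(compound)
    if surrogate is None:
        return None
    if surrogate not in curves:
        raise ValueError(
            f"{compound}: surrogate {surrogate!r} has no calibration curve"
        )
    base = curves[surrogate]
    return replace(
        base,
        tentative=True,
        surrogate_for=tuple(sorted(set(base.surrogate_for) | {compound})),
    )


def background_filter(
    trunk_obs: pd.DataFrame,
    background_obs: pd.DataFrame,
    factor: float = 2.0,
) -> set[str]:
    """Retain features whose trunk signal exceeds the ambient background.

    A feature is retained iff its median trunk area is strictly greater than
    ``factor`` × its median background area; features never seen in any
    background sample are always retained.  Tables need columns
    ``feature_id`` and ``area``.
    """
    if factor < 1:
        raise ValueError("background factor must be >= 1")
    trunk_median = trunk_obs.groupby("feature_id")["area"].median()
    if background_obs.empty:
        return set(trunk_median.index)
    bg_median = background_obs.groupby("feature_id")["area"].median()
    retained = set()
    for feature, med in trunk_median.items():
        bg = bg_median.get(feature)
        if bg is None or med > factor * bg:
            retained.add(feature)
    return retained


def build_emission_table(
    observations: pd.DataFrame,
    samples: list[SampleRecord],
    compound_of_feature: dict[str, str],
    curves: dict[str, CalibrationCurve],
    surrogate_map: dict[str, str],
) -> pd.DataFrame:
    """Convert annotated trunk observations to per-sample emission rates.

    Produces one row per (compound, sample) detection with columns
    ``compound, tree_id, day, replicate, rate, unit, tentative,
    below_calibration``.  Compounds with no curve (own or surrogate) stay in
    area units; everything else is reported in ng dm⁻² h⁻¹.
    """
    by_id = {s.sample_id: s for s in samples}
    rows = []
    for obs in observations.itertuples(index=False):
        compound = compound_of_feature.get(obs.feature_id)
        if compound is None:
            continue
        sample = by_id[obs.sample_id]
        if sample.is_background:
            continue
        curve = surrogate_quantify(compound, curves, surrogate_map)
        if curve is None:
            rate = to_emission_rate(float(obs.area), sample, kind=UNIT_AREA)
            unit, tentative, below = UNIT_AREA, False, False
        else:
            mass, below = area_to_mass(float(obs.area), curve)
            rate = to_emission_rate(mass, sample, kind=UNIT_NG)
            unit, tentative = UNIT_NG, curve.tentative
        rows.append(
            {
                "compound": compound,
                "tree_id": sample.tree_id,
                "day": sample.day,
                "replicate": sample.replicate,
                "rate": rate,
                "unit": unit,
                "tentative": tentative,
                "below_calibration": below,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "compound",
            "tree_id",
            "day",
            "replicate",
            "rate",
            "unit",
            "tentative",
            "below_calibration",
        ],
    )


def load_calibration(path) -> dict[str, CalibrationCurve]:
    """Read `calibration.csv` (compound, mass_ng, area) and fit one curve each."""
    df = pd.read_csv(path)
    curves = {}
    for compound, grp in df.groupby("compound"):
        curves[str(compound)] = fit_calibration(
            str(compound), list(zip(grp["mass_ng"], grp["area"]))
        )
    return curves
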