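"""Synthetic longitudinal cohorts for the hypertension-model endpoints.

Each animal draws a Gaussian baseline and a Gaussian treatment effect per
endpoint; follow-up = baseline + effect. Weekly mean arterial pressure
follows a logistic rise that reaches ~95% of its plateau by week 3 for
the treated group and stays flat for controls. Default parameters are the
published group means +/- SD of an ovine angiotensin-II infusion cohort
(n = 9 treated vs n = 7 control).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from ..errors import InvalidParameterError

#: canonical group labels
GROUP_TREATED = "angii"
GROUP_CONTROL = "control"

#: cohort CSV column order
COHORT_COLUMNS = [
    "animal_id", "group", "week", "map_mmhg",
    "lv_mass_g_baseline", "lv_mass_g_followup",
    "ef_pct_baseline", "ef_pct_followup",
    "sv_ml_baseline", "sv_ml_followup",
    "lv_wall_mm", "septum_mm", "weight_kg", "creatinine_mg_dl",
]


@dataclass(frozen=True)
class EndpointEffect:
    """Gaussian baseline and paired treatment-effect model for one endpoint."""

    baseline_mean: float
    baseline_sd: float
    delta_mean: float = 0.0
    delta_sd: float = 0.0

    def validate(self, name: str) -> None:
        if self.baseline_sd < 0 or self.delta_sd < 0:
            raise InvalidParameterError(f"{name}: SDs must be >= 0")


@dataclass(frozen=True)
class SingleMeasure:
    """Gaussian model for a follow-up-only (e.g. postmortem) endpoint."""

    mean: float
    sd: float

    def validate(self, name: str) -> None:
        if self.sd < 0:
            raise InvalidParameterError(f"{name}: SD must be >= 0")


@dataclass(frozen=True)
class GroupParams:
    n: int
    map_mmhg: EndpointEffect
    lv_mass_g: EndpointEffect
    ef_pct: EndpointEffect
    sv_ml: EndpointEffect
    lv_wall_mm: SingleMeasure
    septum_mm: SingleMeasure
    weight_kg: SingleMeasure
    creatinine_mg_dl: SingleMeasure

    def validate(self, group: str) -> None:
        if self.n < 1:
            raise InvalidParameterError(f"group {group!r}: n must be >= 1, got {self.n}")
        for name in ("map_mmhg", "lv_mass_g", "ef_pct", "sv_ml",
                     "lv_wall_mm", "septum_mm", "weight_kg", "creatinine_mg_dl"):
            getattr(self, name).validate(f"{group}.{name}")


@dataclass(frozen=True)
class CohortParams:
    """Full cohort generation model.

    ``map_rise_rate`` and ``map_rise_midpoint_week`` parameterize the
    logistic MAP trajectory ``rise(w)``, rescaled so rise(0) = 0 and
    rise(inf) = 1; weekly measurement noise is i.i.d. Gaussian.
    """

    groups: Mapping[str, GroupParams]
    weeks: tuple[int, ...] = tuple(range(9))
    map_noise_sd: float = 1.5
    map_rise_midpoint_week: float = 2.0
    map_rise_rate: float = 4.0

    def validate(self) -> None:
        if not self.groups:
            raise InvalidParameterError("at least one group required")
        if self.map_noise_sd < 0:
            raise InvalidParameterError("map_noise_sd must be >= 0")
        if not self.weeks:
            raise InvalidParameterError("at least one observation week required")
        for g, gp in self.groups.items():
            gp.validate(g)

    def rise(self, week) -> np.ndarray:
        """Normalized logistic trajectory fraction in [0, 1)."""
        w = np.asarray(week, dtype=float)
        logistic = 1.0 / (1.0 + np.exp(-self.map_rise_rate * (w - self.map_rise_midpoint_week)))
        l0 = 1.0 / (1.0 + np.exp(self.map_rise_rate * self.map_rise_midpoint_week))
        return (logistic - l0) / (1.0 - l0)

    def without_effects(self) -> "CohortParams":
        """Copy with every treatment effect and the weekly noise set to zero."""
        groups = {}
        for g, gp in self.groups.items():
            groups[g] = replace(
                gp,
                map_mmhg=replace(gp.map_mmhg, delta_mean=0.0, delta_sd=0.0),
                lv_mass_g=replace(gp.lv_mass_g, delta_mean=0.0, delta_sd=0.0),
                ef_pct=replace(gp.ef_pct, delta_mean=0.0, delta_sd=0.0),
                sv_ml=replace(gp.sv_ml, delta_mean=0.0, delta_sd=0.0),
            )
        return replace(self, groups=groups, map_noise_sd=0.0)


def default_cohort_params() -> CohortParams:
    """Defaults matching the published 8-week cohort tables.

    Paired-change SDs are taken from the published change statistics where
    printed (LV mass); otherwise they are derived from baseline/follow-up
    SDs under an independence assumption, sqrt(|sd_f^2 - sd_b^2|), floored
    at a small positive value.
    """

    def derived_sd(sd_b: float, sd_f: float, floor: float = 0.5) -> float:
        return max(float(np.sqrt(abs(sd_f ** 2 - sd_b ** 2))), floor)

    treated = GroupParams(
        n=9,
        map_mmhg=EndpointEffect(87.36, 5.3, 111.84 - 87.36, derived_sd(5.3, 6.9)),
        lv_mass_g=EndpointEffect(111.2, 12.6, 20.33, 13.16),
        ef_pct=EndpointEffect(49.44, 10.43, 42.89 - 49.44, derived_sd(10.43, 9.54)),
        sv_ml=EndpointEffect(51.78, 12.76, 43.78 - 51.78, derived_sd(12.76, 7.71)),
        lv_wall_mm=SingleMeasure(18.82, 4.6),
        septum_mm=SingleMeasure(17.27, 2.24),
        weight_kg=SingleMeasure(78.8, 4.5),
        creatinine_mg_dl=SingleMeasure(0.9, 0.1),
    )
    control = GroupParams(
        n=7,
        map_mmhg=EndpointEffect(89.44, 3.72, 90.49 - 89.44, derived_sd(3.72, 4.19)),
        lv_mass_g=EndpointEffect(109.8, 19.9, -0.2, 8.52),
        ef_pct=EndpointEffect(45.4, 8.79, 49.6 - 45.4, derived_sd(8.79, 11.9)),
        sv_ml=EndpointEffect(55.6, 6.65, 51.2 - 55.6, derived_sd(6.65, 15.51)),
        lv_wall_mm=SingleMeasure(12.14, 1.57),
        septum_mm=SingleMeasure(11.86, 1.57),
        weight_kg=SingleMeasure(73.5, 5.4),
        creatinine_mg_dl=SingleMeasure(1.0, 0.1),
    )
    return CohortParams(groups={GROUP_TREATED: treated, GROUP_CONTROL: control})


def generate_cohort(params: CohortParams, seed: int = 0) -> pd.DataFrame:
    """Draw a per-animal longitudinal cohort table (long over weeks).

    Returns a DataFrame with one row per (animal, week); the non-weekly
    endpoint columns are repeated on every row of an animal. Reproducible:
    a pure function of (params, seed).
    """
    params.validate()
    rng = np.random.default_rng(seed)
    weeks = np.asarray(sorted(params.weeks), dtype=int)
    rise = params.rise(weeks)

    frames = []
    for group in sorted(params.groups):
        gp = params.groups[group]
        prefix = group[:1]
        for i in range(gp.n):
            animal = f"{prefix}{i + 1:02d}"
            m = gp.map_mmhg
            map_base = rng.normal(m.baseline_mean, m.baseline_sd)
            map_delta = rng.normal(m.delta_mean, m.delta_sd)
            noise = (rng.normal(0.0, params.map_noise_sd, size=weeks.size)
                     if params.map_noise_sd > 0 else np.zeros(weeks.size))
            map_weekly = map_base + map_delta * rise + noise

            def paired(e: EndpointEffect) -> tuple[float, float]:
                base = rng.normal(e.baseline_mean, e.baseline_sd)
                return base, base + rng.normal(e.delta_mean, e.delta_sd)

            lv_b, lv_f = paired(gp.lv_mass_g)
            ef_b, ef_f = paired(gp.ef_pct)
            sv_b, sv_f = paired(gp.sv_ml)
            wall = rng.normal(gp.lv_wall_mm.mean, gp.lv_wall_mm.sd)
            septum = rng.normal(gp.septum_mm.mean, gp.septum_mm.sd)
            weight = rng.normal(gp.weight_kg.mean, gp.weight_kg.sd)
            crea = rng.normal(gp.creatinine_mg_dl.mean, gp.creatinine_mg_dl.sd)

            frames.append(pd.DataFrame({
                "animal_id": animal, "group": group, "week": weeks,
                "map_mmhg": map_weekly,
                "lv_mass_g_baseline": lv_b, "lv_mass_g_followup": lv_f,
                "ef_pct_baseline": ef_b, "ef_pct_followup": ef_f,
                "sv_ml_baseline": sv_b, "sv_ml_followup": sv_f,
                "lv_wall_mm": wall, "septum_mm": septum,
                "weight_kg": weight, "creatinine_mg_dl": crea,
            }))

    out = pd.concat(frames, ignore_index=True)
    return out[COHORT_COLUMNS]
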