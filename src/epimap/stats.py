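"""Cohort-level endpoint statistics.

Group summaries are mean +/- sample SD; baseline-vs-follow-up changes are
expressed as mean differences and percent changes; comparisons use
Student's t-test (pooled variance between groups, paired within group,
Gaussian assumed, no multiplicity adjustment) with significance stars at
0.05 / 0.01 / 0.001. Welch's variant is available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidParameterError

log = logging.getLogger(__name__)

#: star-coding thresholds on two-sided p
STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))

#: paired (baseline, follow-up) endpoint column stems in a cohort table
PAIRED_ENDPOINTS = ("lv_mass_g", "ef_pct", "sv_ml")
#: follow-up-only endpoints compared between groups
SINGLE_ENDPOINTS = ("lv_wall_mm", "septum_mm", "weight_kg", "creatinine_mg_dl")


class GroupSummary(NamedTuple):
    n: int
    mean: float
    sd: float


def summarize_group(values: Iterable[float]) -> GroupSummary:
    """n, mean and sample SD (n-1 denominator). n = 1 has no SD -> error."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise InvalidParameterError("cannot summarize an empty group")
    if v.size == 1:
        raise InvalidParameterError("group of size 1 has no sample SD")
    return GroupSummary(int(v.size), float(v.mean()), float(v.std(ddof=1)))


class PercentChange(NamedTuple):
    percent: float  # unrounded
    rounded: float  # displayed value, one decimal


def percent_change(baseline_mean: float, followup_mean: float) -> PercentChange:
    """100 * (follow-up - baseline) / baseline, with its one-decimal display value."""
    if baseline_mean == 0:
        raise InvalidParameterError("percent change undefined for zero baseline")
    pct = 100.0 * (followup_mean - baseline_mean) / baseline_mean
    return PercentChange(pct, round(pct, 1))


def mean_difference(baseline_mean: float, followup_mean: float) -> float:
    """Follow-up minus baseline (the companion of ``percent_change``)."""
    return followup_mean - baseline_mean


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    kind: str  # "unpaired" | "unpaired-welch" | "paired"
    zero_variance: bool = False  # p reported below the numeric floor


def students_t_unpaired(group_a: Sequence[float], group_b: Sequence[float],
                        welch: bool = False) -> TTestResult:
    """Two-sample Student's t-test (pooled variance; Welch behind a flag).

    df = n_a + n_b - 2 for the pooled test; two-sided p. Two constant,
    equal groups give t = 0, p = 1; constant but different groups are
    flagged with p below the numeric floor.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidParameterError("each group needs n >= 2")

    if welch:
        res = sps.ttest_ind(a, b, equal_var=False)
        return TTestResult(float(res.statistic), float(res.df),
                           float(res.pvalue), "unpaired-welch")

    na, nb = a.size, b.size
    df = na + nb - 2
    diff = a.mean() - b.mean()
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    se = np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    if se == 0:
        if diff == 0:
            return TTestResult(0.0, float(df), 1.0, "unpaired")
        t = np.inf if diff > 0 else -np.inf
        return TTestResult(float(t), float(df), 0.0, "unpaired", zero_variance=True)
    t = diff / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(p), "unpaired")


def students_t_paired(pre: Sequence[float], post: Sequence[float]) -> TTestResult:
    """Paired Student's t-test on post - pre differences; df = n - 1."""
    x = np.asarray(list(pre), dtype=float)
    y = np.asarray(list(post), dtype=float)
    if x.size != y.size:
        raise InvalidParameterError("paired test needs equal-length samples")
    if x.size < 2:
        raise InvalidParameterError("paired test needs n >= 2")

    d = y - x
    df = d.size - 1
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return TTestResult(0.0, float(df), 1.0, "paired")
        t = np.inf if d.mean() > 0 else -np.inf
        return TTestResult(float(t), float(df), 0.0, "paired", zero_variance=True)
    t = d.mean() / (sd / np.sqrt(d.size))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(p), "paired")


def p_stars(p: float) -> str:
    for thresh, stars in STAR_THRESHOLDS:
        if p <= thresh:
            return stars
    return ""


@dataclass(frozen=True)
class TrajectorySummary:
    """Weekly MAP group means +/- SD and the per-group plateau week."""

    weekly: pd.DataFrame  # columns: group, week, n, mean, sd
    plateau_week: dict  # group -> int (or None if never reached)
    plateau_fraction: float


def map_trajectory_summary(cohort: pd.DataFrame,
                           plateau_fraction: float = 0.95) -> TrajectorySummary:
    """Weekly group means of MAP and the first week reaching the plateau.

    The plateau threshold is ``plateau_fraction`` times the mean of the
    final four observed weekly group means. Missing weekly values are
    omitted (never interpolated); a week missing for a whole group is
    excluded with a warning.
    """
    if not 0 < plateau_fraction <= 1:
        raise InvalidParameterError("plateau_fraction must be in (0, 1]")
    if cohort.empty:
        raise InvalidParameterError("empty cohort")

    obs = cohort.dropna(subset=["map_mmhg"])
    all_weeks = sorted(cohort["week"].unique())
    rows = []
    plateau: dict = {}
    for group, gdf in obs.groupby("group", sort=True):
        weekly = (gdf.groupby("week")["map_mmhg"]
                  .agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1))
                  .reset_index())
        missing = set(all_weeks) - set(weekly["week"])
        if missing:
            log.warning("group %s: weeks %s have no MAP data; excluded",
                        group, sorted(missing))
        weekly.insert(0, "group", group)
        rows.append(weekly)

        means = weekly.sort_values("week")
        tail = means["mean"].tail(4).mean()
        thresh = plateau_fraction * tail
        reached = means.loc[means["mean"] >= thresh, "week"]
        plateau[group] = int(reached.iloc[0]) if not reached.empty else None

    return TrajectorySummary(weekly=pd.concat(rows, ignore_index=True),
                             plateau_week=plateau,
                             plateau_fraction=float(plateau_fraction))


@dataclass(frozen=True)
class EndpointSummary:
    """One comparison record of the endpoint report.

    For ``comparison == "paired"`` the record compares baseline (a) vs
    follow-up (b) within ``group``; for ``"unpaired"`` it compares the two
    groups' follow-up values (group a = first label, b = second).
    """

    endpoint: str
    comparison: str  # "paired" | "unpaired"
    group: str  # group name, or "a_vs_b" label for unpaired
    n_a: int
    mean_a: float
    sd_a: float
    n_b: int
    mean_b: float
    sd_b: float
    mean_difference: float
    percent_change: float
    percent_change_rounded: float
    t: float
    df: float
    p: float
    stars: str
    zero_variance: bool = False

    def to_record(self) -> dict:
        return asdict(self)


def _per_animal(cohort: pd.DataFrame) -> pd.DataFrame:
    """Collapse the long cohort table to one row per animal, adding MAP
    baseline (first observed week) and follow-up (last observed week)."""
    static_cols = [c for c in cohort.columns if c not in ("week", "map_mmhg")]
    per = cohort.sort_values("week").groupby("animal_id", sort=True)
    first = per.first().reset_index()[["animal_id"] +
                                     [c for c in static_cols if c != "animal_id"]]
    obs = cohort.dropna(subset=["map_mmhg"]).sort_values("week")
    map_base = obs.groupby("animal_id")["map_mmhg"].first()
    map_follow = obs.groupby("animal_id")["map_mmhg"].last()
    first["map_mmhg_baseline"] = first["animal_id"].map(map_base)
    first["map_mmhg_followup"] = first["animal_id"].map(map_follow)
    return first


def _comparison(endpoint: str, comparison: str, group: str,
                a: np.ndarray, b: np.ndarray, test: TTestResult) -> EndpointSummary:
    sa, sb = summarize_group(a), summarize_group(b)
    diff = mean_difference(sa.mean, sb.mean)
    if sa.mean != 0:
        pct = percent_change(sa.mean, sb.mean)
    else:
        pct = PercentChange(float("nan"), float("nan"))
    return EndpointSummary(
        endpoint=endpoint, comparison=comparison, group=group,
        n_a=sa.n, mean_a=sa.mean, sd_a=sa.sd,
        n_b=sb.n, mean_b=sb.mean, sd_b=sb.sd,
        mean_difference=diff, percent_change=pct.percent,
        percent_change_rounded=pct.rounded,
        t=test.t, df=test.df, p=test.p, stars=p_stars(test.p),
        zero_variance=test.zero_variance)


def endpoint_report(cohort: pd.DataFrame, welch: bool = False) -> list[EndpointSummary]:
    """Full endpoint analysis of a cohort table.

    For every paired endpoint (weekly MAP plus the baseline/follow-up
    pairs): a paired within-group test per group and, when two groups are
    present, an unpaired between-group test at follow-up. Follow-up-only
    endpoints get the between-group test only. Endpoints absent for a
    whole group are skipped with a logged reason. Deterministic given the
    cohort table.
    """
    animals = _per_animal(cohort)
    groups = sorted(animals["group"].unique())
    out: list[EndpointSummary] = []

    paired_stems = ("map_mmhg",) + PAIRED_ENDPOINTS
    for stem in paired_stems:
        bcol, fcol = f"{stem}_baseline", f"{stem}_followup"
        if bcol not in animals.columns or fcol not in animals.columns:
            continue
        usable_groups = []
        for g in groups:
            sub = animals[animals["group"] == g]
            pre = sub[bcol].to_numpy(dtype=float)
            post = sub[fcol].to_numpy(dtype=float)
            ok = np.isfinite(pre) & np.isfinite(post)
            if ok.sum() < 2:
                log.warning("endpoint %s absent/insufficient for group %s; skipped",
                            stem, g)
                continue
            pre, post = pre[ok], post[ok]
            test = students_t_paired(pre, post)
            out.append(_comparison(stem, "paired", g, pre, post, test))
            usable_groups.append((g, post))
        if len(usable_groups) == 2:
            (ga, va), (gb, vb) = usable_groups
            test = students_t_unpaired(va, vb, welch=welch)
            out.append(_comparison(stem, "unpaired", f"{ga}_vs_{gb}", va, vb, test))

    for stem in SINGLE_ENDPOINTS:
        if stem not in animals.columns:
            continue
        usable = []
        for g in groups:
            vals = animals.loc[animals["group"] == g, stem].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size < 2:
                log.warning("endpoint %s absent/insufficient for group %s; skipped",
                            stem, g)
                continue
            usable.append((g, vals))
        if len(usable) == 2:
            (ga, va), (gb, vb) = usable
            test = students_t_unpaired(va, vb, welch=welch)
            out.append(_comparison(stem, "unpaired", f"{ga}_vs_{gb}", va, vb, test))

    return out


def report_frame(summaries: list[EndpointSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.to_record() for s in summaries])
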