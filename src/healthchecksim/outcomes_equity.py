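"""Outcome metrics from paired event histories.

Turns the programme and counterfactual arms of a run into the reported
metrics: incident cases prevented by 80 and by 100 (per disease), additional
people alive and free of all four diseases, premature deaths prevented
(before 75 and 80), QALY and life-year totals, per-head / per-eligible /
per-attender / per-check days, deprivation-quintile breakdowns, and the
England-per-year annualisation.

QALYs use a utility table (baseline by age band, multiplicative deprivation
adjustment, multiplicative disease decrements — multiplicative combination
keeps multimorbidity utilities positive).  The death year contributes a half
cycle of person-time; premature-death counts use the recorded event-log age
with no half-cycle.  Per-quintile metrics are computed within the paired
arms before any scaling, so quintile population sizes cancel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import load_json_data

QUINTILES = (1, 2, 3, 4, 5)
DISEASES = ("ihd", "stroke", "dementia", "lung_cancer")
DAYS_PER_YEAR = 365.25


@dataclass
class DisutilityTable:
    """Utility by age band and deprivation, with disease decrements."""

    params: dict

    def __post_init__(self):
        for band in self.params["age_bands"]:
            if not 0.0 <= band["utility"] <= 1.0:
                raise ValueError("baseline utilities must lie in [0,1]")
        for mult in self.params["disease_multiplier"].values():
            if not 0.0 <= mult <= 1.0:
                raise ValueError("disease multipliers must lie in [0,1]")

    @classmethod
    def default(cls) -> "DisutilityTable":
        return cls(load_json_data("eq5d_utilities.json"))

    def utility(self, age, quintile, **disease_flags) -> np.ndarray:
        age = np.asarray(age)
        bounds = np.array([b["max_age"] for b in self.params["age_bands"]])
        base = np.array([b["utility"] for b in self.params["age_bands"]])
        u = base[np.searchsorted(bounds, age)]
        dep = np.array([1.0] + [self.params["deprivation_multiplier"][str(i)] for i in QUINTILES])
        u = u * dep[np.asarray(quintile, dtype=int)]
        for disease, flag in disease_flags.items():
            mult = self.params["disease_multiplier"].get(disease)
            if mult is None:
                raise KeyError(f"no utility decrement for disease '{disease}'")
            u = u * np.where(np.asarray(flag, dtype=bool), mult, 1.0)
        return u


def qalys(history: pd.DataFrame, table: DisutilityTable | None = None,
          half_cycle_death_year: bool = True) -> float:
    """QALYs of one scripted person-year history.

    ``history`` has one row per simulated year with columns ``age``,
    ``deprivation``, the disease flags, and ``died`` marking the death year
    (which contributes half a cycle when the convention is on).
    """
    table = table or DisutilityTable.default()
    flags = {d: history[d].to_numpy() for d in (*DISEASES, "tia") if d in history.columns}
    u = table.utility(history["age"].to_numpy(), history["deprivation"].to_numpy(), **flags)
    died = history["died"].to_numpy() if "died" in history.columns else np.zeros(len(history), bool)
    frac = np.where(died & half_cycle_death_year, 0.5, 1.0)
    return float((u * frac).sum())


@dataclass
class OutcomeTable:
    """Flat metric dictionary for one scenario-vs-reference run."""

    metrics: dict[str, float]
    n: int

    def __getitem__(self, key: str) -> float:
        return self.metrics[key]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"metric": k, "value": v} for k, v in self.metrics.items()]
        )


def _free_at(state, age_cut: float) -> np.ndarray:
    alive_at = np.isnan(state.death_age) | (state.death_age >= age_cut)
    free = alive_at
    for d in DISEASES:
        free = free & ~(state.first_age[d] < age_cut)
    return free


def compare_arms(programme, counterfactual, annualisation_factor: float = 0.73) -> OutcomeTable:
    """Paired per-individual differences, scaled to per-million-at-baseline.

    ``programme`` and ``counterfactual`` are :class:`engine.ArmResult`
    objects sharing the same individuals and random numbers.  Positive values
    mean the programme arm does better (cases/deaths prevented, QALYs and
    life-years gained).
    """
    if programme.n != counterfactual.n or not np.array_equal(programme.quintile, counterfactual.quintile):
        raise ValueError("arms do not share a cohort")
    n = programme.n
    scale = 1e6 / n
    p, c = programme.state, counterfactual.state
    q = programme.quintile
    m: dict[str, float] = {}

    for cut, label in ((80, "80"), (100, "100")):
        for d in DISEASES:
            m[f"cases_prevented_by_{label}.{d}"] = (
                np.count_nonzero(c.first_age[d] < cut) - np.count_nonzero(p.first_age[d] < cut)
            ) * scale
        m[f"disease_free_at_{label}"] = (
            np.count_nonzero(_free_at(p, cut)) - np.count_nonzero(_free_at(c, cut))
        ) * scale
    for cut in (75, 80):
        m[f"deaths_prevented_under_{cut}"] = (
            np.count_nonzero(c.death_age < cut) - np.count_nonzero(p.death_age < cut)
        ) * scale

    d_qaly = p.qalys - c.qalys
    d_ly = p.life_years - c.life_years
    m["qaly_total_per_million"] = d_qaly.sum() * scale
    m["ly_total_per_million"] = d_ly.sum() * scale
    m["qaly_days_per_head"] = d_qaly.mean() * DAYS_PER_YEAR
    m["ly_days_per_head"] = d_ly.mean() * DAYS_PER_YEAR
    # compression-of-morbidity surface: positive when the programme adds more
    # quality-adjusted time than raw survival time per head
    m["morbidity_compression_days"] = m["qaly_days_per_head"] - m["ly_days_per_head"]
    n_eligible = max(int(p.ever_eligible.sum()), 1)
    n_attender = max(int(p.ever_attended.sum()), 1)
    n_checks = max(int(p.n_checks.sum()), 1)
    m["qaly_days_per_eligible"] = d_qaly.sum() * DAYS_PER_YEAR / n_eligible
    m["qaly_days_per_attender"] = d_qaly.sum() * DAYS_PER_YEAR / n_attender
    m["qaly_days_per_check"] = d_qaly.sum() * DAYS_PER_YEAR / n_checks
    for quint in QUINTILES:
        sel = q == quint
        if sel.any():
            m[f"qaly_days_per_head.q{quint}"] = d_qaly[sel].mean() * DAYS_PER_YEAR
            m[f"ly_days_per_head.q{quint}"] = d_ly[sel].mean() * DAYS_PER_YEAR
        else:
            m[f"qaly_days_per_head.q{quint}"] = 0.0
            m[f"ly_days_per_head.q{quint}"] = 0.0

    # process measures for the programme arm (% of population)
    m["pct_ever_eligible"] = 100.0 * p.ever_eligible.mean()
    m["pct_ever_attended"] = 100.0 * p.ever_attended.mean()
    m["checks_per_head"] = float(p.n_checks.mean())
    offered_any = np.zeros(n, dtype=bool)
    for t, arr in p.offered.items():
        m[f"pct_offered_{t}"] = 100.0 * arr.mean()
        m[f"pct_treated_{t}"] = 100.0 * p.treated[t].mean()
        offered_any |= arr
    m["pct_offered_any"] = 100.0 * offered_any.mean()

    m["deaths_prevented_under_80_per_england_year"] = annualise(
        m["deaths_prevented_under_80"], annualisation_factor
    )
    m["disease_free_at_80_per_england_year"] = annualise(
        m["disease_free_at_80"], annualisation_factor
    )
    return OutcomeTable(metrics=m, n=n)


def annualise(per_million_value: float, factor: float = 0.73) -> float:
    """Scale a lifetime per-million-cohort value to an England-per-year value
    (roughly 730,000 adults turn 40 each year)."""
    return per_million_value * factor


def equity_summary(table: OutcomeTable) -> dict:
    """Most- vs least-deprived per-head QALY gain and the equity direction.

    A scenario is equity-improving when the most deprived quintile (Q5)
    gains more quality-adjusted time per head than the least deprived (Q1).
    """
    q5 = table[f"qaly_days_per_head.q5"]
    q1 = table[f"qaly_days_per_head.q1"]
    return {
        "q5_days_per_head": q5,
        "q1_days_per_head": q1,
        "difference": q5 - q1,
        "equity_improving": bool(q5 > q1),
    }


def summarise_runs(tables: list[OutcomeTable]) -> pd.DataFrame:
    """Mean and 2.5/97.5 percentile summary across repeated runs."""
    keys = tables[0].metrics.keys()
    rows = []
    for k in keys:
        vals = np.array([t.metrics[k] for t in tables])
        rows.append({
            "metric": k, "mean": vals.mean(),
            "lo95": np.percentile(vals, 2.5), "hi95": np.percentile(vals, 97.5),
        })
    return pd.DataFrame(rows)
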