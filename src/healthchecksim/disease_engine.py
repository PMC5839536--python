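"""Hazards, event draws and calibration.

The risk scores supply the *relative* ordering of individuals; absolute
levels are anchored to the derived incidence tables by a proportional
calibration per age-sex cell: an individual's annual hazard is

    h_i = incidence(age, sex) * score_i / mean_score(age, sex)

where the cell mean is taken over alive, disease-free individuals on their
counterfactual (untreated) factor paths, so treatment shifts hazards relative
to the anchored baseline.  An extra multiplicative hazard ratio applies to
the CVD hazard of individuals on statins, calibrated so the simulated 5-year
event-rate reduction matches the configured trial value (cholesterol-mediated
risk change alone understates trial efficacy).

New CVD events are allocated to ischaemic heart disease or stroke by the
age-sex incidence shares, then to acute MI vs other IHD presentation
(58%/44% for men/women) and full stroke vs TIA (60:40), with acute fatality
by event type; survivors adopt the chronic case fatality from the next year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import SEXES
from .dismod_rates import AcuteFatalityParams, RateTable

logger = logging.getLogger(__name__)

#: event codes recorded in the event log
EVENT_CODES = {
    "mi": 0, "other_ihd": 1, "stroke": 2, "tia": 3,
    "dementia": 4, "lung_cancer": 5, "other_death": 6,
}


def cell_index(age: np.ndarray, sex_code: np.ndarray, age0: int = 40, max_age: int = 100) -> np.ndarray:
    clamped = np.clip(np.asarray(age, dtype=int), age0, max_age)
    return (clamped - age0) * 2 + np.asarray(sex_code, dtype=int)


def cell_mean_scores(
    scores: np.ndarray,
    age: np.ndarray,
    sex_code: np.ndarray,
    mask: np.ndarray,
    n_ages: int = 61,
    age0: int = 40,
    min_cell_size: int = 20,
) -> np.ndarray:
    """Mean score per (age, sex) cell over ``mask`` rows, with sparse-cell
    fallback to the 5-year age band and then the sex-wide mean."""
    n_cells = n_ages * 2
    idx = cell_index(age, sex_code, age0)
    sums = np.bincount(idx[mask], weights=scores[mask], minlength=n_cells)
    counts = np.bincount(idx[mask], minlength=n_cells)
    means = np.full(n_cells, np.nan)
    ok = counts >= min_cell_size
    means[ok] = sums[ok] / counts[ok]
    if not ok.all():
        for s in (0, 1):
            cells = np.arange(s, n_cells, 2)
            c_sum, c_cnt = sums[cells], counts[cells]
            # 5-year band fallback
            band = np.arange(len(cells)) // 5
            b_sum = np.bincount(band, weights=c_sum)
            b_cnt = np.bincount(band, weights=c_cnt)
            sex_mean = c_sum.sum() / c_cnt.sum() if c_cnt.sum() > 0 else 1.0
            for j, cell in enumerate(cells):
                if not ok[cell]:
                    if b_cnt[band[j]] >= min_cell_size:
                        means[cell] = b_sum[band[j]] / b_cnt[band[j]]
                    else:
                        means[cell] = sex_mean
    return means


@dataclass
class HazardCalibration:
    """Per age-sex multiplicative factors mapping score to absolute hazard."""

    factors: np.ndarray  # flat cell array, index = (age-age0)*2 + sex_code
    age0: int = 40
    statin_extra_multiplier: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.statin_extra_multiplier <= 1.0:
            raise ValueError("statin multiplier must lie in (0, 1]")

    def hazard(self, scores: np.ndarray, age: np.ndarray, sex_code: np.ndarray) -> np.ndarray:
        return np.clip(self.factors[cell_index(age, sex_code, self.age0)] * scores, 0.0, 1.0)


def calibrate_hazards(
    scores: np.ndarray,
    age: np.ndarray,
    sex_code: np.ndarray,
    incidence_by_cell: np.ndarray,
    mask: np.ndarray | None = None,
    min_cell_size: int = 20,
    age0: int = 40,
) -> HazardCalibration:
    """Calibration factors c(a,s) = incidence(a,s) / mean_score(a,s).

    ``incidence_by_cell`` is a flat cell array aligned with
    :func:`cell_index`.  With a homogeneous cohort (identical scores) the
    resulting cohort hazard equals the table incidence exactly; doubling all
    scores halves every factor.
    """
    mask = np.ones(len(scores), dtype=bool) if mask is None else mask
    n_ages = len(incidence_by_cell) // 2
    means = cell_mean_scores(scores, age, sex_code, mask, n_ages=n_ages, age0=age0,
                             min_cell_size=min_cell_size)
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = np.where(means > 0, incidence_by_cell / means, 0.0)
    return HazardCalibration(factors=np.nan_to_num(factors), age0=age0)


def table_cells(table: RateTable, column: str) -> np.ndarray:
    """Flatten one column of a rate table to the (age, sex) cell layout."""
    n = len(table.ages)
    out = np.empty(n * 2)
    for s_code, sex in enumerate(SEXES):
        out[s_code::2] = getattr(table, column)[sex]
    return out


# ---------------------------------------------------------------------------
# Event allocation


@dataclass
class CvdAllocationParams:
    """Subtype mix and acute fatality for new CVD events."""

    acute: AcuteFatalityParams
    ihd_share_by_cell: np.ndarray  # P(event is IHD | first CVD event), per cell
    age0: int = 40

    def allocate(
        self,
        event: np.ndarray,        # bool: had a first CVD event this year
        age: np.ndarray,
        sex_code: np.ndarray,
        u_type: np.ndarray,
        u_sub: np.ndarray,
        u_fatal: np.ndarray,
        mi_cf_mult: float = 1.0,
        stroke_cf_mult: float = 1.0,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Return (event_code, fatal) arrays; code -1 where no event.

        IHD vs stroke by the age-sex incidence share; MI vs other IHD by the
        sex-specific acute-MI fraction; full stroke vs TIA 60:40.  Acute
        fatality: MI by sex, full stroke by sex and the 80-year threshold,
        other IHD presentations and TIAs non-fatal in the event year.
        """
        n = len(event)
        code = np.full(n, -1, dtype=int)
        fatal = np.zeros(n, dtype=bool)
        if not event.any():
            return code, fatal
        female = sex_code == 1
        p_ihd = self.ihd_share_by_cell[cell_index(age, sex_code, self.age0)]
        is_ihd = event & (u_type < p_ihd)
        is_str = event & ~is_ihd
        mi_frac = np.where(female, self.acute.mi_fraction["female"], self.acute.mi_fraction["male"])
        is_mi = is_ihd & (u_sub < mi_frac)
        code[is_mi] = EVENT_CODES["mi"]
        code[is_ihd & ~is_mi] = EVENT_CODES["other_ihd"]
        full = is_str & (u_sub < self.acute.stroke_full_fraction)
        code[full] = EVENT_CODES["stroke"]
        code[is_str & ~full] = EVENT_CODES["tia"]
        mi_cf = np.where(female, self.acute.mi_acute_cf["female"], self.acute.mi_acute_cf["male"])
        st_cf = np.where(
            age < 80,
            np.where(female, self.acute.stroke_acute_cf["under_80"]["female"],
                     self.acute.stroke_acute_cf["under_80"]["male"]),
            np.where(female, self.acute.stroke_acute_cf["over_80"]["female"],
                     self.acute.stroke_acute_cf["over_80"]["male"]),
        )
        fatal[is_mi] = u_fatal[is_mi] < mi_cf[is_mi] * mi_cf_mult
        fatal[full] = u_fatal[full] < st_cf[full] * stroke_cf_mult
        return code, fatal


def other_cause_probability(
    qx: np.ndarray, modelled_cause_mortality: np.ndarray
) -> np.ndarray:
    """All-cause minus modelled-cause annual death probability, floored at 0."""
    adj = qx - modelled_cause_mortality
    n_neg = int(np.count_nonzero(adj < 0))
    if n_neg:
        logger.warning("other-cause adjustment floored at 0 for %d cells", n_neg)
    return np.clip(adj, 0.0, 1.0)


def assign_baseline_disease(
    scores: np.ndarray,
    age: np.ndarray,
    sex_code: np.ndarray,
    prevalence_by_cell: np.ndarray,
    u: np.ndarray,
    age0: int = 40,
) -> np.ndarray:
    """Baseline disease flags with probability proportional to the score,
    matching the target prevalence in every age-sex cell."""
    n_ages = len(prevalence_by_cell) // 2
    means = cell_mean_scores(scores, age, sex_code, np.ones(len(scores), bool), n_ages=n_ages, age0=age0)
    idx = cell_index(age, sex_code, age0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(means[idx] > 0, prevalence_by_cell[idx] * scores / means[idx], 0.0)
    return u < np.clip(p, 0.0, 1.0)


def calibrate_statin_multiplier(
    run_5yr_event_ratio,
    target_5yr_rr: float,
    tol: float = 0.005,
    bracket: tuple[float, float] = (0.05, 1.0),
) -> float:
    """Find the extra CVD hazard ratio for statin users by bisection.

    ``run_5yr_event_ratio(multiplier)`` must return the simulated 5-year
    cumulative CVD event ratio of a statin arm versus a no-statin arm under
    common random numbers (the engine provides this).  Raises if the target
    is below what even a zero multiplier can achieve or above the
    cholesterol-mediated ratio at multiplier 1.
    """
    if not 0.0 < target_5yr_rr <= 1.0:
        raise ValueError("target 5-year relative risk must lie in (0, 1]")
    lo, hi = bracket
    r_hi = run_5yr_event_ratio(hi)
    if r_hi <= target_5yr_rr + tol / 2:
        # cholesterol-mediated reduction alone already reaches the target
        if r_hi < target_5yr_rr - tol:
            raise ValueError(
                f"target RR {target_5yr_rr} unattainable: cholesterol effect alone gives {r_hi:.3f}"
            )
        return hi
    r_lo = run_5yr_event_ratio(lo)
    if r_lo > target_5yr_rr:
        raise ValueError(
            f"target RR {target_5yr_rr} unattainable: ratio at multiplier {lo} is {r_lo:.3f}"
        )
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        r = run_5yr_event_ratio(mid)
        if abs(r - target_5yr_rr) < tol / 2 or (hi - lo) < 1e-4:
            return mid
        if r > target_5yr_rr:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
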