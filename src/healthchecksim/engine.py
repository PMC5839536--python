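"""Paired-arm annual-cycle simulation engine.

One :class:`Simulation` holds the shared inputs — baseline cohort, donor
matcher, solved and recalibrated rate tables, lifetable — and advances two
(or more) programme arms in lockstep over annual cycles from the baseline
ages to 100.  All stochastic inputs for a cycle are drawn once, in a fixed
order, and consumed by every arm: with identical policies the arms are
byte-identical (common random numbers), so paired differences isolate the
programme effect and the null programme yields exactly zero differences.

Within-year event order: (1) counterfactual risk-factor advance by donor
matching, (2) health-check process (offer, attendance, treatment initiation,
adherence update), (3) disease events and chronic-case deaths, (4) other-
cause death, then the age increments.  The counterfactual factor and smoking
trajectories are shared across arms; each arm sees them through its own
active treatment offsets and programme-quit overrides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import FACTORS, SEXES, load_default_config
from .dismod_rates import AcuteFatalityParams, LifeTable, RateTable, SmokingSplitParams, split_incidence_by_smoking
from .disease_engine import (
    EVENT_CODES,
    CvdAllocationParams,
    calibrate_hazards,
    cell_index,
    other_cause_probability,
    assign_baseline_disease,
    table_cells,
)
from .health_check import (
    AdherenceParams,
    ClipLog,
    EligibilityCriteria,
    OfferAttendParams,
    TreatmentEffectParams,
    TreatmentUptakeParams,
    active_offsets,
)
from .outcomes_equity import DisutilityTable
from .risk_scores import CaidePointsTable, CvdCoefficientSet, classify_risk_band
from .trajectory_engine import DonorMatcher, advance_year, apply_offsets

AGE0 = 40
MAX_AGE = 100
N_AGES = MAX_AGE - AGE0 + 1
DISEASES = ("ihd", "stroke", "dementia", "lung_cancer")


class _FastCvdScorer:
    """Vectorised per-cohort CVD score with per-individual coefficient arrays
    (sex and static covariates folded in once).  Matches
    :func:`risk_scores.cvd_10yr_risk` exactly."""

    def __init__(self, coeffs: CvdCoefficientSet, cohort: pd.DataFrame):
        n = len(cohort)
        self.s0 = coeffs.baseline_survival(cohort["sex"].to_numpy())
        self.static = np.zeros(n)
        self.co = {k: np.zeros(n) for k in
                   ("age", "age_squared", "sbp", "tchdl", "bmi", "smoking_ex", "smoking_current")}
        self.ref = {k: np.zeros(n) for k in ("age", "sbp", "tchdl", "bmi")}
        for sex in SEXES:
            m = (cohort["sex"] == sex).to_numpy()
            if not m.any():
                continue
            p = coeffs.params[sex]
            co, ref = p["coefficients"], p["reference"]
            for k in self.co:
                self.co[k][m] = co.get(k, 0.0)
            for k in self.ref:
                self.ref[k][m] = ref[k]
            eth = cohort["ethnicity"].to_numpy()[m]
            self.static[m] = (
                np.vectorize(lambda e: co["ethnicity"][e])(eth).astype(float)
                + co["deprivation"] * (cohort["deprivation"].to_numpy()[m] - ref["deprivation"])
                + co["diabetes"] * cohort["diabetes"].to_numpy()[m]
                + co["treated_hypertension"] * cohort["treated_hypertension"].to_numpy()[m]
            )

    def __call__(self, age, sbp, tc, hdl, bmi, smoking) -> np.ndarray:
        from .risk_scores import CVD_AGE_RANGE

        da = np.clip(age, *CVD_AGE_RANGE) - self.ref["age"]
        lp = (
            self.static
            + self.co["age"] * da + self.co["age_squared"] * da * da
            + self.co["sbp"] * (sbp - self.ref["sbp"])
            + self.co["tchdl"] * (tc / hdl - self.ref["tchdl"])
            + self.co["bmi"] * (bmi - self.ref["bmi"])
            + np.where(smoking == "current", self.co["smoking_current"],
                       np.where(smoking == "ex", self.co["smoking_ex"], 0.0))
        )
        return 1.0 - self.s0 ** np.exp(lp)


class _FastCaideScorer:
    def __init__(self, table: CaidePointsTable, cohort: pd.DataFrame):
        p = table.params
        self.p = p
        self.static = (
            np.vectorize(lambda e: p["education"][e])(cohort["education"].to_numpy()).astype(int)
            + np.vectorize(lambda s: p["sex"][s])(cohort["sex"].to_numpy()).astype(int)
            + int(p["activity_points"])
        )
        self.bounds = np.array([b["max_age"] for b in p["age_bands"]])
        self.age_pts = np.array([b["points"] for b in p["age_bands"]])
        self.map_max = np.array([m["max_points"] for m in p["risk_mapping"]])
        self.map_risk = np.array([m["risk"] for m in p["risk_mapping"]])

    def __call__(self, age, sbp, bmi, tc) -> np.ndarray:
        pts = (
            self.static
            + self.age_pts[np.searchsorted(self.bounds, age)]
            + np.where(sbp > self.p["sbp_threshold"], self.p["sbp_points"], 0)
            + np.where(bmi > self.p["bmi_threshold"], self.p["bmi_points"], 0)
            + np.where(tc > self.p["tc_threshold"], self.p["tc_points"], 0)
        )
        return self.map_risk[np.searchsorted(self.map_max, np.minimum(pts, self.map_max[-1]))]


@dataclass
class TrendAdjuster:
    """Multiplicative calendar-time declines in CVD incidence and fatality,
    plateauing after ``plateau_year``."""

    ihd_incidence_decline: dict[str, float]
    stroke_incidence_decline: float
    ihd_case_fatality_decline: float
    stroke_case_fatality_decline: float
    plateau_year: int = 20

    @classmethod
    def from_config(cls, config: dict | None = None) -> "TrendAdjuster":
        config = config if config is not None else load_default_config()
        t = config["trends"]
        return cls(
            ihd_incidence_decline=dict(t["ihd_incidence_decline"]),
            stroke_incidence_decline=float(t["stroke_incidence_decline"]),
            ihd_case_fatality_decline=float(t["ihd_case_fatality_decline"]),
            stroke_case_fatality_decline=float(t["stroke_case_fatality_decline"]),
            plateau_year=int(t["plateau_year"]),
        )

    def incidence_factor(self, disease: str, year: int, sex_code: np.ndarray) -> np.ndarray | float:
        y = min(year, self.plateau_year)
        if disease == "ihd":
            d = np.where(sex_code == 1, self.ihd_incidence_decline["female"],
                         self.ihd_incidence_decline["male"])
            return (1.0 - d) ** y
        if disease == "stroke":
            return (1.0 - self.stroke_incidence_decline) ** y
        return 1.0

    def fatality_factor(self, disease: str, year: int) -> float:
        y = min(year, self.plateau_year)
        if disease == "ihd":
            return (1.0 - self.ihd_case_fatality_decline) ** y
        if disease == "stroke":
            return (1.0 - self.stroke_case_fatality_decline) ** y
        return 1.0


@dataclass
class ArmPolicy:
    """Programme configuration for one simulation arm."""

    enabled: bool = True
    criteria: EligibilityCriteria = field(default_factory=EligibilityCriteria)
    offer: OfferAttendParams = field(default_factory=OfferAttendParams)
    uptake: TreatmentUptakeParams = field(default_factory=TreatmentUptakeParams)
    adherence: AdherenceParams = field(default_factory=AdherenceParams)
    effects: TreatmentEffectParams = field(default_factory=TreatmentEffectParams)
    statin_extra_multiplier: float = 0.85
    # scenario dials
    attendance_boost: float = 1.0
    attendance_boost_group: str = "none"   # none|all|deprived|smokers|highrisk
    offer_boost_nonattenders: float = 1.0

    @classmethod
    def from_config(cls, config: dict | None = None, enabled: bool = True) -> "ArmPolicy":
        config = config if config is not None else load_default_config()
        return cls(
            enabled=enabled,
            criteria=EligibilityCriteria.from_config(config),
            offer=OfferAttendParams.from_config(config),
            uptake=TreatmentUptakeParams.from_config(config),
            adherence=AdherenceParams.from_config(config),
            effects=TreatmentEffectParams.from_config(config),
            statin_extra_multiplier=float(config["disease_model"].get("statin_extra_multiplier", 0.85)),
        )

    @classmethod
    def null(cls, config: dict | None = None) -> "ArmPolicy":
        """The no-programme counterfactual arm."""
        return cls.from_config(config, enabled=False)


class ArmState:
    def __init__(self, n: int):
        self.alive = np.ones(n, dtype=bool)
        self.flags = {d: np.zeros(n, dtype=bool) for d in DISEASES}
        self.tia = np.zeros(n, dtype=bool)
        self.quit_active = np.zeros(n, dtype=bool)
        self.pending_quit = np.zeros(n, dtype=bool)
        self.quit_year = np.full(n, -1)
        self.on_statin = np.zeros(n, dtype=bool)
        self.on_aht = np.zeros(n, dtype=bool)
        self.statin_year = np.full(n, -10)
        self.aht_year = np.full(n, -10)
        self.weight_year = np.full(n, -10)
        self.weight_active = np.zeros(n, dtype=bool)
        self.last_offer_year = np.full(n, -99)
        self.last_attend_year = np.full(n, -99)
        self.death_age = np.full(n, np.nan)
        self.death_cause = np.full(n, -1)
        self.first_age = {d: np.full(n, np.nan) for d in DISEASES}
        self.tia_age = np.full(n, np.nan)
        self.cvd_event_code = np.full(n, -1)
        self.qalys = np.zeros(n)
        self.life_years = np.zeros(n)
        self.trajectory: list[dict[str, np.ndarray]] = []  # debug factor dumps
        self.ever_eligible = np.zeros(n, dtype=bool)
        self.ever_attended = np.zeros(n, dtype=bool)
        self.n_offers = np.zeros(n, dtype=int)
        self.n_checks = np.zeros(n, dtype=int)
        self.offered = {t: np.zeros(n, dtype=bool) for t in ("statin", "antihypertensive", "smoking", "weight")}
        self.treated = {t: np.zeros(n, dtype=bool) for t in ("statin", "antihypertensive", "smoking", "weight")}

    def has_cvd(self) -> np.ndarray:
        return self.flags["ihd"] | self.flags["stroke"] | self.tia


@dataclass
class ArmResult:
    """Per-individual outcome arrays for one arm."""

    n: int
    quintile: np.ndarray
    state: ArmState
    clip_report: dict[str, int]
    #: per-year counterfactual factor dumps when trajectories are collected
    counterfactual_trajectory: list = field(default_factory=list)

    def events_frame(self) -> pd.DataFrame:
        """Tidy event log (person, age, event, fatal)."""
        code_names = {v: k for k, v in EVENT_CODES.items()}
        rows = []
        st = self.state
        for d in ("dementia", "lung_cancer"):
            idx = np.flatnonzero(~np.isnan(st.first_age[d]))
            rows.append(pd.DataFrame({
                "person": idx, "age": st.first_age[d][idx], "event": d,
                "fatal": st.death_cause[idx] == DISEASES.index(d),
            }))
        cvd = np.flatnonzero(st.cvd_event_code >= 0)
        ages = np.where(~np.isnan(st.first_age["ihd"][cvd]), st.first_age["ihd"][cvd],
                        np.where(~np.isnan(st.first_age["stroke"][cvd]),
                                 st.first_age["stroke"][cvd], st.tia_age[cvd]))
        rows.append(pd.DataFrame({
            "person": cvd, "age": ages,
            "event": [code_names[c] for c in st.cvd_event_code[cvd]],
            "fatal": st.death_age[cvd] == ages,
        }))
        deaths = np.flatnonzero(st.death_cause == 4)
        rows.append(pd.DataFrame({
            "person": deaths, "age": st.death_age[deaths], "event": "other_death",
            "fatal": True,
        }))
        return pd.concat(rows, ignore_index=True).sort_values(["person", "age"]).reset_index(drop=True)


class Simulation:
    """Shared-input paired simulator.

    Parameters
    ----------
    cohort : baseline cohort frame from :func:`synthetic_data.generate_population`.
    matcher : donor matcher over the longitudinal panel.
    tables : recalibrated rate tables per disease.
    lifetable : all-cause lifetable.
    config : full model configuration dict.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        matcher: DonorMatcher | None,
        tables: dict[str, RateTable],
        lifetable: LifeTable,
        config: dict | None = None,
        coeffs: CvdCoefficientSet | None = None,
        caide: CaidePointsTable | None = None,
        utilities: "DisutilityTable | None" = None,
    ):
        self.config = config if config is not None else load_default_config()
        self.cohort = cohort.reset_index(drop=True)
        self.matcher = matcher
        self.tables = tables
        self.lifetable = lifetable
        n = len(cohort)
        self.n = n
        self.sex = cohort["sex"].to_numpy()
        self.sex_code = (self.sex == "female").astype(int)
        self.quintile = cohort["deprivation"].to_numpy().astype(int)
        self.diabetes = cohort["diabetes"].to_numpy().astype(bool)
        self.treated_htn = cohort["treated_hypertension"].to_numpy().astype(bool)
        self.age0 = cohort["age"].to_numpy().astype(int)

        self.coeffs = coeffs or CvdCoefficientSet.default()
        self.caide = caide or CaidePointsTable.default()
        self.cvd_score = _FastCvdScorer(self.coeffs, cohort)
        self.caide_score = _FastCaideScorer(self.caide, cohort)
        self.utilities = utilities or DisutilityTable.default()
        self.acute = AcuteFatalityParams.from_config(self.config)
        self.min_cell = int(self.config["disease_model"].get("min_cell_size", 20))

        # flat (age, sex) cell arrays
        self.inc_cells = {d: table_cells(tables[d], "incidence") for d in DISEASES}
        self.cf_cells = {
            d: table_cells(tables[d], "case_fatality_chronic" if tables[d].case_fatality_chronic else "case_fatality")
            for d in DISEASES
        }
        self.prev_cells = {d: table_cells(tables[d], "prevalence") for d in DISEASES}
        cm_total = sum(table_cells(tables[d], "cause_mortality") for d in DISEASES)
        qx_cells = np.empty(N_AGES * 2)
        for s_code, s in enumerate(SEXES):
            qx_cells[s_code::2] = lifetable.qx[s]
        self.other_q_cells = other_cause_probability(qx_cells, cm_total)

        ihd_inc, str_inc = self.inc_cells["ihd"], self.inc_cells["stroke"]
        with np.errstate(invalid="ignore", divide="ignore"):
            share = np.where(ihd_inc + str_inc > 0, ihd_inc / (ihd_inc + str_inc), 0.5)
        self.alloc = CvdAllocationParams(acute=self.acute, ihd_share_by_cell=share, age0=AGE0)

        # lung-cancer incidence split by baseline smoking prevalence per sex
        paf = float(self.config["epidemiology"]["lung_cancer_paf"])
        self.lc_s_cells = np.empty(N_AGES * 2)
        self.lc_ns_cells = np.empty(N_AGES * 2)
        smoking0 = cohort["smoking"].to_numpy()
        for s_code, s in enumerate(SEXES):
            m = self.sex == s
            p_smoke = float((smoking0[m] == "current").mean()) if m.any() else 0.25
            if p_smoke > 0:
                i_s, i_ns = split_incidence_by_smoking(
                    tables["lung_cancer"].incidence[s],
                    SmokingSplitParams(paf=paf, smoking_prevalence=p_smoke),
                )
            else:
                # no smokers in this cohort: population incidence is the
                # non-smoker incidence and the smoker rate is never used
                i_s = i_ns = tables["lung_cancer"].incidence[s]
            self.lc_s_cells[s_code::2] = i_s
            self.lc_ns_cells[s_code::2] = i_ns

        self.relapse_hazard = 0.0
        if matcher is not None:
            adj = float(self.config["matching"].get("relapse_adjustment", 1.0))
            self.relapse_hazard = matcher.panel.annual_relapse_rate() * adj

    # -- helpers ----------------------------------------------------------

    def _utility(self, age, state: ArmState) -> np.ndarray:
        return self.utilities.utility(
            age, self.quintile,
            ihd=state.flags["ihd"], stroke=state.flags["stroke"], tia=state.tia,
            dementia=state.flags["dementia"], lung_cancer=state.flags["lung_cancer"],
        )

    def _arm_smoking(self, cf_smoking: np.ndarray, state: ArmState) -> np.ndarray:
        return np.where(state.quit_active, "ex", cf_smoking)

    # -- main loop --------------------------------------------------------

    def run(
        self,
        policies: list[ArmPolicy],
        seed: int = 0,
        n_years: int | None = None,
        qrisk_multiplier: float = 1.0,
        trend: TrendAdjuster | None = None,
        collect_trajectories: bool = False,
    ) -> list[ArmResult]:
        self._collect = collect_trajectories
        self._cf_trajectory: list[dict[str, np.ndarray]] = []
        n = self.n
        n_years = n_years if n_years is not None else (MAX_AGE - int(self.age0.min()) + 1)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 2025]))
        states = [ArmState(n) for _ in policies]
        clips = [ClipLog() for _ in policies]

        factors = {f: self.cohort[f].to_numpy().astype(float).copy() for f in FACTORS}
        cf_smoking = self.cohort["smoking"].to_numpy().astype(object).copy()
        age = self.age0.copy()

        # baseline CVD assignment (shared across arms, proportional to score)
        base_score = self.cvd_score(age, factors["sbp"], factors["tc"], factors["hdl"],
                                    factors["bmi"], cf_smoking)
        for d in ("ihd", "stroke"):
            u = rng.random(n)
            flag = assign_baseline_disease(base_score, age, self.sex_code, self.prev_cells[d], u, age0=AGE0)
            for st in states:
                st.flags[d] = flag.copy()

        # pre-compute attendance machinery per policy: static rate-ratio
        # components (sex, ethnicity, deprivation) and the base scale that
        # normalises cohort-mean per-offer attendance to its target
        att_static = []
        base_band = classify_risk_band(base_score)
        for pol in policies:
            rr = self._attendance_static_rr(pol.offer)
            att_static.append(rr)
            if pol.enabled and pol.offer.rate_ratios:
                full_rr = rr * self._attendance_dynamic_rr(pol.offer, self.age0, cf_smoking, base_band)
                pol.offer.base_scale = pol.offer.mean_prob / float(full_rr.mean())

        for year in range(n_years):
            in_follow = age <= MAX_AGE
            union_alive = np.zeros(n, dtype=bool)
            for st in states:
                union_alive |= st.alive & in_follow
            if not union_alive.any():
                break

            # (1) advance the shared counterfactual trajectories
            if year > 0 and self.matcher is not None:
                factors, cf_smoking = advance_year(
                    factors, age, self.sex, cf_smoking, self.matcher, rng, mask=union_alive
                )

            # shared uniforms, fixed draw order
            u = {
                name: rng.random(n)
                for name in (
                    "offer", "attend", "tx_statin", "tx_aht", "tx_smoking", "tx_weight",
                    "adh_statin", "adh_aht", "adh_smoking", "adh_weight", "quit",
                    "disc_statin", "disc_aht", "relapse",
                    "cvd", "cvd_type", "cvd_sub", "cvd_fatal",
                    "dementia", "lungca",
                    "chronic_ihd", "chronic_stroke", "chronic_dementia", "chronic_lung_cancer",
                    "other",
                )
            }

            cf_score = self.cvd_score(age, factors["sbp"], factors["tc"], factors["hdl"],
                                      factors["bmi"], cf_smoking)
            cf_caide = self.caide_score(age, factors["sbp"], factors["bmi"], factors["tc"])
            if collect_trajectories:
                self._cf_trajectory.append({f: factors[f].copy() for f in FACTORS})

            for st, pol, clip, rr_s in zip(states, policies, clips, att_static):
                self._advance_arm(
                    st, pol, clip, year, age, factors, cf_smoking,
                    cf_score, cf_caide, u, qrisk_multiplier, trend, in_follow, rr_s,
                )
            age = age + 1

        results = [
            ArmResult(n=n, quintile=self.quintile, state=st, clip_report=c.report())
            for st, c in zip(states, clips)
        ]
        if collect_trajectories:
            for r in results:
                r.counterfactual_trajectory = self._cf_trajectory
        return results

    def _attendance_static_rr(self, offer: OfferAttendParams) -> np.ndarray:
        rr = np.ones(self.n)
        tables = offer.rate_ratios
        if not tables:
            return rr
        for name, col in (("sex", self.sex), ("ethnicity", self.cohort["ethnicity"].to_numpy()),
                          ("deprivation", self.quintile.astype(str))):
            t = tables.get(name)
            if t:
                rr *= np.vectorize(lambda v: t[v])(col).astype(float)
        return rr

    @staticmethod
    def _attendance_dynamic_rr(offer: OfferAttendParams, age, smoking, band) -> np.ndarray:
        tables = offer.rate_ratios
        rr = np.ones(len(age))
        t = tables.get("age_band")
        if t:
            rr *= np.where(age < 50, t["40-49"], np.where(age < 60, t["50-59"],
                           np.where(age < 75, t["60-74"], t["75+"])))
        t = tables.get("smoking")
        if t:
            rr *= np.where(smoking == "current", t["current"],
                           np.where(smoking == "ex", t["ex"], t["never"]))
        t = tables.get("qrisk_band")
        if t:
            rr *= np.where(band == "high", t["high"], np.where(band == "medium", t["medium"], t["low"]))
        return rr

    def _advance_arm(
        self, st: ArmState, pol: ArmPolicy, clip: ClipLog, year: int,
        age, factors, cf_smoking, cf_score, cf_caide, u,
        qrisk_multiplier, trend, in_follow, att_static_rr,
    ) -> None:
        n = self.n
        alive = st.alive & in_follow
        idx_cell = cell_index(age, self.sex_code, AGE0)

        # activate pending programme quits (quit measured at one year)
        newly_quit = st.pending_quit & (st.quit_year == year)
        st.quit_active |= newly_quit
        st.pending_quit &= ~newly_quit
        # relapse of earlier programme quitters
        can_relapse = st.quit_active & alive & (st.quit_year < year)
        relapsed = can_relapse & (u["relapse"] < self.relapse_hazard)
        st.quit_active &= ~relapsed

        arm_smoking = self._arm_smoking(cf_smoking, st)

        # (2) health check
        if pol.enabled:
            # adherence decay for ongoing treatments
            st.on_statin = st.on_statin & ~((st.statin_year < year) & (u["disc_statin"] < pol.adherence.annual_discontinuation))
            st.on_aht = st.on_aht & ~((st.aht_year < year) & (u["disc_aht"] < pol.adherence.annual_discontinuation))

            offsets = active_offsets(
                pol.effects, self.sex, age, st.on_statin, st.on_aht,
                np.where(st.weight_active & (st.weight_year >= 0), year - st.weight_year, 0),
            )
            arm_factors = apply_offsets(factors, offsets)
            arm_score = self.cvd_score(age, arm_factors["sbp"], arm_factors["tc"],
                                       arm_factors["hdl"], arm_factors["bmi"], arm_smoking)
            band = classify_risk_band(arm_score)

            eligible = alive & (
                (age >= pol.criteria.min_age) & (age <= pol.criteria.max_age)
                & ~(pol.criteria.exclude_diabetes & self.diabetes)
                & ~(pol.criteria.exclude_cvd & st.has_cvd())
                & ~(pol.criteria.exclude_hypertension & self.treated_htn)
            )
            st.ever_eligible |= eligible
            in_window = alive & (age >= pol.criteria.min_age) & (age <= pol.criteria.max_age)

            offer_p = np.full(n, pol.offer.annual_offer_prob)
            if pol.offer_boost_nonattenders != 1.0:
                prev_non = (st.last_offer_year >= year - 5) & (st.last_attend_year < year - 5)
                offer_p = np.where(prev_non, offer_p * pol.offer_boost_nonattenders, offer_p)
                offer_p = clip.clip(offer_p, "offer.nonattenders")
            offered = in_window & (u["offer"] < offer_p)
            st.n_offers += offered
            st.last_offer_year = np.where(offered, year, st.last_offer_year)

            if pol.offer.state_dependent:
                prev_offered = st.last_offer_year > -99
                att_p = np.where(
                    prev_offered,
                    np.where(st.last_attend_year >= year - 5,
                             pol.offer.prob_prev_attender, pol.offer.prob_prev_nonattender),
                    pol.offer.mean_prob,
                )
            else:
                att_p = pol.offer.base_scale * att_static_rr * self._attendance_dynamic_rr(
                    pol.offer, age, arm_smoking, band
                )
            if pol.attendance_boost != 1.0:
                group = {
                    "all": np.ones(n, dtype=bool),
                    "deprived": self.quintile == 5,
                    "smokers": arm_smoking == "current",
                    "highrisk": band == "high",
                    "none": np.zeros(n, dtype=bool),
                }[pol.attendance_boost_group]
                att_p = np.where(group, att_p * pol.attendance_boost, att_p)
            att_p = clip.clip(att_p, "attendance")
            # ineligible drop-ins attend at the flat drop-in probability
            att_p = np.where(eligible, att_p, pol.criteria.ineligible_attendance_prob)
            attended = offered & (u["attend"] < att_p)
            st.n_checks += attended
            st.ever_attended |= attended
            st.last_attend_year = np.where(attended, year, st.last_attend_year)

            if attended.any():
                probs = pol.uptake.offer_probabilities(
                    band, arm_factors["sbp"], arm_factors["bmi"], arm_smoking, clip=clip
                )
                offer_u = {"statin": u["tx_statin"], "antihypertensive": u["tx_aht"],
                           "smoking": u["tx_smoking"], "weight": u["tx_weight"]}
                got = {t: attended & (offer_u[t] < probs[t]) for t in probs}
                for t in probs:
                    st.offered[t] |= got[t]
                start_statin = got["statin"] & ~st.on_statin & (u["adh_statin"] < pol.adherence.statin_initial)
                st.on_statin |= start_statin
                st.statin_year = np.where(start_statin, year, st.statin_year)
                st.treated["statin"] |= start_statin
                start_aht = got["antihypertensive"] & ~st.on_aht & (u["adh_aht"] < pol.adherence.aht_initial)
                st.on_aht |= start_aht
                st.aht_year = np.where(start_aht, year, st.aht_year)
                st.treated["antihypertensive"] |= start_aht
                referred_quit = got["smoking"] & ~st.quit_active & (u["adh_smoking"] < pol.adherence.smoking_referral)
                st.treated["smoking"] |= referred_quit
                succeeds = referred_quit & (u["quit"] < pol.effects.quit_prob_1yr)
                st.pending_quit |= succeeds
                st.quit_year = np.where(succeeds, year + 1, st.quit_year)
                start_weight = got["weight"] & (u["adh_weight"] < pol.adherence.weight_attend)
                st.weight_active = np.where(start_weight, True, st.weight_active)
                st.weight_year = np.where(start_weight, year, st.weight_year)
                st.treated["weight"] |= start_weight

            # recompute offsets with this year's newly started treatments
            offsets = active_offsets(
                pol.effects, self.sex, age, st.on_statin, st.on_aht,
                np.where(st.weight_active & (st.weight_year >= 0), year - st.weight_year, 0),
            )
            arm_factors = apply_offsets(factors, offsets)
        else:
            arm_factors = factors

        if getattr(self, "_collect", False):
            st.trajectory.append({f: np.asarray(arm_factors[f]).copy() for f in FACTORS})

        # (3) disease events
        arm_smoking = self._arm_smoking(cf_smoking, st)
        arm_score = self.cvd_score(age, arm_factors["sbp"], arm_factors["tc"],
                                   arm_factors["hdl"], arm_factors["bmi"], arm_smoking)
        arm_caide = self.caide_score(age, arm_factors["sbp"], arm_factors["bmi"], arm_factors["tc"])

        prevalent_start = {d: st.flags[d].copy() for d in DISEASES}
        cvd_free = alive & ~st.has_cvd()

        cal_cvd = calibrate_hazards(cf_score, age, self.sex_code, self.inc_cells["ihd"] + self.inc_cells["stroke"],
                                    mask=cvd_free, min_cell_size=self.min_cell, age0=AGE0)
        h_cvd = cal_cvd.hazard(arm_score, age, self.sex_code) * qrisk_multiplier
        if trend is not None:
            # blended incidence decline weighted by the IHD share of the cell
            share = self.alloc.ihd_share_by_cell[idx_cell]
            h_cvd = h_cvd * (
                share * trend.incidence_factor("ihd", year, self.sex_code)
                + (1 - share) * trend.incidence_factor("stroke", year, self.sex_code)
            )
        h_cvd = np.where(st.on_statin, h_cvd * pol.statin_extra_multiplier, h_cvd)
        cvd_event = cvd_free & (u["cvd"] < np.clip(h_cvd, 0, 1))
        mi_mult = trend.fatality_factor("ihd", year) if trend is not None else 1.0
        st_mult = trend.fatality_factor("stroke", year) if trend is not None else 1.0
        code, fatal = self.alloc.allocate(
            cvd_event, age, self.sex_code, u["cvd_type"], u["cvd_sub"], u["cvd_fatal"],
            mi_cf_mult=mi_mult, stroke_cf_mult=st_mult,
        )
        is_ihd_event = (code == EVENT_CODES["mi"]) | (code == EVENT_CODES["other_ihd"])
        is_stroke_event = code == EVENT_CODES["stroke"]
        is_tia = code == EVENT_CODES["tia"]
        st.flags["ihd"] |= is_ihd_event
        st.flags["stroke"] |= is_stroke_event
        st.tia |= is_tia
        st.first_age["ihd"] = np.where(is_ihd_event & np.isnan(st.first_age["ihd"]), age + 0.5, st.first_age["ihd"])
        st.first_age["stroke"] = np.where(is_stroke_event & np.isnan(st.first_age["stroke"]), age + 0.5, st.first_age["stroke"])
        st.tia_age = np.where(is_tia & np.isnan(st.tia_age), age + 0.5, st.tia_age)
        st.cvd_event_code = np.where(cvd_event, code, st.cvd_event_code)

        dem_free = alive & ~st.flags["dementia"]
        cal_dem = calibrate_hazards(cf_caide, age, self.sex_code, self.inc_cells["dementia"],
                                    mask=dem_free, min_cell_size=self.min_cell, age0=AGE0)
        dem_event = dem_free & (u["dementia"] < cal_dem.hazard(arm_caide, age, self.sex_code))
        st.flags["dementia"] |= dem_event
        st.first_age["dementia"] = np.where(dem_event, age + 0.5, st.first_age["dementia"])

        lc_free = alive & ~st.flags["lung_cancer"]
        h_lc = np.where(arm_smoking == "current", self.lc_s_cells[idx_cell], self.lc_ns_cells[idx_cell])
        lc_event = lc_free & (u["lungca"] < h_lc)
        st.flags["lung_cancer"] |= lc_event
        st.first_age["lung_cancer"] = np.where(lc_event, age + 0.5, st.first_age["lung_cancer"])

        # deaths: acute CVD, then chronic case fatality, then other causes
        dead_now = cvd_event & fatal
        cause = np.where(dead_now, np.where(is_ihd_event, 0, 1), -1)
        chronic_mult = {"ihd": mi_mult, "stroke": st_mult, "dementia": 1.0, "lung_cancer": 1.0}
        for di, d in enumerate(DISEASES):
            cf = self.cf_cells[d][idx_cell] * chronic_mult[d]
            dies = alive & prevalent_start[d] & (u[f"chronic_{d}"] < cf) & ~dead_now
            cause = np.where(dies, di, cause)
            dead_now |= dies
        other = alive & ~dead_now & (u["other"] < self.other_q_cells[idx_cell])
        cause = np.where(other, 4, cause)
        dead_now |= other

        dead_now &= alive
        st.death_age = np.where(dead_now, age + 0.5, st.death_age)
        st.death_cause = np.where(dead_now, cause, st.death_cause)

        # (4) accumulate person-time and quality-adjusted time
        util = self._utility(age, st)
        frac = np.where(dead_now, 0.5, 1.0)
        st.life_years += np.where(alive, frac, 0.0)
        st.qalys += np.where(alive, frac * util, 0.0)
        st.alive &= ~dead_now

    # -- statin calibration harness ---------------------------------------

    def statin_event_ratio(self, multiplier: float, n_years: int = 5,
                           effects: TreatmentEffectParams | None = None) -> float:
        """5-year cumulative first-CVD-event ratio, everyone-on-statins vs
        nobody, with factors frozen at baseline.

        The event randomness is integrated out exactly: per individual the
        cumulative event probability is ``1 - prod_y (1 - h(y))`` in each
        arm, and the ratio of cohort sums is returned.  This conditional
        expectation removes Monte-Carlo noise from the calibration target;
        the only remaining randomness is the cohort sample itself.
        """
        effects = effects or TreatmentEffectParams.from_config(self.config)
        factors = {f: self.cohort[f].to_numpy().astype(float) for f in FACTORS}
        smoking = self.cohort["smoking"].to_numpy().astype(object)
        age = self.age0.copy()
        on = np.ones(self.n, dtype=bool)
        offs = active_offsets(effects, self.sex, age, on, np.zeros(self.n, bool), np.zeros(self.n, int))
        treated_factors = apply_offsets(factors, offs)
        surv = {"statin": np.ones(self.n), "none": np.ones(self.n)}
        inc_cells = self.inc_cells["ihd"] + self.inc_cells["stroke"]
        all_mask = np.ones(self.n, dtype=bool)
        for year in range(n_years):
            cf_score = self.cvd_score(age, factors["sbp"], factors["tc"], factors["hdl"],
                                      factors["bmi"], smoking)
            cal = calibrate_hazards(cf_score, age, self.sex_code, inc_cells,
                                    mask=all_mask, min_cell_size=self.min_cell, age0=AGE0)
            tr_score = self.cvd_score(age, treated_factors["sbp"], treated_factors["tc"],
                                      treated_factors["hdl"], treated_factors["bmi"], smoking)
            surv["none"] *= 1.0 - cal.hazard(cf_score, age, self.sex_code)
            surv["statin"] *= 1.0 - np.clip(cal.hazard(tr_score, age, self.sex_code) * multiplier, 0, 1)
            age = age + 1
        cum_statin = (1.0 - surv["statin"]).sum()
        cum_none = (1.0 - surv["none"]).sum()
        return float(cum_statin / cum_none) if cum_none else 1.0
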