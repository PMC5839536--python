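"""The health-check programme: eligibility, offers, attendance, treatment
initiation, adherence, and treatment-induced risk-factor offsets.

Treatment-initiation probabilities are programme-attributable *differences*
(attender minus non-attender rates from programme evaluation data): they are
the probability that the check itself starts a treatment, on top of whatever
background care is already embedded in the donor-panel trajectories.

All functions are vectorised over the cohort; the annual simulation engine
composes them.  Probabilities pushed above 1 by scenario multipliers are
clipped and counted in a :class:`ClipLog`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import Uncertain, load_default_config

logger = logging.getLogger(__name__)

TREATMENTS = ("statin", "antihypertensive", "smoking", "weight")


class ClipLog:
    """Counts probability-clipping events per parameter for the run report."""

    def __init__(self):
        self.counts: dict[str, int] = {}

    def clip(self, p: np.ndarray, name: str) -> np.ndarray:
        over = p > 1.0
        n = int(np.count_nonzero(over))
        if n:
            self.counts[name] = self.counts.get(name, 0) + n
            logger.warning("clipped %d probabilities above 1 for '%s'", n, name)
        return np.clip(p, 0.0, 1.0)

    def report(self) -> dict[str, int]:
        return dict(self.counts)


@dataclass
class EligibilityCriteria:
    """Age window and condition exclusions for a programme invitation."""

    min_age: int = 40
    max_age: int = 74
    exclude_diabetes: bool = True
    exclude_cvd: bool = True
    exclude_hypertension: bool = True
    ineligible_attendance_prob: float = 0.05

    def __post_init__(self):
        if self.min_age >= self.max_age:
            raise ValueError("min_age must be below max_age")
        if not 0.0 <= self.ineligible_attendance_prob <= 1.0:
            raise ValueError("ineligible_attendance_prob outside [0,1]")

    @classmethod
    def from_config(cls, config: dict | None = None) -> "EligibilityCriteria":
        config = config if config is not None else load_default_config()
        e = config["health_check"]["eligibility"]
        excl = set(e["excluded_conditions"])
        return cls(
            min_age=int(e["min_age"]),
            max_age=int(e["max_age"]),
            exclude_diabetes="diabetes" in excl,
            exclude_cvd="cvd" in excl,
            exclude_hypertension="hypertension" in excl,
            ineligible_attendance_prob=float(Uncertain(**e["ineligible_attendance_prob"]).value),
        )


def is_eligible(
    age: np.ndarray,
    diabetes: np.ndarray,
    cvd: np.ndarray,
    treated_hypertension: np.ndarray,
    criteria: EligibilityCriteria,
) -> np.ndarray:
    """Programme eligibility under the active criteria (scenario-adjusted)."""
    ok = (np.asarray(age) >= criteria.min_age) & (np.asarray(age) <= criteria.max_age)
    if criteria.exclude_diabetes:
        ok &= ~np.asarray(diabetes, dtype=bool)
    if criteria.exclude_cvd:
        ok &= ~np.asarray(cvd, dtype=bool)
    if criteria.exclude_hypertension:
        ok &= ~np.asarray(treated_hypertension, dtype=bool)
    return ok


@dataclass
class OfferAttendParams:
    """Offer process and covariate-dependent attendance model.

    Attendance is a base per-offer probability times multiplicative rate
    ratios by age band, sex, ethnicity, deprivation quintile, smoking status
    and risk band, normalised (via ``base_scale``, set once on the baseline
    cohort) so the cohort-mean per-offer attendance matches ``mean_prob``.
    """

    annual_offer_prob: float = 0.197
    mean_prob: float = 0.49
    rate_ratios: dict[str, dict[str, float]] = field(default_factory=dict)
    state_dependent: bool = False
    prob_prev_attender: float = 0.70
    prob_prev_nonattender: float = 0.30
    base_scale: float = 1.0

    @classmethod
    def from_config(cls, config: dict | None = None) -> "OfferAttendParams":
        config = config if config is not None else load_default_config()
        hc = config["health_check"]
        att = hc["attendance"]
        return cls(
            annual_offer_prob=float(hc["offer"]["annual_prob"]),
            mean_prob=float(att["mean_prob"]),
            rate_ratios={k: dict(v) for k, v in att["rate_ratios"].items()},
            state_dependent=bool(att["state_dependent"]),
            prob_prev_attender=float(att["prob_prev_attender"]),
            prob_prev_nonattender=float(att["prob_prev_nonattender"]),
        )

    def rate_ratio(
        self,
        age: np.ndarray,
        sex: np.ndarray,
        ethnicity: np.ndarray,
        deprivation: np.ndarray,
        smoking: np.ndarray,
        qrisk_band: np.ndarray,
    ) -> np.ndarray:
        rr = np.ones(len(age), dtype=float)
        bands = np.where(age < 50, "40-49", np.where(age < 60, "50-59", np.where(age < 75, "60-74", "75+")))
        lookups = [
            ("age_band", bands), ("sex", sex), ("ethnicity", ethnicity),
            ("deprivation", deprivation.astype(int).astype(str)),
            ("smoking", smoking), ("qrisk_band", qrisk_band),
        ]
        for name, values in lookups:
            table = self.rate_ratios.get(name)
            if table:
                rr *= np.vectorize(lambda v: table[v])(values).astype(float)
        return rr

    def calibrate_base_scale(self, **covariates) -> None:
        """Set ``base_scale`` so the mean attendance over the given cohort
        equals ``mean_prob``."""
        rr = self.rate_ratio(**covariates)
        self.base_scale = self.mean_prob / float(rr.mean())

    def attendance_prob(self, clip: ClipLog | None = None, **covariates) -> np.ndarray:
        p = self.base_scale * self.rate_ratio(**covariates)
        return clip.clip(p, "attendance") if clip else np.clip(p, 0.0, 1.0)


@dataclass
class TreatmentUptakeParams:
    """Programme-attributable treatment-initiation probabilities among
    attenders, gated on treatment-specific eligibility."""

    statin_low: float = 0.0205
    statin_high: float = 0.1423
    aht_low: float = 0.0154
    aht_high: float = 0.0248
    smoking_referral: float = 0.036
    weight_referral: float = 0.275
    aht_sbp_threshold: float = 140.0
    weight_bmi_threshold: float = 30.0
    multipliers: dict[str, float] = field(default_factory=lambda: {t: 1.0 for t in TREATMENTS})

    @classmethod
    def from_config(cls, config: dict | None = None) -> "TreatmentUptakeParams":
        config = config if config is not None else load_default_config()
        u = config["health_check"]["uptake"]
        return cls(
            statin_low=Uncertain(**u["statin"]["low"]).value,
            statin_high=Uncertain(**u["statin"]["high"]).value,
            aht_low=Uncertain(**u["antihypertensive"]["low"]).value,
            aht_high=Uncertain(**u["antihypertensive"]["high"]).value,
            smoking_referral=Uncertain(**u["smoking_referral"]).value,
            weight_referral=Uncertain(**u["weight_referral"]).value,
            aht_sbp_threshold=float(u["aht_sbp_threshold"]),
            weight_bmi_threshold=float(u["weight_bmi_threshold"]),
        )

    def offer_probabilities(
        self,
        qrisk_band: np.ndarray,
        sbp: np.ndarray,
        bmi: np.ndarray,
        smoking: np.ndarray,
        clip: ClipLog | None = None,
    ) -> dict[str, np.ndarray]:
        """Per-treatment offer probability for attenders this year.

        Gates: antihypertensives require measured SBP above threshold;
        weight referral requires BMI at/above threshold; cessation referral
        requires current smoking; statins use the risk band alone.
        """
        high = np.asarray(qrisk_band, dtype=object) == "high"
        probs = {
            "statin": np.where(high, self.statin_high, self.statin_low),
            "antihypertensive": np.where(
                np.asarray(sbp) > self.aht_sbp_threshold,
                np.where(high, self.aht_high, self.aht_low), 0.0,
            ),
            "smoking": np.where(np.asarray(smoking, dtype=object) == "current", self.smoking_referral, 0.0),
            "weight": np.where(np.asarray(bmi) >= self.weight_bmi_threshold, self.weight_referral, 0.0),
        }
        for t, p in probs.items():
            p = p * self.multipliers.get(t, 1.0)
            probs[t] = clip.clip(p, f"uptake.{t}") if clip else np.clip(p, 0.0, 1.0)
        return probs


@dataclass
class AdherenceParams:
    statin_initial: float = 0.50
    aht_initial: float = 0.55
    annual_discontinuation: float = 0.05
    weight_attend: float = 0.50
    smoking_referral: float = 1.0  # effectiveness estimate already includes non-adherers

    @classmethod
    def from_config(cls, config: dict | None = None) -> "AdherenceParams":
        config = config if config is not None else load_default_config()
        a = config["health_check"]["adherence"]
        return cls(
            statin_initial=Uncertain(**a["statin_initial"]).value,
            aht_initial=Uncertain(**a["aht_initial"]).value,
            annual_discontinuation=Uncertain(**a["annual_discontinuation"]).value,
            weight_attend=Uncertain(**a["weight_attend"]).value,
            smoking_referral=Uncertain(**a["smoking_referral"]).value,
        )


def update_adherence(
    on_treatment: np.ndarray,
    annual_discontinuation: float,
    u: np.ndarray,
) -> np.ndarray:
    """One year of geometric discontinuation; stopping is absorbing."""
    return on_treatment & (u >= annual_discontinuation)


@dataclass
class TreatmentEffectParams:
    """Risk-factor offsets while a treatment is active and adhered to."""

    statin_tc: dict[str, float] = field(default_factory=lambda: {"male": -1.22, "female": -1.16})
    statin_hdl: dict[str, float] = field(default_factory=lambda: {"male": 0.04, "female": 0.036})
    ace_bp: dict[str, float] = field(default_factory=lambda: {"sbp": -6.29, "dbp": -4.14})
    ccb_bp: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "male": {"sbp": -7.6, "dbp": -3.1}, "female": {"sbp": -9.0, "dbp": -3.5},
    })
    ace_age_threshold: int = 55
    weight_bmi_schedule: tuple[float, ...] = (-1.5, -0.9, -0.6, -0.3, 0.0)
    quit_prob_1yr: float = 0.146

    def __post_init__(self):
        if self.weight_bmi_schedule[-1] != 0.0:
            raise ValueError("weight-management BMI schedule must return to 0 by year 5")

    @classmethod
    def from_config(cls, config: dict | None = None) -> "TreatmentEffectParams":
        config = config if config is not None else load_default_config()
        e = config["health_check"]["effects"]
        return cls(
            statin_tc={s: Uncertain(**e["statin_tc"][s]).value for s in ("male", "female")},
            statin_hdl={s: Uncertain(**e["statin_hdl"][s]).value for s in ("male", "female")},
            ace_bp={k: Uncertain(**e["ace_bp"][k]).value for k in ("sbp", "dbp")},
            ccb_bp={
                s: {k: Uncertain(**e["ccb_bp"][s][k]).value for k in ("sbp", "dbp")}
                for s in ("male", "female")
            },
            ace_age_threshold=int(e["ace_age_threshold"]),
            weight_bmi_schedule=tuple(e["weight_bmi_schedule"]),
            quit_prob_1yr=Uncertain(**e["quit_prob_1yr"]).value,
        )


def active_offsets(
    effects: TreatmentEffectParams,
    sex: np.ndarray,
    age: np.ndarray,
    on_statin: np.ndarray,
    on_aht: np.ndarray,
    years_since_weight: np.ndarray,
) -> dict[str, np.ndarray]:
    """Additive factor offsets for the currently active, adhered treatments.

    Statins shift total cholesterol and HDL (sex-specific); antihypertensive
    class is chosen by the age-55 threshold (ACE inhibitor below, calcium
    channel blocker at or above, the latter sex-specific); weight management
    follows the 5-year regain schedule indexed by years since the check
    (``years_since_weight`` < 1 or > 5 contributes nothing).
    """
    n = len(sex)
    female = np.asarray(sex, dtype=object) == "female"
    statin = np.asarray(on_statin, dtype=bool)
    aht = np.asarray(on_aht, dtype=bool)
    tc = np.where(statin, np.where(female, effects.statin_tc["female"], effects.statin_tc["male"]), 0.0)
    hdl = np.where(statin, np.where(female, effects.statin_hdl["female"], effects.statin_hdl["male"]), 0.0)
    young = np.asarray(age) < effects.ace_age_threshold
    sbp = np.where(
        aht,
        np.where(young, effects.ace_bp["sbp"],
                 np.where(female, effects.ccb_bp["female"]["sbp"], effects.ccb_bp["male"]["sbp"])),
        0.0,
    )
    dbp = np.where(
        aht,
        np.where(young, effects.ace_bp["dbp"],
                 np.where(female, effects.ccb_bp["female"]["dbp"], effects.ccb_bp["male"]["dbp"])),
        0.0,
    )
    sched = np.asarray(effects.weight_bmi_schedule)
    ys = np.asarray(years_since_weight)
    in_sched = (ys >= 1) & (ys <= len(sched))
    bmi = np.where(in_sched, sched[np.clip(ys, 1, len(sched)).astype(int) - 1], 0.0)
    return {"tc": tc, "hdl": hdl, "sbp": sbp, "dbp": dbp, "bmi": bmi}


def referral_deltas_from_counts(counts: dict) -> dict[str, float]:
    """Recompute programme-attributable referral probabilities from the
    evaluation counts (attender rate minus non-attender rate)."""
    out = {}
    for name, c in counts.items():
        (na, da), (nn, dn) = c["attender"], c["nonattender"]
        out[name] = na / da - nn / dn
    return out
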