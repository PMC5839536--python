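"""Declarative scenario grid and paired-run orchestration.

A :class:`ScenarioConfig` names one option per axis — eligibility variant,
attendance-uptake variant, treatment-rate multiplier — plus sensitivity
switches (state-dependent attendance, calendar declines in CVD rates, and a
per-run multiplier on the CVD score).  ``max_potential`` expands to widened
eligibility (include treated hypertension, upper age 79), +30% attendance
for everyone and all four treatments at 2.5x uptake.

:func:`run_pair` simulates a scenario and a reference over the same cohort
with common random numbers and returns the paired outcome table.  The
reference is the current programme for programme-variant questions and the
no-programme counterfactual for the headline comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DynamicsParams, PopulationSpec, load_default_config
from .dismod_rates import AcuteFatalityParams, RateTable, recalibrate_case_fatality, solve_rate_table
from .engine import ArmPolicy, Simulation, TrendAdjuster
from .outcomes_equity import OutcomeTable, compare_arms
from .synthetic_data import generate_epidemiology, generate_panel, generate_population
from .trajectory_engine import DonorMatcher, MatchKey

ELIGIBILITY_VARIANTS = ("base", "include_hypertension", "start_50", "upper_79", "start50_upper79")
UPTAKE_VARIANTS = ("none", "all", "deprived", "smokers", "highrisk", "nonattenders")
TREATMENT_TARGETS = ("none", "statin", "antihypertensive", "smoking", "weight", "all")


@dataclass(frozen=True)
class ScenarioConfig:
    """One point on the scenario grid."""

    name: str = "base"
    programme: bool = True
    eligibility: str = "base"
    uptake: str = "none"
    uptake_boost: float = 1.3
    treatment_target: str = "none"
    treatment_multiplier: float = 2.5
    max_potential: bool = False
    attendance_state_dependent: bool = False
    cvd_decline_trends: bool = False
    qrisk_multiplier_sampling: bool = False

    def __post_init__(self):
        if self.eligibility not in ELIGIBILITY_VARIANTS:
            raise ValueError(f"unknown eligibility variant '{self.eligibility}'")
        if self.uptake not in UPTAKE_VARIANTS:
            raise ValueError(f"unknown uptake variant '{self.uptake}'")
        if self.treatment_target not in TREATMENT_TARGETS:
            raise ValueError(f"unknown treatment target '{self.treatment_target}'")

    def expanded(self) -> dict:
        """The concrete policy components this scenario activates; for
        ``max_potential`` these are the four documented pieces."""
        if self.max_potential:
            return {
                "include_hypertension": True,
                "upper_age": 79,
                "uptake": "all",
                "uptake_boost": self.uptake_boost,
                "treatment_target": "all",
                "treatment_multiplier": self.treatment_multiplier,
            }
        return {
            "include_hypertension": self.eligibility == "include_hypertension",
            "upper_age": 79 if self.eligibility in ("upper_79", "start50_upper79") else 74,
            "uptake": self.uptake,
            "uptake_boost": self.uptake_boost if self.uptake != "none" else 1.0,
            "treatment_target": self.treatment_target,
            "treatment_multiplier": self.treatment_multiplier if self.treatment_target != "none" else 1.0,
        }


PRESETS: dict[str, ScenarioConfig] = {
    "no_programme": ScenarioConfig(name="no_programme", programme=False),
    "base": ScenarioConfig(name="base"),
    "include_hypertension": ScenarioConfig(name="include_hypertension", eligibility="include_hypertension"),
    "start_50": ScenarioConfig(name="start_50", eligibility="start_50"),
    "upper_79": ScenarioConfig(name="upper_79", eligibility="upper_79"),
    "start50_upper79": ScenarioConfig(name="start50_upper79", eligibility="start50_upper79"),
    "uptake_all_30": ScenarioConfig(name="uptake_all_30", uptake="all"),
    "uptake_deprived_30": ScenarioConfig(name="uptake_deprived_30", uptake="deprived"),
    "uptake_smokers_30": ScenarioConfig(name="uptake_smokers_30", uptake="smokers"),
    "uptake_highrisk_30": ScenarioConfig(name="uptake_highrisk_30", uptake="highrisk"),
    "uptake_nonattenders_30": ScenarioConfig(name="uptake_nonattenders_30", uptake="nonattenders"),
    "treat_statin_2.5": ScenarioConfig(name="treat_statin_2.5", treatment_target="statin"),
    "treat_aht_2.5": ScenarioConfig(name="treat_aht_2.5", treatment_target="antihypertensive"),
    "treat_smoking_2.5": ScenarioConfig(name="treat_smoking_2.5", treatment_target="smoking"),
    "treat_weight_2.5": ScenarioConfig(name="treat_weight_2.5", treatment_target="weight"),
    "treat_all_2.5": ScenarioConfig(name="treat_all_2.5", treatment_target="all"),
    "max_potential": ScenarioConfig(name="max_potential", max_potential=True),
}


def list_presets() -> list[str]:
    return sorted(PRESETS)


def build_policy(scenario: ScenarioConfig, config: dict | None = None) -> ArmPolicy:
    """Translate a scenario into a concrete arm policy."""
    config = config if config is not None else load_default_config()
    if not scenario.programme:
        return ArmPolicy.null(config)
    sc = scenario
    if sc.max_potential:
        # composite: widened eligibility, +30% uptake for all, all treatments x2.5
        pol = ArmPolicy.from_config(config)
        pol.criteria.exclude_hypertension = False
        pol.criteria.max_age = 79
        pol.attendance_boost, pol.attendance_boost_group = sc.uptake_boost, "all"
        for t in pol.uptake.multipliers:
            pol.uptake.multipliers[t] = sc.treatment_multiplier
        pol.offer.state_dependent = sc.attendance_state_dependent
        return pol
    pol = ArmPolicy.from_config(config)
    if sc.eligibility in ("include_hypertension",):
        pol.criteria.exclude_hypertension = False
    if sc.eligibility in ("start_50", "start50_upper79"):
        pol.criteria.min_age = 50
    if sc.eligibility in ("upper_79", "start50_upper79"):
        pol.criteria.max_age = 79
    if sc.uptake == "nonattenders":
        pol.offer_boost_nonattenders = sc.uptake_boost
    elif sc.uptake != "none":
        pol.attendance_boost = sc.uptake_boost
        pol.attendance_boost_group = sc.uptake
    if sc.treatment_target == "all":
        for t in pol.uptake.multipliers:
            pol.uptake.multipliers[t] = sc.treatment_multiplier
    elif sc.treatment_target != "none":
        pol.uptake.multipliers[sc.treatment_target] = sc.treatment_multiplier
    pol.offer.state_dependent = sc.attendance_state_dependent
    return pol


def derive_rate_tables(config: dict | None = None) -> tuple[dict[str, RateTable], "LifeTable"]:
    """Generate epidemiology, solve the illness-death model per disease, and
    recalibrate CVD case fatality for acute first-year mortality."""
    config = config if config is not None else load_default_config()
    raw, lifetable = generate_epidemiology(config)
    acute = AcuteFatalityParams.from_config(config)
    tables = {}
    for disease, t in raw.items():
        solved = solve_rate_table(disease, t.ages, t.prevalence, t.cause_mortality, lifetable)
        tables[disease] = recalibrate_case_fatality(solved, acute, lifetable)
    return tables, lifetable


def build_simulation(
    config: dict | None = None,
    n_individuals: int = 20000,
    seed: int = 0,
    n_panel: int | None = None,
    tables: dict[str, RateTable] | None = None,
    lifetable=None,
) -> Simulation:
    """Assemble the full pipeline: cohort, donor panel, derived rates."""
    config = config if config is not None else load_default_config()
    ss = np.random.SeedSequence([seed, 11])
    s_pop, s_panel = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
    spec = PopulationSpec.from_config(config, n_individuals=n_individuals, seed=s_pop)
    cohort = generate_population(spec)
    dyn_over = {"n_persons": n_panel} if n_panel else {}
    dynamics = DynamicsParams.from_config(config, **dyn_over)
    panel = generate_panel(spec, dynamics, seed=s_panel)
    matcher = DonorMatcher(panel, MatchKey.from_config(config))
    if tables is None or lifetable is None:
        tables, lifetable = derive_rate_tables(config)
    return Simulation(cohort, matcher, tables, lifetable, config)


def run_pair(
    scenario: ScenarioConfig | str,
    reference: ScenarioConfig | str,
    master_seed: int = 0,
    n_individuals: int = 20000,
    config: dict | None = None,
    sim: Simulation | None = None,
    qrisk_multiplier: float = 1.0,
) -> OutcomeTable:
    """Simulate scenario and reference over one shared cohort and return the
    paired outcome table (scenario minus reference)."""
    config = config if config is not None else load_default_config()
    if isinstance(scenario, str):
        scenario = PRESETS[scenario]
    if isinstance(reference, str):
        reference = PRESETS[reference]
    if sim is None:
        sim = build_simulation(config, n_individuals=n_individuals, seed=master_seed)
    trend = None
    if scenario.cvd_decline_trends or reference.cvd_decline_trends:
        trend = TrendAdjuster.from_config(config)
    pol_s = build_policy(scenario, config)
    pol_r = build_policy(reference, config)
    res_s, res_r = sim.run(
        [pol_s, pol_r], seed=master_seed, qrisk_multiplier=qrisk_multiplier, trend=trend
    )
    factor = float(config["outcomes"]["annualisation_factor"])
    return compare_arms(res_s, res_r, annualisation_factor=factor)


# ---------------------------------------------------------------------------
# Sensitivity helpers


def apply_trends(table: RateTable, config: dict | None = None, calendar_year: int = 0) -> RateTable:
    """Rate table with calendar declines applied: rate(y) = rate(0) *
    (1 - d)^min(y, plateau).  Diseases without configured trends pass
    through unchanged."""
    config = config if config is not None else load_default_config()
    adj = TrendAdjuster.from_config(config)
    inc, cf = {}, {}
    for s_code, sex in enumerate(("male", "female")):
        fi = adj.incidence_factor(table.disease, calendar_year, np.array([s_code]))
        ff = adj.fatality_factor(table.disease, calendar_year)
        inc[sex] = table.incidence[sex] * (fi if np.isscalar(fi) else fi[0])
        cf[sex] = table.case_fatality[sex] * ff
    return RateTable(
        disease=table.disease, ages=table.ages, incidence=inc, case_fatality=cf,
        prevalence={s: table.prevalence[s].copy() for s in ("male", "female")},
        cause_mortality={s: table.cause_mortality[s].copy() for s in ("male", "female")},
    )


@dataclass
class QriskMultiplierDistribution:
    """Log-normal run-level multiplier on the CVD score, parameterised by its
    2.5% and 97.5% quantiles (defaults 0.8 and 1.2).  One value is drawn per
    run and shared by every individual in that run."""

    q_lo: float = 0.8
    q_hi: float = 1.2

    @property
    def mu(self) -> float:
        return 0.5 * (np.log(self.q_lo) + np.log(self.q_hi))

    @property
    def sigma(self) -> float:
        return (np.log(self.q_hi) - np.log(self.q_lo)) / (2 * 1.959963984540054)

    def draw(self, rng: np.random.Generator) -> float:
        if self.q_lo == self.q_hi:
            return float(self.q_lo)
        return float(np.exp(self.mu + self.sigma * rng.standard_normal()))


def apply_qrisk_multiplier(rng: np.random.Generator, config: dict | None = None) -> float:
    config = config if config is not None else load_default_config()
    q = config["qrisk_multiplier"]
    return QriskMultiplierDistribution(q_lo=float(q["q_lo"]), q_hi=float(q["q_hi"])).draw(rng)
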