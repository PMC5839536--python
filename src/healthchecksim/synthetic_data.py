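"""Synthetic stand-ins for the restricted data sources.

Three generators make the whole pipeline testable without restricted
microdata:

* :func:`generate_population` -- a cross-sectional baseline cohort aged
  40-45 whose categorical and continuous marginals match the configured
  survey targets (Gaussian copula over log-transformed risk factors, with
  deprivation gradients in smoking and BMI so equity metrics are
  non-trivially exercised);
* :func:`generate_panel` -- a longitudinal donor panel of person-wave
  records with AR(1) deviations around configurable age trends and smoking
  quit/relapse transitions, used for nonparametric trajectory matching;
* :func:`generate_epidemiology` -- internally consistent age-sex disease
  prevalence and cause-mortality curves plus an all-cause lifetable,
  produced by forward-integrating known incidence/case-fatality curves
  through the same illness-death recurrence the solver later inverts.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special

from .config import (
    FACTORS,
    SEXES,
    ConfigurationError,
    DynamicsParams,
    PopulationSpec,
    load_default_config,
)
from .dismod_rates import LifeTable, RateTable, forward_illness_death

COHORT_COLUMNS = [
    "id", "age", "sex", "ethnicity", "deprivation", "education",
    "sbp", "dbp", "tc", "hdl", "bmi", "hba1c",
    "smoking", "treated_hypertension", "diabetes",
    "ihd", "stroke", "dementia", "lung_cancer", "alive",
]


def _draw_categorical(rng: np.random.Generator, marginal: dict[str, float], n: int) -> np.ndarray:
    labels = list(marginal.keys())
    probs = np.array([marginal[k] for k in labels], dtype=float)
    return rng.choice(np.array(labels, dtype=object), size=n, p=probs / probs.sum())


def _calibrated_logistic(rng, z: np.ndarray, target: float, slope: float) -> np.ndarray:
    """Bernoulli draws whose probability rises with z and whose cohort mean
    equals the target prevalence (intercept solved numerically)."""
    if target <= 0.0:
        return np.zeros(len(z), dtype=bool)
    if target >= 1.0:
        return np.ones(len(z), dtype=bool)

    def mean_gap(a):
        return special.expit(a + slope * z).mean() - target

    a = optimize.brentq(mean_gap, -30.0, 30.0)
    return rng.random(len(z)) < special.expit(a + slope * z)


def generate_population(spec: PopulationSpec) -> pd.DataFrame:
    """Generate the baseline cohort as one row per individual.

    Categorical attributes are drawn from the configured marginals;
    continuous risk factors from a Gaussian copula over log-normal margins.
    Deprivation shifts current-smoking probability (multiplicative gradient,
    renormalised so the overall marginal is preserved exactly) and the BMI
    log-location (zero-mean additive gradient).  Treated-hypertension and
    diabetes prevalences are logistic in SBP and HbA1c respectively, with
    intercepts calibrated so the realised means match the targets.
    """
    n = spec.n_individuals
    rng = np.random.default_rng(spec.seed)
    if n == 0:
        return pd.DataFrame(columns=COHORT_COLUMNS)

    marg = spec.category_marginals
    sex = _draw_categorical(rng, marg["sex"], n)
    ethnicity = _draw_categorical(rng, marg["ethnicity"], n)
    quintile = _draw_categorical(rng, marg["deprivation"], n).astype(int)
    education = _draw_categorical(rng, marg["education"], n)
    age = rng.integers(spec.age_min, spec.age_max + 1, size=n)

    # Smoking with deprivation gradient, marginal-preserving.
    smk = marg["smoking"]
    w_q = np.array([marg["deprivation"][str(q)] for q in range(1, 6)])
    gamma = spec.deprivation_effects.get("smoking_log_gradient", 0.0)
    r_q = np.exp(gamma * (np.arange(1, 6) - 3.0))
    r_q /= (w_q * r_q).sum()  # quintile-weighted mean of r_q == 1
    p_cur_q = np.clip(smk["current"] * r_q, 0.0, 1.0)
    p_cur = p_cur_q[quintile - 1]
    rest = 1.0 - smk["current"]
    p_never = smk["never"] * (1.0 - p_cur) / rest if rest > 0 else np.zeros(n)
    u = rng.random(n)
    smoking = np.where(u < p_cur, "current", np.where(u < p_cur + p_never, "never", "ex"))

    # Continuous risk factors: Gaussian copula over log scale.
    cont = spec.continuous
    order = list(cont.get("order", FACTORS))
    corr = np.asarray(cont["correlation"], dtype=float)
    z = rng.standard_normal((n, len(order))) @ np.linalg.cholesky(corr).T
    beta = spec.deprivation_effects.get("bmi_log_gradient", 0.0)
    qbar = (w_q * np.arange(1, 6)).sum() / w_q.sum()
    factors = {}
    for j, f in enumerate(order):
        mu, s = cont["log_location"][f], cont["log_scale"][f]
        shift = beta * (quintile - qbar) if f == "bmi" else 0.0
        factors[f] = np.exp(mu + shift + s * z[:, j])
    # physiological constraint: HDL below total cholesterol
    factors["hdl"] = np.minimum(factors["hdl"], 0.9 * factors["tc"])

    df = pd.DataFrame({
        "id": np.arange(n),
        "age": age,
        "sex": sex,
        "ethnicity": ethnicity,
        "deprivation": quintile,
        "education": education,
        **{f: factors[f] for f in order},
        "smoking": smoking,
    })
    for cond, cp in spec.condition_prevalence.items():
        cov = np.log(df[cp.get("covariate", "sbp")].to_numpy())
        zc = (cov - cov.mean()) / max(cov.std(), 1e-12)
        df[cond] = _calibrated_logistic(rng, zc, float(cp["target"]), float(cp.get("logistic_slope", 1.0)))
    for cond in ("treated_hypertension", "diabetes"):
        if cond not in df.columns:
            df[cond] = False
    for flag in ("ihd", "stroke", "dementia", "lung_cancer"):
        df[flag] = False
    df["alive"] = True
    return df[COHORT_COLUMNS]


# ---------------------------------------------------------------------------
# Longitudinal donor panel


@dataclass
class PanelDataset:
    """Person-wave donor records with measurements at waves t and t+1.

    Columns: person_id, wave, age, sex, smoking, one column per risk factor
    at wave t, the same with suffix ``_next`` at wave t+1, and
    ``smoking_next``.  Consecutive waves are ``wave_years`` apart.
    """

    df: pd.DataFrame
    wave_years: int = 2

    def __post_init__(self):
        required = {"person_id", "wave", "age", "sex", "smoking", "smoking_next"}
        required |= set(FACTORS) | {f + "_next" for f in FACTORS}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"panel missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.df)

    def annual_relapse_rate(self) -> float:
        """Ex -> current transition rate, converted to an annual probability."""
        ex = self.df[self.df["smoking"] == "ex"]
        if len(ex) == 0:
            return 0.0
        per_wave = float((ex["smoking_next"] == "current").mean())
        return 1.0 - (1.0 - per_wave) ** (1.0 / self.wave_years)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, wave_years: int = 2) -> "PanelDataset":
        return cls(pd.read_csv(path), wave_years=wave_years)


def generate_panel(
    spec: PopulationSpec,
    dynamics: DynamicsParams,
    seed: int = 0,
) -> PanelDataset:
    """Generate the longitudinal donor panel.

    Each factor follows ``x_w = m(age_w) + d_w`` with a linear age trend
    ``m`` anchored at the cohort's natural-scale mean and a stationary AR(1)
    deviation ``d`` (per-wave coefficient ``ar_rho``, stationary SD
    ``deviation_sd``).  Smoking transitions occur per wave at the configured
    quit/relapse probabilities; never-smokers never transition.
    """
    if dynamics.n_waves < 2:
        raise ConfigurationError("n_waves must be at least 2 to derive transitions")
    rng = np.random.default_rng(seed)
    n, w = dynamics.n_persons, dynamics.n_waves
    step = dynamics.wave_years

    age0 = rng.integers(dynamics.age_min, max(dynamics.age_min, dynamics.age_max - step * (w - 1)) + 1, size=n)
    sex = _draw_categorical(rng, spec.category_marginals["sex"], n)
    smoking = _draw_categorical(rng, spec.category_marginals["smoking"], n)

    cont = spec.continuous
    mean_nat = {f: np.exp(cont["log_location"][f] + cont["log_scale"][f] ** 2 / 2.0) for f in FACTORS}
    rho = dynamics.ar_rho
    sd = {f: dynamics.deviation_sd[f] for f in FACTORS}
    trend = {f: dynamics.age_trend.get(f, 0.0) for f in FACTORS}

    dev = {f: rng.standard_normal(n) * sd[f] for f in FACTORS}
    levels = []  # per wave: dict factor -> array
    smoke_waves = [smoking.copy()]
    ages = [age0.copy()]
    for t in range(w):
        a = age0 + step * t
        levels.append({
            f: np.maximum(mean_nat[f] + trend[f] * (a - 42.0) + dev[f], 0.1) for f in FACTORS
        })
        if t < w - 1:
            innov_sd = {f: sd[f] * np.sqrt(max(1.0 - rho**2, 0.0)) for f in FACTORS}
            dev = {f: rho * dev[f] + rng.standard_normal(n) * innov_sd[f] for f in FACTORS}
            cur = smoke_waves[-1]
            u = rng.random(n)
            nxt = cur.copy()
            nxt[(cur == "current") & (u < dynamics.smoking_quit_prob_per_wave)] = "ex"
            nxt[(cur == "ex") & (u < dynamics.smoking_relapse_prob_per_wave)] = "current"
            smoke_waves.append(nxt)
            ages.append(a + step)

    records = []
    for t in range(w - 1):
        rec = {
            "person_id": np.arange(n),
            "wave": t,
            "age": age0 + step * t,
            "sex": sex,
            "smoking": smoke_waves[t],
            "smoking_next": smoke_waves[t + 1],
        }
        for f in FACTORS:
            rec[f] = levels[t][f]
            rec[f + "_next"] = levels[t + 1][f]
        records.append(pd.DataFrame(rec))
    return PanelDataset(pd.concat(records, ignore_index=True), wave_years=step)


# ---------------------------------------------------------------------------
# Synthetic epidemiology


def generate_epidemiology(
    config: dict | None = None,
) -> tuple[dict[str, RateTable], LifeTable]:
    """Build per-disease rate tables and the all-cause lifetable.

    For each disease the configured incidence and case-fatality curves are
    forward-integrated through the illness-death recurrence, and the implied
    prevalence and cause-mortality curves are emitted alongside them.  The
    all-cause lifetable is background mortality plus the summed modelled
    cause mortalities, so the engine's other-cause adjustment recovers the
    background exactly.  Emitted incidence/case-fatality columns are the
    generating truth; the pipeline re-derives them with the solver.
    """
    config = config if config is not None else load_default_config()
    epi = config["epidemiology"]
    a0, a1 = int(epi["age_min"]), int(epi["age_max"])
    if a0 > 40 or a1 < 100:
        raise ConfigurationError("epidemiology ages must cover 40-100")
    ages = np.arange(a0, a1 + 1)
    rel = ages - a0

    background = {
        s: epi["background_mortality"][s]["m0"] * np.exp(epi["background_mortality"][s]["slope"] * rel)
        for s in SEXES
    }

    tables: dict[str, RateTable] = {}
    total_cm = {s: np.zeros(len(ages)) for s in SEXES}
    for disease, d in epi["diseases"].items():
        inc, cf, prev, cm = {}, {}, {}, {}
        for s in SEXES:
            ip = d["incidence"][s]
            inc[s] = np.clip(ip["i0"] * np.exp(ip["slope"] * rel), 0.0, 0.95)
            cf[s] = np.clip(d["case_fatality"]["f0"] + d["case_fatality"]["f_slope"] * rel, 0.0, 0.95)
            prev[s], cm[s] = forward_illness_death(
                inc[s], cf[s], background[s], prev0=float(d["prevalence_at_40"][s])
            )
            total_cm[s] += cm[s]
        tables[disease] = RateTable(
            disease=disease, ages=ages,
            incidence=inc, case_fatality=cf, prevalence=prev, cause_mortality=cm,
        )

    qx = {s: np.clip(background[s] + total_cm[s], 0.0, 1.0) for s in SEXES}
    return tables, LifeTable(ages=ages, qx=qx)
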