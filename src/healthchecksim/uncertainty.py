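"""Probabilistic sensitivity analysis and value-of-information ranking.

Every programme parameter carrying a 95% credible interval is given a
sampling distribution fitted to its point value and interval: beta for
probabilities (concentration solved so the 2.5-97.5 quantile width matches),
normal for effect sizes.  A PSA runs the paired simulation repeatedly, each
run with a fresh joint parameter draw (and the same draw applied to scenario
and reference), and summarises outcomes by their mean and 2.5/97.5
percentiles across runs.

Value of information for one parameter is the expected residual standard
deviation of an outcome if that parameter were learnt exactly:
``sqrt(E[Var(Y | theta)])``, estimated by binning the PSA sample on the
sorted parameter draws (a running-mean conditional-expectation smoother).
The within/between decomposition is exact on the sample, so the law of total
variance holds by construction.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import get_in, load_default_config, set_in
from .scenarios import PRESETS, ScenarioConfig, build_simulation, run_pair

Z95 = stats.norm.ppf(0.975)


@dataclass
class Parameter:
    """One uncertain parameter: point value, 95% CrI, distribution family and
    its location in the configuration tree."""

    name: str
    value: float
    lo: float
    hi: float
    family: str  # beta | normal
    path: tuple[str, ...]

    def __post_init__(self):
        if not self.lo <= self.value <= self.hi:
            raise ValueError(f"{self.name}: CrI ({self.lo}, {self.hi}) does not bracket {self.value}")
        if self.family == "beta" and not (0.0 <= self.lo and self.hi <= 1.0):
            raise ValueError(f"{self.name}: beta family requires a CrI inside [0, 1]")

    def _beta_shapes(self) -> tuple[float, float]:
        mu = self.value
        width = self.hi - self.lo

        def gap(log_kappa):
            k = np.exp(log_kappa)
            a, b = mu * k, (1 - mu) * k
            return (stats.beta.ppf(0.975, a, b) - stats.beta.ppf(0.025, a, b)) - width

        lk = optimize.brentq(gap, np.log(2.1), np.log(1e7))
        k = np.exp(lk)
        return mu * k, (1 - mu) * k

    def sample(self, rng: np.random.Generator) -> float:
        if self.hi == self.lo:
            return float(self.value)
        if self.family == "beta":
            a, b = self._beta_shapes()
            return float(rng.beta(a, b))
        if self.family == "normal":
            sd = (self.hi - self.lo) / (2 * Z95)
            return float(rng.normal(self.value, sd))
        raise ValueError(f"unknown family '{self.family}'")


def default_parameter_set(config: dict | None = None) -> list[Parameter]:
    """All Table-style programme parameters with credible intervals."""
    config = config if config is not None else load_default_config()
    hc = ("health_check",)
    entries = [
        ("ineligible_attendance", "beta", hc + ("eligibility", "ineligible_attendance_prob")),
        ("statin_uptake_low", "beta", hc + ("uptake", "statin", "low")),
        ("statin_uptake_high", "beta", hc + ("uptake", "statin", "high")),
        ("aht_uptake_low", "beta", hc + ("uptake", "antihypertensive", "low")),
        ("aht_uptake_high", "beta", hc + ("uptake", "antihypertensive", "high")),
        ("smoking_referral", "beta", hc + ("uptake", "smoking_referral")),
        ("weight_referral", "beta", hc + ("uptake", "weight_referral")),
        ("statin_initial_adherence", "beta", hc + ("adherence", "statin_initial")),
        ("aht_initial_adherence", "beta", hc + ("adherence", "aht_initial")),
        ("annual_discontinuation", "beta", hc + ("adherence", "annual_discontinuation")),
        ("weight_attendance", "beta", hc + ("adherence", "weight_attend")),
        ("statin_tc_male", "normal", hc + ("effects", "statin_tc", "male")),
        ("statin_tc_female", "normal", hc + ("effects", "statin_tc", "female")),
        ("statin_hdl_male", "normal", hc + ("effects", "statin_hdl", "male")),
        ("statin_hdl_female", "normal", hc + ("effects", "statin_hdl", "female")),
        ("ace_sbp", "normal", hc + ("effects", "ace_bp", "sbp")),
        ("ace_dbp", "normal", hc + ("effects", "ace_bp", "dbp")),
        ("ccb_sbp_male", "normal", hc + ("effects", "ccb_bp", "male", "sbp")),
        ("ccb_sbp_female", "normal", hc + ("effects", "ccb_bp", "female", "sbp")),
        ("quit_prob_1yr", "beta", hc + ("effects", "quit_prob_1yr")),
    ]
    params = []
    for name, family, path in entries:
        entry = get_in(config, *path)
        params.append(Parameter(name=name, family=family, path=path,
                                value=float(entry["value"]), lo=float(entry["lo"]), hi=float(entry["hi"])))
    return params


def sample_parameters(
    params: list[Parameter], master_seed: int, run_index: int
) -> dict[str, float]:
    """Joint draw for one PSA run, reproducible from (master_seed, run_index)."""
    rng = np.random.default_rng(np.random.SeedSequence([master_seed, run_index, 5]))
    return {p.name: p.sample(rng) for p in params}


def inject(config: dict, params: list[Parameter], draws: dict[str, float]) -> dict:
    """New config with each parameter's point value replaced by its draw."""
    out = copy.deepcopy(config)
    for p in params:
        entry = get_in(out, *p.path)
        entry["value"] = float(draws[p.name])
        if p.family == "beta":
            entry["value"] = float(np.clip(entry["value"], 0.0, 1.0))
        entry["lo"] = min(entry["lo"], entry["value"])
        entry["hi"] = max(entry["hi"], entry["value"])
    return out


@dataclass
class PsaResult:
    """Per-run parameter draws and outcomes, with percentile summaries."""

    draws: pd.DataFrame      # one row per run, one column per parameter
    outcomes: pd.DataFrame   # one row per run, one column per outcome metric

    def summary(self) -> pd.DataFrame:
        rows = []
        for col in self.outcomes.columns:
            v = self.outcomes[col].to_numpy()
            rows.append({"metric": col, "mean": v.mean(),
                         "lo95": np.percentile(v, 2.5), "hi95": np.percentile(v, 97.5)})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        pd.concat([self.draws.add_prefix("param."), self.outcomes.add_prefix("outcome.")],
                  axis=1).to_csv(path, index=False)


def psa(
    scenario: ScenarioConfig | str,
    reference: ScenarioConfig | str,
    master_seed: int = 0,
    n_runs: int = 100,
    n_individuals: int = 20000,
    config: dict | None = None,
    params: list[Parameter] | None = None,
) -> PsaResult:
    """Probabilistic sensitivity analysis over the paired comparison.

    The cohort, donor panel and derived rates are built once; each run
    samples the programme parameters jointly (scenario and reference share
    the draw), re-runs the paired simulation with fresh common random
    numbers, and records the outcome table.  When a scenario requests
    CVD-score sampling, one log-normal multiplier is drawn per run.
    """
    config = config if config is not None else load_default_config()
    if isinstance(scenario, str):
        scenario = PRESETS[scenario]
    if isinstance(reference, str):
        reference = PRESETS[reference]
    params = params if params is not None else default_parameter_set(config)
    sim = build_simulation(config, n_individuals=n_individuals, seed=master_seed)

    from .scenarios import QriskMultiplierDistribution

    qdist = QriskMultiplierDistribution(
        q_lo=float(config["qrisk_multiplier"]["q_lo"]),
        q_hi=float(config["qrisk_multiplier"]["q_hi"]),
    )
    draw_rows, outcome_rows = [], []
    for run in range(n_runs):
        draws = sample_parameters(params, master_seed, run)
        cfg_run = inject(config, params, draws)
        qmult = 1.0
        if scenario.qrisk_multiplier_sampling or reference.qrisk_multiplier_sampling:
            qrng = np.random.default_rng(np.random.SeedSequence([master_seed, run, 9]))
            qmult = qdist.draw(qrng)
            draws["qrisk_multiplier"] = qmult
        # fresh simulation randomness per run, paired within the run
        table = run_pair(
            scenario, reference, master_seed=int(np.random.SeedSequence([master_seed, run, 3]).generate_state(1)[0] % 2**31),
            config=cfg_run, sim=sim, qrisk_multiplier=qmult,
        )
        draw_rows.append(draws)
        outcome_rows.append(table.metrics)
    return PsaResult(draws=pd.DataFrame(draw_rows), outcomes=pd.DataFrame(outcome_rows))


def value_of_information(
    result: PsaResult,
    parameter: str,
    outcome: str = "qaly_total_per_million",
    n_bins: int | None = None,
) -> dict[str, float]:
    """SD-if-learnt and variance fraction for one parameter.

    Runs are sorted by the parameter draw and split into roughly equal bins;
    the between-bin variance of the outcome estimates Var(E[Y | theta]) and
    the within-bin remainder estimates E[Var(Y | theta)] (their sum is the
    total sample variance, so the conditional SD never exceeds the marginal
    SD).  Requires at least 30 runs for a stable estimate.
    """
    if parameter not in result.draws.columns:
        raise KeyError(f"parameter '{parameter}' not in the PSA draws")
    x = result.draws[parameter].to_numpy()
    y = result.outcomes[outcome].to_numpy()
    n = len(x)
    if n < 30:
        raise ValueError("value-of-information estimation needs at least 30 runs")
    n_bins = n_bins if n_bins is not None else max(int(np.sqrt(n)), 5)
    order = np.argsort(x, kind="stable")
    y_sorted = y[order]
    bins = np.array_split(y_sorted, n_bins)
    total_var = float(np.var(y))
    if total_var == 0.0 or np.ptp(x) == 0.0:
        return {"sd_if_learnt": float(np.std(y)), "variance_fraction": 0.0,
                "marginal_sd": float(np.std(y))}
    grand = y.mean()
    between = sum(len(b) * (b.mean() - grand) ** 2 for b in bins) / n
    within = sum(len(b) * np.var(b) for b in bins) / n
    return {
        "sd_if_learnt": float(np.sqrt(within)),
        "variance_fraction": float(between / total_var),
        "marginal_sd": float(np.sqrt(total_var)),
    }


def voi_report(result: PsaResult, outcome: str = "qaly_total_per_million") -> pd.DataFrame:
    """Value-of-information ranking over all sampled parameters."""
    rows = []
    for p in result.draws.columns:
        v = value_of_information(result, p, outcome=outcome)
        rows.append({"parameter": p, **v})
    return pd.DataFrame(rows).sort_values("variance_fraction", ascending=False).reset_index(drop=True)
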