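"""Illness-death rate derivation.

Annual age- and sex-specific incidence and case fatality are recovered from
prevalence and cause-specific mortality curves through a discrete three-state
illness-death model (well -> ill -> dead, with independent background
mortality and no remission: diseases are lifelong).  The same forward
recurrence is used by the synthetic epidemiology generator, by the solver,
and by the acute-fatality recalibration, so the three stay mutually
consistent by construction.

Discrete-cycle conventions
--------------------------
States are counted at the start of each one-year cycle.  Incident cases
arise mid-year and are exposed to case fatality for half a year
(``1 - sqrt(1 - f)``); prevalent cases are exposed for the full year.
Background (non-modelled-cause) mortality applies multiplicatively and
independently to both living states, so it cancels from the prevalence
recurrence -- prevalence and cause mortality together identify incidence
and case fatality one age at a time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .config import SEXES


class InfeasibleRatesError(ValueError):
    """Input prevalence/mortality curves admit no non-negative rate solution."""

    def __init__(self, message: str, age: int | None = None):
        super().__init__(message)
        self.age = age


@dataclass
class RateTable:
    """Age x sex table of annual rates for one disease.

    Arrays are indexed by ``age - ages[0]``.  ``case_fatality`` is the
    unadjusted (solved) annual death rate among prevalent cases;
    recalibration adds ``acute_fatality`` (first-year, from the acute event
    mix) and ``case_fatality_chronic`` (down-scaled subsequent-year rate).
    """

    disease: str
    ages: np.ndarray
    incidence: dict[str, np.ndarray]
    case_fatality: dict[str, np.ndarray]
    prevalence: dict[str, np.ndarray]
    cause_mortality: dict[str, np.ndarray]
    acute_fatality: dict[str, np.ndarray] = field(default_factory=dict)
    case_fatality_chronic: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=int)
        for sex in SEXES:
            for d in (self.incidence, self.case_fatality, self.prevalence, self.cause_mortality):
                arr = np.asarray(d[sex], dtype=float)
                if arr.shape != self.ages.shape:
                    raise ValueError(f"{self.disease}/{sex}: rate array length mismatch")
                if np.any(arr < 0):
                    raise ValueError(f"{self.disease}/{sex}: negative rates")
                d[sex] = arr
            if np.any(self.prevalence[sex] > 1):
                raise ValueError(f"{self.disease}/{sex}: prevalence above 1")

    def at(self, sex: str, ages: np.ndarray, column: str) -> np.ndarray:
        """Vectorised lookup of one rate column at integer ages (clamped)."""
        idx = np.clip(np.asarray(ages, dtype=int) - self.ages[0], 0, len(self.ages) - 1)
        return getattr(self, column)[sex][idx]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sex in SEXES:
            d = {
                "disease": self.disease,
                "sex": sex,
                "age": self.ages,
                "prevalence": self.prevalence[sex],
                "incidence": self.incidence[sex],
                "case_fatality": self.case_fatality[sex],
                "cause_mortality": self.cause_mortality[sex],
            }
            if self.acute_fatality:
                d["acute_fatality"] = self.acute_fatality[sex]
                d["case_fatality_chronic"] = self.case_fatality_chronic[sex]
            rows.append(pd.DataFrame(d))
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        # %.17g keeps the text representation lossless for float64
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RateTable":
        disease = df["disease"].iloc[0]
        ages = np.sort(df["age"].unique())
        cols = {c: {} for c in ("incidence", "case_fatality", "prevalence", "cause_mortality")}
        extra = {c: {} for c in ("acute_fatality", "case_fatality_chronic") if c in df.columns}
        for sex in SEXES:
            sub = df[df["sex"] == sex].sort_values("age")
            if np.any(np.diff(sub["age"].to_numpy()) != 1):
                raise ValueError(f"{disease}/{sex}: gaps in age coverage")
            for c in cols:
                cols[c][sex] = sub[c].to_numpy(dtype=float)
            for c in extra:
                extra[c][sex] = sub[c].to_numpy(dtype=float)
        return cls(disease=disease, ages=ages, **cols, **extra)

    @classmethod
    def from_csv(cls, path) -> "RateTable":
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"))


@dataclass
class LifeTable:
    """All-cause annual death probability by age and sex."""

    ages: np.ndarray
    qx: dict[str, np.ndarray]

    def at(self, sex: str, ages: np.ndarray) -> np.ndarray:
        idx = np.clip(np.asarray(ages, dtype=int) - self.ages[0], 0, len(self.ages) - 1)
        return self.qx[sex][idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.concat(
            [pd.DataFrame({"sex": sex, "age": self.ages, "qx": self.qx[sex]}) for sex in SEXES],
            ignore_index=True,
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path, float_precision="round_trip")
        ages = np.sort(df["age"].unique())
        qx = {s: df[df["sex"] == s].sort_values("age")["qx"].to_numpy(dtype=float) for s in SEXES}
        return cls(ages=np.asarray(ages, dtype=int), qx=qx)


def forward_illness_death(
    incidence: np.ndarray,
    case_fatality: np.ndarray,
    background: np.ndarray,
    prev0: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward-integrate the three-state model.

    Returns (prevalence, cause_mortality) on the same age grid as the inputs.
    Prevalence is the start-of-cycle ill fraction among the living; cause
    mortality is cause deaths during the cycle per start-of-cycle living
    person.
    """
    n = len(incidence)
    s, c = 1.0 - prev0, prev0
    prev = np.empty(n)
    cm = np.empty(n)
    for t in range(n):
        i, f, mb = incidence[t], case_fatality[t], background[t]
        alive = s + c
        prev[t] = c / alive if alive > 0 else 0.0
        new = s * i
        half = 1.0 - np.sqrt(max(1.0 - f, 0.0))
        deaths = c * f + new * half
        cm[t] = deaths / alive if alive > 0 else 0.0
        s = s * (1.0 - i) * (1.0 - mb)
        c = (c * (1.0 - f) + new * (1.0 - half)) * (1.0 - mb)
    return prev, cm


def _step_residual(x: np.ndarray, c: float, cm_t: float, prev_next: float) -> np.ndarray:
    i, f = x
    s = 1.0 - c
    half = 1.0 - np.sqrt(max(1.0 - f, 0.0))
    new = s * i
    r1 = (c * f + new * half) - cm_t
    c_next = c * (1.0 - f) + new * (1.0 - half)
    s_next = s * (1.0 - i)
    denom = c_next + s_next
    r2 = (c_next / denom if denom > 0 else 0.0) - prev_next
    return np.array([r1, r2])


def solve_illness_death(
    prevalence: np.ndarray,
    cause_mortality: np.ndarray,
    all_cause_mortality: np.ndarray,
    ages: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Recover annual incidence and case fatality from prevalence and
    cause-specific mortality (remission fixed at zero).

    Solves the discrete balance equations one age at a time: at each age the
    observed cause mortality and the next age's prevalence jointly determine
    the incidence and case-fatality pair.  Background mortality cancels from
    the prevalence recurrence, so ``all_cause_mortality`` only needs to
    dominate ``cause_mortality`` (it is used for feasibility checking).

    Raises :class:`InfeasibleRatesError` naming the first infeasible age.
    """
    prev = np.asarray(prevalence, dtype=float)
    cm = np.asarray(cause_mortality, dtype=float)
    qx = np.asarray(all_cause_mortality, dtype=float)
    n = len(prev)
    if ages is None:
        ages = np.arange(n)
    if np.any(cm > qx + 1e-12):
        a = int(ages[np.argmax(cm > qx + 1e-12)])
        raise InfeasibleRatesError(f"cause mortality exceeds all-cause mortality at age {a}", age=a)

    inc = np.zeros(n)
    cf = np.zeros(n)
    for t in range(n - 1):
        c, cm_t, prev_next = prev[t], cm[t], prev[t + 1]
        s = 1.0 - c
        if cm_t <= 1e-15 and prev_next <= 1e-15 and c <= 1e-15:
            continue  # empty disease at this age
        if cm_t <= 1e-15:
            # no case deaths: closed form i from the prevalence recurrence
            i = (prev_next - c) / (s * (1.0 - prev_next)) if s > 0 else 0.0
            if i < -1e-9:
                raise InfeasibleRatesError(
                    f"prevalence falls without cause deaths at age {int(ages[t])}", age=int(ages[t])
                )
            inc[t], cf[t] = max(i, 0.0), 0.0
            continue
        f_guess = min(cm_t / max(c, 0.02), 0.5)
        i_guess = max(prev_next - c, 1e-6) / max(s, 1e-9)
        sol = optimize.least_squares(
            _step_residual,
            x0=[min(max(i_guess, 1e-8), 0.5), max(f_guess, 1e-8)],
            bounds=([0.0, 0.0], [1.0, 0.999]),
            args=(c, cm_t, prev_next),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        if not sol.success or np.max(np.abs(sol.fun)) > 1e-8:
            raise InfeasibleRatesError(
                f"no non-negative rate solution at age {int(ages[t])} "
                f"(residual {np.max(np.abs(sol.fun)):.2e})",
                age=int(ages[t]),
            )
        inc[t], cf[t] = sol.x
    # Last age has no onward prevalence; carry case fatality and solve
    # incidence from the cause-mortality identity alone.
    cf[-1] = cf[-2] if n > 1 else 0.0
    c, s = prev[-1], 1.0 - prev[-1]
    half = 1.0 - np.sqrt(1.0 - cf[-1])
    rem = cm[-1] - c * cf[-1]
    inc[-1] = max(rem, 0.0) / (s * half) if s * half > 1e-12 else 0.0
    inc[-1] = min(inc[-1], 1.0)
    return inc, cf


def solve_rate_table(
    disease: str,
    ages: np.ndarray,
    prevalence: dict[str, np.ndarray],
    cause_mortality: dict[str, np.ndarray],
    lifetable: LifeTable,
) -> RateTable:
    """Solve the illness-death model for both sexes and assemble a RateTable."""
    inc, cf = {}, {}
    for sex in SEXES:
        inc[sex], cf[sex] = solve_illness_death(
            prevalence[sex], cause_mortality[sex], lifetable.at(sex, ages), ages=ages
        )
    return RateTable(
        disease=disease, ages=ages,
        incidence=inc, case_fatality=cf,
        prevalence={s: np.asarray(prevalence[s], float) for s in SEXES},
        cause_mortality={s: np.asarray(cause_mortality[s], float) for s in SEXES},
    )


# ---------------------------------------------------------------------------
# Acute-fatality recalibration


@dataclass
class AcuteFatalityParams:
    """First-year (acute) fatality structure of CVD events.

    ``mi_fraction``: share of incident IHD presenting as acute MI, by sex;
    ``mi_acute_cf``: fatality of an acute MI; ``stroke_full_fraction``: share
    of cerebrovascular events that are full strokes (the rest are TIAs, which
    carry no acute fatality); ``stroke_acute_cf``: fatality of a full stroke
    by sex and 80-year age threshold.
    """

    mi_fraction: dict[str, float]
    mi_acute_cf: dict[str, float]
    stroke_full_fraction: float
    stroke_acute_cf: dict[str, dict[str, float]]

    def __post_init__(self):
        vals = (
            list(self.mi_fraction.values()) + list(self.mi_acute_cf.values())
            + [self.stroke_full_fraction]
            + [v for d in self.stroke_acute_cf.values() for v in d.values()]
        )
        if any(not 0.0 <= v <= 1.0 for v in vals):
            raise ValueError("acute fatality parameters must lie in [0,1]")

    @classmethod
    def from_config(cls, config: dict) -> "AcuteFatalityParams":
        a = config["acute_fatality"]
        return cls(
            mi_fraction=a["mi_fraction"],
            mi_acute_cf=a["mi_acute_cf"],
            stroke_full_fraction=a["stroke_full_fraction"],
            stroke_acute_cf=a["stroke_acute_cf"],
        )

    def acute_mean(self, disease: str, sex: str, ages: np.ndarray) -> np.ndarray:
        """Expected first-year fatality over the acute event-type mix."""
        ages = np.asarray(ages)
        if disease == "ihd":
            return np.full(ages.shape, self.mi_fraction[sex] * self.mi_acute_cf[sex])
        if disease == "stroke":
            cf = np.where(
                ages < 80,
                self.stroke_acute_cf["under_80"][sex],
                self.stroke_acute_cf["over_80"][sex],
            )
            return self.stroke_full_fraction * cf
        return np.zeros(ages.shape)


def _forward_cause_deaths(
    incidence: np.ndarray,
    chronic_cf: np.ndarray,
    acute: np.ndarray,
    background: np.ndarray,
    prev0: float,
    half_year_new: bool,
) -> float:
    """Cumulative cause deaths under either fatality convention.

    ``half_year_new=True`` reproduces the solver's convention (incident cases
    half-year exposed to the chronic rate); ``False`` applies the acute
    first-year fatality to incident cases instead, with chronic fatality only
    from the following year.
    """
    s, c = 1.0 - prev0, prev0
    total = 0.0
    for t in range(len(incidence)):
        i, f, mb = incidence[t], chronic_cf[t], background[t]
        new = s * i
        if half_year_new:
            first = 1.0 - np.sqrt(max(1.0 - f, 0.0))
        else:
            first = acute[t]
        deaths = c * f + new * first
        total += deaths
        s = s * (1.0 - i) * (1.0 - mb)
        c = (c * (1.0 - f) + new * (1.0 - first)) * (1.0 - mb)
    return total


def recalibrate_case_fatality(
    table: RateTable,
    acute: AcuteFatalityParams,
    lifetable: LifeTable,
) -> RateTable:
    """Split solved case fatality into acute first-year and chronic parts.

    The acute event-type mix fixes the first-year fatality (e.g. men's IHD:
    0.58 MI share x 0.32 MI fatality = 0.1856); the chronic rate for
    subsequent years is scaled by a factor solved per sex so that cumulative
    cause deaths to the end of the age grid match the unadjusted table
    within the solver tolerance.  With zero acute parameters the table is
    returned with an identical chronic rate (identity).
    """
    ages = table.ages
    acute_f, chronic = {}, {}
    for sex in SEXES:
        a = acute.acute_mean(table.disease, sex, ages)
        inc = table.incidence[sex]
        cf = table.case_fatality[sex]
        mb = np.clip(lifetable.at(sex, ages) - table.cause_mortality[sex], 0.0, 1.0)
        prev0 = float(table.prevalence[sex][0])
        target = _forward_cause_deaths(inc, cf, a, mb, prev0, half_year_new=True)
        if np.all(a == 0):
            acute_f[sex], chronic[sex] = a, cf.copy()
            continue
        base_acute = _forward_cause_deaths(inc, np.zeros_like(cf), a, mb, prev0, half_year_new=False)
        if base_acute > target * (1 + 1e-9) and target > 0:
            raise InfeasibleRatesError(
                f"{table.disease}/{sex}: acute deaths alone exceed total implied deaths"
            )

        def gap(theta: float, sex=sex, inc=inc, cf=cf, a=a, mb=mb, prev0=prev0, target=target):
            return _forward_cause_deaths(inc, theta * cf, a, mb, prev0, half_year_new=False) - target

        if target <= 0:
            theta = 1.0
        else:
            theta = optimize.brentq(gap, 0.0, 3.0, xtol=1e-12)
        acute_f[sex], chronic[sex] = a, theta * cf
    return RateTable(
        disease=table.disease, ages=ages,
        incidence={s: table.incidence[s].copy() for s in SEXES},
        case_fatality={s: table.case_fatality[s].copy() for s in SEXES},
        prevalence={s: table.prevalence[s].copy() for s in SEXES},
        cause_mortality={s: table.cause_mortality[s].copy() for s in SEXES},
        acute_fatality=acute_f,
        case_fatality_chronic=chronic,
    )


# ---------------------------------------------------------------------------
# Smoking split


@dataclass
class SmokingSplitParams:
    """Population attributable fraction and smoking prevalence for the
    smoker/non-smoker incidence split."""

    paf: float
    smoking_prevalence: float | np.ndarray

    def __post_init__(self):
        if not 0.0 <= self.paf < 1.0:
            raise ValueError("paf must lie in [0, 1)")


def split_incidence_by_smoking(
    incidence: np.ndarray, split: SmokingSplitParams
) -> tuple[np.ndarray, np.ndarray]:
    """Split incidence into smoker and non-smoker rates.

    Exact closed form of the two identities
    ``p*i_s + (1-p)*i_ns = i`` (mixture conservation) and
    ``(i_s - i_ns) * p / i = paf`` (attributable fraction):
    ``i_ns = i*(1-paf)`` and ``i_s = i_ns + paf*i/p``.
    """
    i = np.asarray(incidence, dtype=float)
    p = np.asarray(split.smoking_prevalence, dtype=float)
    if split.paf > 0 and np.any((p <= 0) & (i > 0)):
        raise ValueError("paf > 0 requires positive smoking prevalence wherever incidence > 0")
    i_ns = i * (1.0 - split.paf)
    with np.errstate(divide="ignore", invalid="ignore"):
        i_s = np.where(i > 0, i_ns + split.paf * i / np.where(p > 0, p, 1.0), 0.0)
    return i_s, i_ns
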