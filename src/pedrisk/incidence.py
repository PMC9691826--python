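"""Population incidence handling.

Two jobs live here:

1. Turning calendar-period incidence tables (age-group x calendar-period rates
   per 100,000 person-years) into birth-cohort incidence curves by averaging
   along the cohort's Lexis diagonal.

2. Constraining the baseline hazard: given the joint population distribution
   of risk profiles (major genotype x polygene level x risk-factor bins, each
   with a hazard-multiplier curve RR_i(t)), find lambda_0(t) such that the
   population-averaged hazard among the still-disease-free equals the
   population rate lambda_pop(t) at every age.  The recursion runs forward
   from age 0, tracking each profile's disease-free survival
   S_i(t) = exp(-sum_{u<t} lambda_0(u) RR_i(u)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, ModelError
from .params import AGE_MAX

PER_100K = 1e5


@dataclass
class CalendarIncidenceTable:
    """Incidence rates per 100,000 person-years on an age x calendar-year grid.

    Internally dense over single years of age 0..79; 5-year (or any) age and
    period groups in input files are expanded by constant interpolation.
    """

    country: str
    sex: str
    cancer: str
    years: np.ndarray            # calendar years, contiguous
    rates: np.ndarray            # shape (80, len(years)), per 100k

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.shape != (AGE_MAX, len(self.years)):
            raise ConfigError("rates must have shape (80, n_years)")
        if np.any(np.diff(self.years) != 1):
            raise ConfigError("calendar years must be contiguous")
        if np.any(self.rates < 0):
            raise ConfigError("rates must be non-negative")

    @classmethod
    def from_tsv(cls, path: str | Path, country: str | None = None,
                 sex: str | None = None, cancer: str | None = None) -> "CalendarIncidenceTable":
        """Read the documented TSV layout: columns country, sex, cancer,
        age_lo, age_hi, year_lo, year_hi, rate_per_100k (inclusive bounds)."""
        df = pd.read_csv(path, sep="\t")
        need = {"country", "sex", "cancer", "age_lo", "age_hi", "year_lo", "year_hi", "rate_per_100k"}
        if not need.issubset(df.columns):
            raise ConfigError(f"{path}: missing columns {sorted(need - set(df.columns))}")
        for col, val in (("country", country), ("sex", sex), ("cancer", cancer)):
            if val is not None:
                df = df[df[col] == val]
        if df.empty:
            raise ConfigError(f"{path}: no rows match the requested table")
        if df[["country", "sex", "cancer"]].drop_duplicates().shape[0] != 1:
            raise ConfigError(f"{path}: ambiguous selection; pass country/sex/cancer")
        y0, y1 = int(df["year_lo"].min()), int(df["year_hi"].max())
        years = np.arange(y0, y1 + 1)
        rates = np.full((AGE_MAX, len(years)), np.nan)
        for _, r in df.iterrows():
            a0, a1 = int(r["age_lo"]), min(int(r["age_hi"]), AGE_MAX - 1)
            rates[a0:a1 + 1, int(r["year_lo"]) - y0:int(r["year_hi"]) - y0 + 1] = float(r["rate_per_100k"])
        if np.isnan(rates).any():
            raise ConfigError(f"{path}: age/period grid does not tile ages 0-79 x {y0}-{y1}")
        row = df.iloc[0]
        return cls(str(row["country"]), str(row["sex"]), str(row["cancer"]), years, rates)

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for a in range(AGE_MAX):
            for j, y in enumerate(self.years):
                rows.append((self.country, self.sex, self.cancer, a, a, y, y, self.rates[a, j]))
        pd.DataFrame(rows, columns=["country", "sex", "cancer", "age_lo", "age_hi",
                                    "year_lo", "year_hi", "rate_per_100k"]
                     ).to_csv(path, sep="\t", index=False)


@dataclass
class CohortIncidenceTable:
    """Per-person-year incidence probabilities lambda_pop(t) for one birth
    cohort, sex and cancer, complete over integer ages 0..79."""

    cohort: str
    sex: str
    cancer: str
    lam: np.ndarray  # shape (80,), per person-year

    def __post_init__(self):
        self.lam = np.asarray(self.lam, dtype=float)
        if self.lam.shape != (AGE_MAX,):
            raise ConfigError("cohort incidence must cover ages 0..79")
        if np.any(self.lam < 0):
            raise ConfigError("cohort incidence must be non-negative")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CohortIncidenceTable":
        df = pd.read_csv(path, sep="\t").sort_values("age")
        lam = np.asarray(df["rate_per_100k"], dtype=float) / PER_100K
        row = df.iloc[0]
        return cls(str(row["cohort"]), str(row["sex"]), str(row["cancer"]), lam)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"cohort": self.cohort, "sex": self.sex, "cancer": self.cancer,
                      "age": np.arange(AGE_MAX), "rate_per_100k": self.lam * PER_100K}
                     ).to_csv(path, sep="\t", index=False)


def build_cohort_incidence(cal: CalendarIncidenceTable,
                           birth_cohort: tuple[int, int] | int,
                           label: str | None = None) -> CohortIncidenceTable:
    """Average calendar rates along the birth cohort's Lexis diagonal.

    For each age t, lambda_pop(t) is the mean over birth years y in the cohort
    of the calendar rate at (age t, period y + t).  Periods beyond the last
    observed calendar year borrow the most recent observed year (and periods
    before the first observed year borrow the earliest).  Rates are converted
    to per-person-year probabilities by dividing by 100,000.
    """
    if isinstance(birth_cohort, int):
        birth_cohort = (birth_cohort, birth_cohort)
    y0, y1 = birth_cohort
    if y1 < y0:
        raise ConfigError("birth cohort range must be ordered")
    ymin, ymax = int(cal.years[0]), int(cal.years[-1])
    if y0 > ymax or y1 + AGE_MAX - 1 < ymin:
        raise ModelError(f"birth cohort {y0}-{y1} has no overlap with calendar years {ymin}-{ymax}")
    ages = np.arange(AGE_MAX)
    births = np.arange(y0, y1 + 1)
    # diagonal lookup with clipping = carry-forward/backward of edge periods
    idx = np.clip(births[None, :] + ages[:, None] - ymin, 0, len(cal.years) - 1)
    lam = cal.rates[ages[:, None], idx].mean(axis=1) / PER_100K
    return CohortIncidenceTable(label or f"{y0}-{y1}", cal.sex, cal.cancer, lam)


@dataclass
class RiskProfileDistribution:
    """Joint population distribution of risk profiles at birth.

    ``masses`` (n,) sums to 1 (zero-mass profiles allowed); ``rr`` (n, 80)
    holds each profile's hazard-multiplier curve over ages 0..79.
    """

    masses: np.ndarray
    rr: np.ndarray

    def __post_init__(self):
        self.masses = np.asarray(self.masses, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)
        if self.rr.ndim != 2 or self.rr.shape != (len(self.masses), AGE_MAX):
            raise ConfigError("rr must have shape (n_profiles, 80)")
        if abs(self.masses.sum() - 1.0) > 1e-12:
            raise ConfigError(f"profile masses sum to {self.masses.sum()}, not 1")
        if np.any(self.masses < 0) or np.any(self.rr <= 0):
            raise ConfigError("masses must be >= 0 and RR curves > 0")

    @classmethod
    def single(cls) -> "RiskProfileDistribution":
        return cls(np.array([1.0]), np.ones((1, AGE_MAX)))

    @classmethod
    def product(cls, *components: tuple[np.ndarray, np.ndarray]) -> "RiskProfileDistribution":
        """Outer product of independent (masses, rr) components.

        Each component's rr may be (k, 80) curves or a length-k vector of
        age-constant multipliers.
        """
        masses = np.array([1.0])
        rr = np.ones((1, AGE_MAX))
        for m, r in components:
            m = np.asarray(m, dtype=float)
            r = np.asarray(r, dtype=float)
            if r.ndim == 1:
                r = np.repeat(r[:, None], AGE_MAX, axis=1)
            masses = np.multiply.outer(masses, m).ravel()
            rr = (rr[:, None, :] * r[None, :, :]).reshape(-1, AGE_MAX)
        return cls(masses, rr)


@dataclass
class BaselineHazard:
    """Constrained baseline hazard lambda_0(t), t = 0..79, together with the
    per-profile disease-free survival trace used to build it."""

    lam0: np.ndarray
    survival: np.ndarray  # (n_profiles, 81): S_i(t) at ages 0..80

    def __post_init__(self):
        if np.any(self.lam0 < 0):
            raise ModelError("baseline hazard must be non-negative")


def constrain_baseline(pop: CohortIncidenceTable,
                       dist: RiskProfileDistribution) -> BaselineHazard:
    """Solve for the baseline hazard that reproduces population incidence.

    Sequentially for each age t (discrete, starting at 0):

        lambda_0(t) = lambda_pop(t) * sum_i m_i S_i(t) / sum_i m_i S_i(t) RR_i(t)
        S_i(t+1)    = S_i(t) * exp(-lambda_0(t) RR_i(t))

    so that the hazard averaged over the disease-free population equals
    lambda_pop(t) at every age.
    """
    m = dist.masses
    rr = dist.rr
    n = len(m)
    lam0 = np.empty(AGE_MAX)
    surv = np.empty((n, AGE_MAX + 1))
    s = np.ones(n)
    for t in range(AGE_MAX):
        surv[:, t] = s
        denom = float(m @ (s * rr[:, t]))
        if denom <= 0.0:
            raise ModelError(f"degenerate risk-profile distribution at age {t}: "
                             "population-average RR among the disease-free is zero")
        lam0[t] = pop.lam[t] * float(m @ s) / denom
        s = s * np.exp(-lam0[t] * rr[:, t])
    surv[:, AGE_MAX] = s
    return BaselineHazard(lam0, surv)


def expected_population_hazard(baseline: BaselineHazard,
                               dist: RiskProfileDistribution, t: int) -> float:
    """Hazard at age ``t`` averaged over the disease-free population
    (verification helper; equals the input incidence after constraining)."""
    if not (0 <= t < AGE_MAX):
        raise ValueError(f"age {t} outside 0..{AGE_MAX - 1}")
    m = dist.masses
    s = baseline.survival[:, t]
    num = float(m @ (s * dist.rr[:, t])) * baseline.lam0[t]
    den = float(m @ s)
    return num / den
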