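"""Deterministic synthetic-data generators.

Everything here is labelled synthetic: the incidence tables are smooth
constant/log-linear rate models, the pathology tables are logistic age trends
with the qualitative gene-specific directions of the real distributions, and
the pedigrees are simulated forward from the model itself (genotypes ->
hazards -> event ages), which makes parameter-recovery tests possible.  None
of the numbers imitate real national registry rates; do not use them for
clinical prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .incidence import CalendarIncidenceTable, PER_100K
from .params import AGE_MAX, PathologyDistribution
from .pedigree import Individual, Pedigree


@dataclass
class FixtureSpec:
    """Reproducible recipe for synthetic data.

    ``rate_model`` is "constant" (rate ``rate0`` everywhere) or "loglinear"
    (``rate0 * exp(age_slope*(age-50) + period_slope*(year-year0))`` capped at
    ``rate_cap``, zero below ``onset_age``).  The same seed always produces
    byte-identical outputs.
    """

    seed: int = 0
    years: tuple[int, int] = (1950, 2019)
    rate_model: str = "loglinear"
    rate0: float = 180.0          # per 100k at age 50 in year0
    age_slope: float = 0.09
    period_slope: float = 0.0
    rate_cap: float = 320.0
    onset_age: int = 20
    pedigree_size: tuple[int, int] = (3, 6)
    missingness: float = 0.5


def make_incidence(spec: FixtureSpec, cancer: str = "bc", sex: str = "F",
                   country: str = "synthetic") -> CalendarIncidenceTable:
    """Synthetic calendar-period incidence on an age x year grid."""
    y0, y1 = spec.years
    if y1 - y0 + 1 < 30:
        raise ConfigError("fixture incidence needs >= 30 calendar years")
    years = np.arange(y0, y1 + 1)
    ages = np.arange(AGE_MAX)
    if spec.rate_model == "constant":
        rates = np.full((AGE_MAX, len(years)), float(spec.rate0))
    elif spec.rate_model == "loglinear":
        grid = spec.rate0 * np.exp(spec.age_slope * (ages[:, None] - 50.0)
                                   + spec.period_slope * (years[None, :] - y0))
        rates = np.minimum(grid, spec.rate_cap)
    else:
        raise ConfigError(f"unknown rate model {spec.rate_model!r}")
    rates[:spec.onset_age, :] = 0.0
    return CalendarIncidenceTable(country, sex, cancer, years, rates)


def default_calendar_tables(spec: FixtureSpec | None = None) -> dict[str, CalendarIncidenceTable]:
    """One synthetic calendar table per modelled cancer endpoint.

    Magnitudes are chosen so lifetime risks land in realistic ranges
    (female breast ~10%, tubo-ovarian ~1.5%, male breast ~0.1%).
    """
    spec = spec or FixtureSpec()
    recipes = {
        "bc": ("F", 180.0, 320.0),
        "eoc": ("F", 22.0, 55.0),
        "mbc": ("M", 1.4, 3.5),
        "prostate": ("M", 120.0, 500.0),
        "pancreas": (None, 10.0, 35.0),
    }
    out = {}
    for cancer, (sex, rate0, cap) in recipes.items():
        s = FixtureSpec(seed=spec.seed, years=spec.years, rate_model=spec.rate_model,
                        rate0=rate0, age_slope=spec.age_slope, rate_cap=cap,
                        onset_age=spec.onset_age)
        out[cancer] = make_incidence(s, cancer=cancer, sex=sex or "both")
    return out


def _logistic_age_curve(ages: np.ndarray, start: float, end: float,
                        mid: float = 50.0, width: float = 12.0) -> np.ndarray:
    frac = 1.0 / (1.0 + np.exp(-(ages - mid) / width))
    return start + (end - start) * frac


def make_pathology_tables(spec: FixtureSpec | None = None) -> dict[str, PathologyDistribution]:
    """Synthetic gene-specific ER/TN tumour distributions.

    Qualitative directions: BARD1/RAD51C/RAD51D carriers predominantly develop
    ER-negative disease with the proportion decreasing with age; CHEK2/ATM
    carriers predominantly ER-positive with the ER-positive share increasing
    with age; among ER-negative tumours most are triple negative except for
    CHEK2.  The population table is age-constant.
    """
    ages = np.arange(20, AGE_MAX)
    tables = {
        "population": (np.full(len(ages), 0.22), np.full(len(ages), 0.55)),
        "BRCA1": (_logistic_age_curve(ages, 0.85, 0.65), np.full(len(ages), 0.80)),
        "BRCA2": (_logistic_age_curve(ages, 0.35, 0.22), np.full(len(ages), 0.45)),
        "PALB2": (_logistic_age_curve(ages, 0.55, 0.35), np.full(len(ages), 0.65)),
        "CHEK2": (_logistic_age_curve(ages, 0.18, 0.08), np.full(len(ages), 0.25)),
        "ATM": (_logistic_age_curve(ages, 0.25, 0.12), np.full(len(ages), 0.55)),
        "BARD1": (_logistic_age_curve(ages, 0.80, 0.55), np.full(len(ages), 0.75)),
        "RAD51C": (_logistic_age_curve(ages, 0.75, 0.50), np.full(len(ages), 0.72)),
        "RAD51D": (_logistic_age_curve(ages, 0.72, 0.48), np.full(len(ages), 0.70)),
    }
    return {name: PathologyDistribution(name, ages, p_er, p_tn)
            for name, (p_er, p_tn) in tables.items()}


# ---------------------------------------------------------------------------
# simulated pedigrees and cohorts


def _sample_event_age(rng: np.random.Generator, hazard: np.ndarray) -> int | None:
    """Sample an event age from a piecewise-constant hazard, None if no event
    by age 80."""
    u = rng.uniform()
    surv = np.exp(-np.cumsum(hazard))  # surv[t] = P(no event through year t)
    if u < surv[-1]:
        return None
    return int(np.argmax(surv < u))


def make_pedigree(spec: FixtureSpec, model, rng: np.random.Generator | None = None) -> Pedigree:
    """A random, structurally valid pedigree with phenotypes simulated from
    ``model`` (genotypes -> hazards -> event ages).

    The structure grows from a founder couple by adding children and their
    spouses; genotypes follow founder priors and Mendelian/polygenic
    transmission; diagnoses are drawn from each individual's genotype-specific
    hazards; test results and measured covariates are thinned by
    ``spec.missingness``.
    """
    rng = rng or np.random.default_rng(spec.seed)
    lo, hi = spec.pedigree_size
    if lo < 1:
        raise ConfigError("pedigree size must be >= 1")
    size = int(rng.integers(lo, hi + 1))
    if size == 2:
        size = 3  # a connected two-parent pedigree needs at least a trio
    prior = model.major_prior()
    masses = model._poly_masses

    people: list[dict] = []

    def new_person(sex, birth_year, father=None, mother=None):
        if father is None:
            g = int(rng.choice(model.n_major, p=prior))
            r = int(rng.choice(model.n_levels, p=masses))
        else:
            gf, rf = people[father]["g"], people[father]["r"]
            gm, rm = people[mother]["g"], people[mother]["r"]
            M = model._major_transmission()
            g = int(rng.choice(model.n_major, p=M[:, gf, gm]))
            from .polygene import transmission_matrix
            g_levels = transmission_matrix(model.n_levels)[:, rf, rm]
            r = int(rng.choice(model.n_levels, p=g_levels))
        people.append({"sex": sex, "birth_year": birth_year, "father": father,
                       "mother": mother, "g": g, "r": r})
        return len(people) - 1

    if size == 1:
        new_person("F", 1960 + int(rng.integers(0, 30)))
    else:
        f0 = new_person("M", 1930 + int(rng.integers(0, 10)))
        m0 = new_person("F", people[f0]["birth_year"] + int(rng.integers(1, 4)))
        couples = [(f0, m0)]
        while len(people) < size:
            f, m = couples[int(rng.integers(len(couples)))]
            by = max(people[f]["birth_year"], people[m]["birth_year"]) + int(rng.integers(20, 35))
            child = new_person("F" if rng.uniform() < 0.5 else "M", by, f, m)
            # occasionally marry the child in and give the couple a child at
            # once, so every added spouse stays connected through offspring
            if len(people) <= size - 2 and rng.uniform() < 0.3:
                spouse = new_person("M" if people[child]["sex"] == "F" else "F",
                                    by + int(rng.integers(-2, 3)))
                pair = (child, spouse) if people[child]["sex"] == "M" else (spouse, child)
                couples.append(pair)
                by2 = max(people[pair[0]]["birth_year"], people[pair[1]]["birth_year"]) \
                    + int(rng.integers(20, 35))
                new_person("F" if rng.uniform() < 0.5 else "M", by2, pair[0], pair[1])

    members = []
    target_idx = int(rng.integers(len(people)))
    for i, p in enumerate(people):
        censor = int(np.clip(2020 - p["birth_year"], 0, AGE_MAX))
        diagnoses = {}
        pathology = None
        for cancer in model._applicable_cancers(p["sex"]):
            lam0 = model.baseline(cancer, p["birth_year"]).lam0
            rr = np.ones(AGE_MAX) if p["g"] == 0 else model.genes[p["g"] - 1].rr_curve(cancer)
            h = lam0 * rr
            if cancer == model.config.primary:
                h = h * model._poly_rr[p["r"]]
            age = _sample_event_age(rng, h)
            if age is not None and age < censor:
                diagnoses[cancer] = age
        if diagnoses:
            first = min(diagnoses.values())
            diagnoses = {c: a for c, a in diagnoses.items() if a == first}
        if "bc" in diagnoses and rng.uniform() > spec.missingness:
            gene = None if p["g"] == 0 else model.gene_names[p["g"] - 1]
            dist = model.config.pathology_for(gene)
            p_er, p_tn = dist._at(diagnoses["bc"])
            if rng.uniform() < p_er:
                pathology = "tn" if rng.uniform() < p_tn else "er_neg_not_tn"
            else:
                pathology = "er_pos"
        tests = {}
        if rng.uniform() > spec.missingness:
            gene = str(rng.choice(model.gene_names))
            gp = model.config.gene(gene)
            carrier = p["g"] == model.gene_names.index(gene) + 1
            positive = carrier and rng.uniform() < gp.sensitivity
            tests[gene] = "pos" if positive else "neg"
        members.append(Individual(
            id=f"I{i}", sex=p["sex"], birth_year=p["birth_year"], censor_age=censor,
            father=None if p["father"] is None else f"I{p['father']}",
            mother=None if p["mother"] is None else f"I{p['mother']}",
            diagnoses=diagnoses, pathology=pathology, tests=tests,
            target=(i == target_idx)))
    return Pedigree(members)


def simulate_cohort(n: int, carrier_prob: float, rr: float, lam0: np.ndarray,
                    rng: np.random.Generator,
                    censor_age: int = AGE_MAX) -> dict[str, np.ndarray]:
    """Simulate ``n`` independent individuals under a single-gene model.

    Each is a carrier with probability ``carrier_prob``; carriers' hazard is
    ``lam0 * rr``.  Returns carrier status, case status and event/censor age.
    """
    carrier = rng.uniform(size=n) < carrier_prob
    hazard = np.where(carrier[:, None], lam0[None, :] * rr, lam0[None, :])
    u = rng.uniform(size=n)
    surv = np.exp(-np.cumsum(hazard[:, :censor_age], axis=1))
    affected = u > surv[:, -1]
    age = np.full(n, censor_age)
    idx = np.argmax(surv < u[:, None], axis=1)
    age[affected] = idx[affected]
    return {"carrier": carrier, "affected": affected, "age": age}


def fit_single_gene_rr(data: dict[str, np.ndarray], lam0: np.ndarray,
                       grid: np.ndarray) -> float:
    """Grid-search maximum-likelihood estimate of a single-gene RR from a
    simulated cohort with observed carrier status."""
    carrier = data["carrier"]
    affected = data["affected"]
    age = data["age"]
    cum0 = np.concatenate([[0.0], np.cumsum(lam0)])
    best_rr, best_ll = None, -np.inf
    for rr in grid:
        mult = np.where(carrier, rr, 1.0)
        lam_at = lam0[np.clip(age, 0, AGE_MAX - 1)] * mult
        ll = -mult * cum0[age] + np.where(affected, np.log(lam_at), 0.0)
        total = float(ll.sum())
        if total > best_ll:
            best_rr, best_ll = float(rr), total
    return best_rr
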