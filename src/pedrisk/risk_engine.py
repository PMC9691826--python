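"""Absolute risk prediction and risk categorisation.

Risks are posterior-weighted cumulative incidences: the pedigree posterior
over the target's genotype states (major gene x polygene level, plus the
conditional distribution of any unmeasured risk-factor bins) weights each
state's cumulative hazard from the current age to the horizon.  Lifetime risk
is the cumulative risk between ages 20 and 80 for a currently unaffected
20-year-old.  Reclassification distributions enumerate/integrate lifetime
risk over the population distribution of unobserved factors (categorical risk
factors exactly, the PRS on a Gauss-Hermite grid).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import continuous_rf as crf
from .errors import ConfigError, ModelError
from .model import RiskModel
from .params import AGE_MAX, RiskCategoryScheme
from .pedigree import Individual, Pedigree, state_posterior

#: default censoring age for the affected mother in the two-person
#: family-history scenario (configurable knob)
MOTHER_CENSOR_AGE = 55


@dataclass
class RiskResult:
    """Risk prediction for one target and cancer endpoint."""

    cancer: str
    ages: np.ndarray          # horizon ages, current age .. horizon
    cumulative: np.ndarray    # cumulative risk at each horizon age
    lifetime: float | None    # cumulative risk age 20..80 (None if N/A)
    category: str | None

    def __post_init__(self):
        if np.any(np.diff(self.cumulative) < -1e-12):
            raise ModelError("risk curve must be non-decreasing")
        if np.any((self.cumulative < -1e-12) | (self.cumulative > 1 + 1e-12)):
            raise ModelError("risk curve must lie in [0, 1]")


@dataclass
class RiskDistribution:
    """Lifetime-risk distribution over unobserved factors for a fixed carrier
    status and family history."""

    risks: np.ndarray
    masses: np.ndarray
    category_proportions: dict[str, float]

    def mean(self) -> float:
        return float(self.masses @ self.risks)


def _target_state_mix(pedigree: Pedigree, model: RiskModel, clamp=None):
    """Joint posterior P(state, rf-combo | data) for the target, split as
    P(state) and P(combo | state), plus the combo hazard multipliers."""
    target = pedigree.target
    post = state_posterior(pedigree, model, clamp=clamp)
    pen, weights = model.phenotype_components(target)
    joint = pen * weights[None, :]
    row = joint.sum(axis=1, keepdims=True)
    cond = np.where(row > 0, joint / np.where(row > 0, row, 1.0), weights[None, :])
    _, rf_rrs, measured = model.rf_components(target)
    return post, cond, rf_rrs, measured


def future_risk(pedigree: Pedigree, model: RiskModel, cancer: str,
                horizon_age: int, clamp=None) -> RiskResult:
    """Cumulative risk of ``cancer`` from the target's current age to each age
    up to ``horizon_age``, weighted by the pedigree posterior."""
    target = pedigree.target
    if cancer in target.diagnoses:
        raise ModelError(f"target already affected with {cancer}; contralateral/"
                         "second-cancer risks are out of scope")
    if cancer not in model._applicable_cancers(target.sex):
        raise ModelError(f"cancer {cancer!r} is not modelled for sex {target.sex}")
    a = target.observation_age
    if not (a < horizon_age <= AGE_MAX):
        raise ModelError(f"horizon {horizon_age} must lie in ({a}, {AGE_MAX}]")
    post, cond, rf_rrs, measured = _target_state_mix(pedigree, model, clamp)
    lam0 = model.baseline(cancer, target.birth_year).lam0
    rr_major = np.vstack([np.ones(AGE_MAX)] + [g.rr_curve(cancer) for g in model.genes])
    h = lam0[None, :] * rr_major
    if cancer == model.config.primary:
        h = h[:, None, None, :] * model._poly_rr[None, :, None, :] \
            * (measured * rf_rrs)[None, None, :, None]
    else:
        h = np.broadcast_to(h[:, None, None, :],
                            (model.n_major, model.n_levels, len(rf_rrs), AGE_MAX))
    h = h.reshape(model.n_states, len(rf_rrs), AGE_MAX)
    ages = np.arange(a + 1, horizon_age + 1)
    cum_h = np.cumsum(h[:, :, a:horizon_age], axis=-1)
    surv = np.exp(-cum_h)  # (states, combos, horizons)
    weights = post[:, None] * cond
    cumulative = 1.0 - np.einsum("sb,sbh->h", weights, surv)
    lifetime = None
    category = None
    if a <= 20 and horizon_age == AGE_MAX:
        i20 = np.searchsorted(ages, 20)
        base = 0.0 if a == 20 else float(cumulative[i20 - 1]) if i20 > 0 else 0.0
        # risk between 20 and 80 conditional on being disease-free at 20
        lifetime = (float(cumulative[-1]) - base) / (1.0 - base) if base < 1 else 0.0
        scheme = model.config.risk_categories.get(cancer)
        if scheme is not None:
            category = scheme.categorize(lifetime)
    return RiskResult(cancer, ages, cumulative, lifetime, category)


def lifetime_risk(pedigree: Pedigree, model: RiskModel, cancer: str,
                  clamp=None) -> float:
    """Cumulative risk between ages 20 and 80 for a currently unaffected
    20-year-old target (the target's censoring age is reset to 20)."""
    target = pedigree.target
    if cancer in target.diagnoses:
        raise ModelError(f"target already affected with {cancer}")
    if target.observation_age != 20:
        target20 = replace(target, censor_age=min(target.censor_age, 20))
        if target20.observation_age != 20:
            raise ModelError("lifetime risk requires a target unaffected at age 20")
        pedigree = pedigree.with_member(target20)
    res = future_risk(pedigree, model, cancer, AGE_MAX, clamp=clamp)
    return float(res.lifetime)


def categorize(risk: float, scheme: RiskCategoryScheme) -> str:
    """Map a lifetime risk to its category label."""
    return scheme.categorize(risk)


def _fh_pedigree(fh: str | Pedigree, model: RiskModel, birth_year: int = 1985,
                 mother_censor_age: int = MOTHER_CENSOR_AGE) -> Pedigree:
    if isinstance(fh, Pedigree):
        return fh
    target = Individual(id="proband", sex="F", birth_year=birth_year,
                        censor_age=20, target=True)
    if fh == "unknown":
        return Pedigree([target])
    if fh == "mother50":
        cancer = "bc" if model.config.primary == "bc" else "eoc"
        mother = Individual(id="mother", sex="F", birth_year=birth_year - 25,
                            censor_age=mother_censor_age, diagnoses={cancer: 50})
        father = Individual(id="father", sex="M", birth_year=birth_year - 27,
                            censor_age=mother_censor_age)
        target = replace(target, father="father", mother="mother")
        return Pedigree([target, mother, father])
    raise ConfigError(f"unknown family-history spec {fh!r}")


def make_rf_risk_functional(model: RiskModel, rf_name: str, birth_year: int = 1985):
    """Build the ``risk_functional(bins, x)`` used for bin-count selection.

    The returned callable swaps the named continuous risk factor's bin set for
    the one supplied (rebuilding the constrained baselines at that bin count,
    cached per ``n``) and returns the lifetime primary-cancer risk of a solo
    unaffected female whose measured factor value is ``x``.
    """
    import dataclasses

    rf0 = next(r for r in model.config.risk_factors
               if isinstance(r, crf.ContinuousRF) and r.name == rf_name)
    models: dict[int, RiskModel] = {}

    def functional(bins: crf.RFBinSet, x: float) -> float:
        n = bins.n_bins
        if n not in models:
            rfs = [dataclasses.replace(r, n_bins=n)
                   if isinstance(r, crf.ContinuousRF) and r.name == rf_name else r
                   for r in model.config.risk_factors]
            cfg = dataclasses.replace(model.config, genes=model.config.genes,
                                      risk_factors=rfs)
            m2 = RiskModel(cfg, model.calendar, cohort_span=model.cohort_span)
            m2._binsets[rf_name] = bins
            models[n] = m2
        m2 = models[n]
        target = Individual(id="t", sex="F", birth_year=birth_year, censor_age=20,
                            target=True, rf_values={rf_name: float(x)})
        return lifetime_risk(Pedigree([target]), m2, m2.config.primary)

    return functional


def _gauss_hermite_prs(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Nodes and weights integrating a standard normal PRS z-score."""
    x, w = np.polynomial.hermite_e.hermegauss(n_nodes)
    return x, w / w.sum()


def risk_distribution(carrier_status: str | None, fh_spec: str | Pedigree,
                      factors: tuple[str, ...], model: RiskModel,
                      n_prs_nodes: int = 64,
                      mother_censor_age: int = MOTHER_CENSOR_AGE) -> RiskDistribution:
    """Lifetime-risk distribution over the population distribution of the
    chosen unobserved factors.

    ``carrier_status`` fixes the target's major genotype (a gene name, or
    None for a population non-carrier); ``factors`` is a subset of the
    modelled categorical risk-factor names plus "prs".  Categorical factors
    are enumerated exactly; the PRS is integrated on a Gauss-Hermite grid.
    """
    ped = _fh_pedigree(fh_spec, model, mother_censor_age=mother_censor_age)
    target = ped.target
    clamp = None
    if carrier_status is not None:
        if carrier_status not in model.gene_names:
            raise ConfigError(f"unknown gene {carrier_status!r}")
        gi = model.gene_names.index(carrier_status) + 1
        mask = np.zeros(model.n_states)
        mask[gi * model.n_levels:(gi + 1) * model.n_levels] = 1.0
        clamp = {target.id: mask}
    else:
        mask = np.zeros(model.n_states)
        mask[: model.n_levels] = 1.0
        clamp = {target.id: mask}

    rf_by_name = {rf.name: rf for rf in model.config.risk_factors}
    grids: list[tuple[str, np.ndarray, np.ndarray]] = []  # (factor, values, masses)
    for f in factors:
        if f == "prs":
            z, w = _gauss_hermite_prs(n_prs_nodes)
            grids.append(("prs", z, w))
        elif f in rf_by_name and isinstance(rf_by_name[f], crf.CategoricalRF):
            rf = rf_by_name[f]
            grids.append((f, np.arange(len(rf.masses), dtype=float), rf.masses))
        else:
            raise ConfigError(f"no population distribution available for factor {f!r}")

    shape = [len(g[1]) for g in grids]
    risks, masses = [], []
    for idx in np.ndindex(*shape) if grids else [()]:
        t = replace(target, rf_values=dict(target.rf_values), tests=dict(target.tests))
        mass = 1.0
        for (name, values, w), k in zip(grids, idx):
            mass *= float(w[k])
            if name == "prs":
                t.prs_z = float(values[k])
            else:
                t.rf_values[name] = float(values[k])
        p = ped.with_member(t)
        risks.append(lifetime_risk(p, model, model.config.primary, clamp=clamp))
        masses.append(mass)
    risks = np.asarray(risks)
    masses = np.asarray(masses)
    scheme = model.config.risk_categories[model.config.primary]
    props = {label: float(masses[[scheme.categorize(r) == label for r in risks]].sum())
             for label in scheme.labels}
    return RiskDistribution(risks, masses, props)
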