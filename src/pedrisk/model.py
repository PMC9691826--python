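"""Assembled risk model: parameters + incidence + polygene + risk factors.

:class:`RiskModel` owns the collapsed genotype state space (non-carrier or
carrier-of-one-gene under dominance, crossed with a discrete polygene level),
founder priors, transmission tensors, per-birth-cohort constrained baseline
hazards, and per-individual observation/penetrance factors.  The pedigree and
risk-engine modules consume it through that surface.

The polygenic component and the modelled risk factors multiply the hazard of
the model's primary cancer only; secondary cancers (e.g. relatives' ovarian,
male breast, prostate and pancreatic cancers in the breast-cancer model)
enter through their major-gene relative risks alone.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from . import continuous_rf as crf
from . import polygene as pg
from .errors import ConfigError, ModelError
from .incidence import (BaselineHazard, CalendarIncidenceTable, CohortIncidenceTable,
                        RiskProfileDistribution, build_cohort_incidence, constrain_baseline)
from .params import AGE_MAX, ModelConfig, default_config, pathology_category_prob
from .pedigree import Individual, test_likelihood

#: Which sex each cancer endpoint applies to.
CANCER_SEX = {"bc": "F", "eoc": "F", "mbc": "M", "prostate": "M", "pancreas": None}


class RiskModel:
    """A ready-to-evaluate multifactorial risk model.

    Parameters
    ----------
    config:
        Validated parameter registry (genes, polygene, pathology, risk
        factors, category schemes).
    calendar:
        Calendar-period incidence table per modelled cancer endpoint.
    cohort_span:
        Width in years of the birth cohorts used when constraining baselines
        (individuals are grouped by birth decade by default).
    """

    state_space_cap = 10_000_000

    def __init__(self, config: ModelConfig, calendar: dict[str, CalendarIncidenceTable],
                 cohort_span: int = 10):
        missing = [c for c in config.cancers if c not in calendar]
        if missing:
            raise ConfigError(f"no calendar incidence table for cancers {missing}")
        self.config = config
        self.calendar = calendar
        self.cohort_span = int(cohort_span)
        self.genes = config.genes
        self.n_major = len(self.genes) + 1
        self.n_levels = config.polygene.n_levels
        self.n_states = self.n_major * self.n_levels
        self._poly_values, self._poly_masses = pg.discretise_polygene(self.n_levels)
        self._poly_rr = pg.polygene_rr_matrix(config.polygene)  # (L, 80)
        self._baseline_cache: dict[tuple[str, int], BaselineHazard] = {}
        self._cohort_cache: dict[tuple[str, int], CohortIncidenceTable] = {}
        self._binsets: dict[str, crf.RFBinSet] = {}
        for rf in config.risk_factors:
            if isinstance(rf, crf.ContinuousRF):
                self._binsets[rf.name] = crf.discretise(rf)

    @classmethod
    def default(cls, primary: str = "bc", calendar=None, **config_overrides) -> "RiskModel":
        """The shipped default model with synthetic fixture incidences."""
        from . import fixtures
        config = default_config(primary)
        for key, val in config_overrides.items():
            setattr(config, key, val)
        if calendar is None:
            calendar = fixtures.default_calendar_tables()
        return cls(config, calendar)

    # -- genotype state space -------------------------------------------------

    @property
    def gene_names(self) -> tuple[str, ...]:
        return self.config.gene_names

    def state_index(self, gene: str | None, level: int) -> int:
        g = 0 if gene is None else self.gene_names.index(gene) + 1
        return g * self.n_levels + level

    def major_prior(self) -> np.ndarray:
        """Founder prior over collapsed major genotypes (dominance collapse of
        independent HWE carrier states)."""
        carrier = np.array([g.carrier_prob for g in self.genes])
        prior = np.empty(self.n_major)
        not_higher = 1.0
        for i, c in enumerate(carrier):
            prior[i + 1] = c * not_higher
            not_higher *= 1.0 - c
        prior[0] = not_higher
        return prior

    def founder_prior_vector(self) -> np.ndarray:
        return np.kron(self.major_prior(), self._poly_masses)

    @lru_cache(maxsize=1)
    def _major_transmission(self) -> np.ndarray:
        """P(child major state | father, mother) under the dominance-collapsed
        representation expanded to per-gene allele counts.

        A parent collapsed to carrier-of-g is heterozygous or homozygous for g
        with the HWE conditional odds and carries no other gene's variant
        (double carriers are O(1e-6) and collapsed away); it transmits a g
        allele with probability q(1-q)+q^2 over its carrier probability.
        A child receiving alleles from both parents collapses to the
        higher-dominance gene.
        """
        G = self.n_major
        transmit = np.zeros(G)
        for i, g in enumerate(self.genes):
            q = g.allele_freq
            transmit[i + 1] = (q * (1 - q) + q * q) / g.carrier_prob
        M = np.zeros((G, G, G))
        for f in range(G):
            for m in range(G):
                af = transmit[f]
                am = transmit[m]
                outcomes = {
                    (True, True): af * am,
                    (True, False): af * (1 - am),
                    (False, True): (1 - af) * am,
                    (False, False): (1 - af) * (1 - am),
                }
                for (from_f, from_m), p in outcomes.items():
                    if p == 0.0:
                        continue
                    if from_f and from_m:
                        child = min(f, m) if f and m else max(f, m)
                    elif from_f:
                        child = f
                    elif from_m:
                        child = m
                    else:
                        child = 0
                    M[child, f, m] += p
        return M

    @lru_cache(maxsize=1)
    def transmission_tensor(self) -> np.ndarray:
        """Joint (major x polygene) transmission, shape (K, K, K)."""
        M = self._major_transmission()
        P = pg.transmission_matrix(self.n_levels)
        L, G = self.n_levels, self.n_major
        T = np.einsum("cfm,xyz->cxfymz", M, P).reshape(G * L, G * L, G * L)
        return T

    # -- incidence and baselines ----------------------------------------------

    def cohort_of(self, birth_year: int) -> int:
        return (int(birth_year) // self.cohort_span) * self.cohort_span

    def cohort_incidence(self, cancer: str, birth_year: int) -> CohortIncidenceTable:
        # cohorts younger than the calendar table borrow its latest cohort
        last = self.cohort_of(int(self.calendar[cancer].years[-1]))
        key = (cancer, min(self.cohort_of(birth_year), last))
        if key not in self._cohort_cache:
            y0 = key[1]
            self._cohort_cache[key] = build_cohort_incidence(
                self.calendar[cancer], (y0, y0 + self.cohort_span - 1))
        return self._cohort_cache[key]

    def profile_distribution(self, cancer: str) -> RiskProfileDistribution:
        """Joint population risk-profile distribution used to constrain the
        baseline hazard for ``cancer``."""
        rr_major = np.vstack([np.ones(AGE_MAX)]
                             + [g.rr_curve(cancer) for g in self.genes])
        comps = [(self.major_prior(), rr_major)]
        if cancer == self.config.primary:
            comps.append((self._poly_masses, self._poly_rr))
            for rf in self.config.risk_factors:
                comps.append(self._rf_population_bins(rf))
        return RiskProfileDistribution.product(*comps)

    def _rf_population_bins(self, rf) -> tuple[np.ndarray, np.ndarray]:
        if isinstance(rf, crf.ContinuousRF):
            b = self._binsets[rf.name]
            return b.masses, b.rrs
        return rf.masses, rf.normalised_rrs

    def baseline(self, cancer: str, birth_year: int) -> BaselineHazard:
        if cancer not in self.config.cancers:
            raise ModelError(f"no baseline available: cancer {cancer!r} is not modelled")
        key = (cancer, self.cohort_of(birth_year))
        if key not in self._baseline_cache:
            pop = self.cohort_incidence(cancer, birth_year)
            self._baseline_cache[key] = constrain_baseline(pop, self.profile_distribution(cancer))
        return self._baseline_cache[key]

    def incidence_weights(self, cancer: str, birth_year: int) -> np.ndarray:
        """Age weights proportional to cohort incidence (for variance
        averaging); uniform if the incidence is identically zero."""
        lam = self.cohort_incidence(cancer, birth_year).lam
        total = lam.sum()
        return np.full(AGE_MAX, 1.0 / AGE_MAX) if total <= 0 else lam / total

    # -- per-individual factors -----------------------------------------------

    def _applicable_cancers(self, sex: str) -> list[str]:
        return [c for c in self.config.cancers
                if CANCER_SEX[c] in (None, sex)]

    def rf_components(self, ind: Individual) -> tuple[np.ndarray, np.ndarray, float]:
        """(weights, rrs, measured_multiplier) for the individual's modelled
        risk factors on the primary cancer.

        Unmeasured factors contribute a mixture over their population bins;
        measured factors contribute a fixed multiplier (continuous factors via
        the zero-mass observed bin at the measured value).
        """
        weights = np.array([1.0])
        rrs = np.array([1.0])
        measured = 1.0
        for rf in self.config.risk_factors:
            if rf.name in ind.rf_values:
                x = ind.rf_values[rf.name]
                if isinstance(rf, crf.ContinuousRF):
                    observed = crf.add_observed_bin(self._binsets[rf.name], float(x))
                    measured *= observed.observed[1]
                else:
                    k = int(x)
                    if not (0 <= k < len(rf.masses)):
                        raise ModelError(f"{ind.id}: category {k} out of range for factor {rf.name}")
                    measured *= float(rf.normalised_rrs[k])
            else:
                m, r = self._rf_population_bins(rf)
                weights = np.multiply.outer(weights, m).ravel()
                rrs = np.multiply.outer(rrs, r).ravel()
        return weights, rrs, measured

    def phenotype_components(self, ind: Individual):
        """Phenotype (and pathology) likelihood split by risk-factor bin.

        Returns ``(pen, weights)`` with ``pen`` of shape (n_states, n_combos)
        and ``weights`` the mixture weights of the unmeasured risk-factor
        combinations; the marginal phenotype likelihood is ``pen @ weights``.
        """
        weights, rf_rrs, measured = self.rf_components(ind)
        B = len(weights)
        pen = np.ones((self.n_states, B))
        t_obs = ind.observation_age
        primary = self.config.primary
        for cancer in self._applicable_cancers(ind.sex):
            lam0 = self.baseline(cancer, ind.birth_year).lam0
            rr_major = np.vstack([np.ones(AGE_MAX)]
                                 + [g.rr_curve(cancer) for g in self.genes])
            # hazard per (major, level, combo, age)
            h = lam0[None, :] * rr_major  # (G, 80)
            if cancer == primary:
                h = h[:, None, None, :] * self._poly_rr[None, :, None, :] \
                    * (measured * rf_rrs)[None, None, :, None]
            else:
                h = np.broadcast_to(h[:, None, None, :],
                                    (self.n_major, self.n_levels, B, AGE_MAX))
            dx_age = ind.diagnoses.get(cancer)
            if dx_age is not None and dx_age <= t_obs:
                cum = h[..., :dx_age].sum(axis=-1)
                fac = np.exp(-cum) * h[..., dx_age]
                if cancer in ("bc", "mbc") and ind.pathology is not None:
                    path = np.array([pathology_category_prob(
                        self.config.pathology_for(None if g == 0 else self.gene_names[g - 1]),
                        ind.pathology, dx_age) for g in range(self.n_major)])
                    fac = fac * path[:, None, None]
            else:
                cum = h[..., :t_obs].sum(axis=-1)
                fac = np.exp(-cum)
            pen = pen * fac.reshape(self.n_states, B)
        return pen, weights

    def phenotype_likelihood_vector(self, ind: Individual) -> np.ndarray:
        pen, weights = self.phenotype_components(ind)
        return pen @ weights

    def observation_factor(self, ind: Individual) -> np.ndarray:
        """Genetic-test and PRS likelihood factor over genotype states."""
        fac_major = np.ones(self.n_major)
        for gene_name, result in ind.tests.items():
            gene = self.config.gene(gene_name)
            gi = self.gene_names.index(gene_name) + 1
            for g in range(self.n_major):
                fac_major[g] *= test_likelihood(result, g == gi, gene.sensitivity)
        fac = np.repeat(fac_major, self.n_levels)
        if ind.prs_z is not None:
            prs = pg.prs_observation_factor(self.config.polygene, ind.prs_z)
            fac = fac * np.tile(prs, self.n_major)
        return fac

    def penetrance(self, ind: Individual) -> np.ndarray:
        """Full per-state observation likelihood for one individual."""
        return self.phenotype_likelihood_vector(ind) * self.observation_factor(ind)


def phenotype_likelihood(ind: Individual, gene: str | None, level: int,
                         model: RiskModel) -> float:
    """Phenotype likelihood of one individual in a single genotype state
    (carrier of ``gene`` or None, polygene level index ``level``)."""
    vec = model.phenotype_likelihood_vector(ind)
    return float(vec[model.state_index(gene, level)])
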