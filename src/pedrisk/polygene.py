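"""Discretised polygenic component.

The residual familial aggregation not explained by the major genes is modelled
as a normally distributed log-hazard modifier with age-specific SD sigma_P(t).
For pedigree computation the polygene is discretised on the standard
binomial/hypergeometric grid: an individual's level is the number of "risk"
alleles at 2N hypothetical biallelic loci, so founders are Binomial(2N, 1/2)
and a child's level given its parents is the convolution of two
Hypergeometric(2N, R_parent, N) draws (each parent passes on a random half of
its alleles).  The standardised level values have exact mean 0 and variance 1.

This module also implements

* removal of newly added major genes' variance from sigma_P (so total familial
  variance is conserved when genes move from the polygene to explicit
  modelling), with the per-gene contribution on the log-RR scale
  v_g(t) = p(1-p) ln^2 RR_g(t), p the gene's carrier probability; and
* conditioning of the polygene on a measured PRS z-score explaining a fraction
  alpha^2 of the polygenic variance: the residual polygene is Normal with mean
  alpha * z * sigma_P and SD sqrt(1 - alpha^2) * sigma_P, realised as a
  shift/scale of the discretised grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

from .errors import ConfigError, ModelError
from .params import AGE_MAX, GeneParams, PolygeneSettings


def discretise_polygene(n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    """Standardised level values and masses of the discrete polygene.

    Masses follow Binomial(n_levels - 1, 1/2); values are the symmetric grid
    (k - N) / sqrt(N/2) with N = (n_levels - 1)/2, giving exact mean 0 and
    variance 1.
    """
    if n_levels < 3 or n_levels % 2 == 0:
        raise ConfigError("n_levels must be an odd integer >= 3")
    k = np.arange(n_levels)
    masses = stats.binom.pmf(k, n_levels - 1, 0.5)
    half = (n_levels - 1) / 2.0  # N; Binomial(2N, 1/2) has variance N/2
    values = (k - half) / np.sqrt(half / 2.0)
    return values, masses


@lru_cache(maxsize=8)
def transmission_matrix(n_levels: int) -> np.ndarray:
    """P(child level | father level, mother level), shape (L, L, L).

    Each parent transmits Hypergeometric(2N, R_parent, N) risk alleles; the
    child's level is their sum.  This keeps Binomial(2N, 1/2) stationary
    across generations and gives midparent means with segregation variance.
    """
    if n_levels < 3 or n_levels % 2 == 0:
        raise ConfigError("n_levels must be an odd integer >= 3")
    L = n_levels
    n2 = L - 1          # 2N loci
    nhalf = n2 // 2     # N alleles transmitted
    # gamete[r, g] = P(transmit g risk alleles | parent has r of 2N)
    gamete = np.zeros((L, nhalf + 1))
    for r in range(L):
        gamete[r] = stats.hypergeom.pmf(np.arange(nhalf + 1), n2, r, nhalf)
    T = np.zeros((L, L, L))
    for f in range(L):
        for m in range(L):
            child = np.convolve(gamete[f], gamete[m])
            T[: len(child), f, m] = child
    return T


@dataclass(frozen=True)
class MajorGeneVarianceContribution:
    """Per-age and incidence-weighted variance of one gene's log-RR
    contribution to familial aggregation."""

    gene: str
    v_by_age: np.ndarray   # v_g(t), shape (80,)
    v_mean: float          # incidence-weighted average


def gene_log_rr_variance(gene: GeneParams, cancer: str,
                         incidence_weights: np.ndarray) -> MajorGeneVarianceContribution:
    """Variance contributed by a major gene on the log-RR scale.

    ``v_g(t) = p (1 - p) ln^2 RR_g(t)`` with ``p`` the carrier probability;
    the summary ``v_mean`` averages over ages with the supplied incidence
    weights (which must sum to 1).
    """
    w = np.asarray(incidence_weights, dtype=float)
    if w.shape != (AGE_MAX,):
        raise ConfigError("incidence weights must cover ages 0..79")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ConfigError("incidence weights must sum to 1")
    p = gene.carrier_prob
    log_rr = np.log(gene.rr_curve(cancer))
    v = p * (1.0 - p) * log_rr**2
    return MajorGeneVarianceContribution(gene.name, v, float(w @ v))


def adjust_polygenic_sd(sd_old: np.ndarray,
                        contributions: list[MajorGeneVarianceContribution]) -> np.ndarray:
    """Shrink sigma_P so total familial variance is conserved when genes are
    added to the explicit major-gene model.

    ``sigma_new(t) = sqrt(sigma_old(t)^2 - sum_g v_g(t))``; raises if the
    genes' combined variance meets or exceeds the polygenic variance.
    """
    sd_old = np.broadcast_to(np.asarray(sd_old, dtype=float), (AGE_MAX,))
    total = np.zeros(AGE_MAX)
    for c in contributions:
        total = total + c.v_by_age
    if np.any(total >= sd_old**2):
        worst = int(np.argmax(total - sd_old**2))
        raise ModelError(f"variance deficit at age {worst}: gene variance "
                         f"{total[worst]:.3g} >= polygenic variance {sd_old[worst]**2:.3g}")
    return np.sqrt(sd_old**2 - total)


@dataclass(frozen=True)
class PolygeneDistribution:
    """A (possibly PRS-conditioned) discrete polygene distribution on the
    standardised scale; multiply values by sigma_P(age) for log-hazard."""

    values: np.ndarray
    masses: np.ndarray

    def moments(self) -> tuple[float, float]:
        mean = float(self.masses @ self.values)
        var = float(self.masses @ (self.values - mean) ** 2)
        return mean, var


def polygene_rr_matrix(settings: PolygeneSettings) -> np.ndarray:
    """Hazard multipliers exp(sigma_P(t) v_k) normalised to population mean 1
    at every age; shape (n_levels, 80)."""
    values, masses = discretise_polygene(settings.n_levels)
    log_rr = np.outer(values, settings.sd)
    rr = np.exp(log_rr)
    norm = masses @ rr  # per-age population mean
    return rr / norm


def condition_on_prs(settings: PolygeneSettings, z: float,
                     age: int | None = None) -> PolygeneDistribution:
    """Condition the discrete polygene on a measured PRS z-score.

    With alpha = sqrt(prs_alpha2), the residual polygene given PRS = z is
    Normal(alpha z, 1 - alpha^2) on the standardised scale, realised here by
    shifting/scaling the grid values (masses unchanged):
    ``v' = alpha z + sqrt(1 - alpha^2) v``.  ``age`` is accepted for symmetry
    with age-varying sigma_P; the standardised grid itself is age-free.
    """
    if not np.isfinite(z):
        raise ConfigError("PRS z-score must be finite")
    a2 = settings.prs_alpha2
    if not (0.0 <= a2 <= 1.0):
        raise ConfigError("prs_alpha2 must lie in [0,1]")
    values, masses = discretise_polygene(settings.n_levels)
    alpha = np.sqrt(a2)
    shifted = alpha * z + np.sqrt(1.0 - a2) * values
    return PolygeneDistribution(shifted, masses.copy())


def prs_observation_factor(settings: PolygeneSettings, z: float) -> np.ndarray:
    """Likelihood of observing PRS z given each discrete polygene level.

    Under PRS = alpha * polygene + independent noise (variance 1 - alpha^2 on
    the standardised scale), the factor is N(z; alpha v_k, 1 - alpha^2).  The
    degenerate alpha^2 = 1 case clamps to the nearest grid level.
    """
    if not np.isfinite(z):
        raise ConfigError("PRS z-score must be finite")
    a2 = settings.prs_alpha2
    values, _ = discretise_polygene(settings.n_levels)
    if a2 == 0.0:
        return np.ones_like(values)
    if a2 >= 1.0:
        out = np.zeros_like(values)
        out[int(np.argmin(np.abs(values - z)))] = 1.0
        return out
    alpha = np.sqrt(a2)
    return stats.norm.pdf(z, loc=alpha * values, scale=np.sqrt(1.0 - a2))
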