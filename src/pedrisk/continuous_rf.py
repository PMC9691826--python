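"""Risk-factor machinery: categorical factors and continuous-factor
discretisation with an infinitesimal "observed-value" bin.

A continuous risk factor with density P(x) and relative-risk function RR(x)
is discretised into ``n`` bins whose probability masses follow the binomial
distribution B(n-1, 1/2); bin boundaries are the corresponding quantiles of
the density.  The per-bin mass is

    P(i) = integral of P(x) over [l_i, u_i]

and the per-bin relative risk is the within-bin average

    RR(i) = (1/P(i)) * integral of RR(x) P(x) over [l_i, u_i],

computed by adaptive quadrature.  All bin RRs are then rescaled by the
population mean Z = sum_i P(i) RR(i) so the population-average RR is exactly 1
(absolute risks are invariant to this choice because the baseline-hazard
constraining step absorbs any constant).

For an individual with a measured value x an (n+1)-th bin of infinitesimal
width is appended: it has zero probability mass and RR equal to RR(x)/Z, so
the baseline constraining is unchanged while the individual's own hazard uses
the exact measured value rather than a bin average.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import integrate, stats

from .errors import ConfigError, ConvergenceError, ModelError

_SUPPORT_SDS = 8.0  # quadrature support: mean +/- 8 SD (tail mass < 1e-15)


@dataclass(frozen=True)
class CategoricalRF:
    """A categorical risk factor: category masses and hazard multipliers.

    RRs are stored as given; ``normalised_rrs`` rescales them to population
    mean 1 (the convention used inside the risk model).
    """

    name: str
    masses: np.ndarray
    rrs: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.masses, dtype=float)
        r = np.asarray(self.rrs, dtype=float)
        if m.shape != r.shape or m.ndim != 1 or len(m) < 2:
            raise ConfigError(f"{self.name}: need matching mass/RR vectors of length >= 2")
        if not np.isclose(m.sum(), 1.0, atol=1e-9):
            raise ConfigError(f"{self.name}: category masses must sum to 1")
        if np.any(m < 0) or np.any(r <= 0):
            raise ConfigError(f"{self.name}: masses must be >= 0 and RRs > 0")
        object.__setattr__(self, "masses", m)
        object.__setattr__(self, "rrs", r)

    @property
    def normalised_rrs(self) -> np.ndarray:
        return self.rrs / float(self.masses @ self.rrs)

    def to_config(self) -> dict:
        return {"name": self.name, "type": "categorical",
                "masses": [float(x) for x in self.masses],
                "rrs": [float(x) for x in self.rrs]}


@dataclass(frozen=True)
class ContinuousRF:
    """A normally distributed continuous risk factor with log-linear RR.

    ``RR(x) = exp(beta * (x - mean)/sd)`` with ``beta`` the log-RR per SD.
    The shipped example is adult height: mean 162.81 cm, SD 6.452 cm,
    beta = 0.10130 for both breast and ovarian cancer.
    """

    name: str
    mean: float
    sd: float
    log_rr_per_sd: float
    n_bins: int = 5

    def __post_init__(self):
        if self.sd <= 0:
            raise ConfigError(f"{self.name}: sd must be positive")
        if self.n_bins < 2:
            raise ConfigError(f"{self.name}: n_bins must be >= 2")

    def density(self, x):
        return stats.norm.pdf(x, loc=self.mean, scale=self.sd)

    def rr(self, x):
        """Unnormalised relative risk at value ``x``."""
        return np.exp(self.log_rr_per_sd * (np.asarray(x, dtype=float) - self.mean) / self.sd)

    def quantile(self, p):
        return stats.norm.ppf(p, loc=self.mean, scale=self.sd)

    def upper_quantile(self, p):
        """Value with upper-tail mass ``p`` (precise for tiny tails)."""
        return stats.norm.isf(p, loc=self.mean, scale=self.sd)

    @property
    def support(self) -> tuple[float, float]:
        return (self.mean - _SUPPORT_SDS * self.sd, self.mean + _SUPPORT_SDS * self.sd)

    def to_config(self) -> dict:
        return {"name": self.name, "type": "continuous", "mean": float(self.mean),
                "sd": float(self.sd), "log_rr_per_sd": float(self.log_rr_per_sd),
                "n_bins": int(self.n_bins)}


@dataclass(frozen=True)
class RFBinSet:
    """A discretised risk factor: bin masses, normalised bin RRs and edges,
    plus at most one zero-mass observed-value bin.

    ``norm`` is the population mean RR (Z) that was divided out; the observed
    bin's RR is RR(x)/Z on the same scale.
    """

    rf: ContinuousRF
    masses: np.ndarray
    rrs: np.ndarray
    edges: np.ndarray
    norm: float
    observed: tuple[float, float] | None = None  # (measured value, normalised RR)

    def __post_init__(self):
        if not np.isclose(self.masses.sum(), 1.0, atol=1e-9):
            raise ConfigError("bin masses must sum to 1")
        if np.any(self.rrs <= 0):
            raise ConfigError("bin RRs must be positive")
        if len(self.edges) != len(self.masses) + 1:
            raise ConfigError("need n+1 edges for n bins")

    @property
    def n_bins(self) -> int:
        return len(self.masses)

    def all_rrs(self) -> tuple[np.ndarray, np.ndarray]:
        """(masses, rrs) including the observed bin (mass 0) if present."""
        if self.observed is None:
            return self.masses, self.rrs
        return (np.append(self.masses, 0.0), np.append(self.rrs, self.observed[1]))


def binomial_bin_masses(n: int) -> np.ndarray:
    """Bin masses of the B(n-1, 1/2) discretisation scheme."""
    if n < 2:
        raise ConfigError("need at least 2 bins")
    return stats.binom.pmf(np.arange(n), n - 1, 0.5)


def discretise(rf: ContinuousRF, n: int | None = None) -> RFBinSet:
    """Discretise ``rf`` into ``n`` bins with binomial masses.

    Bin boundaries are quantiles of the density at the cumulative binomial
    masses; per-bin RRs are density-weighted averages computed by adaptive
    quadrature (relative tolerance 1e-10), then rescaled to population mean 1.
    """
    n = rf.n_bins if n is None else int(n)
    masses = binomial_bin_masses(n)
    # edge quantiles from whichever tail is numerically small, so tiny
    # binomial tail masses survive floating point near 0 and 1
    cum_lo = np.concatenate([[0.0], np.cumsum(masses)])
    cum_hi = np.concatenate([np.cumsum(masses[::-1])[::-1], [0.0]])
    edges = np.where(cum_lo <= 0.5, rf.quantile(cum_lo), rf.upper_quantile(cum_hi))
    lo, hi = rf.support
    # outermost edges are at quantiles 0/1 (infinite); close them far enough
    # out that the enclosed mass matches the binomial tail mass
    edges[0] = min(lo, edges[1] - 4 * rf.sd)
    edges[-1] = max(hi, edges[-2] + 4 * rf.sd)
    rrs = np.empty(n)
    for i in range(n):
        val, err = integrate.quad(lambda x: rf.rr(x) * rf.density(x),
                                  edges[i], edges[i + 1], epsrel=1e-10,
                                  epsabs=0.0, limit=200)
        if masses[i] <= 0 or not np.isfinite(val) or (val > 0 and err / val > 1e-6):
            raise ConvergenceError(f"quadrature failed to converge for bin {i}")
        rrs[i] = val / masses[i]
    z = float(masses @ rrs)
    return RFBinSet(rf=rf, masses=masses, rrs=rrs / z, edges=edges, norm=z)


def add_observed_bin(bins: RFBinSet, x: float) -> RFBinSet:
    """Append the infinitesimal zero-mass bin at the measured value ``x``.

    The bin's RR is RR(x)/Z with Z the normaliser used in :func:`discretise`;
    existing bins are unchanged, so there is no double counting.
    """
    if bins.observed is not None:
        raise ModelError("bin set already contains an observed bin")
    lo, hi = bins.rf.support
    if not (lo <= x <= hi):
        raise ModelError(f"measured value {x} outside the density's support")
    rr_x = float(bins.rf.rr(x)) / bins.norm
    return replace(bins, observed=(float(x), rr_x))


def rr_variance(obj: ContinuousRF | RFBinSet) -> float:
    """Variance of the population-normalised RR.

    Continuous case (log-normal RR): ``exp(beta^2) - 1``.  Discrete case:
    ``sum_i P(i) RR(i)^2 - 1`` over the normalised bins.
    """
    if isinstance(obj, ContinuousRF):
        b = obj.log_rr_per_sd
        return float(np.expm1(b * b))
    if isinstance(obj, RFBinSet):
        return float(obj.masses @ obj.rrs**2 - 1.0)
    if isinstance(obj, CategoricalRF):
        r = obj.normalised_rrs
        return float(obj.masses @ r**2 - 1.0)
    raise TypeError(f"cannot compute RR variance for {type(obj)!r}")


def asymptotic_value(seq: np.ndarray) -> float:
    """Estimate the limit of a convergent sequence from its last three terms
    (Aitken delta-squared extrapolation, falling back to the last term when
    the increments have vanished)."""
    seq = np.asarray(seq, dtype=float)
    if len(seq) < 3:
        return float(seq[-1])
    s0, s1, s2 = seq[-3], seq[-2], seq[-1]
    denom = (s2 - s1) - (s1 - s0)
    if abs(denom) < 1e-300 or abs(s2 - s1) < 1e-15 * max(abs(s2), 1e-300):
        return float(s2)
    return float(s2 - (s2 - s1) ** 2 / denom)


def bin_error_sequence(rf: ContinuousRF, risk_functional, n_values,
                       percentiles: np.ndarray | None = None) -> dict[int, float]:
    """RMS relative discretisation error of the predicted risk per bin count.

    For each ``n`` the lifetime risk is evaluated at 100 percentiles of the
    factor distribution (0.5% to 99.5%, 1% apart, by default); the error at
    ``n`` is the RMS over percentiles of the relative deviation from the
    asymptotic extrapolation of the risk sequence in ``n``.
    """
    if percentiles is None:
        percentiles = np.arange(0.005, 1.0, 0.01)
    xs = rf.quantile(percentiles)
    n_values = sorted(int(n) for n in n_values)
    risks = np.empty((len(n_values), len(xs)))
    for j, n in enumerate(n_values):
        bins = discretise(rf, n)
        risks[j] = [risk_functional(bins, x) for x in xs]
    limits = np.array([asymptotic_value(risks[:, i]) for i in range(len(xs))])
    errors = {}
    for j, n in enumerate(n_values):
        rel = (risks[j] - limits) / limits
        errors[n] = float(np.sqrt(np.mean(rel**2)))
    return errors


def choose_n_bins(rf: ContinuousRF, risk_functional, tolerance: float = 1e-4,
                  cap: int = 64, percentiles: np.ndarray | None = None,
                  return_errors: bool = False):
    """Smallest bin count whose RMS relative discretisation error is below
    ``tolerance``.

    ``risk_functional(bins, x)`` must map a bin set plus a measured value to a
    lifetime risk.  Bin counts are evaluated in increasing order until the risk
    sequence has stabilised enough to extrapolate its asymptote; raises
    :class:`ConvergenceError` if no ``n <= cap`` reaches the tolerance.
    """
    if tolerance <= 0:
        raise ConfigError("tolerance must be positive")
    if percentiles is None:
        percentiles = np.arange(0.005, 1.0, 0.01)
    xs = rf.quantile(percentiles)
    risks: list[np.ndarray] = []
    ns: list[int] = []
    for n in range(2, cap + 1):
        bins = discretise(rf, n)
        risks.append(np.asarray([risk_functional(bins, x) for x in xs]))
        ns.append(n)
        if len(risks) >= 3:
            step = np.max(np.abs(risks[-1] - risks[-2]) / np.abs(risks[-1]))
            prev = np.max(np.abs(risks[-2] - risks[-3]) / np.abs(risks[-2]))
            if max(step, prev) < tolerance * 1e-2:
                break
    arr = np.vstack(risks)
    limits = np.array([asymptotic_value(arr[:, i]) for i in range(arr.shape[1])])
    errors = {}
    for j, n in enumerate(ns):
        rel = (arr[j] - limits) / limits
        errors[n] = float(np.sqrt(np.mean(rel**2)))
    for n in ns:
        if errors[n] < tolerance:
            return (n, errors) if return_errors else n
    raise ConvergenceError(f"no bin count <= {cap} reached RMS error {tolerance}")
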