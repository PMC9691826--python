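"""Pedigree data model, file I/O and exact pedigree likelihoods.

Individuals carry phenotypes (cancer diagnoses with ages, censoring age),
genetic test results per gene, breast-tumour pathology, measured risk-factor
values and an optional PRS z-score.  The joint genotype space per person is
{non-carrier} + {carrier-of-gene-g} (multi-gene carriers collapsed to the
highest-dominance gene) crossed with a discrete polygene level.

The total pedigree likelihood sums founder priors x Mendelian/polygenic
transmission x observation likelihoods over all joint genotype assignments.
It is computed exactly by graph peeling (greedy variable elimination on the
factor graph), with a brute-force enumeration oracle provided for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional

import networkx as nx
import numpy as np

from .errors import ModelError, PedigreeError
from .params import AGE_MAX, PATHOLOGY_CATEGORIES

#: Reference year used when a censoring age must be derived from birth year.
REFERENCE_YEAR = 2020

PEDIGREE_HEADER_TAG = "##pedrisk-pedigree v1"
_CANCER_COLUMNS = ("bc", "eoc", "prostate", "pancreas")
_MISSING = "NA"


@dataclass
class Individual:
    """One pedigree member.

    ``diagnoses`` maps model cancer endpoints ("bc", "mbc", "eoc", "prostate",
    "pancreas") to age at diagnosis.  ``tests`` maps gene names to "neg" or
    "pos" (absent = untested).  ``pathology`` is one of the five ER/TN
    categories, attached to a breast-cancer diagnosis.  ``rf_values`` maps
    risk-factor names to measured values (continuous) or category indices
    (categorical).
    """

    id: str
    sex: str
    birth_year: int
    censor_age: Optional[int] = None
    father: Optional[str] = None
    mother: Optional[str] = None
    diagnoses: dict[str, int] = field(default_factory=dict)
    pathology: Optional[str] = None
    tests: dict[str, str] = field(default_factory=dict)
    rf_values: dict[str, float] = field(default_factory=dict)
    prs_z: Optional[float] = None
    target: bool = False

    def __post_init__(self):
        if self.sex not in ("M", "F"):
            raise PedigreeError(f"{self.id}: sex must be 'M' or 'F'")
        if (self.father is None) != (self.mother is None):
            raise PedigreeError(f"{self.id}: individuals need 0 or 2 recorded parents")
        if self.censor_age is None:
            self.censor_age = min(max(REFERENCE_YEAR - self.birth_year, 0), AGE_MAX)
        if not (0 <= self.censor_age <= AGE_MAX):
            raise PedigreeError(f"{self.id}: censor age {self.censor_age} outside 0..{AGE_MAX}")
        for cancer, age in self.diagnoses.items():
            if not (0 <= age <= AGE_MAX - 1):
                raise PedigreeError(f"{self.id}: diagnosis age {age} outside 0..{AGE_MAX - 1}")
            if age > self.censor_age:
                raise PedigreeError(f"{self.id}: diagnosis age {age} after censor age {self.censor_age}")
        if self.sex == "M" and ("eoc" in self.diagnoses or "bc" in self.diagnoses):
            raise PedigreeError(f"{self.id}: female-specific cancer recorded for a male")
        if self.sex == "F" and ("prostate" in self.diagnoses or "mbc" in self.diagnoses):
            raise PedigreeError(f"{self.id}: male-specific cancer recorded for a female")
        if self.pathology is not None:
            if self.pathology not in PATHOLOGY_CATEGORIES:
                raise PedigreeError(f"{self.id}: unknown pathology category {self.pathology!r}")
            if "bc" not in self.diagnoses and "mbc" not in self.diagnoses:
                raise PedigreeError(f"{self.id}: pathology recorded without a breast-cancer diagnosis")
        for g, res in self.tests.items():
            if res not in ("neg", "pos"):
                raise PedigreeError(f"{self.id}: test result for {g} must be 'neg' or 'pos'")

    @property
    def is_founder(self) -> bool:
        return self.father is None

    @property
    def observation_age(self) -> int:
        """Follow-up stops at the first cancer diagnosis or censoring."""
        ages = list(self.diagnoses.values())
        return min(ages + [self.censor_age])


class Pedigree:
    """A validated pedigree with exactly one target (proband)."""

    def __init__(self, members: list[Individual]):
        self.members: dict[str, Individual] = {}
        for ind in members:
            if ind.id in self.members:
                raise PedigreeError(f"duplicate individual id {ind.id!r}")
            self.members[ind.id] = ind
        if not self.members:
            raise PedigreeError("pedigree is empty")
        targets = [i.id for i in members if i.target]
        if len(targets) != 1:
            raise PedigreeError(f"pedigree must have exactly one target, found {len(targets)}")
        self.target_id = targets[0]
        self._validate_structure()

    def _validate_structure(self):
        g = nx.DiGraph()
        g.add_nodes_from(self.members)
        for ind in self.members.values():
            for parent, want_sex in ((ind.father, "M"), (ind.mother, "F")):
                if parent is None:
                    continue
                if parent not in self.members:
                    raise PedigreeError(f"{ind.id}: unknown parent {parent!r}")
                p = self.members[parent]
                if p.sex != want_sex:
                    raise PedigreeError(f"{ind.id}: parent {parent} has wrong sex for its role")
                if p.birth_year >= ind.birth_year:
                    raise PedigreeError(f"{ind.id}: born {ind.birth_year}, not after parent "
                                        f"{parent} born {p.birth_year}")
                g.add_edge(parent, ind.id)
        if not nx.is_directed_acyclic_graph(g):
            raise PedigreeError("cyclic parentage")
        if len(self.members) > 1 and not nx.is_weakly_connected(g):
            raise PedigreeError("pedigree is not connected")
        # consanguinity (inbreeding loops) is out of scope: reject clearly
        anc = {i: nx.ancestors(g, i) | {i} for i in self.members}
        for ind in self.members.values():
            if ind.father is not None and anc[ind.father] & anc[ind.mother]:
                raise PedigreeError(f"{ind.id}: parents are blood relatives "
                                    "(consanguineous pedigrees are not supported)")

    @property
    def target(self) -> Individual:
        return self.members[self.target_id]

    def __len__(self):
        return len(self.members)

    def ordered(self) -> list[Individual]:
        """Members ordered parents-before-children."""
        return sorted(self.members.values(), key=lambda i: (i.birth_year, i.id))

    def with_member(self, ind: Individual) -> "Pedigree":
        """A copy with one member replaced (used for what-if predictions)."""
        out = [ind if m.id == ind.id else m for m in self.members.values()]
        return Pedigree(out)


# ---------------------------------------------------------------------------
# file I/O


def _fmt(v) -> str:
    return _MISSING if v is None else str(v)


def write_pedigree(p: Pedigree, path: str | Path) -> None:
    """Write the tab-separated pedigree exchange format (lossless)."""
    genes = sorted({g for i in p.members.values() for g in i.tests})
    rfs = sorted({r for i in p.members.values() for r in i.rf_values})
    cols = (["id", "father", "mother", "sex", "birth_year", "censor_age", "target"]
            + list(_CANCER_COLUMNS) + ["pathology", "prs_z"]
            + [f"test_{g}" for g in genes] + [f"rf_{r}" for r in rfs])
    lines = [PEDIGREE_HEADER_TAG, "\t".join(cols)]
    for ind in p.ordered():
        dx = dict(ind.diagnoses)
        if "mbc" in dx:  # male breast cancer shares the bc column
            dx["bc"] = dx.pop("mbc")
        row = [ind.id, _fmt(ind.father), _fmt(ind.mother), ind.sex,
               str(ind.birth_year), str(ind.censor_age), "1" if ind.target else "0"]
        row += [_fmt(dx.get(c)) for c in _CANCER_COLUMNS]
        row += [_fmt(ind.pathology), _fmt(ind.prs_z)]
        row += [_fmt(ind.tests.get(g)) for g in genes]
        row += [_fmt(ind.rf_values.get(r)) for r in rfs]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_pedigree(path: str | Path) -> Pedigree:
    """Read the tab-separated pedigree exchange format."""
    lines = Path(path).read_text().rstrip("\n").split("\n")
    if not lines or not lines[0].startswith("##pedrisk-pedigree"):
        raise PedigreeError(f"{path}: missing pedigree header tag")
    if lines[0].strip() != PEDIGREE_HEADER_TAG:
        raise PedigreeError(f"{path}: unsupported format version {lines[0].strip()!r}")
    header = lines[1].split("\t")
    col = {name: i for i, name in enumerate(header)}
    for need in ("id", "father", "mother", "sex", "birth_year", "censor_age", "target"):
        if need not in col:
            raise PedigreeError(f"{path}: missing column {need!r}")
    genes = [c[5:] for c in header if c.startswith("test_")]
    rfs = [c[3:] for c in header if c.startswith("rf_")]
    members = []
    for lineno, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        f = line.split("\t")
        if len(f) != len(header):
            raise PedigreeError(f"{path} line {lineno}: expected {len(header)} fields, got {len(f)}")

        def get(name):
            v = f[col[name]]
            return None if v == _MISSING else v

        try:
            sex = f[col["sex"]]
            diagnoses = {}
            for c in _CANCER_COLUMNS:
                if c in col and get(c) is not None:
                    key = "mbc" if (c == "bc" and sex == "M") else c
                    diagnoses[key] = int(get(c))
            tests = {g: {"neg": "neg", "pos": "pos"}[get(f"test_{g}")]
                     for g in genes if get(f"test_{g}") is not None}
            rf_values = {r: float(get(f"rf_{r}")) for r in rfs if get(f"rf_{r}") is not None}
            members.append(Individual(
                id=f[col["id"]], sex=sex,
                birth_year=int(f[col["birth_year"]]),
                censor_age=None if get("censor_age") is None else int(get("censor_age")),
                father=get("father"), mother=get("mother"),
                diagnoses=diagnoses,
                pathology=get("pathology") if "pathology" in col else None,
                tests=tests, rf_values=rf_values,
                prs_z=None if "prs_z" not in col or get("prs_z") is None else float(get("prs_z")),
                target=f[col["target"]] == "1"))
        except (KeyError, ValueError, PedigreeError) as exc:
            raise PedigreeError(f"{path} line {lineno}: {exc}") from exc
    return Pedigree(members)


# ---------------------------------------------------------------------------
# observation likelihoods


def test_likelihood(result: str, is_carrier: bool, sensitivity: float) -> float:
    """Likelihood of a genetic test ``result`` given carrier status.

    The screening sensitivity is the probability a true carrier tests
    positive; specificity is 1 (a detected variant is real).
    """
    if not (0.0 < sensitivity <= 1.0):
        raise ModelError(f"sensitivity {sensitivity} outside (0, 1]")
    if result == "neg":
        return 1.0 - sensitivity if is_carrier else 1.0
    if result == "pos":
        return sensitivity if is_carrier else 0.0
    raise ModelError(f"unknown test result {result!r}")


# ---------------------------------------------------------------------------
# exact likelihood: graph peeling (variable elimination) and enumeration


def _combine_and_sum(group, v, K):
    union = sorted(set().union(*(set(fv) for fv, _ in group)))
    letters = {u: chr(97 + i) for i, u in enumerate(union)}
    inputs = ",".join("".join(letters[u] for u in fv) for fv, _ in group)
    out = "".join(letters[u] for u in union if u != v)
    arr = np.einsum(inputs + "->" + out, *(a for _, a in group), optimize=True)
    return tuple(u for u in union if u != v), arr


def _eliminate(factors, n_vars: int, keep=()):
    """Sum-product variable elimination; returns (array over keep vars in
    sorted order, log rescaling constant)."""
    factors = [(tuple(v), np.asarray(a, dtype=float)) for v, a in factors]
    K = factors[0][1].shape[0] if factors and factors[0][0] else None
    log_c = 0.0
    remaining = [v for v in range(n_vars) if v not in keep]
    while remaining:
        best, best_cost = None, None
        for v in remaining:
            union = set()
            for fv, _ in factors:
                if v in fv:
                    union |= set(fv)
            cost = len(union)
            if best_cost is None or cost < best_cost:
                best, best_cost = v, cost
        v = best
        remaining.remove(v)
        group = [f for f in factors if v in f[0]]
        rest = [f for f in factors if v not in f[0]]
        if not group:
            continue
        fv, arr = _combine_and_sum(group, v, K)
        peak = arr.max()
        if peak > 0:
            arr = arr / peak
            log_c += float(np.log(peak))
        rest.append((fv, arr))
        factors = rest
    # multiply whatever is left (scalars and factors over keep vars)
    keep = tuple(sorted(keep))
    letters = {u: chr(97 + i) for i, u in enumerate(keep)}
    inputs, arrays = [], []
    for fv, a in factors:
        inputs.append("".join(letters[u] for u in fv))
        arrays.append(a)
    if not arrays:
        return np.ones(()) if not keep else np.ones((1,) * len(keep)), log_c
    out = "".join(letters[u] for u in keep)
    res = np.einsum(",".join(inputs) + "->" + out, *arrays, optimize=True)
    return res, log_c


def _build_factors(pedigree: Pedigree, model, clamp=None):
    """Factor list for the pedigree under ``model``.

    ``clamp`` optionally maps individual ids to boolean masks over the
    genotype state space (used to condition on carrier status).
    """
    order = pedigree.ordered()
    index = {ind.id: i for i, ind in enumerate(order)}
    prior = model.founder_prior_vector()
    T = model.transmission_tensor()
    factors = []
    for ind in order:
        pen = model.penetrance(ind)
        if clamp and ind.id in clamp:
            pen = pen * np.asarray(clamp[ind.id], dtype=float)
        if ind.is_founder:
            factors.append(((index[ind.id],), prior * pen))
        else:
            f, m = index[ind.father], index[ind.mother]
            arr = T * pen[:, None, None]
            factors.append(((index[ind.id], f, m), arr))
    return factors, index


def peel_likelihood(pedigree: Pedigree, model, clamp=None, log: bool = False):
    """Exact pedigree likelihood by graph peeling.

    Sums founder priors x transmission x observation likelihoods over all
    joint genotype-state assignments.  With ``log=True`` returns the
    log-likelihood (robust for large pedigrees).
    """
    n_states = model.n_states
    cap = getattr(model, "state_space_cap", 10_000_000)
    if n_states**3 > cap:
        raise ModelError("genotype state space too large for peeling; "
                         "reduce the number of polygene levels")
    factors, _ = _build_factors(pedigree, model, clamp)
    arr, log_c = _eliminate(factors, len(pedigree))
    val = float(arr)
    if log:
        return float(np.log(val)) + log_c if val > 0 else -np.inf
    return val * float(np.exp(log_c))


def enumerate_likelihood(pedigree: Pedigree, model, clamp=None) -> float:
    """Brute-force likelihood: explicit sum over every joint assignment of
    genotype states to pedigree members (test oracle for peeling)."""
    factors, _ = _build_factors(pedigree, model, clamp)
    n = len(pedigree)
    K = model.n_states
    if K**n > 20_000_000:
        raise ModelError("joint state space too large to enumerate")
    idx = np.indices((K,) * n).reshape(n, -1)
    like = np.ones(K**n)
    for fv, arr in factors:
        like *= arr[tuple(idx[v] for v in fv)]
    return float(like.sum())


def state_posterior(pedigree: Pedigree, model, clamp=None) -> np.ndarray:
    """Posterior over the target's collapsed genotype x polygene states."""
    factors, index = _build_factors(pedigree, model, clamp)
    arr, _ = _eliminate(factors, len(pedigree), keep=(index[pedigree.target_id],))
    total = arr.sum()
    if total <= 0:
        raise ModelError("zero total likelihood: observations are inconsistent "
                         "with the model (e.g. impossible test configuration)")
    return arr / total


def carrier_probabilities(pedigree: Pedigree, model) -> dict[str, float]:
    """Posterior probability that the target carries a pathogenic variant in
    each modelled gene (plus 'none'), given all pedigree data."""
    post = state_posterior(pedigree, model)
    by_gene = post.reshape(model.n_major, model.n_levels).sum(axis=1)
    out = {"none": float(by_gene[0])}
    for i, name in enumerate(model.gene_names):
        out[name] = float(by_gene[i + 1])
    return out
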