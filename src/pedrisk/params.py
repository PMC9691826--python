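"""Typed registry of model parameters.

Holds the major-gene parameters (population allele frequency, clinical
screening-test sensitivity, age-piecewise relative-risk functions per cancer,
dominance rank), breast-tumour pathology distributions (ER / triple-negative
status by age of onset), lifetime-risk category schemes, and risk-factor
definitions, together with TSV/YAML loading, validation and exact round-trip
writing.

Ages are integer years 0..79 and hazards are piecewise-constant on [t, t+1).
Relative-risk functions are either constants or log-linear ``exp(u + v*age)``
on inclusive integer age intervals; ages not covered by any segment default
to RR = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from . import continuous_rf as crf

AGE_MAX = 80  # exclusive upper bound; model ages are 0..79
AGES = np.arange(AGE_MAX)

#: Cancer endpoints the models know about. "bc" is female breast cancer,
#: "mbc" male breast cancer, "eoc" epithelial tubo-ovarian cancer.
CANCERS = ("bc", "eoc", "mbc", "prostate", "pancreas")

#: Five-level breast-tumour pathology observation scheme.
PATHOLOGY_CATEGORIES = (
    "er_unknown",        # no pathology information
    "er_pos",            # ER-positive
    "er_neg_tn_unknown", # ER-negative, TN status unknown
    "er_neg_not_tn",     # ER-negative but not triple negative
    "tn",                # triple negative (ER-, PR-, HER2-)
)


@dataclass(frozen=True)
class Segment:
    """One age interval of a piecewise relative-risk function.

    ``lo``/``hi`` are inclusive integer ages.  ``kind`` is ``"const"``
    (value ``c``) or ``"loglin"`` (value ``exp(u + v*age)``).
    """

    lo: int
    hi: int
    kind: str
    c: float = 1.0
    u: float = 0.0
    v: float = 0.0

    def value(self, age):
        if self.kind == "const":
            return np.broadcast_to(float(self.c), np.shape(age)) if np.ndim(age) else float(self.c)
        return np.exp(self.u + self.v * np.asarray(age, dtype=float)) if np.ndim(age) else math.exp(self.u + self.v * age)


class AgePiecewiseRR:
    """Piecewise relative-risk function of age over 0..79.

    Segments must not overlap; gaps are filled with RR = 1.
    """

    def __init__(self, segments: Sequence[Segment]):
        segs = sorted(segments, key=lambda s: s.lo)
        for s in segs:
            if not (0 <= s.lo <= s.hi <= AGE_MAX - 1):
                raise ConfigError(f"segment [{s.lo},{s.hi}] outside ages 0..{AGE_MAX - 1}")
            if s.kind not in ("const", "loglin"):
                raise ConfigError(f"unknown segment form {s.kind!r}")
        for a, b in zip(segs, segs[1:]):
            if b.lo <= a.hi:
                raise ConfigError(f"overlapping segments [{a.lo},{a.hi}] and [{b.lo},{b.hi}]")
        # fill gaps with RR=1 so segments tile 0..79
        filled: list[Segment] = []
        cursor = 0
        for s in segs:
            if s.lo > cursor:
                filled.append(Segment(cursor, s.lo - 1, "const", 1.0))
            filled.append(s)
            cursor = s.hi + 1
        if cursor <= AGE_MAX - 1:
            filled.append(Segment(cursor, AGE_MAX - 1, "const", 1.0))
        self.segments = tuple(filled)
        curve = self.curve()
        if not np.all(curve > 0):
            raise ConfigError("relative risk must be strictly positive at every age")

    @classmethod
    def constant(cls, value: float) -> "AgePiecewiseRR":
        return cls([Segment(0, AGE_MAX - 1, "const", value)])

    def __call__(self, age):
        age_arr = np.asarray(age)
        if np.any(age_arr < 0) or np.any(age_arr > AGE_MAX - 1):
            raise ValueError(f"age {age} outside 0..{AGE_MAX - 1}")
        if age_arr.ndim == 0:
            a = int(age_arr)
            for s in self.segments:
                if s.lo <= a <= s.hi:
                    return float(s.value(a))
            raise AssertionError("segments must tile 0..79")
        return self.curve()[age_arr.astype(int)]

    def curve(self) -> np.ndarray:
        """RR evaluated at every integer age 0..79."""
        out = np.empty(AGE_MAX)
        for s in self.segments:
            ages = np.arange(s.lo, s.hi + 1)
            out[ages] = s.value(ages)
        return out

    def __eq__(self, other):
        return isinstance(other, AgePiecewiseRR) and self.segments == other.segments

    def __repr__(self):
        return f"AgePiecewiseRR({list(self.segments)!r})"


@dataclass(frozen=True)
class GeneParams:
    """Parameters of one major susceptibility gene.

    ``allele_freq`` is the pathogenic-variant allele frequency in the general
    population, ``sensitivity`` the probability that a clinical screening test
    detects a variant in a true carrier (non-carriers never test positive),
    ``rr`` maps cancer endpoints to age-piecewise relative risks (absent
    endpoints mean RR = 1) and ``dominance_rank`` orders the collapse of
    multi-gene carriers (1 = most dominant).
    """

    name: str
    allele_freq: float
    sensitivity: float
    rr: Mapping[str, AgePiecewiseRR] = field(default_factory=dict)
    dominance_rank: int = 1

    def __post_init__(self):
        if not (0.0 < self.allele_freq < 0.01):
            raise ConfigError(f"{self.name}: allele_freq {self.allele_freq} outside (0, 0.01)")
        if not (0.0 < self.sensitivity <= 1.0):
            raise ConfigError(f"{self.name}: sensitivity {self.sensitivity} outside (0, 1]")
        for c in self.rr:
            if c not in CANCERS:
                raise ConfigError(f"{self.name}: unknown cancer endpoint {c!r}")

    @property
    def carrier_prob(self) -> float:
        """Probability of carrying >=1 pathogenic allele (HWE)."""
        q = self.allele_freq
        return 2 * q * (1 - q) + q * q

    def rr_curve(self, cancer: str) -> np.ndarray:
        fn = self.rr.get(cancer)
        return fn.curve() if fn is not None else np.ones(AGE_MAX)


def relative_risk(gene: GeneParams, cancer: str, age: int) -> float:
    """RR of ``cancer`` at ``age`` for a carrier of a variant in ``gene``.

    Returns 1 if the gene has no modelled association with that cancer.
    """
    if cancer not in CANCERS:
        raise ConfigError(f"unknown cancer endpoint {cancer!r}")
    if not (0 <= age <= AGE_MAX - 1):
        raise ValueError(f"age {age} outside 0..{AGE_MAX - 1}")
    fn = gene.rr.get(cancer)
    return 1.0 if fn is None else float(fn(age))


def carrier_prevalence(genes: Iterable[GeneParams]) -> float:
    """Probability of carrying >=1 pathogenic allele in >=1 of ``genes``.

    Assumes Hardy-Weinberg equilibrium within genes and independence across
    genes: ``1 - prod_g (1 - q_g)^2``.
    """
    genes = list(genes)
    if not genes:
        raise ConfigError("carrier_prevalence requires a non-empty gene set")
    log_none = sum(2 * math.log1p(-g.allele_freq) for g in genes)
    return -math.expm1(log_none)


class PathologyDistribution:
    """Age-of-onset-dependent ER / TN tumour distribution for one gene
    (or the general population).

    ``table`` maps onset age to ``(P(ER- | onset), P(TN | ER-, onset))``;
    ages outside the tabulated range use the nearest tabulated age.
    """

    def __init__(self, label: str, ages: Sequence[int], p_er_neg: Sequence[float],
                 p_tn_given_er_neg: Sequence[float]):
        self.label = label
        order = np.argsort(ages)
        self.ages = np.asarray(ages, dtype=int)[order]
        self.p_er_neg = np.asarray(p_er_neg, dtype=float)[order]
        self.p_tn_given_er_neg = np.asarray(p_tn_given_er_neg, dtype=float)[order]
        if len(self.ages) == 0:
            raise ConfigError(f"pathology table {label!r} is empty")
        for name, arr in (("p_er_neg", self.p_er_neg), ("p_tn_given_er_neg", self.p_tn_given_er_neg)):
            if np.any((arr < 0) | (arr > 1)):
                raise ConfigError(f"pathology table {label!r}: {name} outside [0,1]")

    def _at(self, age: int) -> tuple[float, float]:
        i = int(np.argmin(np.abs(self.ages - age)))
        return float(self.p_er_neg[i]), float(self.p_tn_given_er_neg[i])

    def category_prob(self, category: str, age: int) -> float:
        return pathology_category_prob(self, category, age)


def pathology_category_prob(dist: PathologyDistribution, category: str, age: int) -> float:
    """Probability of observing a pathology ``category`` given onset at ``age``.

    The five categories follow the ER/TN observation scheme: "er_unknown"
    carries no information (probability 1); the three mutually exclusive fully
    observed categories (er_pos, er_neg_not_tn, tn) partition probability 1;
    "er_neg_tn_unknown" marginalises TN status within ER-negative.
    """
    if category not in PATHOLOGY_CATEGORIES:
        raise ConfigError(f"unknown pathology category {category!r}")
    if category == "er_unknown":
        return 1.0
    p_er_neg, p_tn = dist._at(age)
    if category == "er_pos":
        return 1.0 - p_er_neg
    if category == "er_neg_tn_unknown":
        return p_er_neg
    if category == "er_neg_not_tn":
        return p_er_neg * (1.0 - p_tn)
    return p_er_neg * p_tn  # "tn"


@dataclass(frozen=True)
class RiskCategoryScheme:
    """Ordered lifetime-risk categories for one cancer endpoint."""

    cancer: str
    thresholds: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self):
        if len(self.labels) != len(self.thresholds) + 1:
            raise ConfigError("need exactly one more label than thresholds")
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ConfigError("thresholds must be strictly increasing")

    def categorize(self, risk: float) -> str:
        if not (0.0 <= risk <= 1.0):
            raise ValueError(f"risk {risk} outside [0,1]")
        return self.labels[int(np.searchsorted(self.thresholds, risk, side="right"))]


@dataclass
class PolygeneSettings:
    """Configuration of the polygenic component.

    ``sd`` is sigma_P(t): the per-age SD of the polygenic log-relative-hazard
    (a scalar is broadcast over ages); ``prs_alpha2`` the fraction of polygenic
    variance explained by the measured PRS.
    """

    sd: np.ndarray
    n_levels: int = 7
    prs_alpha2: float = 0.20

    def __post_init__(self):
        self.sd = np.broadcast_to(np.asarray(self.sd, dtype=float), (AGE_MAX,)).copy()
        if np.any(self.sd <= 0):
            raise ConfigError("polygenic SD must be positive at every age")
        if self.n_levels < 3 or self.n_levels % 2 == 0:
            raise ConfigError("n_levels must be an odd integer >= 3")
        if not (0.0 <= self.prs_alpha2 <= 1.0):
            raise ConfigError("prs_alpha2 must lie in [0,1]")


@dataclass
class ModelConfig:
    """Validated registry of everything a risk model needs.

    ``genes`` is ordered by dominance rank.  ``pathology`` maps gene names to
    their ER/TN tables; genes without a table use ``pathology["population"]``.
    """

    primary: str
    cancers: tuple[str, ...]
    genes: tuple[GeneParams, ...]
    polygene: PolygeneSettings
    pathology: dict[str, PathologyDistribution]
    risk_categories: dict[str, RiskCategoryScheme]
    risk_factors: list = field(default_factory=list)

    def __post_init__(self):
        if self.primary not in self.cancers:
            raise ConfigError(f"primary cancer {self.primary!r} not in modelled cancers")
        ranks = [g.dominance_rank for g in self.genes]
        if len(set(ranks)) != len(ranks):
            raise ConfigError("dominance ranks must be unique")
        self.genes = tuple(sorted(self.genes, key=lambda g: g.dominance_rank))
        if "population" not in self.pathology:
            raise ConfigError("pathology registry must include a 'population' table")

    @property
    def gene_names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.genes)

    def gene(self, name: str) -> GeneParams:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)

    def pathology_for(self, gene_name: str | None) -> PathologyDistribution:
        if gene_name is not None and gene_name in self.pathology:
            return self.pathology[gene_name]
        return self.pathology["population"]


# ---------------------------------------------------------------------------
# file loading / writing


def _load_gene_tables(gene_path: Path, rr_path: Path, model: str) -> tuple[GeneParams, ...]:
    gdf = pd.read_csv(gene_path, sep="\t", float_precision="round_trip")
    rdf = pd.read_csv(rr_path, sep="\t", float_precision="round_trip")
    for col in ("gene", "model", "allele_freq", "sensitivity", "dominance_rank"):
        if col not in gdf.columns:
            raise ConfigError(f"{gene_path}: missing column {col!r}")
    for col in ("gene", "cancer", "age_lo", "age_hi", "form", "c", "u", "v"):
        if col not in rdf.columns:
            raise ConfigError(f"{rr_path}: missing column {col!r}")
    genes = []
    sub = gdf[gdf["model"] == model]
    if sub.empty:
        raise ConfigError(f"{gene_path}: no genes for model {model!r}")
    for idx, row in sub.iterrows():
        rrs: dict[str, AgePiecewiseRR] = {}
        for cancer, block in rdf[rdf["gene"] == row["gene"]].groupby("cancer"):
            segs = []
            for ridx, r in block.iterrows():
                try:
                    segs.append(Segment(int(r["age_lo"]), int(r["age_hi"]), str(r["form"]),
                                        float(r["c"]), float(r["u"]), float(r["v"])))
                except (ValueError, ConfigError) as exc:
                    raise ConfigError(f"{rr_path} row {ridx}: {exc}") from exc
            try:
                rrs[str(cancer)] = AgePiecewiseRR(segs)
            except ConfigError as exc:
                raise ConfigError(f"{rr_path}: gene {row['gene']} cancer {cancer}: {exc}") from exc
        try:
            genes.append(GeneParams(str(row["gene"]), float(row["allele_freq"]),
                                    float(row["sensitivity"]), rrs, int(row["dominance_rank"])))
        except ConfigError as exc:
            raise ConfigError(f"{gene_path} row {idx}: {exc}") from exc
    return tuple(genes)


def _load_pathology_table(path: Path) -> dict[str, PathologyDistribution]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    out = {}
    for label, block in df.groupby("gene"):
        out[str(label)] = PathologyDistribution(
            str(label), block["age"].to_numpy(), block["p_er_neg"].to_numpy(),
            block["p_tn_given_er_neg"].to_numpy())
    return out


def _parse_risk_factor(entry: Mapping) -> object:
    kind = entry.get("type")
    if kind == "continuous":
        return crf.ContinuousRF(name=entry["name"], mean=float(entry["mean"]),
                                sd=float(entry["sd"]),
                                log_rr_per_sd=float(entry["log_rr_per_sd"]),
                                n_bins=int(entry.get("n_bins", 5)))
    if kind == "categorical":
        return crf.CategoricalRF(name=entry["name"],
                                 masses=np.asarray(entry["masses"], dtype=float),
                                 rrs=np.asarray(entry["rrs"], dtype=float))
    raise ConfigError(f"risk factor {entry.get('name')!r}: unknown type {kind!r}")


def load_model_config(path: str | Path) -> ModelConfig:
    """Load and validate a model configuration from a YAML file.

    Relative file references inside the YAML are resolved against the YAML's
    own directory.  ``pathology: synthetic`` requests the deterministic
    synthetic tables from :mod:`pedrisk.fixtures`.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file {path} does not exist")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict) or raw.get("schema") != 1:
        raise ConfigError(f"{path}: unrecognised or missing schema version")
    base = path.parent
    model = raw.get("model", "bc")
    genes = _load_gene_tables(base / raw["genes_file"], base / raw["rr_file"], model)
    pathology_spec = raw.get("pathology", "synthetic")
    if pathology_spec == "synthetic":
        from . import fixtures  # lazy: fixtures imports params
        pathology = fixtures.make_pathology_tables()
    else:
        pathology = _load_pathology_table(base / pathology_spec)
    pg = raw.get("polygene", {})
    polygene = PolygeneSettings(sd=np.asarray(pg.get("sd", 1.0), dtype=float),
                                n_levels=int(pg.get("n_levels", 7)),
                                prs_alpha2=float(pg.get("prs_alpha2", 0.2)))
    cats = {}
    for cancer, spec in raw.get("risk_categories", {}).items():
        cats[cancer] = RiskCategoryScheme(cancer, tuple(spec["thresholds"]), tuple(spec["labels"]))
    rfs = [_parse_risk_factor(e) for e in raw.get("risk_factors", [])]
    return ModelConfig(primary=raw["primary"], cancers=tuple(raw["cancers"]),
                       genes=genes, polygene=polygene, pathology=pathology,
                       risk_categories=cats, risk_factors=rfs)


def write_config(config: ModelConfig, path: str | Path) -> None:
    """Write ``config`` back to a YAML + TSV bundle under ``path``'s directory.

    Numeric parameters round-trip exactly (written with full repr precision).
    """
    path = Path(path)
    base = path.parent
    base.mkdir(parents=True, exist_ok=True)
    stem = path.stem
    genes_file = f"{stem}_genes.tsv"
    rr_file = f"{stem}_rr.tsv"
    pathology_file = f"{stem}_pathology.tsv"
    model = "custom"
    with open(base / genes_file, "w") as fh:
        fh.write("gene\tmodel\tallele_freq\tsensitivity\tdominance_rank\n")
        for g in config.genes:
            fh.write(f"{g.name}\t{model}\t{g.allele_freq!r}\t{g.sensitivity!r}\t{g.dominance_rank}\n")
    with open(base / rr_file, "w") as fh:
        fh.write("gene\tcancer\tage_lo\tage_hi\tform\tc\tu\tv\n")
        for g in config.genes:
            for cancer, fn in g.rr.items():
                for s in fn.segments:
                    fh.write(f"{g.name}\t{cancer}\t{s.lo}\t{s.hi}\t{s.kind}\t{s.c!r}\t{s.u!r}\t{s.v!r}\n")
    with open(base / pathology_file, "w") as fh:
        fh.write("gene\tage\tp_er_neg\tp_tn_given_er_neg\n")
        for label, dist in config.pathology.items():
            for a, pe, pt in zip(dist.ages, dist.p_er_neg, dist.p_tn_given_er_neg):
                fh.write(f"{label}\t{int(a)}\t{float(pe)!r}\t{float(pt)!r}\n")
    doc = {
        "schema": 1,
        "model": model,
        "primary": config.primary,
        "cancers": list(config.cancers),
        "genes_file": genes_file,
        "rr_file": rr_file,
        "pathology": pathology_file,
        "polygene": {
            "sd": [float(x) for x in config.polygene.sd],
            "n_levels": config.polygene.n_levels,
            "prs_alpha2": config.polygene.prs_alpha2,
        },
        "risk_categories": {c: {"thresholds": [float(t) for t in s.thresholds],
                                "labels": list(s.labels)}
                            for c, s in config.risk_categories.items()},
        "risk_factors": [rf.to_config() for rf in config.risk_factors],
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))


def default_config(model: str = "bc") -> ModelConfig:
    """The shipped default configuration for the ``bc`` or ``eoc`` model."""
    if model not in ("bc", "eoc"):
        raise ConfigError(f"unknown model {model!r}")
    with resources.as_file(resources.files("pedrisk.data") / f"config_{model}.yaml") as p:
        return load_model_config(p)
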