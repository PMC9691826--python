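import numpy as np
import pytest

import pedrisk as pk
from pedrisk.params import (AgePiecewiseRR, GeneParams, ModelConfig,
                            PathologyDistribution, PolygeneSettings,
                            RiskCategoryScheme)


def build_small_config(n_levels=3, sd=1.0, rfs=(), genes=None, prs_alpha2=0.2,
                       cancers=("bc",), primary="bc"):
    """A two-gene single-cancer model small enough for brute-force oracles."""
    if genes is None:
        genes = (
            GeneParams("G1", 0.003, 0.9, {"bc": AgePiecewiseRR.constant(3.0)}, 1),
            GeneParams("G2", 0.002, 0.8, {"bc": AgePiecewiseRR.constant(1.8)}, 2),
        )
    pathology = {
        "population": PathologyDistribution("population", [30, 50, 70],
                                            [0.30, 0.22, 0.15], [0.5, 0.5, 0.5]),
        "G1": PathologyDistribution("G1", [30, 50, 70],
                                    [0.80, 0.70, 0.55], [0.8, 0.75, 0.7]),
    }
    return ModelConfig(
        primary=primary, cancers=cancers, genes=genes,
        polygene=PolygeneSettings(sd=np.asarray(sd), n_levels=n_levels,
                                  prs_alpha2=prs_alpha2),
        pathology=pathology,
        risk_categories={"bc": RiskCategoryScheme("bc", (0.17, 0.30),
                                                  ("near-population", "moderate", "high")),
                         "eoc": RiskCategoryScheme("eoc", (0.05, 0.10),
                                                   ("near-population", "moderate", "high"))},
        risk_factors=list(rfs))


def build_small_model(**kwargs) -> pk.RiskModel:
    config = build_small_config(**kwargs)
    calendar = {c: pk.make_incidence(pk.FixtureSpec(), cancer=c)
                for c in config.cancers}
    return pk.RiskModel(config, calendar)


@pytest.fixture(scope="session")
def small_model():
    return build_small_model()


@pytest.fixture(scope="session")
def height():
    return pk.ContinuousRF("height", mean=162.81, sd=6.452,
                           log_rr_per_sd=0.10130, n_bins=5)


@pytest.fixture(scope="session")
def default_bc_model():
    return pk.RiskModel.default("bc")


@pytest.fixture(scope="session")
def bc_config():
    return pk.default_config("bc")


@pytest.fixture(scope="session")
def eoc_config():
    return pk.default_config("eoc")


def solo_target(birth_year=1985, censor_age=20, **kwargs) -> pk.Pedigree:
    return pk.Pedigree([pk.Individual(id="t", sex="F", birth_year=birth_year,
                                      censor_age=censor_age, target=True, **kwargs)])


def clamp_gene(model: pk.RiskModel, gene: str | None, target_id: str = "t"):
    """Clamp mask fixing the target's collapsed major genotype."""
    gi = 0 if gene is None else model.gene_names.index(gene) + 1
    mask = np.zeros(model.n_states)
    mask[gi * model.n_levels:(gi + 1) * model.n_levels] = 1.0
    return {target_id: mask}
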