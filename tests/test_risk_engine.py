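import numpy as np
import pytest

import pedrisk as pk
from pedrisk.errors import ModelError
from pedrisk.params import AGE_MAX
from pedrisk import risk_engine as re
from conftest import build_small_config, build_small_model, clamp_gene, solo_target


class TestFutureRisk:
    def test_population_cumulative_risk_no_family_history(self, small_model):
        # marginal over all states must reproduce the population cumulative
        # risk implied by the incidence the baseline was constrained to
        ped = solo_target(birth_year=1985, censor_age=20)
        res = re.future_risk(ped, small_model, "bc", AGE_MAX)
        lam = small_model.cohort_incidence("bc", 1985).lam
        assert res.cumulative[-1] == pytest.approx(-np.expm1(-lam[20:].sum()), rel=5e-3)

    def test_constant_hazard_closed_form_single_state(self):
        lam = np.zeros(AGE_MAX)
        lam[20:] = 0.01
        years = np.arange(1950, 2020)
        cal = {"bc": pk.CalendarIncidenceTable(
            "syn", "F", "bc", years,
            np.repeat(lam[:, None] * 1e5, len(years), axis=1))}
        genes = (pk.GeneParams("G1", 1e-6, 0.9, {}, 1),)  # negligible carrier mass
        config = build_small_config(genes=genes, sd=1e-9)  # degenerate polygene
        model = pk.RiskModel(config, cal)
        ped = solo_target(birth_year=1985, censor_age=20)
        res = re.future_risk(ped, model, "bc", AGE_MAX)
        assert res.cumulative[-1] == pytest.approx(-np.expm1(-0.6), rel=1e-6)

    def test_carrier_curve_dominates_population_everywhere(self, small_model):
        ped = solo_target(birth_year=1985, censor_age=20)
        carrier = re.future_risk(ped, small_model, "bc", AGE_MAX,
                                 clamp=clamp_gene(small_model, "G1"))
        pop = re.future_risk(ped, small_model, "bc", AGE_MAX,
                             clamp=clamp_gene(small_model, None))
        assert np.all(carrier.cumulative >= pop.cumulative)
        assert carrier.cumulative[-1] > pop.cumulative[-1]

    def test_curve_monotone_and_bounded(self, small_model):
        ped = solo_target(birth_year=1985, censor_age=30)
        res = re.future_risk(ped, small_model, "bc", AGE_MAX)
        assert np.all(np.diff(res.cumulative) >= -1e-15)
        assert res.cumulative[0] >= 0 and res.cumulative[-1] <= 1

    def test_affected_target_rejected(self, small_model):
        ped = pk.Pedigree([pk.Individual(id="t", sex="F", birth_year=1960,
                                         censor_age=60, diagnoses={"bc": 50},
                                         target=True)])
        with pytest.raises(ModelError, match="affected"):
            re.future_risk(ped, small_model, "bc", AGE_MAX)

    def test_doubling_rr_increases_risk(self):
        m1 = build_small_model(genes=(
            pk.GeneParams("G1", 0.003, 0.9, {"bc": pk.AgePiecewiseRR.constant(2.0)}, 1),))
        m2 = build_small_model(genes=(
            pk.GeneParams("G1", 0.003, 0.9, {"bc": pk.AgePiecewiseRR.constant(4.0)}, 1),))
        ped = solo_target()
        r1 = re.lifetime_risk(ped, m1, "bc", clamp=clamp_gene(m1, "G1"))
        r2 = re.lifetime_risk(ped, m2, "bc", clamp=clamp_gene(m2, "G1"))
        assert r2 > r1


class TestLifetimeRisk:
    def test_zero_incidence_gives_zero_risk(self):
        years = np.arange(1950, 2020)
        cal = {"bc": pk.CalendarIncidenceTable("syn", "F", "bc", years,
                                               np.zeros((AGE_MAX, len(years))))}
        model = pk.RiskModel(build_small_config(), cal)
        assert re.lifetime_risk(solo_target(), model, "bc") == 0.0

    def test_new_gene_risk_ordering_matches_rr_ordering(self, default_bc_model):
        ped = solo_target(birth_year=1985, censor_age=20)
        risks = {g: re.lifetime_risk(ped, default_bc_model, "bc",
                                     clamp=clamp_gene(default_bc_model, g))
                 for g in ("BARD1", "RAD51C", "RAD51D")}
        assert risks["BARD1"] > risks["RAD51C"] > risks["RAD51D"]

    def test_family_history_increases_risk(self, small_model):
        unknown = re._fh_pedigree("unknown", small_model)
        mother = re._fh_pedigree("mother50", small_model)
        r0 = re.lifetime_risk(unknown, small_model, "bc")
        r1 = re.lifetime_risk(mother, small_model, "bc")
        assert r1 > r0


class TestCategorize:
    def test_published_bc_thresholds(self, small_model):
        scheme = small_model.config.risk_categories["bc"]
        assert re.categorize(0.169, scheme) == "near-population"
        assert re.categorize(0.20, scheme) == "moderate"
        assert re.categorize(0.30, scheme) == "high"

    def test_published_eoc_thresholds(self, small_model):
        scheme = small_model.config.risk_categories["eoc"]
        assert re.categorize(0.050, scheme) == "moderate"
        assert re.categorize(0.12, scheme) == "high"


@pytest.fixture(scope="module")
def factor_model(height):
    qrf = pk.CategoricalRF("qrf", np.array([0.25, 0.5, 0.25]),
                           np.array([0.7, 1.0, 1.5]))
    return build_small_model(rfs=(height, qrf))


class TestRiskDistribution:

    def test_no_factors_gives_point_mass(self, factor_model):
        d = re.risk_distribution("G1", "unknown", (), factor_model)
        assert len(d.risks) == 1 and d.masses[0] == 1.0
        assert sum(d.category_proportions.values()) == pytest.approx(1.0)

    def test_prs_with_zero_alpha_is_point_mass(self, height):
        model = build_small_model(rfs=(), prs_alpha2=0.0)
        d = re.risk_distribution("G1", "unknown", ("prs",), model, n_prs_nodes=8)
        assert np.allclose(d.risks, d.risks[0])

    def test_proportions_sum_to_one_and_match_monte_carlo(self, factor_model):
        d = re.risk_distribution("G1", "unknown", ("qrf", "prs"), factor_model,
                                 n_prs_nodes=32)
        assert sum(d.category_proportions.values()) == pytest.approx(1.0, abs=1e-12)
        # seeded Monte-Carlo sampler of the same joint factor distribution
        rng = np.random.default_rng(123)
        n = 400
        qrf = next(r for r in factor_model.config.risk_factors if r.name == "qrf")
        ped = re._fh_pedigree("unknown", factor_model)
        clamp = clamp_gene(factor_model, "G1", target_id=ped.target_id)
        scheme = factor_model.config.risk_categories["bc"]
        labels = []
        for _ in range(n):
            t = ped.target
            t = pk.Individual(id=t.id, sex=t.sex, birth_year=t.birth_year,
                              censor_age=t.censor_age, target=True,
                              rf_values={"qrf": int(rng.choice(3, p=qrf.masses))},
                              prs_z=float(rng.standard_normal()))
            risk = re.lifetime_risk(ped.with_member(t), factor_model, "bc",
                                    clamp=clamp)
            labels.append(scheme.categorize(risk))
        for label, p in d.category_proportions.items():
            p_hat = labels.count(label) / n
            se = np.sqrt(max(p * (1 - p), 1e-4) / n)
            assert abs(p_hat - p) <= 3 * se + 1e-9

    def test_population_average_equals_marginal_risk_exactly(self, small_model):
        # prior-weighted carrier-specific risks must equal the unclamped
        # marginal risk: the clamping/posterior wiring conserves probability
        prior = small_model.major_prior()
        ped = solo_target(birth_year=1985, censor_age=20)
        risks = [re.lifetime_risk(ped, small_model, "bc",
                                  clamp=clamp_gene(small_model, g))
                 for g in (None, "G1", "G2")]
        avg = float(prior @ np.asarray(risks))
        marginal = re.lifetime_risk(ped, small_model, "bc")
        assert avg == pytest.approx(marginal, rel=1e-10)

    def test_population_average_reproduces_population_risk(self):
        # internal calibration: averaging risk over the full risk-profile
        # distribution recovers the population lifetime risk implied by the
        # incidence input.  The residual is the second-order (Jensen) term of
        # hazard-matching in discrete time, which grows with the hazard
        # multiplier variance; at moderate polygenic SD it sits well below
        # the 1e-3 tolerance.
        model = build_small_model(sd=0.7)
        prior = model.major_prior()
        ped = solo_target(birth_year=1985, censor_age=20)
        risks = [re.lifetime_risk(ped, model, "bc", clamp=clamp_gene(model, g))
                 for g in (None, "G1", "G2")]
        avg = float(prior @ np.asarray(risks))
        lam = model.cohort_incidence("bc", 1985).lam
        pop = -np.expm1(-lam[20:].sum())
        assert abs(avg - pop) / pop < 1e-3


class TestPrsConditioning:
    def test_high_prs_increases_risk(self, small_model):
        lo = solo_target(prs_z=-1.5)
        hi = solo_target(prs_z=1.5)
        assert (re.lifetime_risk(hi, small_model, "bc")
                > re.lifetime_risk(lo, small_model, "bc"))

    def test_measured_height_shifts_risk_monotonically(self, height):
        model = build_small_model(rfs=(height,))
        risks = [re.lifetime_risk(solo_target(rf_values={"height": x}), model, "bc")
                 for x in (150.0, 162.81, 175.0)]
        assert risks[0] < risks[1] < risks[2]
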