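import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pedrisk as pk
from pedrisk.errors import ModelError, PedigreeError
from pedrisk.model import phenotype_likelihood
from conftest import build_small_model, clamp_gene, solo_target


def trio(child_kwargs=None, mother_kwargs=None, father_kwargs=None):
    return pk.Pedigree([
        pk.Individual(id="f", sex="M", birth_year=1950, censor_age=70,
                      **(father_kwargs or {})),
        pk.Individual(id="m", sex="F", birth_year=1952, censor_age=68,
                      **(mother_kwargs or {})),
        pk.Individual(id="c", sex="F", birth_year=1985, censor_age=35,
                      father="f", mother="m", target=True, **(child_kwargs or {})),
    ])


class TestPedigreeStructure:
    def test_minimal_single_founder(self):
        ped = solo_target()
        assert len(ped) == 1 and ped.target.is_founder

    def test_child_older_than_parent_rejected(self):
        with pytest.raises(PedigreeError, match="born"):
            pk.Pedigree([
                pk.Individual(id="m", sex="F", birth_year=1990, censor_age=30),
                pk.Individual(id="f", sex="M", birth_year=1990, censor_age=30),
                pk.Individual(id="c", sex="F", birth_year=1980, censor_age=40,
                              father="f", mother="m", target=True)])

    def test_single_parent_rejected(self):
        with pytest.raises(PedigreeError, match="0 or 2"):
            pk.Individual(id="c", sex="F", birth_year=1980, mother="m")

    def test_duplicate_ids_rejected(self):
        with pytest.raises(PedigreeError, match="duplicate"):
            pk.Pedigree([pk.Individual(id="x", sex="F", birth_year=1980, target=True),
                         pk.Individual(id="x", sex="F", birth_year=1985)])

    def test_sex_incompatible_phenotype_rejected(self):
        with pytest.raises(PedigreeError):
            pk.Individual(id="x", sex="M", birth_year=1960, censor_age=60,
                          diagnoses={"eoc": 50})

    def test_pathology_requires_bc_diagnosis(self):
        with pytest.raises(PedigreeError):
            pk.Individual(id="x", sex="F", birth_year=1960, censor_age=60,
                          pathology="tn")

    def test_consanguineous_loop_rejected(self):
        with pytest.raises(PedigreeError, match="blood relatives"):
            pk.Pedigree([
                pk.Individual(id="f", sex="M", birth_year=1930, censor_age=80),
                pk.Individual(id="m", sex="F", birth_year=1932, censor_age=80),
                pk.Individual(id="s", sex="M", birth_year=1955, censor_age=65,
                              father="f", mother="m"),
                pk.Individual(id="d", sex="F", birth_year=1957, censor_age=63,
                              father="f", mother="m"),
                pk.Individual(id="c", sex="F", birth_year=1980, censor_age=40,
                              father="s", mother="d", target=True)])


class TestPedigreeIO:
    def test_roundtrip_is_lossless(self, tmp_path, default_bc_model):
        ped = pk.make_pedigree(pk.FixtureSpec(seed=5, pedigree_size=(4, 6)),
                               default_bc_model, np.random.default_rng(5))
        path = tmp_path / "ped.tsv"
        pk.write_pedigree(ped, path)
        back = pk.read_pedigree(path)
        assert set(back.members) == set(ped.members)
        for i, ind in ped.members.items():
            assert vars(back.members[i]) == vars(ind)

    def test_diagnosis_round_trips_as_printed(self, tmp_path):
        ped = trio(mother_kwargs={"diagnoses": {"bc": 50}, "pathology": "er_pos"})
        path = tmp_path / "trio.tsv"
        pk.write_pedigree(ped, path)
        back = pk.read_pedigree(path)
        assert back.members["m"].diagnoses == {"bc": 50}
        assert back.members["m"].pathology == "er_pos"

    def test_missing_header_tag_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("id\tfather\tmother\n")
        with pytest.raises(PedigreeError, match="header"):
            pk.read_pedigree(p)

    def test_parse_error_names_the_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(pk.pedigree.PEDIGREE_HEADER_TAG + "\n"
                     "id\tfather\tmother\tsex\tbirth_year\tcensor_age\ttarget\n"
                     "x\tNA\tNA\tF\tnot_a_year\t20\t1\n")
        with pytest.raises(PedigreeError, match="line 3"):
            pk.read_pedigree(p)


class TestTestLikelihood:
    @pytest.mark.parametrize("result,carrier,ss,expected", [
        ("neg", True, 1.0, 0.0),
        ("neg", True, 0.78, 0.22),   # published RAD51C sensitivity
        ("neg", False, 0.78, 1.0),
        ("pos", True, 0.78, 0.78),
        ("pos", False, 0.5, 0.0),    # specificity fixed at 1
    ])
    def test_values(self, result, carrier, ss, expected):
        assert pk.test_likelihood(result, carrier, ss) == pytest.approx(expected)

    def test_invalid_sensitivity_rejected(self):
        with pytest.raises(ModelError):
            pk.test_likelihood("neg", True, 0.0)


class TestPhenotypeLikelihood:
    def test_unaffected_newborn_is_one(self, small_model):
        ind = pk.Individual(id="x", sex="F", birth_year=2020, censor_age=0)
        assert np.allclose(small_model.phenotype_likelihood_vector(ind), 1.0)

    def test_affected_noncarrier_matches_closed_form(self, small_model):
        a = 50
        ind = pk.Individual(id="x", sex="F", birth_year=1960, censor_age=60,
                            diagnoses={"bc": a})
        lam0 = small_model.baseline("bc", 1960).lam0
        rr = small_model._poly_rr[1]  # middle polygene level
        expected = np.exp(-(lam0[:a] * rr[:a]).sum()) * lam0[a] * rr[a]
        got = phenotype_likelihood(ind, None, 1, small_model)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_pathology_multiplies_category_probability(self, small_model):
        a = 40
        plain = pk.Individual(id="x", sex="F", birth_year=1960, censor_age=60,
                              diagnoses={"bc": a})
        tn = pk.Individual(id="x", sex="F", birth_year=1960, censor_age=60,
                           diagnoses={"bc": a}, pathology="tn")
        for gene in (None, "G1"):
            dist = small_model.config.pathology_for(gene)
            factor = pk.pathology_category_prob(dist, "tn", a)
            assert (phenotype_likelihood(tn, gene, 1, small_model)
                    == pytest.approx(factor * phenotype_likelihood(plain, gene, 1, small_model)))


class TestPeeling:
    def test_single_untested_newborn_likelihood_is_one(self, small_model):
        ped = solo_target(birth_year=2020, censor_age=0)
        assert pk.peel_likelihood(ped, small_model) == pytest.approx(1.0, abs=1e-12)

    def test_trio_matches_enumeration(self, small_model):
        ped = trio(mother_kwargs={"diagnoses": {"bc": 50}, "pathology": "tn",
                                  "tests": {"G1": "neg"}},
                   child_kwargs={"prs_z": 1.2})
        a = pk.peel_likelihood(ped, small_model)
        b = pk.enumerate_likelihood(ped, small_model)
        assert a == pytest.approx(b, rel=1e-12)

    def test_likelihood_invariant_to_relabelling(self, small_model):
        ped1 = trio()
        relabel = {"f": "zzz", "m": "qqq", "c": "aaa"}
        members = []
        for ind in ped1.members.values():
            members.append(pk.Individual(
                id=relabel[ind.id], sex=ind.sex, birth_year=ind.birth_year,
                censor_age=ind.censor_age,
                father=None if ind.father is None else relabel[ind.father],
                mother=None if ind.mother is None else relabel[ind.mother],
                target=ind.target))
        ped2 = pk.Pedigree(members)
        assert pk.peel_likelihood(ped1, small_model) == pytest.approx(
            pk.peel_likelihood(ped2, small_model), rel=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_peeling_equals_enumeration_random_pedigrees(self, seed):
        model = build_small_model()
        spec = pk.FixtureSpec(seed=seed, pedigree_size=(1, 6))
        ped = pk.make_pedigree(spec, model, np.random.default_rng(seed))
        a = pk.peel_likelihood(ped, model)
        b = pk.enumerate_likelihood(ped, model)
        assert a == pytest.approx(b, rel=1e-9)


class TestCarrierProbabilities:
    def test_untested_newborn_recovers_collapsed_prior(self, small_model):
        ped = solo_target(birth_year=2020, censor_age=0)
        post = pk.carrier_probabilities(ped, small_model)
        prior = small_model.major_prior()
        assert post["none"] == pytest.approx(prior[0], abs=1e-12)
        assert post["G1"] == pytest.approx(prior[1], abs=1e-12)
        assert post["G2"] == pytest.approx(prior[2], abs=1e-12)

    def test_posteriors_sum_to_one(self, small_model):
        ped = trio(mother_kwargs={"diagnoses": {"bc": 45}})
        post = pk.carrier_probabilities(ped, small_model)
        assert sum(post.values()) == pytest.approx(1.0, abs=1e-12)

    def test_negative_test_closed_form_bayes(self, small_model):
        ped = solo_target(birth_year=2020, censor_age=0, tests={"G1": "neg"})
        post = pk.carrier_probabilities(ped, small_model)
        g = small_model.config.gene("G1")
        prior = small_model.major_prior()
        # closed form over the three collapsed states
        num = prior[1] * (1 - g.sensitivity)
        den = num + prior[0] + prior[2]
        assert post["G1"] == pytest.approx(num / den, rel=1e-12)

    def test_positive_test_with_full_sensitivity_is_certain(self):
        model = build_small_model(genes=(
            pk.GeneParams("G1", 0.003, 1.0, {"bc": pk.AgePiecewiseRR.constant(3.0)}, 1),
            pk.GeneParams("G2", 0.002, 0.8, {"bc": pk.AgePiecewiseRR.constant(1.8)}, 2)))
        ped = solo_target(tests={"G1": "pos"})
        post = pk.carrier_probabilities(ped, model)
        assert post["G1"] == pytest.approx(1.0, abs=1e-12)

    def test_impossible_observation_raises(self):
        model = build_small_model()
        ped = solo_target(tests={"G1": "pos", "G2": "pos"})
        # collapsed representation cannot carry two genes at once
        with pytest.raises(ModelError, match="inconsistent"):
            pk.state_posterior(ped, model)

    def test_tn_diagnosis_raises_er_neg_gene_posterior(self, small_model):
        # G1's pathology table is ER-negative/TN enriched relative to the
        # population; a TN tumour should raise its posterior over an ER+ one
        def posterior(pathology):
            ped = solo_target(birth_year=1960, censor_age=60,
                              diagnoses={"bc": 40}, pathology=pathology)
            return pk.carrier_probabilities(ped, small_model)["G1"]
        assert posterior("tn") > posterior("er_pos")

    def test_uninformative_relative_leaves_posterior_unchanged(self, small_model):
        base = trio(mother_kwargs={"diagnoses": {"bc": 50}})
        post1 = pk.carrier_probabilities(base, small_model)
        extra = list(base.members.values()) + [
            pk.Individual(id="sib", sex="M", birth_year=1990, censor_age=0,
                          father="f", mother="m")]
        post2 = pk.carrier_probabilities(pk.Pedigree(extra), small_model)
        for k in post1:
            assert post2[k] == pytest.approx(post1[k], abs=1e-12)
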