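import numpy as np
import pytest

from hybridpanel._errors import ValidationError
from hybridpanel.genotype_core.model import HET, HOM1, HOM2, MISSING, concatenate
from hybridpanel.hybrid_classify import (
    PRIOR_COMBINATIONS,
    CategoryPosterior,
    ClassifierConfig,
    GenotypeFrequencyClass,
    classify,
    decide,
    default_categories,
    genotype_likelihood,
    mirror_category,
)
from hybridpanel.hybrid_sim import simulate_class
from hybridpanel.synthetic_data import AlleleFrequencyModel, sample_population

from conftest import make_loci, make_matrix

CATEGORY_NAMES = tuple(c.name for c in default_categories())


class TestCategories:
    def test_ten_defaults(self):
        cats = default_categories()
        assert len(cats) == 10
        assert cats[0].g == (1.0, 0.0, 0.0)
        assert cats[1].g == (0.0, 0.0, 1.0)

    def test_invalid_triple(self):
        with pytest.raises(ValidationError):
            GenotypeFrequencyClass(name="x", g=(0.5, 0.2, 0.2))

    def test_mirror(self):
        assert mirror_category("BC2w") == "BC2d"
        assert mirror_category("W") == "D"
        assert mirror_category("F1") == "F1"


class TestGenotypeLikelihood:
    def test_diagnostic_f1_het(self):
        assert genotype_likelihood(HET, 1.0, 0.0, (0, 1, 0)) == 1.0

    def test_diagnostic_parental_hom(self):
        assert genotype_likelihood(HOM1, 1.0, 0.0, (1, 0, 0)) == 1.0

    def test_f2_hom1_arithmetic(self):
        # 0.25*0.81 + 0.5*0.09 + 0.25*0.01 = 0.25
        val = genotype_likelihood(HOM1, 0.9, 0.1, (0.25, 0.5, 0.25))
        assert val == pytest.approx(0.25)

    def test_missing_is_one(self):
        assert genotype_likelihood(MISSING, 0.3, 0.7, (0.25, 0.5, 0.25)) == 1.0

    def test_normalisation(self):
        g = (0.5, 0.5, 0.0)
        total = sum(genotype_likelihood(c, 0.8, 0.3, g) for c in (HOM1, HET, HOM2))
        assert total == pytest.approx(1.0)

    def test_relabel_symmetry(self):
        for call in (HOM1, HET, HOM2):
            assert genotype_likelihood(call, 0.8, 0.25, (0.25, 0.5, 0.25)) == pytest.approx(
                genotype_likelihood(2 - call, 0.2, 0.75, (0.25, 0.5, 0.25)))

    def test_frequency_bounds(self):
        with pytest.raises(ValidationError):
            genotype_likelihood(HET, 1.2, 0.0, (0, 1, 0))


class TestDecide:
    def _post(self, **kv):
        q = np.zeros(len(CATEGORY_NAMES))
        for name, val in kv.items():
            q[CATEGORY_NAMES.index(name)] = val
        return CategoryPosterior(individual_id="x", categories=CATEGORY_NAMES, q=q)

    def test_assigned_and_hybrid(self):
        cfg = ClassifierConfig()
        post = decide(self._post(F1=0.6, F2=0.4), cfg)
        assert post.assigned_category == "F1"
        assert post.hybrid_detected

    def test_below_half_unassigned(self):
        post = decide(self._post(F1=0.45, BC1w=0.3, W=0.25), ClassifierConfig())
        assert post.assigned_category is None

    def test_parental_not_hybrid(self):
        post = decide(self._post(W=0.8, BC1w=0.2), ClassifierConfig())
        assert post.assigned_category == "W"
        assert post.hybrid_sum == pytest.approx(0.2)
        assert not post.hybrid_detected

    def test_exactly_threshold(self):
        post = decide(self._post(F1=0.5, W=0.5), ClassifierConfig())
        assert post.assigned_category is not None  # >= 0.5 assigns
        post2 = decide(self._post(F1=0.7, W=0.3), ClassifierConfig())
        assert not post2.hybrid_detected  # hybrid_sum must exceed 0.7 strictly


@pytest.fixture(scope="module")
def diagnostic_setup():
    """Small diagnostic dataset with clamped parental reference."""
    model = AlleleFrequencyModel(
        loci=make_loci(40),
        p_wolf=np.full(40, 0.97), p_dog=np.full(40, 0.08),
    )
    wolves = sample_population(model, "wolf", 25, seed=1, id_prefix="w")
    dogs = sample_population(model, "dog", 25, seed=2, id_prefix="d")
    known = {i.id: "W" for i in wolves.individuals}
    known.update({i.id: "D" for i in dogs.individuals})
    return model, wolves, dogs, known


class TestClassify:
    def test_f1_diagnostic(self, diagnostic_setup):
        model, wolves, dogs, known = diagnostic_setup
        f1 = make_matrix(np.full((2, 40), HET), groups=["F1?", "F1?"], loci=model.loci)
        data = concatenate([wolves, dogs, f1])
        cfg = ClassifierConfig(burn_in=1000, sweeps=4000, known_assignments=known, seed=3)
        res = classify(data, cfg)
        for post in res.posteriors[-2:]:
            assert post.q_of("F1") > 0.99
            assert post.q.sum() == pytest.approx(1.0, abs=1e-9)

    def test_prior_combinations_agree_on_diagnostic_input(self, diagnostic_setup):
        model, wolves, dogs, known = diagnostic_setup
        sims = [simulate_class(c, model.p_wolf, model.p_dog, 4, seed=9, loci=model.loci)
                for c in ("F1", "BC1w", "W")]
        data = concatenate([wolves, dogs] + sims)
        assignments = []
        for pi_p, th_p in PRIOR_COMBINATIONS:
            cfg = ClassifierConfig(pi_prior=pi_p, theta_prior=th_p, burn_in=1000,
                                   sweeps=4000, known_assignments=known, seed=4)
            res = classify(data, cfg)
            assignments.append([p.assigned_category for p in res.posteriors[50:]])
        for other in assignments[1:]:
            assert other == assignments[0]

    def test_oracle_single_free_individual(self, diagnostic_setup):
        """Exhaustive-enumeration posterior for one free individual.

        With a dense clamped parental panel, theta is pinned near its
        posterior mean and pi integrates to uniform over categories for a
        single free individual, so q(c) ~ prod_l P(g_l | theta, c) / C.
        """
        model = AlleleFrequencyModel(loci=make_loci(2), p_wolf=np.array([0.8, 0.9]),
                                     p_dog=np.array([0.2, 0.25]))
        wolves = sample_population(model, "wolf", 300, seed=5, id_prefix="w")
        dogs = sample_population(model, "dog", 300, seed=6, id_prefix="d")
        known = {i.id: "W" for i in wolves.individuals}
        known.update({i.id: "D" for i in dogs.individuals})
        free = make_matrix(np.array([[HET, HOM1]], dtype=np.int8), groups=["?"],
                           loci=model.loci)
        data = concatenate([wolves, dogs, free])
        cfg = ClassifierConfig(burn_in=2000, sweeps=30_000, known_assignments=known,
                               seed=7, estimator="rao-blackwell")
        res = classify(data, cfg)
        q_mcmc = res.posteriors[-1].q

        theta_w = res.theta_mean[0]
        theta_d = res.theta_mean[1]
        cats = default_categories()
        weights = np.array([
            np.prod([genotype_likelihood(int(free.calls[0, l]), theta_w[l], theta_d[l], c.g)
                     for l in range(2)])
            for c in cats
        ])
        oracle = weights / weights.sum()
        np.testing.assert_allclose(q_mcmc, oracle, atol=0.03)

    def test_species_swap_symmetry(self, diagnostic_setup):
        model, wolves, dogs, known = diagnostic_setup
        bc1w = simulate_class("BC1w", model.p_wolf, model.p_dog, 3, seed=11,
                              loci=model.loci)
        data = concatenate([wolves, dogs, bc1w])
        cfg = ClassifierConfig(burn_in=1500, sweeps=8000, known_assignments=known, seed=8)
        res = classify(data, cfg)

        # mirror the dataset: flip every call and swap the clamped labels
        mirrored = make_matrix((2 - data.calls) % 3, groups=data.groups, loci=data.loci)
        mirrored.calls[data.calls == MISSING] = MISSING
        for i, ind in enumerate(data.individuals):
            mirrored.individuals[i] = ind
        known_swapped = {k: mirror_category(v) for k, v in known.items()}
        cfg2 = ClassifierConfig(burn_in=1500, sweeps=8000,
                                known_assignments=known_swapped, seed=8)
        res2 = classify(mirrored, cfg2)
        names = res.config.category_names
        for p1, p2 in zip(res.posteriors[-3:], res2.posteriors[-3:]):
            for name in names:
                assert p1.q_of(name) == pytest.approx(p2.q_of(mirror_category(name)),
                                                      abs=0.05)

    def test_deterministic(self, diagnostic_setup):
        model, wolves, dogs, known = diagnostic_setup
        data = concatenate([wolves, dogs])
        cfg = ClassifierConfig(burn_in=500, sweeps=1000, known_assignments=known, seed=5)
        q1 = classify(data, cfg).posteriors[0].q
        q2 = classify(data, cfg).posteriors[0].q
        np.testing.assert_array_equal(q1, q2)

    def test_q_sums_to_one(self, diagnostic_setup):
        model, wolves, dogs, known = diagnostic_setup
        data = concatenate([wolves, dogs])
        cfg = ClassifierConfig(burn_in=500, sweeps=1500, seed=6)
        for post in classify(data, cfg).posteriors:
            assert post.q.sum() == pytest.approx(1.0, abs=1e-9)

    def test_needs_two_individuals(self):
        m = make_matrix(np.zeros((1, 3), dtype=np.int8))
        with pytest.raises(ValidationError):
            classify(m, ClassifierConfig(burn_in=10, sweeps=10))

    def test_unknown_clamp_target(self, diagnostic_setup):
        model, wolves, dogs, _ = diagnostic_setup
        data = concatenate([wolves, dogs])
        with pytest.raises(ValidationError):
            classify(data, ClassifierConfig(burn_in=10, sweeps=10,
                                            known_assignments={"w1": "BC9x"}))

    def test_config_contracts(self):
        with pytest.raises(ValidationError):
            ClassifierConfig(pi_prior="flat")
        with pytest.raises(ValidationError):
            ClassifierConfig(burn_in=0)
        with pytest.raises(ValidationError):
            ClassifierConfig(categories=[])
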