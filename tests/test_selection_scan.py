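"""Selection index components, null simulation and FDR machinery."""

import math

import msprime
import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from beanscan.selection_scan import (
    DemographicModel,
    MonomorphicFragmentError,
    Normalization,
    ParameterPriors,
    PriorSpec,
    bh_adjust,
    component_stats,
    empirical_p,
    model1,
    model2,
    reconstructed_priors,
    selection_index,
    simulate_null,
)
from beanscan.seqdata import LocusAlignment


class TestDemographicModel:
    def test_validation_rejects_bad_ordering(self):
        with pytest.raises(ValueError):
            DemographicModel(T_BMD=5000, T_EMD=6000).validate()

    def test_intensity_bounds(self):
        with pytest.raises(ValueError):
            DemographicModel(I_MD=0.0).validate()
        with pytest.raises(ValueError):
            DemographicModel(I_MD=150.0).validate()

    def test_bottleneck_size_from_intensity(self):
        m = DemographicModel(I_MD=2.0, N_MWANC=100_000)
        assert m.bottleneck_size_md == pytest.approx(2000.0)

    def test_both_models_build_demographies(self):
        for m in (model1(), model2()):
            for two_pop in (True, False):
                d = m.to_demography(two_population=two_pop)
                d.validate()  # msprime internal consistency

    def test_four_population_topology_simulates(self):
        ts = msprime.sim_ancestry(
            samples={"MW": 3, "MD": 3, "AW": 3, "AD": 3},
            demography=model1().to_demography(two_population=False),
            sequence_length=100, ploidy=1, random_seed=5)
        assert ts.num_samples == 12


class TestPriors:
    def test_rejection_respects_invariants(self, rng):
        priors = ParameterPriors(demography={
            "T_BMD": PriorSpec("uniform", 5000, 10000),
            "T_EMD": PriorSpec("uniform", 4000, 9000),
        })
        for _ in range(50):
            m = priors.sample_model(DemographicModel(), rng)
            assert m.T_EMD < m.T_BMD

    def test_reconstructed_priors_sample(self, rng):
        priors = reconstructed_priors(DemographicModel())
        m = priors.sample_model(DemographicModel(), rng)
        m.validate()
        assert priors.sample_mu("exonic", rng) < priors.sample_mu(
            "intronic", rng) * 10


class TestComponentStats:
    def test_identical_populations_near_zero(self):
        w = LocusAlignment("f", {"w1": "ACGTAT", "w2": "ACGTAA"})
        d = LocusAlignment("f", {"d1": "ACGTAT", "d2": "ACGTAA"})
        fst, branch, delta = component_stats(w, d)
        assert abs(fst) < 1e-9 or fst < 0
        assert delta == 0.0

    def test_monomorphic_excluded(self):
        w = LocusAlignment("f", {"w1": "ACGT", "w2": "ACGT"})
        d = LocusAlignment("f", {"d1": "ACGT", "d2": "ACGT"})
        with pytest.raises(MonomorphicFragmentError):
            component_stats(w, d)

    def test_sweep_like_fragment_all_positive(self):
        # wild polymorphic, domesticated fixed for a diverged haplotype
        w = LocusAlignment("f", {"w1": "AAAAAA", "w2": "AAAATA",
                                 "w3": "AAATAA", "w4": "AAAAAA"})
        d = LocusAlignment("f", {f"d{i}": "TTAAAA" for i in range(4)})
        fst, branch, delta = component_stats(w, d)
        assert fst > 0 and branch > 0 and delta > 0
        assert branch == pytest.approx(-math.log(1 - fst), abs=1e-12)

    def test_branch_length_closed_form(self):
        assert -math.log(1 - 0.5) == pytest.approx(0.6931, abs=1e-4)


class TestSelectionIndex:
    def test_all_identical_fragments_zero(self):
        comps = np.ones((5, 3))
        norm = Normalization.from_components(comps)
        assert np.allclose(selection_index(comps, norm), 0.0)

    def test_two_fragments_symmetric(self):
        comps = np.array([[1.0, 1, 1], [3.0, 3, 3]])
        norm = Normalization.from_components(comps)
        idx = selection_index(comps, norm)
        assert idx[0] == pytest.approx(-idx[1])
        assert idx[1] == pytest.approx(3.0)  # three z-scores of +1

    def test_location_invariance(self, rng):
        comps = rng.normal(size=(10, 3))
        shifted = comps + np.array([5.0, -2.0, 7.0])
        n1 = Normalization.from_components(comps)
        n2 = Normalization.from_components(shifted)
        assert np.allclose(selection_index(comps, n1),
                           selection_index(shifted, n2))


class TestEmpiricalP:
    def test_extremes(self):
        null = np.arange(10, dtype=float)
        assert empirical_p(100.0, null) == 0.0
        assert empirical_p(-1.0, null) == 1.0

    def test_median(self):
        null = np.arange(100, dtype=float)
        assert empirical_p(49.5, null) == 0.50

    def test_add_one_variant(self):
        null = np.arange(99, dtype=float)
        assert empirical_p(1000.0, null, add_one=True) == 1 / 100


class TestBH:
    def test_worked_example(self):
        q = bh_adjust([0.01, 0.02, 0.04, 0.5])
        assert np.allclose(q, [0.04, 0.04, 0.04 * 4 / 3, 0.5])

    def test_single_p_identity(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_equal_ps(self):
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_matches_statsmodels(self, rng):
        for _ in range(200):
            p = rng.uniform(size=int(rng.integers(1, 30)))
            q_ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(bh_adjust(p), q_ref, atol=1e-12)

    def test_flagged_set_monotone_in_alpha(self, rng):
        p = rng.uniform(size=40)
        q = bh_adjust(p)
        small = set(np.flatnonzero(q < 0.05))
        large = set(np.flatnonzero(q < 0.20))
        assert small <= large


class TestSimulateNull:
    def test_single_population_watterson(self):
        """Collapsing to one panmictic population reproduces the neutral
        expectation E[S] = theta * a_n * L."""
        N, mu, L, n = 10_000.0, 1e-7, 500, 20
        model = DemographicModel(
            N_MW=N, N_MD=N, N_MWANC=N, N_ANC=N, M_WD=0.0, I_MD=100.0)
        # I=100% makes the bottleneck a no-op; MD merges into MW -> panmixia
        reps = msprime.sim_ancestry(
            samples={"MW": n}, demography=model.to_demography(),
            sequence_length=L, ploidy=1, num_replicates=400, random_seed=3)
        S = []
        rng = np.random.default_rng(7)
        for ts in reps:
            mts = msprime.sim_mutations(
                ts, rate=mu, random_seed=int(rng.integers(1, 2 ** 31)))
            S.append(mts.num_sites)
        a_n = sum(1 / i for i in range(1, n))
        expected = 2 * N * mu * a_n * L
        se = np.std(S, ddof=1) / np.sqrt(len(S))
        assert abs(np.mean(S) - expected) < 3 * se

    def test_deterministic_under_seed(self):
        model = DemographicModel()
        lengths = {"exonic": [300], "intronic": [400]}
        a = simulate_null(model, lengths, n_sims=30, seed=42)
        b = simulate_null(model, lengths, n_sims=30, seed=42)
        for cls in a.components:
            assert np.array_equal(a.components[cls], b.components[cls])
        assert a.n_monomorphic == b.n_monomorphic

    def test_monomorphic_sims_recorded_and_excluded(self):
        # huge N, negligible mu -> fragments mostly monomorphic
        model = DemographicModel()
        priors = ParameterPriors(mutation_rate={
            "exonic": PriorSpec("fixed", 1e-13),
            "intronic": PriorSpec("fixed", 1e-13)})
        null = simulate_null(model, {"exonic": [150], "intronic": [150]},
                             n_sims=20, priors=priors, seed=1)
        total = sum(null.n_monomorphic.values()) + sum(
            len(v) for v in null.components.values())
        assert total == 40
        assert sum(null.n_monomorphic.values()) > 30

    def test_severe_bottleneck_gives_positive_delta(self):
        model = DemographicModel(I_MD=0.05, M_WD=0.0)
        null = simulate_null(model, {"intronic": [800]}, n_sims=150, seed=2)
        delta = null.components["intronic"][:, 2]
        assert delta.mean() > 0.2
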