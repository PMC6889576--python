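"""Coalescent simulator: genealogy laws, mutations, demography, inference."""

import math

import numpy as np
import pytest

from regionpop import coalsim, diversity


CONST = coalsim.DemographicModel.constant(10_000)


class TestGenealogyLaws:
    def test_pairwise_tmrca_expectation(self):
        rng = np.random.default_rng(1)
        times = [coalsim.sample_genealogy(2, CONST, rng).tmrca
                 for _ in range(5000)]
        se = np.std(times) / math.sqrt(len(times))
        assert abs(np.mean(times) - 20_000) < 2 * se

    def test_watterson_expected_segregating_sites(self):
        rng = np.random.default_rng(2)
        S = [coalsim.simulate(10, 5.0, CONST, rng, build_matrix=False).S
             for _ in range(4000)]
        expect = 5.0 * diversity.watterson_a1(10)
        se = np.std(S) / math.sqrt(len(S))
        assert abs(np.mean(S) - expect) < 2 * se

    def test_seeded_determinism(self):
        a = coalsim.simulate(12, 6.0, CONST, seed=99)
        b = coalsim.simulate(12, 6.0, CONST, seed=99)
        assert np.array_equal(a.matrix, b.matrix)
        assert np.array_equal(a.positions, b.positions)
        assert a.genealogy.tmrca == b.genealogy.tmrca

    def test_sfs_matches_neutral_expectation(self):
        """E[number of sites at derived count i] = theta / i per replicate.

        Per-replicate class counts are correlated and overdispersed (shared
        genealogy), so each class is checked with its own empirical standard
        error rather than a Poisson chi-square.
        """
        n, theta, reps = 20, 10.0, 4000
        rng = np.random.default_rng(3)
        per_rep = np.zeros((reps, n - 1))
        for r in range(reps):
            sim = coalsim.simulate(n, theta, CONST, rng, build_matrix=False)
            dc = sim.derived_counts
            dc = dc[(dc > 0) & (dc < n)]
            per_rep[r] = np.bincount(dc, minlength=n)[1:n]
        means = per_rep.mean(axis=0)
        ses = per_rep.std(axis=0) / math.sqrt(reps)
        expected = theta / np.arange(1, n)
        z = (means - expected) / ses
        assert np.all(np.abs(z) < 4.0)

    def test_matrix_consistent_with_counts(self):
        sim = coalsim.simulate(15, 8.0, CONST, seed=4)
        assert np.array_equal(sim.matrix.sum(axis=0), sim.derived_counts)
        assert np.all(np.diff(sim.positions) > 0)

    def test_cross_check_against_msprime(self):
        """Independent oracle: msprime's mean S and TMRCA for the same
        configuration (tiny scale)."""
        msprime = pytest.importorskip("msprime")
        n, theta, N, reps = 10, 5.0, 10_000, 1500
        rng = np.random.default_rng(5)
        mine_S = [coalsim.simulate(n, theta, CONST, rng, build_matrix=False).S
                  for _ in range(reps)]
        mine_T = [coalsim.sample_genealogy(n, CONST, rng).tmrca
                  for _ in range(reps)]
        mu = theta / (4 * N)  # per-region rate
        other_S, other_T = [], []
        # ploidy=1 with population_size=2N reproduces the diploid timescale
        for ts in msprime.sim_ancestry(
                samples=n, population_size=2 * N, ploidy=1,
                num_replicates=reps, random_seed=11):
            other_T.append(ts.max_root_time)
            mts = msprime.sim_mutations(
                ts, rate=mu, random_seed=int(ts.max_root_time) % 100_000 + 1,
                discrete_genome=False)
            other_S.append(mts.num_sites)
        for mine, other in ((mine_S, other_S), (mine_T, other_T)):
            se = math.hypot(np.std(mine) / math.sqrt(reps),
                            np.std(other) / math.sqrt(reps))
            assert abs(np.mean(mine) - np.mean(other)) < 3 * se


class TestDemography:
    def test_epoch_validation(self):
        with pytest.raises(ValueError):
            coalsim.DemographicModel((coalsim.Epoch(10.0, 100.0),))
        with pytest.raises(ValueError):
            coalsim.DemographicModel((coalsim.Epoch(0, 100), coalsim.Epoch(0, 50)))

    def test_scenario_families_enumerated(self):
        for f in (2, 4, 6, 8, 10):
            assert f"african:{f}x" in coalsim.SCENARIOS
        for f in (10, 20, 40):
            assert f"ooa:{f}x" in coalsim.SCENARIOS
        with pytest.raises(ValueError):
            coalsim.scenario_model("african:3x")

    def test_growth_model_sizes(self):
        m = coalsim.african_growth_model(10)
        assert m.present_size == pytest.approx(100_000)
        # at the growth onset the size is back to the base
        e = m.epochs[0]
        assert e.size_at(3500) == pytest.approx(10_000, rel=1e-9)

    def test_demography_shifts_tajimas_d(self):
        """Growth pushes D negative, a bottleneck pushes it positive."""
        rng = np.random.default_rng(7)
        means = {}
        for name in ("african:10x", "constant", "ooa:10x"):
            model = coalsim.scenario_model(name)
            vals = []
            for _ in range(600):
                sim = coalsim.simulate(40, 10.0, model, rng, build_matrix=False)
                if sim.S:
                    vals.append(diversity.tajimas_d_from_counts(
                        sim.derived_counts, 40))
            means[name] = np.mean(vals)
        assert means["ooa:10x"] > means["constant"] > means["african:10x"]


class TestNullPvalue:
    def test_extreme_observation_convention(self):
        p = coalsim.null_pvalue(99.0, "D", 10, 5.0, CONST, reps=200,
                                tail="upper", seed=1)
        assert p == pytest.approx(1 / 201)
        p_lo = coalsim.null_pvalue(99.0, "D", 10, 5.0, CONST, reps=200,
                                   tail="lower", seed=1)
        assert p_lo == pytest.approx(1.0)

    def test_median_observation_near_half(self):
        _, null = coalsim.null_pvalue(0.0, "D", 20, 8.0, CONST, reps=400,
                                      tail="lower", seed=2, return_null=True)
        med = float(np.median(null))
        p = coalsim.null_pvalue(med, "D", 20, 8.0, CONST, reps=400,
                                tail="lower", seed=3)
        assert 0.3 < p < 0.7

    def test_zero_s_replicates_resampled(self):
        # theta tiny: many replicates have S = 0 and must be redrawn
        null = coalsim.null_distribution("D", 6, 0.05, CONST, reps=50,
                                         seed=4)
        assert null.size == 50
        assert not np.isnan(null).any()

    def test_small_reps_warns(self):
        with pytest.warns(UserWarning):
            coalsim.null_pvalue(0.0, "D", 6, 2.0, CONST, reps=50, seed=5)


class TestStructured:
    def test_split_time_zero_is_panmictic(self):
        rng = np.random.default_rng(8)
        model = coalsim.TwoDemeModel(N=10_000, M=0.0, split_time=0.0)
        times = [coalsim.sample_structured_genealogy((1, 1), model, rng).tmrca
                 for _ in range(3000)]
        se = np.std(times) / math.sqrt(len(times))
        assert abs(np.mean(times) - 20_000) < 2 * se

    def test_deadlock_without_split_or_migration(self):
        model = coalsim.TwoDemeModel(N=1000, M=0.0)
        with pytest.raises(RuntimeError):
            coalsim.sample_structured_genealogy((1, 1), model,
                                                np.random.default_rng(0))

    def test_deme_labels(self):
        model = coalsim.TwoDemeModel(N=1000, M=2.0)
        g = coalsim.sample_structured_genealogy((3, 4), model,
                                                np.random.default_rng(1))
        assert list(g.leaf_deme) == [0, 0, 0, 1, 1, 1, 1]


class TestAgesAndTmrca:
    def test_age_increases_with_derived_count(self):
        rng = np.random.default_rng(9)
        lo, _ = coalsim.allele_age_mc(1, 12, CONST, reps=3000, seed=rng)
        hi, _ = coalsim.allele_age_mc(11, 12, CONST, reps=3000, seed=rng)
        assert hi > lo

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            coalsim.allele_age_mc(0, 10, CONST, reps=10)

    def test_tmrca_constant_closed_form(self):
        assert coalsim.tmrca_expectation(2, CONST) == pytest.approx(400_000)
        assert coalsim.tmrca_expectation(1000, CONST) == pytest.approx(
            800_000, rel=0.01)

    def test_tmrca_monte_carlo_stability(self):
        model = coalsim.scenario_model("ooa:10x")
        a = coalsim.tmrca_expectation(20, model, reps=3000, seed=1)
        b = coalsim.tmrca_expectation(20, model, reps=3000, seed=2)
        assert abs(a - b) / a < 0.1

    @pytest.mark.parametrize("theta,mu,expected", [
        (4e-4, 1e-8, 10_000), (8e-4, 1e-8, 20_000)])
    def test_ne_from_theta(self, theta, mu, expected):
        assert coalsim.ne_from_theta(theta, mu) == pytest.approx(expected)

    def test_ne_linearity_and_validation(self):
        assert coalsim.ne_from_theta(2e-4, 1e-8) * 2 == pytest.approx(
            coalsim.ne_from_theta(4e-4, 1e-8))
        with pytest.raises(ValueError):
            coalsim.ne_from_theta(0.0, 1e-8)
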