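"""Synthetic-data generators: determinism, truth records, forward dynamics."""

import math

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from regionpop import coalsim, diversity, synthetic, sweep


class TestNeutralRegion:
    def test_seeded_vcf_bytes_identical(self, tmp_path):
        a = tmp_path / "a"
        b = tmp_path / "b"
        synthetic.make_neutral_region(20, 5.0, "constant", L=5000, seed=3,
                                      out_dir=a)
        synthetic.make_neutral_region(20, 5.0, "constant", L=5000, seed=3,
                                      out_dir=b)
        assert (a / "panel.vcf").read_bytes() == (b / "panel.vcf").read_bytes()
        assert (a / "ancestral.fa").read_bytes() == (b / "ancestral.fa").read_bytes()

    def test_truth_record_consistent(self):
        panel, truth = synthetic.make_neutral_region(30, 8.0, "constant",
                                                     L=10_000, seed=5)
        assert panel.n_sites == truth["S"]
        assert np.array_equal(panel.matrix.sum(axis=0),
                              truth["derived_counts"])
        assert truth["tmrca_generations"] > 0

    def test_watterson_mean_over_replicates(self):
        rng = np.random.default_rng(6)
        theta, n = 6.0, 24
        S = []
        for _ in range(800):
            panel, truth = synthetic.make_neutral_region(
                n, theta, "constant", L=10_000, seed=rng)
            S.append(truth["S"])
        expect = theta * diversity.watterson_a1(n)
        se = np.std(S) / math.sqrt(len(S))
        assert abs(np.mean(S) - expect) < 2.5 * se

    def test_scenario_accepted(self):
        panel, _ = synthetic.make_neutral_region(10, 5.0, "ooa:20x",
                                                 L=5000, seed=1)
        assert panel.n_chromosomes == 10


class TestForwardSimulator:
    def test_population_size_conserved_and_binary(self):
        params = synthetic.SweepSimParams(N=50, L=10_000, u=5e-6, r=1e-7,
                                          mode="neutral", n_sample=20)
        rng = np.random.default_rng(8)
        pop = synthetic._ForwardPop(params, rng)
        for _ in range(15):
            pop.step()
            assert pop.mat.shape[0] == 100
            assert pop.mat.max(initial=0) <= 1
            pop.prune()  # pruning is lazy; force it before the invariant
            freqs = pop.mat.mean(axis=0)
            assert np.all((freqs > 0) & (freqs < 1))

    def test_neutral_heterozygosity_decay_matches_drift(self):
        """E[H_t] = H_0 (1 - 1/2N)^t for a neutral biallelic locus."""
        N, t = 50, 25
        rng = np.random.default_rng(9)
        params = synthetic.SweepSimParams(N=N, L=1000, u=0.0, r=0.0,
                                          mode="neutral", n_sample=10)
        hets = []
        for _ in range(400):
            pop = synthetic._ForwardPop(params, rng)
            rows = rng.choice(2 * N, size=N, replace=False)
            pop.add_mutation(500.0, rows)  # start at frequency 1/2
            pop.focal_pos = 500.0          # exempt from pruning
            for _ in range(t):
                pop.step()
            f = pop.focal_freq()
            hets.append(2 * f * (1 - f))
        expected = 0.5 * (1 - 1 / (2 * N)) ** t
        se = np.std(hets) / math.sqrt(len(hets))
        assert abs(np.mean(hets) - expected) < 3 * se

    def test_forward_neutral_matches_coalescent(self):
        """S and pi from the forward simulator are statistically
        indistinguishable from the coalescent at matched theta."""
        N, L = 100, 20_000
        u = 10.0 / (4 * N * L)  # theta_region = 10
        rng = np.random.default_rng(10)
        S_f, pi_f, S_c, pi_c = [], [], [], []
        for _ in range(120):
            panel = synthetic.forward_neutral_panel(
                N=N, L=L, u=u, r=0.0, generations=100, n_sample=30, seed=rng)
            S_f.append(panel.n_sites)
            pi_f.append(diversity.theta_pi(panel.matrix)[1])
            sim = coalsim.simulate(30, 10.0,
                                   coalsim.DemographicModel.constant(N), rng,
                                   build_matrix=False)
            S_c.append(sim.S)
            pi_c.append(diversity.pi_from_counts(sim.derived_counts, 30))
        assert mannwhitneyu(S_f, S_c).pvalue > 0.01
        assert mannwhitneyu(pi_f, pi_c).pvalue > 0.01


class TestSweepPanels:
    def test_hard_sweep_reaches_window_and_records_truth(self):
        params = synthetic.SweepSimParams(N=300, L=100_000, s=0.08,
                                          u=1e-7, r=1e-7,
                                          n_sample=60, seed=21)
        panel, truth = synthetic.make_sweep_panel(params)
        f = truth["trajectory"][-1]
        assert 0.6 <= f <= 0.9
        fi = truth["focal_index"]
        dc = panel.matrix[:, fi].mean()
        assert abs(dc - f) < 0.2  # sample frequency tracks population
        assert panel.sites[fi].position == truth["focal_position"]

    def test_sweep_elevates_derived_ehh(self):
        params = synthetic.SweepSimParams(N=300, L=100_000, s=0.08,
                                          u=1e-7, r=1e-7,
                                          n_sample=60, seed=22)
        panel, truth = synthetic.make_sweep_panel(params)
        fi = truth["focal_index"]
        cd = sweep.ehh_curve(panel, fi, 1)
        ca = sweep.ehh_curve(panel, fi, 0)
        off = 20_000
        d = (sweep.ehh_at(cd, off) + sweep.ehh_at(cd, -off)) / 2
        a = (sweep.ehh_at(ca, off) + sweep.ehh_at(ca, -off)) / 2
        assert d > a

    def test_soft_standing_more_origin_haplotypes_than_hard(self):
        """Soft sweeps from standing variation leave the selected allele on
        more distinct haplotype backgrounds than hard sweeps."""
        def distinct_carrier_haps(mode, seed):
            params = synthetic.SweepSimParams(
                N=300, L=100_000, s=0.08, mode=mode, f0=0.05,
                u=1e-7, r=1e-7, n_sample=60, seed=seed)
            panel, truth = synthetic.make_sweep_panel(params)
            fi = truth["focal_index"]
            carriers = panel.matrix[panel.matrix[:, fi] == 1]
            return np.unique(carriers, axis=0).shape[0]

        hard = [distinct_carrier_haps("hard", 100 + i) for i in range(8)]
        soft = [distinct_carrier_haps("soft-standing", 200 + i)
                for i in range(8)]
        assert np.median(soft) > np.median(hard)

    def test_soft_recurrent_records_origin_count(self):
        params = synthetic.SweepSimParams(N=200, L=50_000, s=0.1,
                                          mode="soft-recurrent", k_origins=3,
                                          u=2e-7, r=2e-7,
                                          n_sample=40, seed=31)
        panel, truth = synthetic.make_sweep_panel(params)
        assert truth["origins"] >= 1

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            synthetic.SweepSimParams(s=0.0)
        with pytest.raises(ValueError):
            synthetic.SweepSimParams(f0=1.5)
        with pytest.warns(UserWarning):
            synthetic.SweepSimParams(N=50, s=0.01)


class TestArchaicPair:
    def test_shallow_split_shares_more_than_deep(self):
        _, _, shallow = synthetic.make_archaic_pair(
            30, 8.0, N=10_000, split_time=5_000, seed=41)
        _, _, deep = synthetic.make_archaic_pair(
            30, 8.0, N=10_000, split_time=500_000, seed=41)
        f_shallow = np.mean(shallow["shared"]["Archaic1"])
        f_deep = np.mean(deep["shared"]["Archaic1"])
        assert f_shallow > f_deep
        assert f_deep <= 0.05

    def test_split_zero_archaic_is_panel_member(self):
        panel, arch, truth = synthetic.make_archaic_pair(
            20, 6.0, N=10_000, split_time=0.0, seed=42)
        # with no isolation the archaic behaves like any sampled chromosome:
        # every site where it carries the derived allele is flagged shared
        from regionpop.region_io import share_with_archaic
        df = share_with_archaic(panel, arch)
        assert df["Archaic1"].tolist() == list(truth["shared"]["Archaic1"])

    def test_panel_readable_by_region_io(self, tmp_path):
        from regionpop.region_io import read_vcf_region, write_vcf
        panel, _, _ = synthetic.make_archaic_pair(
            20, 6.0, N=10_000, split_time=10_000, seed=43)
        write_vcf(panel, tmp_path / "a.vcf")
        back = read_vcf_region(tmp_path / "a.vcf", panel.region,
                               {s: "P1" for s in panel.samples})
        assert back.n_sites == panel.n_sites
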