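"""SFS estimators, haplotype summaries, MAF classes, regional sharing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from regionpop import coalsim, diversity

from conftest import make_panel


def matrix_from_counts(counts, n, rng=None):
    """Binary matrix with given derived counts per column."""
    rng = rng or np.random.default_rng(0)
    cols = []
    for i in counts:
        col = np.zeros(n, dtype=np.uint8)
        col[rng.choice(n, size=i, replace=False)] = 1
        cols.append(col)
    return np.column_stack(cols) if cols else np.zeros((n, 0), np.uint8)


class TestThetaPi:
    def test_closed_form(self):
        mat = matrix_from_counts([2, 3], 4)
        per_site, counts = diversity.theta_pi(mat, L=100)
        assert counts == pytest.approx(8 / 12 + 6 / 12)
        assert per_site == pytest.approx(1.1667 / 100, rel=1e-3)

    def test_monomorphic_zero(self):
        assert diversity.theta_pi(np.zeros((6, 4), np.uint8))[1] == 0.0

    def test_requires_two_chromosomes(self):
        with pytest.raises(ValueError):
            diversity.theta_pi(np.zeros((1, 3), np.uint8))


class TestThetaW:
    def test_closed_form(self):
        per_site, counts = diversity.theta_w(3, 4, L=100)
        assert counts == pytest.approx(3 / (11 / 6))
        assert per_site == pytest.approx(0.016364, rel=1e-4)

    def test_no_segregating_sites(self):
        assert diversity.theta_w(0, 10)[1] == 0.0


def test_estimators_unbiased_under_neutral_coalescent():
    """E[pi] = E[theta_W] = theta for the constant-size coalescent."""
    theta, n, reps = 10.0, 50, 2000
    model = coalsim.DemographicModel.constant(10_000)
    rng = np.random.default_rng(42)
    pis, tws = [], []
    for _ in range(reps):
        sim = coalsim.simulate(n, theta, model, rng, build_matrix=False)
        pis.append(diversity.pi_from_counts(sim.derived_counts, n))
        tws.append(diversity.theta_w(sim.S, n)[1])
    for vals in (pis, tws):
        se = np.std(vals) / math.sqrt(reps)
        assert abs(np.mean(vals) - theta) < 2 * se


class TestTajimasD:
    def test_undefined_without_segregating_sites(self):
        assert math.isnan(diversity.tajimas_d(np.zeros((10, 3), np.uint8)))

    def test_against_independent_constant_evaluation(self):
        # oracle: evaluate Tajima's 1989 variance constants from scratch
        n, counts = 10, [1, 1, 1, 1, 1]
        mat = matrix_from_counts(counts, n)
        S = len(counts)
        pi = sum(2 * i * (n - i) for i in counts) / (n * (n - 1))
        a1 = sum(1 / i for i in range(1, n))
        a2 = sum(1 / i**2 for i in range(1, n))
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        expected = (pi - S / a1) / math.sqrt(
            (c1 / a1) * S + (c2 / (a1**2 + a2)) * S * (S - 1))
        assert diversity.tajimas_d(mat) == pytest.approx(expected, rel=1e-12)
        assert expected < 0  # all singletons: rare-variant excess

    def test_invariant_to_chromosome_relabeling(self, rng):
        mat = (rng.random((20, 15)) < 0.3).astype(np.uint8)
        perm = rng.permutation(20)
        d1 = diversity.tajimas_d(mat)
        d2 = diversity.tajimas_d(mat[perm])
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_neutral_mean_near_zero(self):
        # E[D] under neutrality is slightly negative at finite S (about
        # -0.1 at n=50, E[S]~45; the same value is produced by msprime)
        model = coalsim.DemographicModel.constant(10_000)
        rng = np.random.default_rng(5)
        vals = []
        for _ in range(2000):
            sim = coalsim.simulate(50, 10.0, model, rng, build_matrix=False)
            if sim.S:
                vals.append(diversity.tajimas_d_from_counts(sim.derived_counts, 50))
        assert -0.15 < np.mean(vals) < 0.05


class TestFayWuH:
    def test_high_frequency_derived_site(self):
        mat = matrix_from_counts([3], 4)
        # pi = 2*3*1/12 = 0.5; thetaH = 2*9/12 = 1.5
        assert diversity.fay_wu_h(mat) == pytest.approx(-1.0)

    def test_singleton_site(self):
        mat = matrix_from_counts([1], 4)
        assert diversity.fay_wu_h(mat) == pytest.approx(0.5 - 2 / 12)

    def test_unpolarized_sites_excluded(self):
        mat = matrix_from_counts([3, 1], 4)
        h = diversity.fay_wu_h(mat, polarized=np.array([True, False]))
        assert h == pytest.approx(-1.0)
        assert math.isnan(diversity.fay_wu_h(mat, polarized=np.array([False, False])))

    def test_polarity_flip_maps_counts(self, rng):
        # flipping all polarities maps derived count i -> n-i
        mat = (rng.random((12, 10)) < 0.4).astype(np.uint8)
        dc = mat.sum(axis=0)
        seg = (dc > 0) & (dc < 12)
        h_flip = diversity.fay_wu_h(1 - mat)
        expected = diversity.pi_from_counts(12 - dc[seg], 12) - \
            diversity.theta_h_from_counts(12 - dc[seg], 12)
        assert h_flip == pytest.approx(expected)

    def test_neutral_mean_near_zero(self):
        model = coalsim.DemographicModel.constant(10_000)
        rng = np.random.default_rng(6)
        vals = []
        for _ in range(2000):
            sim = coalsim.simulate(50, 10.0, model, rng, build_matrix=False)
            if sim.S:
                vals.append(diversity.fay_wu_h_from_counts(sim.derived_counts, 50))
        se = np.std(vals) / math.sqrt(len(vals))
        assert abs(np.mean(vals)) < 2 * se


class TestHaplotypeSpectrum:
    def test_all_distinct(self):
        mat = np.eye(5, 5, dtype=np.uint8)
        spec = diversity.haplotype_spectrum(mat)
        assert spec.h == 5
        assert spec.h_diversity == pytest.approx(1.0)

    def test_two_equal_classes(self):
        mat = np.repeat([[0, 0], [1, 1]], 5, axis=0).astype(np.uint8)
        spec = diversity.haplotype_spectrum(mat)
        assert spec.h == 2
        assert spec.h_diversity == pytest.approx((10 / 9) * 0.5)

    def test_counts_sum_to_n(self, rng):
        mat = (rng.random((30, 8)) < 0.5).astype(np.uint8)
        spec = diversity.haplotype_spectrum(mat)
        assert spec.counts.sum() == 30

    def test_zero_diversity_iff_identical(self):
        mat = np.ones((8, 3), np.uint8)
        assert diversity.haplotype_spectrum(mat).h_diversity == 0.0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(2, 20), st.integers(1, 8), st.integers(0, 10_000))
def test_h_diversity_bounds(n, s, seed):
    mat = (np.random.default_rng(seed).random((n, s)) < 0.5).astype(np.uint8)
    hd = diversity.haplotype_spectrum(mat).h_diversity
    assert 0.0 <= hd <= 1.0 + 1e-12


class TestMafClassification:
    @pytest.mark.parametrize("count,n,expected", [
        (5, 100, "common"),    # MAF exactly 5% is common (boundary inclusive)
        (3, 100, "rare"),
        (0, 100, "rare"),      # monomorphic: MAF 0
        (95, 100, "common"),   # minor allele is the reference one
    ])
    def test_boundary(self, count, n, expected):
        mat = matrix_from_counts([count], n) if count else np.zeros((n, 1), np.uint8)
        maf, classes = diversity.classify_maf(mat)
        assert classes[0] == expected
        assert maf[0] == pytest.approx(min(count, n - count) / n)


class TestRegionalSharing:
    def _panel(self):
        # 8 chromosomes in 4 pops across 2 regions; 4 sites with designed sharing
        mat = np.array([
            # site0 private A, site1 private B, site2 shared, site3 monomorphic
            [1, 0, 1, 0],
            [0, 0, 0, 0],
            [1, 0, 1, 0],
            [0, 0, 0, 0],
            [0, 1, 1, 0],
            [0, 0, 0, 0],
            [0, 1, 1, 0],
            [0, 0, 0, 0],
        ], dtype=np.uint8)
        pops = np.array(["p1", "p1", "p2", "p2", "p3", "p3", "p4", "p4"])
        return make_panel(mat, pops=pops)

    def test_venn_cells(self):
        panel = self._panel()
        cells = diversity.regional_sharing(
            panel, {"p1": "A", "p2": "A", "p3": "B", "p4": "B"})
        assert cells[frozenset({"A"})] == 1
        assert cells[frozenset({"B"})] == 1
        assert cells[frozenset({"A", "B"})] == 1

    def test_cells_partition_segregating_sites(self):
        panel = self._panel()
        cells = diversity.regional_sharing(
            panel, {"p1": "A", "p2": "A", "p3": "B", "p4": "B"})
        assert sum(cells.values()) == 3  # site3 is monomorphic everywhere

    def test_exclusions_respected(self):
        panel = self._panel()
        cells = diversity.regional_sharing(
            panel, {"p1": "A", "p2": "A", "p3": "B", "p4": "B"},
            exclude=("p1", "p2"))
        assert frozenset({"A"}) not in cells or cells.get(frozenset({"A"}), 0) == 0


def test_sfs_summary_consistent_with_parts():
    rng = np.random.default_rng(3)
    mat = (rng.random((20, 30)) < 0.25).astype(np.uint8)
    s = diversity.sfs_summary(mat, L=1000)
    assert s.theta_pi_per_site == pytest.approx(diversity.theta_pi(mat, 1000)[0])
    assert s.D_T == pytest.approx(diversity.tajimas_d(mat), nan_ok=True)
    assert s.H == pytest.approx(diversity.fay_wu_h(mat), nan_ok=True)
    minor = np.minimum(mat.sum(0), 20 - mat.sum(0))
    assert s.singletons == int(np.count_nonzero(minor == 1))
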