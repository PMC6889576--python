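"""Seeded synthetic fixtures for every pipeline stage.

Four generators:

* neutral region panels drawn from the package's coalescent simulator under
  the demographic scenario families, written as phased VCF with an AA tag
  and an ancestral FASTA;
* selective-sweep panels from a discrete-generation diploid Wright-Fisher
  forward simulation with recombination (hard, soft-standing and
  soft-recurrent modes), initialized at neutral coalescent equilibrium;
* a coding gene fixture with within-population polymorphism and outgroup
  divergence at a controllable synonymous/nonsynonymous mix, with the true
  McDonald-Kreitman counts recorded;
* an "archaic" sample pair: extra lineages from a population that split at
  a deep time, for derived-allele-sharing tests.

Every generator takes a seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import coalsim, coding
from .region_io import (ArchaicPanel, GeneModel, GenomicRegion, HaplotypePanel,
                        Site, write_fasta, write_vcf)

__all__ = ["SweepSimParams", "make_neutral_region", "make_sweep_panel",
           "make_gene_fixture", "make_archaic_pair", "forward_neutral_panel"]

_BASES = np.array(list("ACGT"))


def _rng(seed):
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _assign_bases(n_sites: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Random ancestral base per site and a distinct derived base."""
    anc = rng.integers(0, 4, n_sites)
    der = (anc + rng.integers(1, 4, n_sites)) % 4
    return _BASES[anc], _BASES[der]


def _panel_from_binary(matrix: np.ndarray, positions_bp: np.ndarray,
                       region: GenomicRegion, rng,
                       pop_labels: np.ndarray | None = None,
                       p_ref_is_ancestral: float = 0.9) -> HaplotypePanel:
    """Wrap a derived-oriented binary matrix as a polarized HaplotypePanel.

    The VCF ref allele is the ancestral base with probability
    ``p_ref_is_ancestral`` (and the derived base otherwise), so written
    fixtures exercise the polarization machinery.
    """
    n, S = matrix.shape
    if n % 2:
        raise ValueError("need an even number of chromosomes for diploid VCF")
    anc, der = _assign_bases(S, rng)
    ref_is_anc = rng.random(S) < p_ref_is_ancestral
    sites = []
    for j in range(S):
        if ref_is_anc[j]:
            ref, alt, derived_is_alt = anc[j], der[j], True
        else:
            ref, alt, derived_is_alt = der[j], anc[j], False
        sites.append(Site(position=int(positions_bp[j]), ref_allele=str(ref),
                          alt_allele=str(alt), ancestral_allele=str(anc[j]),
                          derived_is_alt=derived_is_alt, polarized=True))
    if pop_labels is None:
        pop_labels = np.repeat("P1", n)
    samples = [f"S{i:04d}" for i in range(n // 2)]
    return HaplotypePanel(region=region, sites=sites, matrix=matrix,
                          chrom_labels=np.asarray(pop_labels), samples=samples)


def _unique_int_positions(rel_positions: np.ndarray, L: int) -> np.ndarray:
    """Map sorted relative positions in (0,1) to strictly increasing 1-based bp."""
    pos = np.floor(np.asarray(rel_positions) * L).astype(np.int64) + 1
    for i in range(1, pos.size):
        if pos[i] <= pos[i - 1]:
            pos[i] = pos[i - 1] + 1
    return pos


def _ancestral_fasta(panel: HaplotypePanel, rng) -> dict[str, str]:
    """Region-length ancestral sequence consistent with the panel's AA."""
    region = panel.region
    seq = rng.choice(list("ACGT"), size=region.length)
    for s in panel.sites:
        seq[s.position - region.start] = s.ancestral_allele
    return {f"{region.chrom}:{region.start}-{region.end}": "".join(seq)}


def make_neutral_region(n: int, theta: float, scenario="constant",
                        L: int = 10_000, seed=None, out_dir=None,
                        chrom: str = "chrS", p_ref_is_ancestral: float = 0.9):
    """Neutral coalescent panel under a named scenario (or a
    DemographicModel), positions uniform on [1, L].

    Returns (panel, truth) where truth records the genealogy, TMRCA and S.
    With ``out_dir``, writes panel.vcf, ancestral.fa and samples.tsv there.
    """
    rng = _rng(seed)
    model = (scenario if isinstance(scenario, coalsim.DemographicModel)
             else coalsim.scenario_model(scenario))
    sim = coalsim.simulate(n, theta, model, rng)
    region = GenomicRegion(chrom, 1, L)
    pos = _unique_int_positions(sim.positions, L)
    panel = _panel_from_binary(sim.matrix, pos, region, rng,
                               p_ref_is_ancestral=p_ref_is_ancestral)
    truth = {"tmrca_generations": sim.genealogy.tmrca, "S": sim.S,
             "genealogy": sim.genealogy, "derived_counts": sim.derived_counts,
             "model": model}
    if out_dir is not None:
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_vcf(panel, out / "panel.vcf")
        write_fasta(_ancestral_fasta(panel, rng), out / "ancestral.fa")
        with open(out / "samples.tsv", "w") as fh:
            fh.write("sample\tpopulation\n")
            for smp, lab in zip(panel.samples, panel.chrom_labels[::2]):
                fh.write(f"{smp}\t{lab}\n")
    return panel, truth


# ---------------------------------------------------------------------------
# forward Wright-Fisher simulation


@dataclass
class SweepSimParams:
    """Forward-simulation parameters for a selective sweep panel.

    Defaults give a desk-scale sweep that is detectable by haplotype scans:
    N*s = 50 >> 1; recombination keeps the human per-bp rate (which
    preserves the sweep-versus-recombination balance s/r for the unscaled
    selection coefficient), while the mutation rate is raised 4x so the
    reduced population still yields enough markers (about one SNP per
    1.5 kb in a sample) to resolve haplotype identity.
    """

    N: int = 1000                 # diploid population size
    L: int = 600_000              # region length, bp
    r: float = 1e-8               # per-bp per-generation recombination rate
    u: float = 4e-8               # per-bp per-generation mutation rate
    s: float = 0.05               # selection coefficient of the focal allele
    h_dom: float = 0.5            # dominance
    mode: str = "hard"            # hard | soft-standing | soft-recurrent | neutral
    f0: float = 0.05              # start frequency for soft-standing
    k_origins: int = 4            # origins for soft-recurrent
    sample_freq_window: tuple[float, float] = (0.6, 0.9)
    n_sample: int = 100
    burnin_generations: int | None = None  # default 2N (see docs/methods.md)
    max_generations: int = 20_000
    max_restarts: int = 2000
    seed: int | None = None

    @property
    def burnin(self) -> int:
        return (2 * self.N if self.burnin_generations is None
                else self.burnin_generations)

    def __post_init__(self):
        if self.mode != "neutral" and not 0 < self.s <= 1:
            raise ValueError("selection coefficient must be in (0, 1]")
        if not 0 <= self.f0 < 1:
            raise ValueError("f0 must be in [0, 1)")
        if self.mode != "neutral" and self.N * self.s < 10:
            import warnings
            warnings.warn("N*s < 10: sweep may be undetectable")


class _ForwardPop:
    """Mutable forward-simulation state.

    Columns are NOT kept position-sorted during evolution (new mutations are
    appended); consumers sort by ``pos`` when sampling.
    """

    def __init__(self, params: SweepSimParams, rng):
        self.p = params
        self.rng = rng
        N, L = params.N, params.L
        theta = 4.0 * N * params.u * L
        sim = coalsim.simulate(2 * N, max(theta, 1e-6),
                               coalsim.DemographicModel.constant(N), rng)
        self.mat = np.ascontiguousarray(sim.matrix)
        self.pos = sim.positions * L  # float bp
        self.focal_pos: float | None = None
        self.fixed_derived = 0
        self._gen = 0

    @property
    def n_chrom(self) -> int:
        return 2 * self.p.N

    def focal_index(self) -> int | None:
        if self.focal_pos is None:
            return None
        idx = np.nonzero(self.pos == self.focal_pos)[0]
        return int(idx[0]) if idx.size else None

    def focal_freq(self) -> float:
        idx = self.focal_index()
        if idx is None:
            return 0.0
        return float(self.mat[:, idx].sum()) / self.n_chrom

    def add_mutation(self, position: float, rows) -> None:
        col = np.zeros((self.n_chrom, 1), dtype=np.uint8)
        col[rows, 0] = 1
        self.mat = np.concatenate([self.mat, col], axis=1)
        self.pos = np.append(self.pos, position)

    def step(self) -> None:
        """One Wright-Fisher generation with selection at the focal site,
        free recombination at rate r per bp, and new mutations."""
        p, rng = self.p, self.rng
        N = p.N
        two_n = 2 * N
        fi = self.focal_index()
        if fi is not None and p.mode != "neutral":
            x = self.mat[:, fi]
            g = x[0::2].astype(np.int64) + x[1::2]
            w = 1.0 + p.h_dom * p.s * (g == 1) + p.s * (g == 2)
        else:
            w = np.ones(N)
        cw = np.cumsum(w)
        parents = np.searchsorted(cw, rng.random(two_n) * cw[-1])
        start = rng.integers(0, 2, two_n)
        ncx = rng.poisson(p.r * p.L, two_n)
        rows = 2 * parents + start
        child = self.mat[rows]  # fancy indexing already copies
        cx = np.nonzero(ncx)[0]
        single = cx[ncx[cx] == 1]
        if single.size:  # one crossover: a broadcast handles all gametes
            breaks = rng.random(single.size) * p.L
            tail = self.pos[None, :] >= breaks[:, None]
            a = self.mat[2 * parents[single] + start[single]]
            b = self.mat[2 * parents[single] + 1 - start[single]]
            child[single] = np.where(tail, b, a)
        for i in cx[ncx[cx] >= 2]:
            breaks = np.sort(rng.random(ncx[i]) * p.L)
            parity = np.searchsorted(breaks, self.pos) % 2
            a = self.mat[2 * parents[i] + start[i]]
            b = self.mat[2 * parents[i] + 1 - start[i]]
            child[i] = np.where(parity == 0, a, b)
        self.mat = child
        # new neutral mutations, appended in one block per generation
        n_mut = rng.poisson(two_n * p.u * p.L)
        if n_mut:
            new_pos = rng.random(n_mut) * p.L
            new_rows = rng.integers(0, two_n, n_mut)
            cols = np.zeros((two_n, n_mut), dtype=np.uint8)
            cols[new_rows, np.arange(n_mut)] = 1
            self.mat = np.concatenate([self.mat, cols], axis=1)
            self.pos = np.append(self.pos, new_pos)
        self._gen += 1
        if self._gen % 4 == 0:  # fixed/lost columns are inert; prune lazily
            self.prune()

    def checkpoint(self) -> tuple[np.ndarray, np.ndarray]:
        return self.mat.copy(), self.pos.copy()

    def restore(self, state: tuple[np.ndarray, np.ndarray]) -> None:
        self.mat, self.pos = state[0].copy(), state[1].copy()
        self.focal_pos = None

    def prune(self) -> None:
        sums = self.mat.sum(axis=0)
        keep = (sums > 0) & (sums < self.n_chrom)
        if self.focal_pos is not None:
            fi = self.focal_index()
            if fi is not None:
                keep[fi] = True
        self.fixed_derived += int(np.count_nonzero(sums == self.n_chrom))
        if not keep.all():
            self.mat = self.mat[:, keep]
            self.pos = self.pos[keep]


def _inject_focal(pop: _ForwardPop, rng) -> None:
    p = pop.p
    pop.focal_pos = p.L / 2.0
    if p.mode in ("hard", "soft-recurrent", "neutral"):
        pop.add_mutation(pop.focal_pos, int(rng.integers(0, pop.n_chrom)))
    elif p.mode == "soft-standing":
        k = max(1, round(p.f0 * pop.n_chrom))
        rows = rng.choice(pop.n_chrom, size=k, replace=False)
        pop.add_mutation(pop.focal_pos, rows)
    else:
        raise ValueError(f"unknown mode {p.mode!r}")


def make_sweep_panel(params: SweepSimParams):
    """Forward-simulate a sweep and sample a panel once the focal derived
    allele is inside ``sample_freq_window``.

    Returns (panel, truth); truth records the focal position, the frequency
    trajectory, the number of restarts, and (for soft-recurrent) the origin
    count.  Raises RuntimeError if the allele never reaches the window
    within the restart budget.
    """
    p = params
    rng = _rng(p.seed)
    lo, hi = p.sample_freq_window
    restarts = 0
    origins = 0
    # equilibrate haplotype/LD structure once, then restart sweeps from the
    # burned-in state (the coalescent start has no recombination history)
    pop = _ForwardPop(p, rng)
    for _ in range(p.burnin):
        pop.step()
    state = pop.checkpoint()
    while restarts <= p.max_restarts:
        pop.restore(state)
        _inject_focal(pop, rng)
        # sample when the allele first reaches a target drawn uniformly in
        # the window, so sampled frequencies span the whole window
        target = rng.uniform(lo, hi)
        origins = 1 if p.mode != "soft-standing" else \
            int(round(p.f0 * pop.n_chrom))
        trajectory = [pop.focal_freq()]
        lost = False
        for gen in range(p.max_generations):
            pop.step()
            f = pop.focal_freq()
            if (p.mode == "soft-recurrent" and origins < p.k_origins
                    and 0.0 < f < lo):
                carriers = pop.mat[:, pop.focal_index()]
                non = np.nonzero(carriers == 0)[0]
                if non.size:
                    pop.mat[int(rng.choice(non)), pop.focal_index()] = 1
                    origins += 1
            trajectory.append(f)
            if f == 0.0:
                lost = True
                break
            if target <= f <= hi and gen > 0:
                rows = rng.choice(pop.n_chrom, size=p.n_sample, replace=False)
                return _finish_sweep(pop, rows, trajectory, restarts, origins, rng)
            if f >= 1.0:
                lost = True  # overshot to fixation: outside the window
                break
        if not lost and p.mode == "neutral":
            rows = rng.choice(pop.n_chrom, size=p.n_sample, replace=False)
            return _finish_sweep(pop, rows, trajectory, restarts, origins, rng)
        restarts += 1
    raise RuntimeError(
        f"focal allele never reached {p.sample_freq_window} in "
        f"{p.max_restarts} restarts")


def _finish_sweep(pop: _ForwardPop, rows, trajectory, restarts, origins, rng):
    p = pop.p
    sample = pop.mat[rows]
    sums = sample.sum(axis=0)
    keep = (sums > 0) & (sums < len(rows))
    fi = pop.focal_index()
    if fi is not None:
        keep[fi] = True
    sample = sample[:, keep]
    pos = pop.pos[keep]
    order = np.argsort(pos)  # columns are unsorted during evolution
    sample = np.ascontiguousarray(sample[:, order])
    pos = pos[order]
    ipos = _unique_int_positions(pos / p.L, p.L)
    focal_col = int(np.nonzero(pos == pop.focal_pos)[0][0])
    region = GenomicRegion("chrF", 1, p.L)
    panel = _panel_from_binary(sample, ipos, region, rng)
    truth = {"focal_position": int(ipos[focal_col]), "focal_index": focal_col,
             "trajectory": np.asarray(trajectory), "restarts": restarts,
             "origins": origins, "mode": p.mode}
    return panel, truth


def forward_neutral_panel(N: int, L: int, u: float, r: float,
                          generations: int | None = None,
                          n_sample: int = 50, seed=None):
    """Neutral forward simulation: coalescent-equilibrium start, then
    ``generations`` (default 2N) Wright-Fisher generations so that the
    recombination history equilibrates."""
    if generations is None:
        generations = 2 * N
    params = SweepSimParams(N=N, L=L, u=u, r=r, s=0.0,
                            mode="neutral", n_sample=n_sample, seed=None)
    rng = _rng(seed)
    pop = _ForwardPop(params, rng)
    for _ in range(generations):
        pop.step()
    rows = rng.choice(pop.n_chrom, size=n_sample, replace=False)
    sample = pop.mat[rows]
    sums = sample.sum(axis=0)
    keep = (sums > 0) & (sums < n_sample)
    sample = sample[:, keep]
    pos = pop.pos[keep]
    order = np.argsort(pos)
    sample = np.ascontiguousarray(sample[:, order])
    ipos = _unique_int_positions(pos[order] / L, L)
    region = GenomicRegion("chrN", 1, L)
    return _panel_from_binary(sample, ipos, region, rng)


# ---------------------------------------------------------------------------
# coding gene fixture


_NONSTOP = [c for c, aa in coding.CODON_TABLE.items() if aa != "*"]


def make_gene_fixture(cds_length: int, n: int, divergence: float = 0.01,
                      syn_nonsyn_ratio: float = 1.0, n_poly: int = 8,
                      seed=None):
    """Random coding fixture for the McDonald-Kreitman machinery.

    Builds a stop-free CDS, places ``n_poly`` within-population
    polymorphisms and Poisson(divergence x length) outgroup substitutions,
    drawing each event's class so that synonymous : nonsynonymous events
    occur in expectation at ``syn_nonsyn_ratio``.  Returns
    (ingroup_matrix, ref_cds, outgroup_cds, gene_model, truth) where
    ingroup_matrix is the n x L character matrix of phased CDS alleles and
    truth holds the generator's own MKCounts.
    """
    if cds_length % 3:
        raise ValueError("CDS length must be divisible by 3")
    rng = _rng(seed)
    codons = ["ATG"] + [ _NONSTOP[int(rng.integers(len(_NONSTOP)))]
                         for _ in range(cds_length // 3 - 1) ]
    ref = "".join(codons)
    p_syn = syn_nonsyn_ratio / (1.0 + syn_nonsyn_ratio)

    used: set[int] = set()

    def _draw_event(target_effect: str) -> tuple[int, str]:
        for _ in range(10_000):
            j = int(rng.integers(cds_length))
            if j in used:
                continue
            choices = [b for b in "ACGT" if b != ref[j]]
            alt = choices[int(rng.integers(3))]
            if coding.classify_codon_effect(ref, j, alt) == target_effect:
                used.add(j)
                return j, alt
        raise RuntimeError("could not place event with requested effect")

    mat = np.array([list(ref)] * n)
    truth = coding.MKCounts()
    for _ in range(n_poly):
        effect = "synonymous" if rng.random() < p_syn else "nonsynonymous"
        j, alt = _draw_event(effect)
        # SFS-like frequency: derived count i with probability proportional to 1/i
        weights = 1.0 / np.arange(1, n)
        i = int(rng.choice(np.arange(1, n), p=weights / weights.sum()))
        rows = rng.choice(n, size=i, replace=False)
        mat[rows, j] = alt
        if effect == "synonymous":
            truth.P_S += 1
        else:
            truth.P_N += 1
    out = list(ref)
    n_div = int(rng.poisson(divergence * cds_length))
    for _ in range(n_div):
        effect = "synonymous" if rng.random() < p_syn else "nonsynonymous"
        j, alt = _draw_event(effect)
        out[j] = alt
        if effect == "synonymous":
            truth.D_S += 1
        else:
            truth.D_N += 1
    gene = GeneModel(chrom="chrG", exons=((200, 200 + cds_length),),
                     cds=((200, 200 + cds_length),), strand="+")
    return mat, ref, "".join(out), gene, truth


# ---------------------------------------------------------------------------
# archaic pair


def make_archaic_pair(n_modern: int, theta: float, N: float,
                      split_time: float, seed=None, n_archaic: int = 2,
                      L: int = 10_000):
    """Modern panel plus archaic lineages from a population that split
    ``split_time`` generations ago (no post-split migration).

    Returns (panel, archaic, truth): truth['shared'] holds, per retained
    site and archaic chromosome, whether the archaic truly carries the
    modern derived allele (mutations older than the split are shared up to
    incomplete lineage sorting, younger ones are not).
    """
    rng = _rng(seed)
    model = coalsim.TwoDemeModel(N=N, M=0.0, split_time=float(split_time))
    gen = coalsim.sample_structured_genealogy((n_modern, n_archaic), model, rng)
    sim = coalsim._drop_mutations(gen, theta, N, rng)
    modern = sim.matrix[:n_modern]
    arch_rows = sim.matrix[n_modern:]
    # keep sites segregating among moderns
    dc = modern.sum(axis=0)
    keep = (dc > 0) & (dc < n_modern)
    modern = np.ascontiguousarray(modern[:, keep])
    arch_rows = arch_rows[:, keep]
    pos = _unique_int_positions(sim.positions[keep], L)
    region = GenomicRegion("chrA", 1, L)
    panel = _panel_from_binary(modern, pos, region, rng, p_ref_is_ancestral=1.0)
    sources = {}
    shared = {}
    for a in range(n_archaic):
        name = f"Archaic{a + 1}"
        alleles = [s.derived_allele if arch_rows[a, j] else s.ancestral_allele
                   for j, s in enumerate(panel.sites)]
        sources[name] = alleles
        shared[name] = arch_rows[a].astype(bool)
    archaic = ArchaicPanel(positions=panel.positions, alleles=sources)
    truth = {"shared": shared, "split_time": split_time,
             "genealogy": gen}
    return panel, archaic, truth
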