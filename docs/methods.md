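# Methods

`regionpop` implements the statistical toolkit used in region-scale scans
for natural selection on human genes: site-frequency-spectrum diversity and
neutrality statistics judged against coalescent demographic nulls, the
McDonald–Kreitman (M-K) test, pairwise D′ linkage disequilibrium,
haplotype-length selection statistics (EHH, iHS, nSL), Weir–Cockerham
F<sub>ST</sub>, median-joining haplotype networks, and genealogy-based
allele ages.  This note records the models, the defaults and why they were
chosen, and the numerical conventions that a reader reproducing results
needs to know.

## Data model

The central container is the `HaplotypePanel`: a phased binary matrix of
`n_chromosomes x n_sites` over bi-allelic SNPs with per-chromosome
population labels.  After polarization against an ancestral source (FASTA
outgroup or the VCF INFO `AA` tag), matrix entry 1 means the derived
allele; sites whose ancestral base matches neither ref nor alt are flagged
unpolarized and left in ref/alt orientation (they are excluded from
statistics that need polarity, e.g. Fay & Wu's H and iHS cores).
File interfaces are 1-based closed (VCF/GFF convention); interval
arithmetic inside the gene model is 0-based half-open.  Multi-allelic
records, indels, and sites with unphased or missing genotypes are dropped
with a logged count (strict mode raises instead).

## Diversity and neutrality statistics

* θ<sub>π</sub> (mean pairwise differences) and Watterson's θ<sub>W</sub> =
  S/a₁ are reported on the region-total (counts) scale and per site.
* Tajima's D uses the 1989 variance constants; Fay & Wu's H is the
  unnormalized θ<sub>π</sub> − θ<sub>H</sub> (counts scale), matching the
  magnitudes DnaSP prints.  Both are undefined (NaN) at S = 0.
  Note that E[D] under neutrality is slightly negative at realistic S
  (≈ −0.1 at n = 50, E[S] ≈ 45); this is a property of the statistic, not
  a simulator bias — msprime reproduces the same mean.
* "Singletons" are sites whose **minor** allele appears exactly once in the
  population's chromosomes; the minor-allele reading keeps the count
  defined at unpolarized sites.
* Haplotype diversity is Nei's n/(n−1)(1 − Σp²); distinct haplotypes are
  keyed by the exact allele string over all retained sites.
* MAF classes: common at MAF ≥ 5% (boundary inclusive), rare below.

## Coalescent simulator and demographic nulls

The simulator draws Kingman genealogies by inverse-integrated-hazard
sampling under a piecewise history of constant or exponentially growing
epochs, then drops infinite-sites mutations as a Poisson process at rate
θ/(4N₀) per lineage-generation (θ is the region-total scaled mutation
rate; N₀ the present-day diploid size, the ms convention).  Two scenario
families are built in, with a 20-year generation time:

* `african:{2,4,6,8,10}x` — exponential growth reaching f-fold over a
  10,000 base size, starting 70 kya (3,500 generations);
* `ooa:{10,20,40}x` — a bottleneck 10,000 → 2,000 at 60 kya followed by
  f-fold exponential growth from 50 kya to the present.

"f-fold growth from T until now" is implemented as a continuous exponential
over [0, T] (an instantaneous-change variant can be expressed by adding
epochs directly).  A property of the composite bottleneck-plus-growth
histories worth knowing: strong recent growth (20–40-fold) dominates the
bottleneck's signature, so their mean Tajima's D sits at or below the
constant-size mean rather than above it — growth loads the site frequency
spectrum with rare variants faster than the bottleneck removes them, and
increasingly so at larger sample sizes (cross-checked against msprime).
Null simulations condition on θ, not on the observed S;
by default the pipeline sets θ from the population's observed region
θ<sub>W</sub>.  No recombination enters the null simulations — consistent
with single-locus nulls at a 10-kb scale — and replicates with S = 0
(statistic undefined) are discarded and redrawn.  Empirical p-values use
the (1 + #{sim ≥ obs}) / (reps + 1) convention.

### Structured coalescent

A symmetric island model with an optional clean split supports the
F<sub>ST</sub> calibration and the "archaic" fixture.  The migration
parameter M is defined as the **scaled co-location rate**: a pair of
lineages in different demes reunites at rate M/(4N) per generation
(per-lineage rate M(d−1)/(8N) for d demes).  With this parameterization
the equilibrium Weir–Cockerham F<sub>ST</sub> equals 1/(1+M) exactly for
any number of demes, which keeps the familiar island-model closed form
valid at d = 2 (under the per-lineage-fraction convention the d = 2
expectation would instead be 1/(1+4Nm·d/(d−1))).

### Allele ages and TMRCA

The age of a derived allele seen in i of n chromosomes is estimated by
Monte Carlo over neutral genealogies: every branch subtending exactly i
leaves is weighted by its length, a mutation age is drawn uniformly along
it, and the estimate is the pooled branch-length-weighted mean age (in
years via the generation time).  The length weighting implements the
size-biased conditioning "given that a mutation of this frequency
occurred"; it reproduces the classical mean allele age
−2x·ln(x)/(1−x) (in 2N-generation units) at interior frequencies to
within Monte-Carlo error, and for i = 1, n = 2 its closed form is
E[T₂²]/(2E[T₂]) = 2N generations (not E[T₂]/2: long genealogies carry
proportionally more mutations).  TMRCA is analytic, 4N(1−1/n)
generations, for constant size, and Monte Carlo otherwise.  This
frequency-conditioned weighting is a deliberate simplification of
full importance sampling over site configurations (GENETREE-style);
parity with point estimates from that machinery is not claimed.

## McDonald–Kreitman test

Each coding change is classified synonymous/nonsynonymous by translating
the codon with all other positions held at the ingroup-major allele
(single-pathway convention; a strict mode drops codons with more than one
hit).  A site segregating in the population is polymorphic even if it also
differs from the outgroup; a fixed difference requires a within-population
frequency of 100% for the outgroup-mismatched allele.  The two-sided
Fisher exact P sums hypergeometric masses ≤ the observed table's mass,
with a 1e−7 relative tie tolerance (floating-point equality of
hypergeometric masses decides inclusion); empty-margin tables return
P = 1 by convention.  No divergence correction (Jukes–Cantor) and no
polarized M-K variant are applied.

## Linkage disequilibrium

Phased gametes are counted directly (no EM over genotypes).  D′ is
Lewontin's normalization; LOD is the log10 multinomial likelihood ratio of
the observed haplotype frequencies versus linkage equilibrium, zero exactly
when the estimated D is zero.  The default MAF filter is 1%, and the
"complete LD" display convention is D′×100 = 100 after integer rounding.
Hardy–Weinberg or missingness filters are not applied.

## Haplotype-length statistics

EHH for a core allele class is Σ C(n_h,2)/C(n_c,2) over distinct
haplotypes among carriers extended from the core, computed separately left
and right; it starts at 1 and is non-increasing.  iHH integrates the curve
over physical distance with the trapezoid rule, including the segment that
first crosses the EHH cutoff (default 0.05) and stopping there; an arm
that reaches the region edge, or an inter-site gap above 200 kb, while
still above the cutoff marks the core truncated.  Truncated cores are
dropped from scans by default (kept with a flag in permissive mode).
iHS is ln(iHH_A/iHH_D) — negative when the derived allele rides long
haplotypes.  nSL replaces physical distance with the mean pairwise
identical-tract length counted in segregating sites (core included).
Cores need a derived frequency in [5%, 95%] and at least two carriers of
each allele.

Standardization z-scores the raw statistic within derived-allele-frequency
bins: 100 equal-width bins merged left-to-right until each holds at least
20 scores.  |standardized| > 2 (strict) flags outliers — the most extreme
≈5% under approximate normality.

## Weir–Cockerham F<sub>ST</sub>

Phased inputs make chromosomes haploid observations, so the default
estimator is the one-way-ANOVA (haploid) Weir–Cockerham form:
a = (MSP − MSG)/n_c among populations and MSG within, with
F<sub>ST</sub> = a/(a + MSG); the full diploid a/b/c split (with observed
heterozygosity) is available for parity with genotype-based tools.
Multi-locus summaries are reported both as the ratio of sums ("weighted")
and the mean of per-site ratios, because the two differ and downstream
tools print either.  The per-site ratio has a small negative bias at
F<sub>ST</sub> = 0 (the component a is the unbiased quantity).  Percentile
ranks against a background distribution use weak-inequality counting, with
outlier calls at ≤ 2.5th / ≥ 95th percentiles.

## Median-joining network

Nodes start as the distinct observed haplotypes; the network is the
minimum spanning network (union of all MSTs, relaxed by ε; default ε = 0).
Candidate medians are the site-wise majority vectors of node triplets and
are admitted greedily whenever they strictly lower the total MST cost, to
a fixpoint; unobserved medians of degree < 3 are pruned.  With binary
characters the quasi-median is exactly the majority vector, so the
procedure is a Steiner-point search under Hamming distance.  All
tie-breaking (MST construction, median admission) is lexicographic on
haplotype strings, making the output independent of input order.
Character weights are uniform; unpolarized/missing sites are excluded from
the characters.  Cluster membership in published figures is a visual
annotation; the package reports components and per-group node counts and
does not claim an automatic cluster partition.

## Synthetic data

The generators produce every fixture the pipeline consumes, all seeded and
written in standard formats (phased VCF with an `AA` tag, ancestral FASTA,
sample maps):

* **Neutral regions** map coalescent mutations to uniform integer
  positions on [1, L]; the VCF ref allele is the ancestral base with
  probability 0.9 so that polarization is genuinely exercised.
* **Sweep panels** come from a discrete-generation diploid Wright–Fisher
  forward simulation with multiplicative fitness (1, 1+hs, 1+s; h = 0.5),
  uniform recombination and neutral mutation.  The population is
  initialized at the neutral coalescent equilibrium and then burned in
  forward for 2N generations, so the recombination history (which the
  single-tree coalescent start lacks) equilibrates at the length scales
  the haplotype statistics integrate over; sweep restarts after loss of
  the focal allele resume from a checkpoint of the burned-in state.
  Hard sweeps start from one copy, soft-standing sweeps from f₀·2N
  uniformly chosen carriers, soft-recurrent sweeps add origins while the
  allele is below the sampling window.  Each replicate samples when the
  focal frequency first reaches a target drawn uniformly in the window
  (default 0.6–0.9), mirroring incomplete sweeps across the whole window.
  Defaults N = 1000, L = 600 kb, s = 0.05 (Ns = 50), r = 1e−8 and
  u = 4e−8: recombination keeps the human per-bp rate — the haplotype
  footprint of a sweep is governed by s/r, so scaling r up with reduced N
  would emulate a much weaker sweep than the stated s — while the
  mutation rate is raised so the small population still yields about one
  SNP per 1.5 kb in a sample of 100.  For other population sizes, scale
  u (and, if emulating a rescaled s, r) by the same factor.
* **Coding gene fixtures** build a stop-free CDS and place within-
  population polymorphisms (SFS-like frequencies ∝ 1/i) and outgroup
  substitutions with a controllable synonymous:nonsynonymous mix,
  recording the true M-K counts for oracle-identity tests.
* **Archaic pairs** add lineages from a deme that split at a chosen time
  with no migration; the truth record marks which modern derived alleles
  the archaic chromosomes truly carry (older-than-split mutations are
  shared up to incomplete lineage sorting).

What the generators do **not** emulate: sequencing or phasing error,
gene conversion, background selection, mutation-rate or recombination-rate
heterogeneity, GC bias, and realistic human chromosome-scale LD.  Passing
tests therefore demonstrate the statistics' correctness and their power
under clean scaled-down scenarios, not their behaviour on real 1000
Genomes data.

## Problem sizes used in tests and the acceptance script

Estimator unbiasedness and neutrality centering use 2,000 constant-size
replicates at n = 50, θ = 10 (acceptance script: 1,500).  The type-I-error
check draws 2,000 observations each tested against 500-replicate nulls
(script: 500 × 300).  Sweep power uses 50 forward sweeps at the generator
defaults (N = 1000, L = 600 kb, s = 0.05) sampled at derived frequency
0.6–0.9, against 50 matched neutral forward panels from the same
generator (script: 20 + 20).  The island-model calibration pools ~500
two-deme replicates at M = 9.  Allele ages use 2–3·10⁴ genealogies for
n = 2 and 5–6·10³ for n = 50.  These sizes were chosen so each check
resolves its expectation within Monte-Carlo error.

## Known limitations

* No genetic-map (cM) support in iHS — physical distance only.
* No XP-EHH or cross-population haplotype statistics; no r², no
  Gabriel-block partitioning; no normalized H or Zeng's E.
* The coalescent has no recombination (ARGs out of scope); recombination
  exists only in the forward simulator.
* Full-likelihood allele ages (importance sampling over site
  configurations) are approximated by frequency-conditioned weighting.
* Outlier thresholds (|score| > 2) inherit their "extreme 5%" meaning from
  genome-scale standardization; on small simulated regions the tail
  fraction is approximate.
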