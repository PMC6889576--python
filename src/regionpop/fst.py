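"""Weir-Cockerham F_ST from phased chromosomes.

Because input chromosomes are phased haploids, the default estimator is the
haploid (one-way ANOVA over alleles) form of Weir & Cockerham (1984): the
among-individual and within-individual components of the diploid estimator
collapse into a single within-population component.  A diploid variant that
pairs consecutive chromosomes into individuals (splitting b and c, with
observed heterozygosity) is available for parity checks with genotype-based
tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["FstComponents", "wc_fst_site", "wc_fst_site_diploid", "wc_fst_mean",
           "empirical_percentile", "fst_by_site"]


@dataclass
class FstComponents:
    """Variance components at one site: a (among populations),
    b (among individuals within populations; 0 in the haploid form),
    c (within individuals / within populations)."""

    a: float
    b: float
    c: float

    @property
    def total(self) -> float:
        return self.a + self.b + self.c

    @property
    def fst(self) -> float:
        t = self.total
        return self.a / t if t != 0.0 else math.nan


def wc_fst_site(alt_counts, sizes) -> FstComponents:
    """Haploid Weir-Cockerham components from per-population derived-allele
    counts and chromosome sample sizes.

    Equivalent to a one-way ANOVA over 0/1 allele indicators:
    a = (MSP - MSG)/n_c with MSP the among-population mean square and MSG the
    within-population mean square, so F_ST = a / (a + MSG).
    """
    counts = np.asarray(alt_counts, dtype=np.float64)
    n_i = np.asarray(sizes, dtype=np.float64)
    r = counts.size
    if r < 2 or np.any(n_i < 1):
        raise ValueError("need >= 2 populations with >= 1 chromosome each")
    n_tot = n_i.sum()
    p_i = counts / n_i
    p_bar = counts.sum() / n_tot
    if p_bar in (0.0, 1.0):
        return FstComponents(math.nan, 0.0, math.nan)
    msp = float(np.sum(n_i * (p_i - p_bar) ** 2) / (r - 1))
    msg = float(np.sum(n_i * p_i * (1.0 - p_i)) / (n_tot - r))
    n_c = (n_tot - float(np.sum(n_i ** 2)) / n_tot) / (r - 1)
    a = (msp - msg) / n_c
    return FstComponents(a=a, b=0.0, c=msg)


def wc_fst_site_diploid(geno_counts, sizes, het_counts) -> FstComponents:
    """Diploid Weir-Cockerham (1984) components with the full a/b/c split.

    ``geno_counts``: per-population count of the allele over 2n_i gene
    copies; ``sizes``: diploid individuals n_i; ``het_counts``: observed
    heterozygotes per population.
    """
    n_i = np.asarray(sizes, dtype=np.float64)
    r = n_i.size
    if r < 2 or np.any(n_i < 1):
        raise ValueError("need >= 2 populations with >= 1 individual each")
    p_i = np.asarray(geno_counts, dtype=np.float64) / (2.0 * n_i)
    h_i = np.asarray(het_counts, dtype=np.float64) / n_i
    n_bar = n_i.mean()
    n_c = (n_i.sum() - np.sum(n_i ** 2) / n_i.sum()) / (r - 1)
    p_bar = float(np.sum(n_i * p_i) / (r * n_bar))
    if p_bar in (0.0, 1.0):
        return FstComponents(math.nan, math.nan, math.nan)
    s2 = float(np.sum(n_i * (p_i - p_bar) ** 2) / ((r - 1) * n_bar))
    h_bar = float(np.sum(n_i * h_i) / (r * n_bar))
    pq = p_bar * (1.0 - p_bar)
    a = (n_bar / n_c) * (s2 - (pq - (r - 1) / r * s2 - h_bar / 4.0) / (n_bar - 1))
    b = (n_bar / (n_bar - 1)) * (pq - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
    c = h_bar / 2.0
    return FstComponents(a=a, b=b, c=c)


def wc_fst_mean(components: list[FstComponents]) -> dict[str, float]:
    """Multi-locus summaries: ratio-of-sums ("weighted", vcftools' weighted
    F_ST) and mean of per-site ratios ("mean"). NaN sites are skipped."""
    valid = [c for c in components if not math.isnan(c.a)]
    if not valid:
        raise ValueError("no defined per-site components")
    num = sum(c.a for c in valid)
    den = sum(c.total for c in valid)
    ratios = [c.fst for c in valid if not math.isnan(c.fst)]
    return {
        "weighted": num / den if den != 0 else math.nan,
        "mean": float(np.mean(ratios)) if ratios else math.nan,
        "n_sites": len(valid),
    }


def fst_by_site(panel, group_of: dict[str, str]) -> tuple[np.ndarray, list[FstComponents]]:
    """Per-site haploid W-C F_ST over a panel grouped by ``group_of``
    (population label -> group). Returns (fst array with NaN at monomorphic
    sites, component list)."""
    mat = np.asarray(getattr(panel, "matrix", panel))
    labels = np.asarray(panel.chrom_labels)
    groups = sorted(set(group_of.values()))
    rows = [np.isin(labels, [p for p, g in group_of.items() if g == grp])
            for grp in groups]
    sizes = [int(r.sum()) for r in rows]
    comps = []
    fst = np.empty(mat.shape[1])
    for j in range(mat.shape[1]):
        counts = [int(mat[r, j].sum()) for r in rows]
        comp = wc_fst_site(counts, sizes)
        comps.append(comp)
        fst[j] = comp.fst
    return fst, comps


def empirical_percentile(value: float, background) -> tuple[float, str]:
    """Percentile rank of ``value`` in a background distribution
    (weak-inequality counting: 100 * fraction of background <= value), with
    the outlier call used for genome-wide F_ST comparisons
    (low tail <= 2.5th percentile, high tail >= 95th)."""
    bg = np.asarray(background, dtype=np.float64)
    bg = bg[~np.isnan(bg)]
    if bg.size == 0:
        raise ValueError("empty background distribution")
    pct = 100.0 * np.count_nonzero(bg <= value) / bg.size
    if pct <= 2.5:
        flag = "outlier-low"
    elif pct >= 95.0:
        flag = "outlier-high"
    else:
        flag = "none"
    return pct, flag
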