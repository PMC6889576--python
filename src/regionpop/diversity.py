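"""Site-frequency-spectrum and haplotype diversity summaries.

All estimators operate per population on a phased binary matrix
(chromosomes x sites, 1 = derived where polarized, else 1 = alt).  The
count-scale forms (``*_from_counts``) take the vector of derived (or minor)
allele counts directly; the panel-facing wrappers accept either a numpy
matrix or any object with ``.matrix`` (a ``HaplotypePanel``).

Tajima's D and Fay & Wu's H are reported on the region-total (counts) scale,
the convention of DnaSP; theta_pi and theta_W are additionally reported per
site when a surveyed length L is given.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "SfsSummary",
    "HaplotypeSpectrum",
    "theta_pi",
    "theta_w",
    "tajimas_d",
    "fay_wu_h",
    "sfs_summary",
    "haplotype_spectrum",
    "classify_maf",
    "regional_sharing",
    "pi_from_counts",
    "theta_h_from_counts",
    "tajimas_d_from_counts",
    "fay_wu_h_from_counts",
    "watterson_a1",
]


def _as_matrix(panel) -> np.ndarray:
    mat = getattr(panel, "matrix", panel)
    return np.ascontiguousarray(mat)


@lru_cache(maxsize=None)
def watterson_a1(n: int) -> float:
    return sum(1.0 / i for i in range(1, n))


@lru_cache(maxsize=None)
def _tajima_constants(n: int) -> tuple[float, float]:
    """(e1, e2) of Tajima (1989), used in the variance of pi - S/a1."""
    a1 = watterson_a1(n)
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return e1, e2


def pi_from_counts(counts: np.ndarray, n: int) -> float:
    """Mean pairwise differences (counts scale): sum 2 i (n-i) / (n (n-1))."""
    i = np.asarray(counts, dtype=np.float64)
    return float(np.sum(2.0 * i * (n - i)) / (n * (n - 1)))


def theta_h_from_counts(counts: np.ndarray, n: int) -> float:
    """Fay & Wu's theta_H (counts scale): sum 2 i^2 / (n (n-1)) over derived counts."""
    i = np.asarray(counts, dtype=np.float64)
    return float(np.sum(2.0 * i ** 2) / (n * (n - 1)))


def tajimas_d_from_counts(counts: np.ndarray, n: int) -> float:
    counts = np.asarray(counts)
    counts = counts[(counts > 0) & (counts < n)]
    S = counts.size
    if S == 0:
        return math.nan
    pi = pi_from_counts(counts, n)
    a1 = watterson_a1(n)
    e1, e2 = _tajima_constants(n)
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def fay_wu_h_from_counts(counts: np.ndarray, n: int) -> float:
    """Unnormalized H = pi - theta_H (Fay & Wu 2000), counts scale."""
    counts = np.asarray(counts)
    counts = counts[(counts > 0) & (counts < n)]
    if counts.size == 0:
        return math.nan
    return pi_from_counts(counts, n) - theta_h_from_counts(counts, n)


def _derived_counts(mat: np.ndarray) -> np.ndarray:
    return np.asarray(mat, dtype=np.int64).sum(axis=0)


def _segregating(mat: np.ndarray) -> np.ndarray:
    dc = _derived_counts(mat)
    n = mat.shape[0]
    return dc[(dc > 0) & (dc < n)]


def theta_pi(panel, L: int | None = None) -> tuple[float | None, float]:
    """Nucleotide diversity: (per-site, counts-scale) mean pairwise differences.

    Uses derived counts where polarized, which is equivalent to minor counts
    for this statistic (i(n-i) is symmetric in i -> n-i).
    """
    mat = _as_matrix(panel)
    n = mat.shape[0]
    if n < 2:
        raise ValueError("need at least 2 chromosomes")
    pi = pi_from_counts(_derived_counts(mat), n)
    per_site = pi / L if L else None
    return per_site, pi


def theta_w(S: int, n: int, L: int | None = None) -> tuple[float | None, float]:
    """Watterson's estimator: (per-site, counts-scale) S / a1."""
    if n < 2:
        raise ValueError("need at least 2 chromosomes")
    counts = S / watterson_a1(n)
    per_site = counts / L if L else None
    return per_site, counts


def tajimas_d(panel) -> float:
    mat = _as_matrix(panel)
    return tajimas_d_from_counts(_derived_counts(mat), mat.shape[0])


def fay_wu_h(panel, polarized: np.ndarray | None = None) -> float:
    """Unnormalized Fay & Wu's H; ``polarized`` masks columns with a known
    ancestral state (unpolarized columns are excluded)."""
    mat = _as_matrix(panel)
    if polarized is None:
        polarized = getattr(panel, "polarized", None)
    if polarized is not None:
        mat = mat[:, np.asarray(polarized, dtype=bool)]
    if mat.shape[1] == 0:
        return math.nan
    return fay_wu_h_from_counts(_derived_counts(mat), mat.shape[0])


@dataclass
class SfsSummary:
    """Per-population Table-1-style summary of a region."""

    n: int
    S: int
    singletons: int
    L: int
    theta_pi_per_site: float
    theta_w_per_site: float
    pi_counts: float
    thetaw_counts: float
    thetaH_counts: float
    D_T: float
    H: float


def sfs_summary(panel, L: int, polarized: np.ndarray | None = None) -> SfsSummary:
    """All SFS summaries in one pass over a single-population slice."""
    mat = _as_matrix(panel)
    n = mat.shape[0]
    if n < 2:
        raise ValueError("need at least 2 chromosomes")
    dc = _derived_counts(mat)
    seg = dc[(dc > 0) & (dc < n)]
    S = int(seg.size)
    minor = np.minimum(seg, n - seg)
    singletons = int(np.count_nonzero(minor == 1))
    pi = pi_from_counts(seg, n)
    _, tw = theta_w(S, n)
    return SfsSummary(
        n=n, S=S, singletons=singletons, L=L,
        theta_pi_per_site=pi / L, theta_w_per_site=tw / L,
        pi_counts=pi, thetaw_counts=tw,
        thetaH_counts=theta_h_from_counts(seg, n) if S else 0.0,
        D_T=tajimas_d_from_counts(seg, n),
        H=fay_wu_h(mat, polarized=polarized),
    )


@dataclass
class HaplotypeSpectrum:
    """Distinct haplotypes over a region with their counts."""

    haplotypes: list[str]        # allele strings, e.g. "0110...", sorted by count desc
    counts: np.ndarray           # pooled counts, same order
    n: int

    @property
    def h(self) -> int:
        return len(self.haplotypes)

    @property
    def h_diversity(self) -> float:
        """Nei haplotype diversity n/(n-1) (1 - sum p_i^2)."""
        n = self.n
        if n < 2:
            return 0.0
        p = self.counts / n
        return n / (n - 1) * (1.0 - float(np.sum(p ** 2)))


def haplotype_spectrum(panel) -> HaplotypeSpectrum:
    """Distinct haplotype strings over all retained sites, with counts."""
    mat = _as_matrix(panel)
    uniq, counts = np.unique(mat, axis=0, return_counts=True)
    strings = ["".join(map(str, row)) for row in uniq]
    order = sorted(range(len(strings)), key=lambda i: (-counts[i], strings[i]))
    return HaplotypeSpectrum(
        haplotypes=[strings[i] for i in order],
        counts=counts[order],
        n=mat.shape[0],
    )


def classify_maf(panel, threshold: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Per-site minor allele frequency and common/rare class.

    MAF is the frequency of the second-most-frequent allele; sites with
    MAF >= threshold (boundary inclusive) are "common", the rest "rare".
    """
    mat = _as_matrix(panel)
    n = mat.shape[0]
    dc = _derived_counts(mat)
    maf = np.minimum(dc, n - dc) / n
    classes = np.where(maf >= threshold, "common", "rare")
    return maf, classes


def regional_sharing(panel, region_of: dict[str, str],
                     exclude: tuple[str, ...] = ()) -> dict[frozenset, int]:
    """Venn-cell counts: for every nonempty region subset, the number of
    sites segregating in exactly those geographic regions.

    ``region_of`` maps population label -> region name; populations listed
    in ``exclude`` are dropped before counting.
    """
    mat = _as_matrix(panel)
    labels = np.asarray(panel.chrom_labels)
    regions = sorted({r for p, r in region_of.items() if p not in exclude})
    seg_by_region = {}
    for reg in regions:
        pops = [p for p, r in region_of.items() if r == reg and p not in exclude]
        rows = np.isin(labels, pops)
        sub = mat[rows]
        dc = sub.sum(axis=0)
        seg_by_region[reg] = (dc > 0) & (dc < sub.shape[0])
    cells: dict[frozenset, int] = {}
    any_seg = np.zeros(mat.shape[1], dtype=bool)
    for reg in regions:
        any_seg |= seg_by_region[reg]
    for subset_mask in range(1, 2 ** len(regions)):
        members = frozenset(r for i, r in enumerate(regions) if subset_mask >> i & 1)
        in_cell = any_seg.copy()
        for reg in regions:
            if reg in members:
                in_cell &= seg_by_region[reg]
            else:
                in_cell &= ~seg_by_region[reg]
        cells[members] = int(np.count_nonzero(in_cell))
    return cells
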