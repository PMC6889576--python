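"""Pairwise linkage disequilibrium (D, D', LOD) from phased haplotypes.

Because the inputs are phased, two-site gamete counts are observed directly
and no EM step over genotypes is needed. D' follows Lewontin's
normalization, and LOD is the log10 likelihood ratio of the multinomial
gamete likelihood at the estimated D versus D = 0 (linkage equilibrium).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["LdPair", "d_prime", "d_prime_from_counts", "ld_matrix"]


@dataclass
class LdPair:
    site_a: int
    site_b: int
    D: float
    D_prime: float
    LOD: float

    @property
    def d_prime_x100(self) -> int:
        """Figure convention: |D'| x 100 rounded to integer."""
        return int(round(self.D_prime * 100))


def d_prime_from_counts(n_AB: int, n_Ab: int, n_aB: int, n_ab: int,
                        pos_a: int = 0, pos_b: int = 0) -> LdPair:
    """D, |D'| and LOD from the four phased gamete counts.

    A/a are the two alleles at the first site and B/b at the second; the
    result is invariant to which allele is labelled which.
    """
    n = n_AB + n_Ab + n_aB + n_ab
    if n == 0:
        raise ValueError("no gametes")
    counts = np.array([n_AB, n_Ab, n_aB, n_ab], dtype=np.float64)
    pA = (n_AB + n_Ab) / n
    pB = (n_AB + n_aB) / n
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise ValueError("monomorphic site in LD pair")
    pAB = n_AB / n
    D = pAB - pA * pB
    if D > 0:
        d_max = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        d_max = min(pA * pB, (1 - pA) * (1 - pB))
    d_prime_val = abs(D) / d_max if d_max > 0 else 0.0
    # likelihood ratio at the MLE (observed frequencies) vs independence
    f_hat = np.array([pAB, pA - pAB, pB - pAB, 1 - pA - pB + pAB])
    f_null = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    nz = counts > 0
    lod = float(np.sum(counts[nz] * (np.log10(f_hat[nz]) - np.log10(f_null[nz]))))
    return LdPair(site_a=pos_a, site_b=pos_b, D=D,
                  D_prime=min(d_prime_val, 1.0), LOD=max(lod, 0.0))


def d_prime(panel, idx_a: int, idx_b: int) -> LdPair:
    """LD between two site columns of a phased panel slice."""
    mat = getattr(panel, "matrix", panel)
    a = np.asarray(mat[:, idx_a])
    b = np.asarray(mat[:, idx_b])
    n_AB = int(np.count_nonzero((a == 1) & (b == 1)))
    n_Ab = int(np.count_nonzero((a == 1) & (b == 0)))
    n_aB = int(np.count_nonzero((a == 0) & (b == 1)))
    n_ab = int(np.count_nonzero((a == 0) & (b == 0)))
    positions = getattr(panel, "positions", None)
    pa = int(positions[idx_a]) if positions is not None else idx_a
    pb = int(positions[idx_b]) if positions is not None else idx_b
    return d_prime_from_counts(n_AB, n_Ab, n_aB, n_ab, pa, pb)


def ld_matrix(panel, window: tuple[int, int] | None = None,
              window2: tuple[int, int] | None = None,
              maf_min: float = 0.01) -> pd.DataFrame:
    """All pairwise LD values within a window (or between two windows).

    Sites with minor allele frequency < ``maf_min`` (default 1%) are
    excluded first.  Returns a long-format frame with columns pos_a, pos_b,
    D, Dprime_x100, LOD; pairs are emitted once with pos_a < pos_b.
    """
    mat = np.asarray(getattr(panel, "matrix", panel))
    positions = np.asarray(getattr(panel, "positions", np.arange(mat.shape[1])))
    n = mat.shape[0]
    freq = mat.sum(axis=0) / n
    maf = np.minimum(freq, 1 - freq)
    keep = maf >= maf_min

    def _in(win):
        return (positions >= win[0]) & (positions <= win[1]) & keep

    if window is None:
        idx_1 = np.nonzero(keep)[0]
    else:
        idx_1 = np.nonzero(_in(window))[0]
    if window2 is not None:
        idx_2 = np.nonzero(_in(window2))[0]
        pairs = [(a, b) for a in idx_1 for b in idx_2 if a != b]
    else:
        pairs = list(combinations(idx_1, 2))
    rows = []
    for a, b in pairs:
        if a > b:
            a, b = b, a
        pair = d_prime(panel if hasattr(panel, "matrix") else mat, a, b)
        rows.append((int(positions[a]), int(positions[b]), pair.D,
                     pair.d_prime_x100, pair.LOD))
    if not rows:
        log.warning("no site pairs left after MAF >= %g filter", maf_min)
    return pd.DataFrame(rows, columns=["pos_a", "pos_b", "D", "Dprime_x100", "LOD"])
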