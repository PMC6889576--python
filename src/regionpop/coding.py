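"""Codon-aware variant classification and the McDonald-Kreitman test.

The M-K test contrasts replacement (nonsynonymous) and silent (synonymous)
variation within a population (polymorphism, P_N / P_S) against fixed
differences from an outgroup (divergence, D_N / D_S); under neutrality the
two ratios are equal, and departures are assessed with Fisher's exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

log = logging.getLogger(__name__)

__all__ = ["MKCounts", "classify_codon_effect", "count_mk", "fisher_exact_2x2"]

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


@dataclass
class MKCounts:
    P_N: int = 0
    P_S: int = 0
    D_N: int = 0
    D_S: int = 0

    def table(self) -> list[list[int]]:
        """[[D_N, D_S], [P_N, P_S]] for the Fisher test."""
        return [[self.D_N, self.D_S], [self.P_N, self.P_S]]


def classify_codon_effect(cds_sequence: str, site_offset: int, alt_base: str) -> str:
    """"synonymous" or "nonsynonymous" for substituting ``alt_base`` at
    0-based CDS position ``site_offset``; other codon positions are held at
    the background (ingroup-major) sequence. Stop gain/loss is nonsynonymous.
    """
    cds = cds_sequence.upper()
    alt = alt_base.upper()
    if not 0 <= site_offset < len(cds):
        raise ValueError("site offset outside the CDS")
    if alt not in "ACGT":
        raise ValueError(f"ambiguous base {alt_base!r}")
    codon_idx = site_offset // 3
    pos = site_offset % 3
    codon = cds[3 * codon_idx: 3 * codon_idx + 3]
    if len(codon) < 3 or any(b not in "ACGT" for b in codon):
        raise ValueError("frame disrupted or ambiguous codon")
    mutated = codon[:pos] + alt + codon[pos + 1:]
    return "synonymous" if CODON_TABLE[codon] == CODON_TABLE[mutated] else "nonsynonymous"


def count_mk(ingroup_cds: np.ndarray | list[str], outgroup_cds: str,
             strict_multihit: bool = False) -> MKCounts:
    """McDonald-Kreitman site counts from aligned coding sequences.

    ``ingroup_cds`` is the population's phased CDS alleles: an array of
    single-character rows (n_chromosomes x cds_length) or a list of equal
    length strings. A site segregating within the ingroup is polymorphic
    (even if it also differs from the outgroup); a site monomorphic in the
    ingroup but different from the outgroup is divergent. Each change is
    classified against the codon background of ingroup-major alleles;
    ``strict_multihit`` instead drops codons carrying more than one change.
    """
    if isinstance(ingroup_cds, (list, tuple)):
        mat = np.array([list(s.upper()) for s in ingroup_cds])
    else:
        mat = np.char.upper(np.asarray(ingroup_cds))
    out = outgroup_cds.upper()
    L = mat.shape[1]
    if L != len(out):
        raise ValueError("outgroup CDS length does not match ingroup")
    if L % 3 != 0:
        raise ValueError("frame disrupted: CDS length not divisible by 3")
    # ingroup-major background
    major = []
    for j in range(L):
        vals, counts = np.unique(mat[:, j], return_counts=True)
        major.append(vals[np.argmax(counts)])
    background = "".join(major)

    events: list[tuple[int, str, str]] = []  # (offset, alt, kind)
    for j in range(L):
        alleles = set(mat[:, j])
        if len(alleles) > 2:
            log.warning("site %d has >2 ingroup alleles; skipped", j)
            continue
        if len(alleles) == 2:
            minor = (alleles - {background[j]}).pop()
            events.append((j, minor, "P"))
        elif out[j] != background[j]:
            if out[j] not in "ACGT":
                continue  # gap or ambiguity in the outgroup: not countable
            events.append((j, out[j], "D"))

    if strict_multihit:
        from collections import Counter
        per_codon = Counter(j // 3 for j, _, _ in events)
        events = [e for e in events if per_codon[e[0] // 3] == 1]

    mk = MKCounts()
    for j, alt, kind in events:
        effect = classify_codon_effect(background, j, alt)
        if kind == "P":
            if effect == "synonymous":
                mk.P_S += 1
            else:
                mk.P_N += 1
        else:
            if effect == "synonymous":
                mk.D_S += 1
            else:
                mk.D_N += 1
    return mk


def fisher_exact_2x2(table, tie_rtol: float = 1e-7) -> float:
    """Two-sided Fisher exact P for a 2x2 count table.

    Sums hypergeometric probabilities of all tables with the observed
    margins whose probability is <= that of the observed table (within
    ``tie_rtol`` relative tolerance for floating-point ties). A table with
    an empty row or column carries no information: P = 1.0 by convention.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of nonnegative integers")
    r1, r2 = t.sum(axis=1)
    c1, c2 = t.sum(axis=0)
    N = int(t.sum())
    if min(r1, r2, c1, c2) == 0:
        log.info("degenerate margin in Fisher table %s; P = 1", t.tolist())
        return 1.0
    # cell (0,0) ranges over the support of Hypergeom(N, r1, c1)
    k_obs = int(t[0, 0])
    kmin = max(0, r1 + c1 - N)
    kmax = min(r1, c1)
    ks = np.arange(kmin, kmax + 1)
    pmf = hypergeom.pmf(ks, N, r1, c1)
    p_obs = pmf[k_obs - kmin]
    return float(min(1.0, pmf[pmf <= p_obs * (1.0 + tie_rtol)].sum()))
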