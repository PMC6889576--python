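"""Haplotype-length selection statistics: EHH, iHS, nSL.

EHH for a core allele class is the probability that two randomly drawn
carrier chromosomes are identical over the interval from the core out to a
given flanking site.  iHS integrates the EHH curves of the ancestral and
derived classes over physical distance (trapezoid rule, truncated where EHH
falls below a cutoff) and takes ln(iHH_A / iHH_D); under a sweep on the
derived allele the derived curve decays slowly, so the score is negative.
nSL replaces physical distance by the number of consecutive segregating
sites over which chromosome pairs are identical, making it insensitive to
local recombination-rate variation.  Unstandardized scores are z-scored
within derived-allele-frequency bins before outlier calling at |score| > 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["EhhCurve", "ehh_curve", "ehh_at", "ihs_unstandardized",
           "nsl_unstandardized", "standardize", "call_outliers", "scan"]


@dataclass
class EhhCurve:
    core_index: int
    allele: int                  # 0 = ancestral class, 1 = derived class
    offsets: np.ndarray          # signed bp offsets from the core, ascending
    values: np.ndarray           # EHH at each offset; EHH(0) = 1


def _homozygosity(groups: np.ndarray, n: int) -> float:
    """sum C(n_h, 2) / C(n, 2) over haplotype-group sizes."""
    _, counts = np.unique(groups, return_counts=True)
    return float(np.sum(counts * (counts - 1)) / (n * (n - 1)))


def _ehh_one_side(mat: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """EHH after extending the haplotype over each successive column."""
    n = mat.shape[0]
    groups = np.zeros(n, dtype=np.int64)
    out = np.empty(cols.size)
    for k, c in enumerate(cols):
        # refine the current partition by the alleles at column c
        groups = groups * 2 + mat[:, c]
        _, groups = np.unique(groups, return_inverse=True)
        out[k] = _homozygosity(groups, n)
    return out


def ehh_curve(panel, core: int, allele: int) -> EhhCurve:
    """EHH decay curve for the carriers of ``allele`` at site index ``core``.

    Values start at 1 at the core and are non-increasing with |offset|,
    computed independently to the left and right.
    """
    mat = np.asarray(getattr(panel, "matrix", panel))
    positions = np.asarray(getattr(panel, "positions", np.arange(mat.shape[1])))
    carriers = mat[:, core] == allele
    n_c = int(carriers.sum())
    if n_c < 2:
        raise ValueError(f"need >= 2 carriers of allele {allele} at the core")
    sub = mat[carriers]
    right = np.arange(core + 1, mat.shape[1])
    left = np.arange(core - 1, -1, -1)
    ehh_r = _ehh_one_side(sub, right)
    ehh_l = _ehh_one_side(sub, left)
    offsets = np.concatenate([(positions[left] - positions[core])[::-1], [0],
                              positions[right] - positions[core]])
    values = np.concatenate([ehh_l[::-1], [1.0], ehh_r])
    return EhhCurve(core_index=core, allele=allele, offsets=offsets, values=values)


def ehh_at(curve: EhhCurve, offset: float) -> float:
    """EHH interpolated at a signed physical offset (step-down between sites)."""
    side = curve.offsets >= 0 if offset >= 0 else curve.offsets <= 0
    off = np.abs(curve.offsets[side])
    val = curve.values[side]
    order = np.argsort(off)
    off, val = off[order], val[order]
    idx = np.searchsorted(off, abs(offset), side="right") - 1
    return float(val[max(idx, 0)])


def _ihh_one_side(offsets: np.ndarray, values: np.ndarray, cutoff: float,
                  max_gap: float, region_span: float) -> tuple[float, bool]:
    """Trapezoid integral of one EHH arm (offsets ascending from 0),
    stopping at the first point below ``cutoff``. Returns (iHH, truncated):
    truncated means the arm hit the region edge, or a gap > max_gap, with
    EHH still above the cutoff."""
    ihh = 0.0
    for k in range(1, offsets.size):
        gap = offsets[k] - offsets[k - 1]
        if gap > max_gap:
            return ihh, True
        ihh += 0.5 * (values[k] + values[k - 1]) * gap
        if values[k] < cutoff:
            return ihh, False
    return ihh, True  # ran out of sites while EHH >= cutoff


def ihs_unstandardized(panel, core: int, ehh_cutoff: float = 0.05,
                       max_gap: float = 200_000.0) -> dict:
    """Unstandardized iHS at one core site.

    Returns a dict with iHH_A, iHH_D, score = ln(iHH_A/iHH_D) and a
    truncated flag (either class's integral cut short by the region edge or
    an inter-site gap larger than ``max_gap``).
    """
    mat = np.asarray(getattr(panel, "matrix", panel))
    positions = np.asarray(getattr(panel, "positions", np.arange(mat.shape[1])))
    span = positions[-1] - positions[0]
    out = {}
    truncated = False
    for allele, key in ((0, "iHH_A"), (1, "iHH_D")):
        curve = ehh_curve(panel, core, allele)
        pos_side = curve.offsets >= 0
        r_off, r_val = curve.offsets[pos_side], curve.values[pos_side]
        l_off = -curve.offsets[~pos_side][::-1]
        l_val = curve.values[~pos_side][::-1]
        l_off = np.concatenate([[0.0], l_off])
        l_val = np.concatenate([[1.0], l_val])
        ihh_r, trunc_r = _ihh_one_side(r_off, r_val, ehh_cutoff, max_gap, span)
        ihh_l, trunc_l = _ihh_one_side(l_off, l_val, ehh_cutoff, max_gap, span)
        out[key] = ihh_r + ihh_l
        truncated |= trunc_r or trunc_l
    out["truncated"] = truncated
    if out["iHH_D"] == 0.0 or out["iHH_A"] == 0.0:
        out["score"] = math.nan
    else:
        out["score"] = math.log(out["iHH_A"] / out["iHH_D"])
    return out


def _mean_shared_length(sub: np.ndarray, core: int) -> float:
    """Mean over chromosome pairs of the number of consecutive sites
    (including the core) over which the pair is identical."""
    n, S = sub.shape
    total = 0.0
    pairs = 0
    for a in range(n - 1):
        diff = sub[a + 1:] != sub[a]  # (n-a-1) x S
        # right: first mismatch at or right of core+1; left: first at or left of core-1
        right = diff[:, core + 1:]
        left = diff[:, :core][:, ::-1]
        if right.shape[1]:
            r_ext = np.where(right.any(axis=1), right.argmax(axis=1),
                             right.shape[1])
        else:
            r_ext = np.zeros(diff.shape[0], dtype=int)
        if left.shape[1]:
            l_ext = np.where(left.any(axis=1), left.argmax(axis=1),
                             left.shape[1])
        else:
            l_ext = np.zeros(diff.shape[0], dtype=int)
        same_core = ~diff[:, core]
        lengths = np.where(same_core, 1 + r_ext + l_ext, 0)
        total += lengths.sum()
        pairs += lengths.size
    return total / pairs


def nsl_unstandardized(panel, core: int) -> dict:
    """Unstandardized nSL at one core site: ln(SL_A / SL_D), where SL is the
    mean pairwise identical-tract length in numbers of segregating sites."""
    mat = np.asarray(getattr(panel, "matrix", panel))
    out = {}
    for allele, key in ((0, "SL_A"), (1, "SL_D")):
        carriers = mat[:, core] == allele
        if carriers.sum() < 2:
            out[key] = math.nan
        else:
            out[key] = _mean_shared_length(mat[carriers], core)
    if any(math.isnan(out[k]) or out[k] == 0.0 for k in ("SL_A", "SL_D")):
        out["score"] = math.nan
    else:
        out["score"] = math.log(out["SL_A"] / out["SL_D"])
    return out


def standardize(scores, freqs, n_bins: int = 100, min_per_bin: int = 20) -> np.ndarray:
    """Z-score unstandardized values within derived-allele-frequency bins.

    Frequencies are cut into ``n_bins`` equal-width bins on [0, 1]; adjacent
    bins are merged left-to-right until each holds >= ``min_per_bin``
    defined scores. Within each merged bin the mean is subtracted and the
    standard deviation divided out; degenerate bins (zero variance) yield
    NaN, as does a panel with fewer defined scores than ``min_per_bin``.
    """
    scores = np.asarray(scores, dtype=np.float64)
    freqs = np.asarray(freqs, dtype=np.float64)
    out = np.full(scores.shape, np.nan)
    defined = ~np.isnan(scores)
    if defined.sum() < 2:
        return out
    raw_bin = np.clip((freqs * n_bins).astype(int), 0, n_bins - 1)
    # merge adjacent raw bins until each merged bin has enough scores
    edges = []  # list of (lo_bin, hi_bin) inclusive
    lo = 0
    count = 0
    occupancy = np.bincount(raw_bin[defined], minlength=n_bins)
    for b in range(n_bins):
        count += occupancy[b]
        if count >= min_per_bin:
            edges.append((lo, b))
            lo = b + 1
            count = 0
    if lo <= n_bins - 1 or count > 0:
        if edges:
            edges[-1] = (edges[-1][0], n_bins - 1)
        else:
            edges.append((0, n_bins - 1))
    for lo_b, hi_b in edges:
        sel = defined & (raw_bin >= lo_b) & (raw_bin <= hi_b)
        if sel.sum() < 2:
            continue
        vals = scores[sel]
        sd = vals.std()
        if sd == 0.0:
            continue
        out[sel] = (vals - vals.mean()) / sd
    return out


def call_outliers(std_scores, positions=None, freqs=None,
                  threshold: float = 2.0) -> pd.DataFrame:
    """Sites with |standardized score| strictly greater than ``threshold``
    (the most extreme ~5% under normality at the default of 2)."""
    std_scores = np.asarray(std_scores, dtype=np.float64)
    flag = np.abs(std_scores) > threshold
    flag &= ~np.isnan(std_scores)
    idx = np.nonzero(flag)[0]
    data = {"index": idx, "score": std_scores[idx]}
    if positions is not None:
        data["position"] = np.asarray(positions)[idx]
    if freqs is not None:
        data["freq_derived"] = np.asarray(freqs)[idx]
    return pd.DataFrame(data)


def scan(panel, stat: str = "ihs", maf_min: float = 0.05,
         ehh_cutoff: float = 0.05, max_gap: float = 200_000.0,
         n_bins: int = 100, keep_truncated: bool = False,
         standardized: bool = True) -> pd.DataFrame:
    """Genome/region scan: unstandardized iHS or nSL at every eligible core.

    Cores must be polarized (the panel's matrix must encode derived = 1) and
    have derived frequency within [maf_min, 1 - maf_min].  Truncated cores
    are dropped unless ``keep_truncated``.
    """
    mat = np.asarray(getattr(panel, "matrix", panel))
    positions = np.asarray(getattr(panel, "positions", np.arange(mat.shape[1])))
    n = mat.shape[0]
    freqs = mat.sum(axis=0) / n
    rows = []
    for core in range(mat.shape[1]):
        f = freqs[core]
        if not maf_min <= f <= 1.0 - maf_min:
            continue
        dc = int(round(f * n))
        if min(dc, n - dc) < 2:
            continue  # a class with < 2 carriers has no EHH curve
        if stat == "ihs":
            res = ihs_unstandardized(panel, core, ehh_cutoff, max_gap)
            truncated = res["truncated"]
        elif stat == "nsl":
            res = nsl_unstandardized(panel, core)
            truncated = False
        else:
            raise ValueError("stat must be 'ihs' or 'nsl'")
        rows.append((int(positions[core]), f, res["score"], truncated))
    df = pd.DataFrame(rows, columns=["position", "freq_derived", "unstd", "truncated"])
    if not keep_truncated and len(df):
        df.loc[df["truncated"], "unstd"] = np.nan
    if standardized and len(df):
        df["std"] = standardize(df["unstd"].to_numpy(),
                                df["freq_derived"].to_numpy(), n_bins=n_bins)
        df["outlier"] = np.abs(df["std"]) > 2.0
        df.loc[df["std"].isna(), "outlier"] = False
    return df
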