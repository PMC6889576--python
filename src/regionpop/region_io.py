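"""Panel ingestion: phased VCF, ancestral/archaic FASTA, gene models.

The central container is the :class:`HaplotypePanel`: a chromosomes x sites
binary matrix over bi-allelic SNPs (1 = derived at polarized sites, else
1 = alt), with per-chromosome population labels.  File interfaces follow
the VCF/GFF convention (1-based, closed intervals); interval arithmetic
inside the gene model is 0-based half-open.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "GenomicRegion", "GeneModel", "Site", "HaplotypePanel", "ArchaicPanel",
    "read_vcf_region", "write_vcf", "polarize", "classify_sites",
    "share_with_archaic", "load_sample_map", "load_gene_model_tsv",
    "load_fasta", "write_fasta",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


@dataclass(frozen=True)
class GenomicRegion:
    """1-based closed genomic interval (VCF convention)."""

    chrom: str
    start: int
    end: int
    assembly: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("region start must be <= end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @classmethod
    def parse(cls, text: str, assembly: str = "") -> "GenomicRegion":
        m = re.fullmatch(r"([^:]+):([\d,]+)-([\d,]+)", text)
        if not m:
            raise ValueError(f"cannot parse region {text!r}")
        return cls(m.group(1), int(m.group(2).replace(",", "")),
                   int(m.group(3).replace(",", "")), assembly)


@dataclass(frozen=True)
class GeneModel:
    """Exon/CDS structure of a single gene.

    ``exons``: genomic intervals, 0-based half-open, in transcription order;
    ``cds``: same for coding intervals. ``strand`` is '+' or '-'.
    """

    chrom: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]
    strand: str = "+"

    def __post_init__(self):
        for ivs in (self.exons, self.cds):
            genomic = sorted(ivs)
            if any(b0 < a1 for (a0, a1), (b0, b1) in zip(genomic, genomic[1:])):
                raise ValueError("overlapping intervals in gene model")
        if self.cds_length % 3 != 0:
            raise ValueError("CDS length must be divisible by 3")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def span(self) -> tuple[int, int]:
        ivs = sorted(self.exons)
        return ivs[0][0], ivs[-1][1]

    def cds_offset(self, pos0: int) -> int | None:
        """0-based offset within the coding sequence of genomic pos0,
        or None outside the CDS (strand-aware)."""
        if not any(s <= pos0 < e for s, e in self.cds):
            return None
        ordered = sorted(self.cds, reverse=(self.strand == "-"))
        off = 0
        for s, e in ordered:
            if s <= pos0 < e:
                return off + (pos0 - s if self.strand == "+" else e - 1 - pos0)
            off += e - s
        return None


@dataclass
class Site:
    position: int                # 1-based genomic position
    ref_allele: str
    alt_allele: str
    ancestral_allele: str | None = None
    derived_is_alt: bool = True
    polarized: bool = False
    region_class: str = "unclassified"
    coding_effect: str = "unknown"
    cds_offset: int | None = None
    rsid: str | None = None

    @property
    def derived_allele(self) -> str:
        return self.alt_allele if self.derived_is_alt else self.ref_allele


@dataclass
class HaplotypePanel:
    """Phased binary haplotype matrix with site and population metadata."""

    region: GenomicRegion
    sites: list[Site]
    matrix: np.ndarray                 # uint8, n_chromosomes x n_sites
    chrom_labels: np.ndarray           # population per chromosome
    samples: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.sites):
            raise ValueError("matrix shape does not match sites")
        if len(self.chrom_labels) != self.matrix.shape[0]:
            raise ValueError("one population label per chromosome required")
        pos = self.positions
        if np.any(np.diff(pos) <= 0):
            raise ValueError("site positions must be strictly increasing")
        if self.matrix.size and self.matrix.max() > 1:
            raise ValueError("matrix entries must be 0/1")

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.sites])

    @property
    def polarized(self) -> np.ndarray:
        return np.array([s.polarized for s in self.sites])

    @property
    def n_chromosomes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    @property
    def populations(self) -> list[str]:
        seen = dict.fromkeys(self.chrom_labels.tolist())
        return list(seen)

    def restrict(self, population: str | None = None,
                 interval: tuple[int, int] | None = None) -> "HaplotypePanel":
        """Sub-panel for one population and/or a 1-based closed interval."""
        rows = slice(None) if population is None else \
            np.asarray(self.chrom_labels) == population
        if interval is None:
            cols = np.ones(self.n_sites, dtype=bool)
        else:
            pos = self.positions
            cols = (pos >= interval[0]) & (pos <= interval[1])
        import copy
        return HaplotypePanel(
            region=self.region,
            sites=[copy.copy(s) for s, k in zip(self.sites, cols) if k],
            matrix=self.matrix[rows][:, cols],
            chrom_labels=np.asarray(self.chrom_labels)[rows],
            samples=self.samples,
        )


@dataclass
class ArchaicPanel:
    """Observed alleles for archaic sources at (a subset of) panel positions."""

    positions: np.ndarray
    alleles: dict[str, list[str | None]]   # source -> allele per position

    def allele_at(self, source: str, position: int) -> str | None:
        idx = np.nonzero(self.positions == position)[0]
        if idx.size == 0:
            return None
        return self.alleles[source][int(idx[0])]


# ---------------------------------------------------------------------------
# readers / writers


def load_sample_map(path) -> dict[str, str]:
    """TSV with columns sample, population -> mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if "sample" not in cols or "population" not in cols:
        df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"],
                         dtype=str)
    return dict(zip(df["sample"], df["population"]))


def read_vcf_region(path, region: GenomicRegion, sample_map: dict[str, str],
                    strict: bool = False) -> HaplotypePanel:
    """Phased bi-allelic SNPs from a VCF for the samples in ``sample_map``.

    Multi-allelic records, indels, and sites with any unphased or missing
    genotype among the selected samples are dropped (with a logged count);
    in ``strict`` mode an unphased genotype raises instead.  The INFO "AA"
    tag, when present, is stored as the site's ancestral allele (the panel
    is NOT polarized until :func:`polarize` is called).
    """
    from cyvcf2 import VCF

    want = list(sample_map)
    vcf = VCF(str(path), samples=want)
    got = set(vcf.samples)
    missing = [s for s in want if s not in got]
    if missing:
        raise ValueError(f"samples not found in VCF: {', '.join(missing)}")
    samples = list(vcf.samples)
    sites: list[Site] = []
    columns: list[np.ndarray] = []
    n_dropped = {"multiallelic_or_indel": 0, "unphased_or_missing": 0}
    try:
        records = list(vcf(str(region)))  # fast path: tabix-indexed file
    except Exception:
        records = [v for v in VCF(str(path), samples=want)
                   if v.CHROM == region.chrom
                   and region.start <= v.POS <= region.end]
    for v in records:
        if len(v.ALT) != 1 or not v.is_snp:
            n_dropped["multiallelic_or_indel"] += 1
            continue
        gts = v.genotypes  # [allele_a, allele_b, phased] per sample
        ok = all(len(g) == 3 and g[2] and g[0] >= 0 and g[1] >= 0 for g in gts)
        if not ok:
            if strict:
                raise ValueError(f"unphased or missing genotype at {v.POS}")
            n_dropped["unphased_or_missing"] += 1
            continue
        col = np.fromiter((g[i] for g in gts for i in (0, 1)), dtype=np.uint8)
        aa = v.INFO.get("AA")
        if isinstance(aa, str):
            aa = aa.split("|")[0].strip().upper() or None
            if aa is not None and aa not in "ACGT":
                aa = None
        sites.append(Site(position=v.POS, ref_allele=v.REF.upper(),
                          alt_allele=v.ALT[0].upper(), ancestral_allele=aa,
                          rsid=v.ID))
        columns.append(col)
    for reason, count in n_dropped.items():
        if count:
            log.info("dropped %d sites (%s)", count, reason)
    matrix = np.column_stack(columns) if columns else \
        np.empty((2 * len(samples), 0), dtype=np.uint8)
    labels = np.repeat([sample_map[s] for s in samples], 2)
    return HaplotypePanel(region=region, sites=sites, matrix=matrix,
                          chrom_labels=labels, samples=samples)


def write_vcf(panel: HaplotypePanel, path) -> None:
    """Phased VCF 4.2 with the panel's genotypes; AA is written when known.

    The matrix is emitted in ref/alt orientation regardless of polarization,
    so read_vcf_region . write_vcf is the identity on the stored alleles.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"##contig=<ID={panel.region.chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.samples) + "\n")
        for j, site in enumerate(panel.sites):
            col = panel.matrix[:, j]
            if site.polarized and not site.derived_is_alt:
                col = 1 - col  # back to 1 = alt
            info = f"AA={site.ancestral_allele}" if site.ancestral_allele else "."
            gts = "\t".join(f"{col[2*i]}|{col[2*i+1]}"
                            for i in range(len(panel.samples)))
            fh.write(f"{panel.region.chrom}\t{site.position}\t{site.rsid or '.'}\t"
                     f"{site.ref_allele}\t{site.alt_allele}\t.\t.\t{info}\tGT\t{gts}\n")


def load_fasta(path) -> dict[str, str]:
    """Plain FASTA -> {name: sequence}; headers may carry a 'chr:start-end'
    region tag used by :func:`polarize` to anchor coordinates."""
    seqs: dict[str, str] = {}
    name = None
    parts: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(parts)
                name = line[1:].split()[0]
                parts = []
            elif line:
                parts.append(line)
    if name is not None:
        seqs[name] = "".join(parts)
    return seqs


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _ancestral_lookup(source, panel: HaplotypePanel):
    """Build position -> ancestral base from a FASTA path/dict, a mapping,
    or the string 'AA' (use the stored INFO tag)."""
    if source == "AA":
        return {s.position: s.ancestral_allele for s in panel.sites
                if s.ancestral_allele}
    if isinstance(source, dict) and all(isinstance(k, int) for k in source):
        return {int(k): str(v).upper() for k, v in source.items()}
    seqs = source if isinstance(source, dict) else load_fasta(source)
    # find a record anchored to the panel's region
    for name, seq in seqs.items():
        m = re.fullmatch(r"([^:]+):(\d+)-(\d+)", name)
        if m and m.group(1) == panel.region.chrom:
            offset = int(m.group(2))
            return {p: seq[p - offset].upper()
                    for p in panel.positions if 0 <= p - offset < len(seq)}
        if name == panel.region.chrom:
            return {p: seq[p - 1].upper()
                    for p in panel.positions if p - 1 < len(seq)}
    raise ValueError("no FASTA record matches the panel's chromosome")


def polarize(panel: HaplotypePanel, ancestral_source) -> HaplotypePanel:
    """Orient the panel so matrix 1 = derived allele.

    ``ancestral_source``: FASTA path (record named 'chrom' or
    'chrom:start-end'), a {position: base} mapping, or "AA" to use the VCF
    INFO tag.  Where the ancestral base (case-insensitive) matches neither
    ref nor alt, or is not A/C/G/T, the site is flagged unpolarized and its
    column left in ref/alt orientation.  Calling polarize twice with the
    same source is idempotent.
    """
    lookup = _ancestral_lookup(ancestral_source, panel)
    matrix = panel.matrix.copy()
    sites = []
    n_unpolarized = 0
    for j, s in enumerate(panel.sites):
        anc = lookup.get(s.position)
        anc = anc.upper() if isinstance(anc, str) else None
        if anc not in ("A", "C", "G", "T"):
            anc = None
        new = replace_site(s)
        if anc == s.ref_allele:
            want_alt_is_derived = True
        elif anc == s.alt_allele:
            want_alt_is_derived = False
        else:
            new.polarized = False
            new.derived_is_alt = True
            if s.polarized and not s.derived_is_alt:
                matrix[:, j] = 1 - matrix[:, j]
            new.ancestral_allele = anc
            n_unpolarized += 1
            sites.append(new)
            continue
        currently_alt = s.derived_is_alt  # matrix 1 currently means this allele
        if currently_alt != want_alt_is_derived:
            matrix[:, j] = 1 - matrix[:, j]
        new.polarized = True
        new.derived_is_alt = want_alt_is_derived
        new.ancestral_allele = anc
        sites.append(new)
    if n_unpolarized:
        log.info("%d sites could not be polarized", n_unpolarized)
    return HaplotypePanel(region=panel.region, sites=sites, matrix=matrix,
                          chrom_labels=panel.chrom_labels, samples=panel.samples)


def replace_site(s: Site) -> Site:
    import copy
    return copy.copy(s)


def classify_sites(panel: HaplotypePanel, gene: GeneModel,
                   cds_sequence: str | None = None) -> HaplotypePanel:
    """Assign every site a region class and, within the CDS, a codon effect.

    Classes: "CDS", "intron", "UTR/non-coding-exon" (exonic outside the
    CDS), "upstream/intergenic" (outside the gene span).  ``cds_sequence``
    is the sense-strand coding sequence used to translate codons; without it
    CDS sites keep coding_effect "unknown".
    """
    from . import coding

    if cds_sequence is not None and len(cds_sequence) != gene.cds_length:
        raise ValueError("cds_sequence length does not match gene model")
    span = gene.span
    sites = []
    for s in panel.sites:
        new = replace_site(s)
        p0 = s.position - 1
        off = gene.cds_offset(p0)
        if off is not None:
            new.region_class = "CDS"
            new.cds_offset = off
            if cds_sequence is not None:
                alt = s.alt_allele
                if gene.strand == "-":
                    alt = alt.translate(_COMPLEMENT).upper()
                new.coding_effect = coding.classify_codon_effect(
                    cds_sequence, off, alt)
            else:
                new.coding_effect = "unknown"
        elif any(a <= p0 < b for a, b in gene.exons):
            new.region_class = "UTR/non-coding-exon"
            new.coding_effect = "not-coding"
        elif span[0] <= p0 < span[1]:
            new.region_class = "intron"
            new.coding_effect = "not-coding"
        else:
            new.region_class = "upstream/intergenic"
            new.coding_effect = "not-coding"
        sites.append(new)
    return HaplotypePanel(region=panel.region, sites=sites, matrix=panel.matrix,
                          chrom_labels=panel.chrom_labels, samples=panel.samples)


def load_gene_model_tsv(path) -> GeneModel:
    """BED-like TSV (chrom, start, end, feature in {exon, CDS}, strand),
    1-based closed coordinates in the file."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "feature", "strand"])
    exons, cds = [], []
    strand = "+"
    chrom = str(df["chrom"].iloc[0])
    for _, row in df.iterrows():
        iv = (int(row["start"]) - 1, int(row["end"]))  # to 0-based half-open
        strand = str(row["strand"])
        if str(row["feature"]).lower() == "exon":
            exons.append(iv)
        elif str(row["feature"]).upper() == "CDS":
            cds.append(iv)
    reverse = strand == "-"
    return GeneModel(chrom=chrom, exons=tuple(sorted(exons, reverse=reverse)),
                     cds=tuple(sorted(cds, reverse=reverse)), strand=strand)


def share_with_archaic(panel: HaplotypePanel, archaic: ArchaicPanel) -> pd.DataFrame:
    """Per-site sharing of the modern derived allele with each archaic source.

    shared_derived is True when the archaic carries the derived allele,
    False when it carries a different base, and None (unknown) when the
    archaic has no data at the site or the site is unpolarized.
    """
    rows = []
    for s in panel.sites:
        row = {"position": s.position, "derived_allele":
               s.derived_allele if s.polarized else None}
        for source in archaic.alleles:
            if not s.polarized:
                row[source] = None
                continue
            allele = archaic.allele_at(source, s.position)
            if allele is None or allele.upper() not in "ACGT":
                row[source] = None
            else:
                row[source] = allele.upper() == s.derived_allele
        rows.append(row)
    return pd.DataFrame(rows)
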