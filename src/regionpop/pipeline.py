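"""End-to-end orchestration: VCF -> per-population report directory.

``run_report`` chains the stages (ingest, polarize, classify, diversity
summaries with demographic-null p-values, LD, scans, FST, haplotype
network, allele ages) and emits deterministic TSV reports.  Every number it
writes is computed by the stage functions; the pipeline adds no math of its
own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coalsim, diversity, fst as fst_mod, ld as ld_mod, mjnet, sweep
from .region_io import (GenomicRegion, load_gene_model_tsv, load_sample_map,
                        polarize, read_vcf_region, classify_sites)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "validate_config", "run_report"]


@dataclass
class RunConfig:
    vcf: str
    region: str
    samples: str
    out_dir: str
    ancestral: str | None = None       # FASTA path or "AA"
    gene_model: str | None = None
    scenarios: list[str] = field(default_factory=lambda: ["constant"])
    groups: dict[str, str] = field(default_factory=dict)
    reps: int = 1000
    seed: int = 0
    maf_ld: float = 0.01
    maf_scan: float = 0.05
    outlier_threshold: float = 2.0
    age_reps: int = 2000
    run_ld: bool = True
    run_scan: bool = True
    run_network: bool = True
    run_ages: bool = True

    def region_obj(self) -> GenomicRegion:
        return GenomicRegion.parse(self.region)


_REQUIRED = ("vcf", "region", "samples", "out_dir")


def validate_config(source) -> tuple[RunConfig | None, list[str]]:
    """Parse a YAML path or dict into a RunConfig, collecting ALL errors.

    Unknown keys produce warnings in the returned list (prefixed
    "warning:"); missing required keys or invalid values are errors and
    yield config None.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(source)
    problems: list[str] = []
    known = set(RunConfig.__dataclass_fields__)
    for key in data:
        if key not in known:
            problems.append(f"warning: unknown key {key!r}")
    for key in _REQUIRED:
        if key not in data:
            problems.append(f"missing required key {key!r}")
    filtered = {k: v for k, v in data.items() if k in known}
    if any(not p.startswith("warning:") for p in problems):
        return None, problems
    cfg = RunConfig(**filtered)
    try:
        cfg.region_obj()
    except ValueError as exc:
        problems.append(f"bad region: {exc}")
    for key in ("vcf", "samples"):
        if not Path(getattr(cfg, key)).exists():
            problems.append(f"file for {key!r} does not exist: {getattr(cfg, key)}")
    for name in cfg.scenarios:
        if name not in coalsim.SCENARIOS:
            problems.append(f"unknown scenario {name!r}")
    if any(not p.startswith("warning:") for p in problems):
        return None, problems
    return cfg, problems


def _pop_pvalues(panel_pop, summary, scenarios, reps, rng):
    """Lower-tail D and H p-values under each scenario, with theta set from
    the population's observed region theta_W (counts scale)."""
    out = {}
    theta = max(summary.thetaw_counts, 1e-3)
    for name in scenarios:
        model = coalsim.scenario_model(name)
        for stat, obs in (("D", summary.D_T), ("H", summary.H)):
            key = f"P_{stat}_{name}"
            if np.isnan(obs):
                out[key] = np.nan
                continue
            out[key] = coalsim.null_pvalue(obs, stat, summary.n, theta, model,
                                           reps=reps, tail="lower", seed=rng)
    return out


def run_report(config: RunConfig) -> Path:
    """Run the full analysis; returns the output directory.

    Any stage failure aborts with the stage name; files created by the
    failed run are removed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    rng = np.random.default_rng(config.seed)
    stage = "setup"

    def _emit(df: pd.DataFrame, rel: str):
        path = out / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        created.append(path)

    try:
        stage = "ingest"
        region = config.region_obj()
        sample_map = load_sample_map(config.samples)
        panel = read_vcf_region(config.vcf, region, sample_map)
        if config.ancestral:
            panel = polarize(panel, config.ancestral)
        if config.gene_model:
            panel = classify_sites(panel, load_gene_model_tsv(config.gene_model))
        pops = panel.populations
        L = region.length

        stage = "diversity"
        rows = []
        for pop in pops:
            sub = panel.restrict(population=pop)
            summary = diversity.sfs_summary(sub, L=L)
            spectrum = diversity.haplotype_spectrum(sub)
            row = {"population": pop, "2N": summary.n, "S": summary.S,
                   "singletons": summary.singletons, "h": spectrum.h,
                   "h_diversity": spectrum.h_diversity,
                   "theta_pi": summary.theta_pi_per_site,
                   "theta_w": summary.theta_w_per_site,
                   "D_T": summary.D_T, "H": summary.H}
            row.update(_pop_pvalues(sub, summary, config.scenarios,
                                    config.reps, rng))
            rows.append(row)
        _emit(pd.DataFrame(rows), "table1.tsv")

        stage = "sites"
        site_rows = []
        n_all = panel.n_chromosomes
        maf, maf_class = diversity.classify_maf(panel)
        fst_vals = None
        if config.groups:
            fst_vals, _ = fst_mod.fst_by_site(panel, config.groups)
        for j, s in enumerate(panel.sites):
            row = {"position": s.position, "ref": s.ref_allele,
                   "alt": s.alt_allele, "ancestral": s.ancestral_allele or ".",
                   "polarized": s.polarized, "region_class": s.region_class,
                   "coding_effect": s.coding_effect,
                   "maf_pooled": maf[j], "maf_class": maf_class[j]}
            for pop in pops:
                sel = np.asarray(panel.chrom_labels) == pop
                row[f"freq_{pop}"] = float(panel.matrix[sel, j].mean())
            if fst_vals is not None:
                row["fst"] = fst_vals[j]
            site_rows.append(row)
        _emit(pd.DataFrame(site_rows), "sites.tsv")

        stage = "haplotypes"
        spectrum = diversity.haplotype_spectrum(panel)
        _emit(pd.DataFrame({"haplotype": spectrum.haplotypes,
                            "count": spectrum.counts}), "haplotypes.tsv")

        if config.run_ld:
            stage = "ld"
            for pop in pops:
                sub = panel.restrict(population=pop)
                _emit(ld_mod.ld_matrix(sub, maf_min=config.maf_ld),
                      f"ld/{pop}.tsv")

        if config.run_scan:
            stage = "scan"
            for pop in pops:
                sub = panel.restrict(population=pop)
                for stat in ("ihs", "nsl"):
                    df = sweep.scan(sub, stat=stat, maf_min=config.maf_scan)
                    _emit(df, f"scan/{pop}_{stat}.tsv")

        if config.groups:
            stage = "fst"
            _, comps = fst_mod.fst_by_site(panel, config.groups)
            summary = fst_mod.wc_fst_mean(comps)
            _emit(pd.DataFrame([summary]), "fst_summary.tsv")

        if config.run_network:
            stage = "network"
            groups = {pop: (np.asarray(
                [np.count_nonzero((np.asarray(panel.chrom_labels) == pop)
                                  & (np.all(panel.matrix ==
                                            np.array([int(c) for c in h],
                                                     dtype=np.uint8), axis=1)))
                 for h in spectrum.haplotypes]))
                for pop in pops}
            net = mjnet.median_joining(spectrum.haplotypes,
                                       counts=spectrum.counts, groups=None)
            report = mjnet.cluster_report(net)
            nodes = report["nodes"]
            for pop in pops:
                nodes[f"count_{pop}"] = [groups[pop][spectrum.haplotypes.index(h)]
                                         if h in spectrum.haplotypes else 0
                                         for h in net.haplotypes]
            _emit(nodes, "network/nodes.tsv")
            _emit(pd.DataFrame(
                [{"node_a": a, "node_b": b,
                  "sites": ",".join(map(str, d))} for a, b, d in net.edges]),
                "network/edges.tsv")

        if config.run_ages:
            stage = "ages"
            age_rows = []
            model = coalsim.scenario_model(config.scenarios[0]) \
                if config.scenarios else coalsim.DemographicModel.constant(10_000)
            n = panel.n_chromosomes
            dc = panel.matrix.sum(axis=0)
            age_cache: dict[int, tuple[float, float]] = {}
            for j, s in enumerate(panel.sites):
                if not s.polarized or not 0 < dc[j] < n:
                    continue
                i = int(dc[j])
                if i not in age_cache:
                    age_cache[i] = coalsim.allele_age_mc(
                        i, n, model, reps=config.age_reps, seed=rng)
                mean, sd = age_cache[i]
                age_rows.append({"position": s.position, "derived_count": i,
                                 "age_years": mean, "age_sd_years": sd})
            _emit(pd.DataFrame(age_rows), "ages.tsv")

        stage = "log"
        import regionpop
        with open(out / "run.log", "w") as fh:
            fh.write(f"regionpop {regionpop.__version__}\n")
            fh.write(f"seed {config.seed}\n")
            fh.write(f"region {config.region}\n")
            fh.write(f"n_chromosomes {panel.n_chromosomes}\n")
            fh.write(f"n_sites {panel.n_sites}\n")
        created.append(out / "run.log")
    except Exception as exc:
        for path in created:
            if path.exists():
                path.unlink()
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
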