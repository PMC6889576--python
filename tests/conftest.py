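import numpy as np
import pytest

from regionpop import synthetic
from regionpop.region_io import GenomicRegion, HaplotypePanel, Site


def make_panel(matrix, positions=None, pops=None, polarized=True,
               region=None) -> HaplotypePanel:
    """Hand-rolled panel from a binary matrix for unit tests."""
    matrix = np.asarray(matrix, dtype=np.uint8)
    n, S = matrix.shape
    if positions is None:
        positions = 100 * (np.arange(S) + 1)
    region = region or GenomicRegion("chrT", 1, int(max(positions)) + 100)
    sites = [Site(position=int(p), ref_allele="A", alt_allele="G",
                  ancestral_allele="A", derived_is_alt=True,
                  polarized=polarized) for p in positions]
    if pops is None:
        pops = np.repeat("P1", n)
    samples = [f"S{i}" for i in range(n // 2)] if n % 2 == 0 else []
    return HaplotypePanel(region=region, sites=sites, matrix=matrix,
                          chrom_labels=np.asarray(pops), samples=samples)


@pytest.fixture(scope="session")
def neutral_fixture_dir(tmp_path_factory):
    """A seeded neutral panel written out as VCF + ancestral FASTA."""
    out = tmp_path_factory.mktemp("neutral_fix")
    panel, truth = synthetic.make_neutral_region(
        20, 5.0, "constant", L=10_000, seed=7, out_dir=out)
    return out, panel, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
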