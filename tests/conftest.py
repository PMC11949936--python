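import pytest

from tilescreen import (
    GenomicInterval,
    GuideLibrary,
    SgRNA,
    annotate_exonic,
    apply_design_filters,
    scan_protospacers,
)
from tilescreen.synthetic_data import ScreenSimParams, simulate_region


def make_guide(guide_id, cut_site, strand="+", chrom="chrS", spacer=None, exonic=False):
    """Hand-construct a consistent SgRNA from its cut site."""
    start = cut_site - (17 if strand == "+" else 3)
    return SgRNA(
        guide_id=guide_id,
        spacer=spacer or "ACGTACGTACGTACGTACGT",
        pam="AGG",
        chrom=chrom,
        spacer_start=start,
        spacer_end=start + 20,
        strand=strand,
        cut_site=cut_site,
        exonic=exonic,
    )


@pytest.fixture
def toy_library():
    """Three guides with distinct spacers at cut sites 100, 125, 300."""
    guides = [
        make_guide("sg-0001", 100, spacer="ACGTACGTACGTACGTACGT"),
        make_guide("sg-0002", 125, strand="-", spacer="TTGCATGCATGCATGCATGC"),
        make_guide("sg-0003", 300, spacer="GGCCGGCCGGCCGGCCGGCC", exonic=True),
    ]
    return GuideLibrary(
        guides=guides, target_interval=GenomicInterval("chrS", 0, 1000)
    )


@pytest.fixture(scope="session")
def sim_params():
    return ScreenSimParams(seed=1)


@pytest.fixture(scope="session")
def sim_region(sim_params):
    return simulate_region(sim_params)


@pytest.fixture(scope="session")
def designed_library(sim_params, sim_region):
    """Default-pipeline library on the seed-1 synthetic region."""
    lib = scan_protospacers(sim_region.sequence, sim_region.interval)
    lib = apply_design_filters(lib)
    return annotate_exonic(lib, sim_region.annotation)
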