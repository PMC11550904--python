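import numpy as np
import pytest
from hypothesis import settings

from macall.io_formats import SiteCounts, SiteTable
from macall.site_model import SiteEstimate

settings.register_profile("reproducible", derandomize=True)
settings.load_profile("reproducible")


def make_site(counts, ref="A", scaffold="s1", position=1):
    """SiteCounts from a list of (nA, nC, nG, nT) tuples."""
    return SiteCounts(scaffold, position, ref, tuple(tuple(c) for c in counts))


def make_estimate(
    major="A",
    minor="C",
    eps=0.001,
    freqs=(0.9, 0.05, 0.05),
    lrt=0.0,
    p=1.0,
):
    return SiteEstimate(
        major_nt=major,
        minor_nt=minor,
        eps_hat=eps,
        geno_freqs=freqs,
        loglik_full=0.0,
        loglik_mono=0.0,
        lrt_stat=lrt,
        polymorphic_p=p,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_mutation_table():
    """14-line table: one clean het mutation, one shared site, clean rest.

    Site 1: line L01 heterozygous A/C (the candidate); all others
    homozygous A.  Site 2: two lines carry the same variant (must be
    discarded by exclusivity).  Site 3: monomorphic reference.
    """
    hom = (12, 0, 0, 0)
    het = (6, 6, 0, 0)
    site1 = [het] + [hom] * 13
    site2 = [het, het] + [hom] * 12
    site3 = [hom] * 14
    sites = [
        make_site(site1, ref="A", position=101),
        make_site(site2, ref="A", position=202),
        make_site(site3, ref="A", position=303),
    ]
    return SiteTable.from_sites(sites)
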