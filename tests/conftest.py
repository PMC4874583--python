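import numpy as np
import pytest

from cisgraph.types import IntegrationSite, TranscriptionalElement


def make_sites(positions, chrom="chr1", labels=None, row_offset=0):
    """Sorted IntegrationSite list from bare positions (single chromosome)."""
    labels = labels or ["lab"] * len(positions)
    sites = [IntegrationSite(chrom, int(p), str(l), row_offset + i)
             for i, (p, l) in enumerate(zip(positions, labels))]
    return sorted(sites, key=lambda s: s.sort_key)


def make_tes(entries, chrom="chr1"):
    """TranscriptionalElement list from (tss, name) pairs."""
    tes = [TranscriptionalElement(chrom, int(t), str(n)) for t, n in entries]
    return sorted(tes, key=lambda t: t.sort_key)


@pytest.fixture
def rng():
    return np.random.default_rng(20150)


@pytest.fixture
def chain_sites():
    """The chaining fixture: consecutive gaps of 900 bp, total span 2700 bp.

    With threshold 1000 the graph caller chains all four into one CIS even
    though the extremes are 2700 bp apart; a rigid 1000-bp window can hold
    at most two consecutive sites.
    """
    return make_sites([0 + 1, 900 + 1, 1800 + 1, 2700 + 1])
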