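"""Gene atmosphere: linking integration sites to nearby transcription starts.

The annotation graph is bipartite: IS nodes on one side, transcriptional
elements (TEs, reduced to their TSS point) on the other, with a link whenever
the same-chromosome distance is below the annotation threshold. Distances are
measured to the TSS only, never to gene bodies, and strand is ignored —
regulatory influence of an insertion is taken as symmetric around the start
site at this resolution. Aggregating the links of a CIS's members gives its
gene atmosphere: the candidate target genes of that hotspot.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from collections import defaultdict
from typing import Sequence

from .exceptions import ParameterError
from .types import CIS, GALink, GeneAtmosphere, IntegrationSite, \
    TranscriptionalElement


def link_is_to_te(
    sites: Sequence[IntegrationSite],
    tes: Sequence[TranscriptionalElement],
    ga_threshold: int,
    inclusive: bool = False,
) -> list[GALink]:
    """All same-chromosome (IS, TE) pairs with |pos - tss| below the
    threshold, by sweep over the two sorted lists.

    An IS may link zero, one or many TEs and a TE may serve many IS; the
    result is sorted by (site order, tss, name) and deterministic.
    """
    if ga_threshold < 1:
        raise ParameterError(f"ga_threshold must be >= 1, got {ga_threshold}")
    by_chrom: dict[str, list[TranscriptionalElement]] = defaultdict(list)
    for te in tes:
        by_chrom[te.chrom].append(te)
    tss_index = {c: [t.tss for t in lst] for c, lst in by_chrom.items()}

    links: list[GALink] = []
    for s in sites:
        lst = by_chrom.get(s.chrom)
        if not lst:
            continue
        tss = tss_index[s.chrom]
        if inclusive:
            lo = bisect_left(tss, s.pos - ga_threshold)
            hi = bisect_right(tss, s.pos + ga_threshold)
        else:
            lo = bisect_right(tss, s.pos - ga_threshold)
            hi = bisect_left(tss, s.pos + ga_threshold)
        for te in lst[lo:hi]:
            links.append(GALink(site=s, te=te, distance=abs(s.pos - te.tss)))
    return links


def build_gene_atmosphere(cis_list: Sequence[CIS],
                          links: Sequence[GALink]) -> list[GeneAtmosphere]:
    """Gather each CIS's member links into a per-CIS atmosphere.

    A CIS with no nearby TE yields an empty atmosphere, retained in the
    output rather than dropped — "no annotated neighbour" is a result.
    """
    by_row: dict[int, list[GALink]] = defaultdict(list)
    for ln in links:
        by_row[ln.site.row_id].append(ln)
    out = []
    for cis in cis_list:
        cis_links = [ln for m in cis.members for ln in by_row.get(m.row_id, [])]
        out.append(GeneAtmosphere(cis_ref=cis.name, links=cis_links))
    return out


def dataset_gene_set(ga_list: Sequence[GeneAtmosphere]) -> list[str]:
    """Sorted union of gene names over all atmospheres — the dataset-level
    candidate gene collection."""
    return sorted(set().union(*[set(ga.genes) for ga in ga_list])) \
        if ga_list else []
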