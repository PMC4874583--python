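"""Standard window method (SWM) baseline, next-gene assignment and
gene-set comparison.

The SWM calls a CIS wherever at least k sites fall inside a fixed window of
w_k bp, with wider windows licensed for higher orders. Implemented as a
deterministic greedy left-to-right scan per chromosome: at each unconsumed
site, every rule is tested for a window starting there; the qualifying
window capturing the most sites is reported and the scan advances past it.
Because windows are rigid, a chain of sites each within threshold of the
next can be split into several SWM calls where the graph-based caller
returns one — the contrast the comparison machinery here quantifies.
"""

from __future__ import annotations

from bisect import bisect_left
from itertools import groupby
from typing import Sequence

from .exceptions import ContractError
from .graph import _check_sorted, _number_components
from .types import CIS, IntegrationSite, SetComparison, TranscriptionalElement, \
    WindowRule

#: Classic fixed-window rules: 2 sites / 30 kb, 3 / 50 kb, >=4 / 100 kb.
DEFAULT_RULES = (
    WindowRule(k=2, window=30_000),
    WindowRule(k=3, window=50_000),
    WindowRule(k=4, window=100_000),
)

NO_GENE = "<no-gene>"


def _validate_rules(rules: Sequence[WindowRule]) -> list[WindowRule]:
    rules = sorted(rules, key=lambda r: r.k)
    if not rules:
        raise ContractError("at least one window rule is required")
    for a, b in zip(rules, rules[1:]):
        if b.window < a.window:
            raise ContractError(
                f"window widths must be non-decreasing in order: "
                f"w_{b.k}={b.window} < w_{a.k}={a.window}")
        if b.k == a.k:
            raise ContractError(f"duplicate rule order k={a.k}")
    return rules


def swm_call(sites: Sequence[IntegrationSite],
             rules: Sequence[WindowRule] = DEFAULT_RULES) -> list[CIS]:
    """Call CIS with the fixed-window method.

    Returns non-overlapping CIS ordered and numbered like the graph-based
    caller. Sites satisfying no rule are left uncalled (not returned as
    singletons — a lone site is never an SWM CIS).
    """
    _check_sorted(sites)
    rules = _validate_rules(rules)
    comps: list[list[IntegrationSite]] = []
    for _, group in groupby(sites, key=lambda s: s.chrom):
        chrom_sites = list(group)
        pos = [s.pos for s in chrom_sites]
        i = 0
        while i < len(chrom_sites):
            best: list[IntegrationSite] | None = None
            for rule in reversed(rules):  # largest k first
                # sites in [pos[i], pos[i] + window), window anchored here
                hi = bisect_left(pos, pos[i] + rule.window, lo=i)
                count = hi - i
                if count >= rule.k and (best is None or count > len(best)):
                    best = chrom_sites[i:hi]
            if best is not None:
                comps.append(best)
                i += len(best)
            else:
                i += 1
    return _number_components(comps)


def next_gene(cis: CIS, tes: Sequence[TranscriptionalElement]) -> str:
    """Next-gene assignment: the TE whose TSS is closest to the CIS median
    position on the same chromosome. Ties break toward the smaller TSS,
    then lexicographic name; returns the ``NO_GENE`` sentinel when the
    chromosome carries no annotation."""
    from .stats import median_position

    anchor = median_position(cis.members)
    candidates = [t for t in tes if t.chrom == cis.chrom]
    if not candidates:
        return NO_GENE
    return min(candidates,
               key=lambda t: (abs(t.tss - anchor), t.tss, t.name)).name


def swm_gene_set(cis_list: Sequence[CIS],
                 tes: Sequence[TranscriptionalElement]) -> list[str]:
    """Sorted unique next-gene assignments over SWM CIS (sentinel excluded)."""
    genes = {next_gene(c, tes) for c in cis_list}
    genes.discard(NO_GENE)
    return sorted(genes)


def compare_gene_sets(gbf_genes: Sequence[str],
                      swm_genes: Sequence[str]) -> SetComparison:
    """Three-way partition of the two gene collections: found only by the
    graph-based caller, only by the window baseline, or by both."""
    gbf, swm = set(gbf_genes), set(swm_genes)
    return SetComparison(
        only_gbf=sorted(gbf - swm),
        only_swm=sorted(swm - gbf),
        both=sorted(gbf & swm),
    )
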