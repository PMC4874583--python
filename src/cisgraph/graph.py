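"""Proximity-graph construction and connected-component CIS extraction.

A node per integration site; an edge joins two same-chromosome sites whose
distance is below the threshold (strictly, by default). Connected components
of this graph are the CIS: clusters grow by chaining, so two sites further
apart than the threshold may share a CIS through intermediates — the
"stretchy" alternative to fixed windows.

On a sorted 1-D axis the component partition is fully determined by
consecutive gaps (a new component starts exactly where the gap to the
previous site reaches the threshold), so the default path is a linear gap
scan; the explicit graph is materialised only on request, for export and
cross-checking, and the two paths agree exactly.
"""

from __future__ import annotations

from itertools import groupby
from typing import Sequence

import networkx as nx

from .exceptions import ContractError, ParameterError
from .types import CIS, IntegrationSite, chrom_sort_key


def _check_sorted(sites: Sequence[IntegrationSite]) -> None:
    for a, b in zip(sites, sites[1:]):
        if (chrom_sort_key(a.chrom), a.pos) > (chrom_sort_key(b.chrom), b.pos):
            raise ContractError(
                "sites must be sorted by (chrom, pos); use io.read_is_table "
                "or sort with IntegrationSite.sort_key")


def _qualifies(distance: int, threshold: int, inclusive: bool) -> bool:
    return distance <= threshold if inclusive else distance < threshold


def build_graph(sites: Sequence[IntegrationSite], threshold: int,
                inclusive: bool = False) -> nx.Graph:
    """Build the explicit IS proximity graph.

    Nodes are keyed by ``row_id`` (site attached as the ``site`` attribute);
    an edge joins every same-chromosome pair at distance below ``threshold``
    (``<= threshold`` with ``inclusive=True``). Exploits sortedness: each
    site is compared only against predecessors within the threshold window,
    which yields the same edge set as the all-pairs nested loop.
    """
    if threshold < 1:
        raise ParameterError(f"threshold must be >= 1, got {threshold}")
    _check_sorted(sites)
    g = nx.Graph(threshold=threshold, inclusive=inclusive)
    for s in sites:
        g.add_node(s.row_id, site=s)
    window: list[IntegrationSite] = []
    for s in sites:
        window = [w for w in window
                  if w.chrom == s.chrom
                  and _qualifies(s.pos - w.pos, threshold, inclusive)]
        for w in window:
            g.add_edge(w.row_id, s.row_id, distance=s.pos - w.pos)
        window.append(s)
    return g


def connected_components(graph: nx.Graph) -> list[CIS]:
    """Partition the explicit graph into CIS (statistics unset).

    Components are ordered by (chromosome, first member position) and
    numbered sequentially from 1. Singletons are returned; dropping
    low-order components is a separate explicit step
    (:func:`filter_by_order`).
    """
    comps = []
    for nodes in nx.connected_components(graph):
        members = sorted((graph.nodes[n]["site"] for n in nodes),
                         key=lambda s: s.sort_key)
        comps.append(members)
    return _number_components(comps)


def gap_scan_components(sites: Sequence[IntegrationSite], threshold: int,
                        inclusive: bool = False) -> list[CIS]:
    """Component partition by linear scan of consecutive gaps.

    Equivalent to single-linkage clustering cut at the threshold: walking
    the sorted sites of one chromosome, a new component starts exactly where
    the gap to the previous site fails the edge rule. Identical output to
    ``connected_components(build_graph(...))`` without materialising edges.
    """
    if threshold < 1:
        raise ParameterError(f"threshold must be >= 1, got {threshold}")
    _check_sorted(sites)
    comps: list[list[IntegrationSite]] = []
    for _, chrom_sites in groupby(sites, key=lambda s: s.chrom):
        current: list[IntegrationSite] = []
        for s in chrom_sites:
            if current and not _qualifies(s.pos - current[-1].pos,
                                          threshold, inclusive):
                comps.append(current)
                current = []
            current.append(s)
        if current:
            comps.append(current)
    return _number_components(comps)


def _number_components(comps: list[list[IntegrationSite]]) -> list[CIS]:
    comps.sort(key=lambda ms: (chrom_sort_key(ms[0].chrom), ms[0].pos,
                               ms[0].row_id))
    return [CIS(number=i, chrom=ms[0].chrom, members=ms)
            for i, ms in enumerate(comps, start=1)]


def filter_by_order(cis_list: Sequence[CIS], min_order: int) -> list[CIS]:
    """Keep CIS with at least ``min_order`` members, renumbering from 1.

    A component of order 1 is a lone integration, not a *common* one; the
    cutoff is explicit rather than built into extraction.
    """
    if min_order < 1:
        raise ParameterError(f"min_order must be >= 1, got {min_order}")
    kept = [c for c in cis_list if c.order >= min_order]
    return [CIS(number=i, chrom=c.chrom, members=c.members, stats=c.stats)
            for i, c in enumerate(kept, start=1)]


def write_edge_list(graph: nx.Graph, path) -> None:
    """Export edges as TSV (row_id_u, row_id_v, distance)."""
    with open(path, "w") as fh:
        fh.write("u\tv\tdistance\n")
        for u, v, d in sorted(graph.edges(data="distance")):
            fh.write(f"{u}\t{v}\t{d}\n")


def write_graphml(graph: nx.Graph, path) -> None:
    """Export the graph as GraphML (Cytoscape-compatible)."""
    g = nx.Graph(**graph.graph)
    for n, data in graph.nodes(data=True):
        s = data["site"]
        g.add_node(n, chrom=s.chrom, pos=s.pos, label=s.label)
    for u, v, d in graph.edges(data="distance"):
        g.add_edge(u, v, distance=d)
    nx.write_graphml(g, path)
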