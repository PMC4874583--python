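"""Independent brute-force oracles used to validate the implementation.

These deliberately take the slow, obvious route (all-pairs enumeration,
hand-rolled BFS, scipy hierarchical clustering, Monte-Carlo placement) and
never call the code paths they check.
"""

from __future__ import annotations

from collections import defaultdict, deque

import numpy as np

from cisgraph.types import IntegrationSite, TranscriptionalElement


def all_pairs_edges(sites, threshold, inclusive=False):
    """Every same-chromosome pair below the threshold, by O(n^2) scan."""
    edges = set()
    for i, a in enumerate(sites):
        for b in sites[i + 1:]:
            if a.chrom != b.chrom:
                continue
            d = abs(a.pos - b.pos)
            if d <= threshold if inclusive else d < threshold:
                edges.add(frozenset((a.row_id, b.row_id)))
    return edges


def bfs_partition(sites, threshold, inclusive=False):
    """Component partition by breadth-first search over the explicit
    all-pairs edge list. Returns a frozenset of frozensets of row_ids."""
    adj = defaultdict(set)
    for e in all_pairs_edges(sites, threshold, inclusive):
        u, v = tuple(e)
        adj[u].add(v)
        adj[v].add(u)
    seen, comps = set(), []
    for s in sites:
        if s.row_id in seen:
            continue
        comp, queue = set(), deque([s.row_id])
        while queue:
            u = queue.popleft()
            if u in comp:
                continue
            comp.add(u)
            queue.extend(adj[u] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return frozenset(comps)


def single_linkage_partition(sites, threshold):
    """Strict-< partition via scipy single-linkage dendrogram cutting,
    per chromosome. Integer distances make < t equivalent to <= t - 1."""
    from scipy.cluster.hierarchy import fcluster, linkage

    by_chrom = defaultdict(list)
    for s in sites:
        by_chrom[s.chrom].append(s)
    comps = []
    for chrom_sites in by_chrom.values():
        if len(chrom_sites) == 1:
            comps.append(frozenset({chrom_sites[0].row_id}))
            continue
        x = np.array([[s.pos] for s in chrom_sites], dtype=float)
        z = linkage(x, method="single")
        labels = fcluster(z, t=threshold - 1, criterion="distance")
        groups = defaultdict(set)
        for s, lab in zip(chrom_sites, labels):
            groups[lab].add(s.row_id)
        comps.extend(frozenset(g) for g in groups.values())
    return frozenset(comps)


def partition_of(cis_list):
    """Canonical form of a CIS list for comparison with oracles."""
    return frozenset(frozenset(m.row_id for m in c.members) for c in cis_list)


def all_pairs_links(sites, tes, threshold, inclusive=False):
    """IS-TE link set by O(n*m) scan: {(row_id, te_name, distance)}."""
    out = set()
    for s in sites:
        for t in tes:
            if s.chrom != t.chrom:
                continue
            d = abs(s.pos - t.tss)
            if d <= threshold if inclusive else d < threshold:
                out.add((s.row_id, t.name, d))
    return out


def mc_window_pvalue(order, dim, total_is, genome_size, reps, rng):
    """Monte-Carlo estimate of P[>= order sites in a fixed dim-bp window]
    under uniform placement of total_is sites on genome_size bp, plus its
    standard error."""
    hits = 0
    chunk = max(1, int(2e6) // total_is)
    done = 0
    while done < reps:
        k = min(chunk, reps - done)
        pos = rng.integers(1, genome_size + 1, size=(k, total_is))
        hits += int(((pos <= dim).sum(axis=1) >= order).sum())
        done += k
    p = hits / reps
    se = float(np.sqrt(max(p * (1 - p), 1e-12) / reps))
    return p, se


def random_sites(rng, n, n_chrom=3, max_pos=100_000, n_labels=3):
    """Random unsorted IntegrationSite list for property tests."""
    chroms = [f"chr{i + 1}" for i in range(n_chrom)]
    sites = [IntegrationSite(chroms[int(rng.integers(n_chrom))],
                             int(rng.integers(1, max_pos + 1)),
                             f"lab{int(rng.integers(n_labels))}", i)
             for i in range(n)]
    return sites


def random_tes(rng, m, n_chrom=3, max_pos=100_000):
    chroms = [f"chr{i + 1}" for i in range(n_chrom)]
    return [TranscriptionalElement(chroms[int(rng.integers(n_chrom))],
                                   int(rng.integers(1, max_pos + 1)),
                                   f"G{j:03d}")
            for j in range(m)]
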