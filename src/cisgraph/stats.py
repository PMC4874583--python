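"""Per-CIS statistics: position summaries, label entropy, cluster significance.

Entropy quantifies the diversity of the categorical *entropy labels*
(tumour model, virus type, ...) carried by the member sites: a CIS fed by
many experimental sources is biologically more convincing than one private
to a single screen. Two normalisations are reported: by log(n) over the
labels present in the CIS (``entropy``), and by log(N) over all labels in
the dataset (``norm_entropy``), so 0 <= norm_entropy <= entropy <= 1.

Clustering significance uses a uniform-placement null: all M dataset sites
fall independently and uniformly on G genomic base pairs, so the count
inside a fixed window of d bp is Binomial(M, d/G). The CIS p-value is the
upper tail P[X >= O] and the log-likelihood ratio contrasts the local
Poisson rate MLE O/d with the global rate M/G. Output headers label this
null explicitly (``null=uniform-binomial``).
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Mapping, Sequence

from scipy.stats import binom

from .exceptions import ContractError, ParameterError
from .types import CIS, CISStatistics, IntegrationSite


def average_position(members: Sequence[IntegrationSite]) -> float:
    """Midpoint (first + last) / 2 of the member span, in bp."""
    if not members:
        raise ContractError("CIS has no members")
    return (members[0].pos + members[-1].pos) / 2


def median_position(members: Sequence[IntegrationSite]) -> float:
    """Median member position: central site for odd order, mean of the two
    central sites for even order. For skewed member layouts this locates the
    dense side, unlike the span midpoint."""
    if not members:
        raise ContractError("CIS has no members")
    n = len(members)
    mid = n // 2
    if n % 2:
        return float(members[mid].pos)
    return (members[mid - 1].pos + members[mid].pos) / 2


def dimension(members: Sequence[IntegrationSite],
              span_exclusive: bool = False) -> int:
    """Base pairs containing all members: last - first + 1 (inclusive), so a
    singleton CIS occupies 1 bp. ``span_exclusive`` gives last - first."""
    if not members:
        raise ContractError("CIS has no members")
    span = members[-1].pos - members[0].pos
    return span if span_exclusive else span + 1


def cis_entropy(label_counts: Mapping[str, int], order: int) -> float:
    """Shannon entropy of the within-CIS label counts, normalised by
    log(n) over the n labels present; 0 when a single label is present.
    Base-invariant: the log base cancels in the ratio."""
    counts = [c for c in label_counts.values() if c > 0]
    if sum(counts) != order:
        raise ContractError(
            f"label counts sum to {sum(counts)}, expected order {order}")
    n = len(counts)
    if n <= 1:
        return 0.0
    h = -sum((c / order) * math.log(c / order) for c in counts)
    return min(max(h / math.log(n), 0.0), 1.0)  # clip float round-off


def normalized_entropy(label_counts: Mapping[str, int], order: int,
                       n_dataset_labels: int) -> float:
    """Entropy normalised by log(N) over the N dataset-wide labels; labels
    absent from the CIS contribute 0 (0*log 0 := 0). 0 when N = 1."""
    counts = [c for c in label_counts.values() if c > 0]
    if sum(counts) != order:
        raise ContractError(
            f"label counts sum to {sum(counts)}, expected order {order}")
    if n_dataset_labels < len(counts):
        raise ContractError(
            f"dataset-wide label count {n_dataset_labels} < labels in CIS "
            f"{len(counts)}")
    if n_dataset_labels <= 1:
        return 0.0
    h = -sum((c / order) * math.log(c / order) for c in counts)
    return min(max(h / math.log(n_dataset_labels), 0.0), 1.0)


def cis_pvalue(order: int, dim: int, total_is: int, genome_size: int) -> float:
    """P[X >= order], X ~ Binomial(total_is, dim / genome_size): the chance
    that uniform placement puts at least this many of the M dataset sites
    into a window of the CIS's dimension. Decreasing in order at fixed
    dimension; increasing in dimension at fixed order."""
    if dim < 1 or dim > genome_size:
        raise ParameterError(
            f"dimension must be in [1, genome size], got {dim} vs {genome_size}")
    if order < 1 or order > total_is:
        raise ParameterError(
            f"order must be in [1, total IS], got {order} vs {total_is}")
    p = float(binom.sf(order - 1, total_is, dim / genome_size))
    return min(max(p, 5e-324), 1.0)


def loglik_ratio(order: int, dim: int, total_is: int, genome_size: int) -> float:
    """2*(l1 - l0): Poisson log-likelihood of `order` counts on `dim` bp at
    the local MLE rate order/dim versus the global rate total_is/genome_size.
    0 exactly when the local density equals the global one."""
    if dim < 1 or dim > genome_size:
        raise ParameterError(
            f"dimension must be in [1, genome size], got {dim} vs {genome_size}")
    if order < 1 or order > total_is:
        raise ParameterError(
            f"order must be in [1, total IS], got {order} vs {total_is}")
    mu0 = total_is / genome_size * dim  # expected count under the global rate
    llr = 2.0 * (order * math.log(order / mu0) - (order - mu0))
    return max(llr, 0.0)


def compute_statistics(
    cis_list: Sequence[CIS],
    n_dataset_labels: int | None = None,
    total_is: int | None = None,
    genome_size: int | None = None,
    span_exclusive: bool = False,
    per_chromosome: bool = False,
    fdr: bool = False,
) -> list[CIS]:
    """Attach a :class:`CISStatistics` record to every CIS, in place.

    ``n_dataset_labels`` and ``total_is`` default to what the CIS list
    itself contains; ``genome_size`` defaults to the sum over chromosomes of
    the maximum observed position (a conservative lower bound on the true
    assembly size). With ``per_chromosome=True`` the null density uses each
    chromosome's own site count and extent instead of the genome-wide one.
    ``fdr=True`` adds Benjamini-Hochberg q-values across the list.
    """
    if not cis_list:
        return list(cis_list)
    all_members = [m for c in cis_list for m in c.members]
    if n_dataset_labels is None:
        n_dataset_labels = len({m.label for m in all_members})
    if total_is is None:
        total_is = len(all_members)

    chrom_max: dict[str, int] = {}
    chrom_count: dict[str, int] = {}
    for m in all_members:
        chrom_max[m.chrom] = max(chrom_max.get(m.chrom, 0), m.pos)
        chrom_count[m.chrom] = chrom_count.get(m.chrom, 0) + 1
    if genome_size is None:
        genome_size = sum(chrom_max.values())

    for cis in cis_list:
        counts = dict(Counter(m.label for m in cis.members))
        d = dimension(cis.members, span_exclusive=span_exclusive)
        d_stat = max(d, 1)  # exclusive span of a singleton is 0 bp
        if per_chromosome:
            m_null, g_null = chrom_count[cis.chrom], chrom_max[cis.chrom]
        else:
            m_null, g_null = total_is, genome_size
        cis.stats = CISStatistics(
            order=cis.order,
            dimension=d,
            avg_pos=average_position(cis.members),
            median_pos=median_position(cis.members),
            n_labels=len(counts),
            label_counts=counts,
            entropy=cis_entropy(counts, cis.order),
            norm_entropy=normalized_entropy(counts, cis.order,
                                            n_dataset_labels),
            p_value=cis_pvalue(cis.order, min(d_stat, g_null), m_null, g_null),
            loglik_ratio=loglik_ratio(cis.order, min(d_stat, g_null),
                                      m_null, g_null),
        )
    if fdr:
        from statsmodels.stats.multitest import multipletests

        qs = multipletests([c.stats.p_value for c in cis_list],
                           method="fdr_bh")[1]
        for cis, q in zip(cis_list, qs):
            cis.stats.fdr_q = float(q)
    return list(cis_list)
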