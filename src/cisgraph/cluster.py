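"""Estimator front-ends: CIS calling and annotation as fit/transform objects.

`CISClusterer` is the graph-based caller (single-linkage proximity
clustering with per-CIS statistics), `WindowCISCaller` the fixed-window
baseline, `GeneAtmosphereAnnotator` the TSS-proximity annotator. All follow
scikit-learn conventions — constructor parameters, ``fit``, trailing
underscore fitted attributes, ``get_params``/``set_params`` — so they
compose with sklearn model-selection tooling; the functional API in
`graph`, `stats`, `swm` and `atmosphere` is what they delegate to.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from . import atmosphere as _atmosphere
from . import graph as _graph
from . import stats as _stats
from . import swm as _swm
from .exceptions import ContractError
from .types import CIS, IntegrationSite, TranscriptionalElement, WindowRule


def _as_sites(X) -> list[IntegrationSite]:
    """Coerce a DataFrame (chrom/pos/label columns) or an IntegrationSite
    sequence into a canonically sorted site list; row_id = input row."""
    if isinstance(X, pd.DataFrame):
        from .simulate import sites_from_frame

        return sites_from_frame(X)
    sites = list(X)
    if not all(isinstance(s, IntegrationSite) for s in sites):
        raise ContractError(
            "X must be a DataFrame with chrom/pos/label columns or a "
            "sequence of IntegrationSite")
    return sorted(sites, key=lambda s: s.sort_key)


def _as_tes(annotation) -> list[TranscriptionalElement]:
    if isinstance(annotation, pd.DataFrame):
        from .simulate import tes_from_frame

        return tes_from_frame(annotation)
    tes = list(annotation)
    if not all(isinstance(t, TranscriptionalElement) for t in tes):
        raise ContractError(
            "annotation must be a DataFrame with chrom/tss[/name] columns "
            "or a sequence of TranscriptionalElement")
    return sorted(tes, key=lambda t: t.sort_key)


def _member_labels(n_rows: int, cis_list: Sequence[CIS]) -> np.ndarray:
    labels = np.full(n_rows, -1, dtype=int)
    for cis in cis_list:
        for m in cis.members:
            labels[m.row_id] = cis.number
    return labels


class CISClusterer(ClusterMixin, BaseEstimator):
    """Graph-based common-integration-site caller.

    Builds the proximity graph over integration sites (edge when two
    same-chromosome sites lie closer than ``threshold``), takes connected
    components as CIS, optionally filters by minimum order, and computes
    the full per-CIS statistics record.

    Parameters
    ----------
    threshold : int, default 30_000
        Edge distance threshold in bp. 30 kb echoes the smallest classic
        fixed-window scale, keeping graph/window comparisons commensurable.
    inclusive : bool, default False
        Use ``distance <= threshold`` instead of the strict ``<``.
    min_order : int, default 1
        Drop CIS with fewer members after extraction (1 keeps singletons).
    genome_size : int or None
        Genome length G for the uniform-placement null; None sums the
        per-chromosome maximum observed positions.
    per_chromosome : bool, default False
        Compute the null density per chromosome instead of genome-wide.
    span_exclusive : bool, default False
        Report dimension as last - first instead of last - first + 1.
    fdr : bool, default False
        Add Benjamini-Hochberg q-values across the called CIS.
    emit_graph : bool, default False
        Materialise the explicit networkx graph as ``graph_`` (the default
        path is an equivalent linear gap scan).

    Attributes
    ----------
    cis_list_ : list of CIS with populated statistics.
    labels_ : ndarray, CIS number per input row, -1 for filtered-out rows.
    n_cis_ : number of called CIS.
    genome_size_, total_is_, n_dataset_labels_ : null-model inputs used.
    graph_ : networkx.Graph, only when ``emit_graph=True``.
    """

    def __init__(self, threshold: int = 30_000, inclusive: bool = False,
                 min_order: int = 1, genome_size: int | None = None,
                 per_chromosome: bool = False, span_exclusive: bool = False,
                 fdr: bool = False, emit_graph: bool = False):
        self.threshold = threshold
        self.inclusive = inclusive
        self.min_order = min_order
        self.genome_size = genome_size
        self.per_chromosome = per_chromosome
        self.span_exclusive = span_exclusive
        self.fdr = fdr
        self.emit_graph = emit_graph

    def fit(self, X, y=None):
        sites = _as_sites(X)
        self.sites_ = sites
        if self.emit_graph:
            self.graph_ = _graph.build_graph(sites, self.threshold,
                                             self.inclusive)
            cis_list = _graph.connected_components(self.graph_)
        else:
            cis_list = _graph.gap_scan_components(sites, self.threshold,
                                                  self.inclusive)
        cis_list = _graph.filter_by_order(cis_list, self.min_order)
        self.total_is_ = len(sites)
        self.n_dataset_labels_ = len({s.label for s in sites})
        chrom_max: dict[str, int] = {}
        for s in sites:
            chrom_max[s.chrom] = max(chrom_max.get(s.chrom, 0), s.pos)
        self.genome_size_ = (self.genome_size if self.genome_size is not None
                             else sum(chrom_max.values()))
        _stats.compute_statistics(
            cis_list,
            n_dataset_labels=self.n_dataset_labels_,
            total_is=self.total_is_,
            genome_size=self.genome_size_,
            span_exclusive=self.span_exclusive,
            per_chromosome=self.per_chromosome,
            fdr=self.fdr,
        )
        self.cis_list_ = cis_list
        self.n_cis_ = len(cis_list)
        n_rows = 1 + max((s.row_id for s in sites), default=-1)
        self.labels_ = _member_labels(n_rows, cis_list)
        return self


class WindowCISCaller(ClusterMixin, BaseEstimator):
    """Fixed-window (standard window method) CIS caller.

    Parameters
    ----------
    rules : sequence of WindowRule or (k, window) pairs
        Calling rules; default 2/30 kb, 3/50 kb, >=4/100 kb.

    Attributes
    ----------
    cis_list_ : called CIS, statistics unset (the baseline reports
        membership only).
    labels_ : CIS number per input row, -1 for uncalled sites.
    """

    def __init__(self, rules: Sequence = _swm.DEFAULT_RULES):
        self.rules = rules

    def _rules(self) -> list[WindowRule]:
        return [r if isinstance(r, WindowRule) else WindowRule(*r)
                for r in self.rules]

    def fit(self, X, y=None):
        sites = _as_sites(X)
        self.sites_ = sites
        self.cis_list_ = _swm.swm_call(sites, self._rules())
        self.n_cis_ = len(self.cis_list_)
        n_rows = 1 + max((s.row_id for s in sites), default=-1)
        self.labels_ = _member_labels(n_rows, self.cis_list_)
        return self


class GeneAtmosphereAnnotator(BaseEstimator):
    """TSS-proximity annotator: fit on an annotation table, transform CIS
    lists into gene atmospheres.

    Parameters
    ----------
    threshold : int, default 100_000
        Annotation distance in bp — a regulatory-neighbourhood scale,
        independent of the clustering threshold.
    inclusive : bool, default False
        ``<=`` instead of strict ``<``.
    """

    def __init__(self, threshold: int = 100_000, inclusive: bool = False):
        self.threshold = threshold
        self.inclusive = inclusive

    def fit(self, annotation, y=None):
        self.tes_ = _as_tes(annotation)
        return self

    def link_sites(self, sites: Sequence[IntegrationSite]):
        """All (IS, TE) proximity links for the given sites."""
        return _atmosphere.link_is_to_te(sorted(sites, key=lambda s: s.sort_key),
                                         self.tes_, self.threshold,
                                         self.inclusive)

    def transform(self, cis_list: Sequence[CIS]):
        """Gene atmosphere per CIS (empty atmospheres retained)."""
        members = [m for c in cis_list for m in c.members]
        links = self.link_sites(members)
        return _atmosphere.build_gene_atmosphere(cis_list, links)

    def fit_transform(self, annotation, cis_list):
        return self.fit(annotation).transform(cis_list)

    def gene_set(self, cis_list: Sequence[CIS]) -> list[str]:
        """Dataset-level sorted unique gene names over all atmospheres."""
        return _atmosphere.dataset_gene_set(self.transform(cis_list))
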