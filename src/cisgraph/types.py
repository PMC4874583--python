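"""Domain types: integration sites, transcriptional elements, CIS records.

Coordinates are 1-based inclusive base-pair positions throughout. BED input
(0-based, half-open) is converted on read (position = start + 1); the single
base pair where the provirus joined the host genome is the unit of analysis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .exceptions import ContractError

_CHROM_NUM = re.compile(r"^(?:chr)?(\d+)$", re.IGNORECASE)


def normalize_chrom(chrom: str, strip_prefix: bool = False) -> str:
    """Trim whitespace and optionally drop a leading ``chr`` prefix."""
    c = str(chrom).strip()
    if strip_prefix and c.lower().startswith("chr"):
        c = c[3:]
    return c


def chrom_sort_key(chrom: str):
    """Natural ordering for chromosome names: 1 < 2 < ... < 10 < X < Y.

    Numeric chromosomes (with or without a ``chr`` prefix) sort numerically
    before non-numeric ones (X, Y, MT, scaffolds), which sort
    lexicographically. Keeps output deterministic across mixed sources.
    """
    m = _CHROM_NUM.match(str(chrom))
    if m:
        return (0, int(m.group(1)), "")
    c = str(chrom)
    if c.lower().startswith("chr"):
        c = c[3:]
    return (1, 0, c)


@dataclass(frozen=True)
class IntegrationSite:
    """One genomic integration event.

    Attributes
    ----------
    chrom : str
        Chromosome identifier ("1".."22", "X", "Y" or "chr"-prefixed).
    pos : int
        1-based base-pair coordinate of the insertion, >= 1.
    label : str
        Entropy label: free-text experimental factor (tumour model, virus
        type) over which per-CIS label diversity is computed.
    row_id : int
        Index of the origin row in the source table; unique per dataset.
    """

    chrom: str
    pos: int
    label: str
    row_id: int

    def __post_init__(self):
        if self.pos < 1:
            raise ContractError(f"position must be >= 1, got {self.pos}")
        if not str(self.chrom).strip():
            raise ContractError("chromosome must be non-empty")
        if not str(self.label).strip():
            raise ContractError("entropy label must be non-empty")

    @property
    def sort_key(self):
        return (chrom_sort_key(self.chrom), self.pos, self.row_id)


@dataclass(frozen=True)
class TranscriptionalElement:
    """Annotated element reduced to its transcription start site (TSS)."""

    chrom: str
    tss: int
    name: str

    def __post_init__(self):
        if self.tss < 1:
            raise ContractError(f"TSS must be >= 1, got {self.tss}")
        if not str(self.name).strip():
            raise ContractError("element name must be non-empty")

    @property
    def sort_key(self):
        return (chrom_sort_key(self.chrom), self.tss, self.name)


@dataclass
class CISStatistics:
    """Per-CIS statistics record.

    order
        Number of member IS (O).
    dimension
        Base pairs spanned by the members, inclusive (last - first + 1).
    avg_pos
        (first + last) / 2, the midpoint of the span.
    median_pos
        Median member position; for skewed member layouts a better locator
        than the midpoint.
    n_labels / label_counts
        Distinct entropy labels within the CIS and their counts.
    entropy
        Shannon entropy of the label counts normalised by log(n_labels),
        in [0, 1]; 0 when a single label is present.
    norm_entropy
        Same numerator normalised by log(N) where N is the dataset-wide
        distinct label count; norm_entropy <= entropy always.
    p_value
        Tail probability of observing >= O sites in a window of length
        `dimension` under uniform independent placement of all M dataset
        sites on G genomic base pairs (binomial null).
    loglik_ratio
        2*(l1 - l0), Poisson log-likelihood ratio between the local MLE
        rate O/dimension and the global rate M/G; 0 when they coincide.
    """

    order: int
    dimension: int
    avg_pos: float
    median_pos: float
    n_labels: int
    label_counts: dict[str, int] = field(default_factory=dict)
    entropy: float = 0.0
    norm_entropy: float = 0.0
    p_value: float = 1.0
    loglik_ratio: float = 0.0
    fdr_q: float | None = None


@dataclass
class CIS:
    """A common integration site: one connected component of the IS graph."""

    number: int
    chrom: str
    members: list[IntegrationSite]
    stats: CISStatistics | None = None

    def __post_init__(self):
        if not self.members:
            raise ContractError("a CIS must have at least one member IS")
        if len({m.chrom for m in self.members}) != 1:
            raise ContractError("all CIS members must share one chromosome")

    @property
    def name(self) -> str:
        """Chromosome + CIS number, e.g. ``chr3_1``."""
        return f"{self.chrom}_{self.number}"

    @property
    def order(self) -> int:
        return len(self.members)

    @property
    def first(self) -> int:
        return self.members[0].pos

    @property
    def last(self) -> int:
        return self.members[-1].pos

    @property
    def positions(self) -> list[int]:
        return [m.pos for m in self.members]


@dataclass(frozen=True)
class GALink:
    """One IS-to-TE proximity link of the gene atmosphere."""

    site: IntegrationSite
    te: TranscriptionalElement
    distance: int


@dataclass
class GeneAtmosphere:
    """Transcriptional elements within the annotation threshold of a CIS."""

    cis_ref: str
    links: list[GALink] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        """Deduplicated, lexicographically sorted linked TE names."""
        return sorted({ln.te.name for ln in self.links})


@dataclass(frozen=True)
class WindowRule:
    """Fixed-window calling rule: >= k sites within a window of w_k bp."""

    k: int
    window: int

    def __post_init__(self):
        if self.k < 2:
            raise ContractError(f"window rule order must be >= 2, got {self.k}")
        if self.window < 1:
            raise ContractError("window width must be >= 1")


@dataclass
class SetComparison:
    """Three-way partition of two gene-name sets (Venn-diagram style)."""

    only_gbf: list[str]
    only_swm: list[str]
    both: list[str]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "only_gbf": len(self.only_gbf),
            "only_swm": len(self.only_swm),
            "both": len(self.both),
        }
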