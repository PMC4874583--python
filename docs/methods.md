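# Methods

## The clustering model

Integration sites are points on chromosomes; the only attributes the caller
needs are chromosome, 1-based position, and a categorical *entropy label*
(the experimental factor a site came from — tumour model, virus type,
patient). The IS proximity graph has one node per site and an undirected
edge between two same-chromosome sites whose distance is strictly below the
threshold *t*; connected components of this graph are the called CIS.

On a 1-D axis this is exactly single-linkage clustering cut at *t*: after
sorting, a new component starts precisely where the gap between consecutive
sites reaches *t*. The implementation therefore uses a linear gap scan by
default and materialises the explicit graph (networkx) only when asked
(`emit_graph`, GraphML/edge-list export); the test suite asserts the two
paths produce identical partitions, and checks both against a brute-force
BFS oracle over the all-pairs edge list and against scipy's single-linkage
dendrogram. Component extraction over the explicit graph delegates to
networkx's connected-components routine.

Consequences of the model worth keeping in mind:

- **Chaining.** A component may span far more than *t* end-to-end; that is
  the point (rigid windows truncate dense runs), but in very dense data a
  low threshold is advisable or everything merges.
- **Strict inequality.** Distance `< t` makes an edge; equality does not
  (`inclusive=True` switches to `<=`). Coincident duplicates are distance 0
  and always merge; duplicates are never removed, only counted in a log.
- **Determinism.** Sites are canonically sorted (natural chromosome order,
  then position), components numbered 1..K in (chromosome, first-member)
  order, and the CIS name is `<chrom>_<number>`. Shuffling input rows
  changes nothing; repeated runs are byte-identical.

## Per-CIS statistics

For a CIS with sorted member positions IS₍₁₎ … IS₍O₎:

- order O; dimension = IS₍O₎ − IS₍₁₎ + 1 (inclusive span: a singleton
  occupies one base pair; `span_exclusive` gives the bare difference);
- average position (IS₍₁₎ + IS₍O₎)/2; median position = central member
  (odd O) or mean of the two central members (even O) — preferred for
  skewed layouts;
- entropy E = −Σ (nᵢ/O) log(nᵢ/O) / log n over the n labels present
  (defined as 0 when n = 1, where the normalisation degenerates), and
  normalised entropy with log N over the N dataset-wide labels. Both are
  base-invariant and clipped to [0, 1] against float round-off. High
  entropy means a hotspot is fed by many independent sources.

### Significance

The null model is uniform independent placement: the M sites of the
dataset fall uniformly on G base pairs, so the count in a fixed window of
d bp is Binomial(M, d/G). The reported p-value is the upper tail
P[X ≥ O] evaluated with scipy at the CIS's own dimension, and the
log-likelihood ratio is the Poisson contrast
2·[O·ln(O/μ₀) − (O − μ₀)], μ₀ = (M/G)·d, which is 0 exactly when the
local density equals the global one. A Monte-Carlo placement simulation in
the test suite confirms the tail within 3 standard errors at 10⁵
replicates on a small (M, G, d, O) grid.

Two deliberate simplifications: the window is fixed at the observed CIS
locus (no scan-statistic correction for the number of windows examined),
and G defaults to the sum of per-chromosome maximum observed positions —
a conservative stand-in when no assembly size is given
(`genome_size` overrides it; `per_chromosome=True` conditions the null on
each chromosome's own count and extent instead). P-values are clamped to
(0, 1] and no multiple-testing correction is applied by default;
`fdr=True` adds a Benjamini–Hochberg q-value column via statsmodels.
Because the windows are data-chosen, these p-values rank candidate CIS;
they are not calibrated genome-wide error rates.

## Gene atmosphere

Annotation reduces each transcriptional element to its TSS point (for BED
input the 5' end: start+1 on the plus strand, end on the minus strand).
An IS links to every same-chromosome TE with |pos − tss| strictly below
the annotation threshold; a CIS's gene atmosphere is the union of its
members' links, deduplicated and sorted. Distances are point-to-point and
strand-blind — at the 100 kb default scale a regulatory neighbourhood,
deliberately independent of the 30 kb clustering scale. The sweep uses
binary search over the sorted TSS list and is validated against an
all-pairs oracle. Empty atmospheres are kept in the output: "no annotated
neighbour" is a finding.

## Fixed-window baseline and comparison

The SWM baseline calls a CIS when ≥ k sites fit in w_k bp; defaults
2/30 kb, 3/50 kb, ≥4/100 kb — the classic fixed-window family — and fully
configurable, since published variants differ. Mechanics (the literature
leaves them loose) are fixed here deterministically: a greedy
left-to-right scan per chromosome anchors a window at each unconsumed
site, tests the rules from the highest order down, reports the qualifying
window that captures the most sites, and advances past it. Uncalled sites
are never emitted as singleton CIS. Next-gene assignment gives each
window CIS the TE nearest its median position (ties toward the smaller
TSS, then name; a sentinel when the chromosome has no annotation).

When the graph threshold is at least the widest window, every
fixed-window call is a subset of exactly one graph component (consecutive
gaps inside a w-bp window are < w ≤ t), so the window method can only
fragment what the graph method joins — the chain fixture (four sites 900 bp
apart, threshold/window 1000 bp: one order-4 component vs two order-2
windows) is the minimal illustration. `compare_gene_sets` partitions the
two callers' gene collections into only-graph / shared / only-window.

## Synthetic data

The generator emulates a small tagging screen on a toy genome (three
chromosomes, 150 Mb total): uniform background integrations spread
proportionally to chromosome length, plus planted hotspots — n sites
uniform on [centre − spread, centre + spread] with labels drawn i.i.d.
from a per-hotspot mixture — and uniformly placed TSS annotation. The
defaults (300 background sites, six hotspots of 12 sites with 2 kb spread
and ≥ 200 kb separation, label mixtures spanning pure to uniform, 400
TEs) were chosen so that planted structure is unambiguous at the 30 kb
threshold while background still produces chance pairs. Everything
derives from one integer seed; equal configs give byte-identical tables.

Under *spread ≪ gaps* and *2·spread < t < min gap*, with no background,
recovery of the planted hotspots is exact by construction — the suite
verifies count and membership across 50 seeds, and recovery of the
planted mixture entropy to ±0.005 at order 10⁴. What the generator does
not emulate — integration-sequence bias, mappability gaps, clonal
expansion inflating site counts — bounds what passing tests say about real
data: they certify the algorithms, not the biology of any particular
dataset.

## Problem sizes and runtime

The validation suite runs in seconds on one CPU: 200 random datasets of up
to 500 sites for the oracle-equivalence checks (the brute-force oracle is
O(n²)), 50 simulation seeds for recovery, 10⁵ Monte-Carlo replicates per
grid point for the p-value check, 100 random instances for containment.
The production paths themselves are O(n log n) in the number of sites and
comfortably handle the 10⁴–10⁵ sites of current datasets.

## Known limitations

- The significance model is a pragmatic uniform-placement null, not a
  corrected scan statistic; use the FDR column and rank-based
  interpretation for real screens.
- Thresholds are global, not adaptive to local gene density or
  chromatin accessibility.
- Gene atmosphere ignores strand and gene bodies (TSS points only), and
  functional enrichment of the resulting gene lists is out of scope — the
  gene-list output is plain text ready for external enrichment tools.
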