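# Methods

This note records the models, conventions and open design choices
behind `synnetflow`, in the spirit of a software methods supplement.
It states no empirical result that the test suite does not itself
compute.

## Coordinates and gene distance

Annotations are normalized to 1-based inclusive coordinates (GFF3 read
as-is; BED starts shifted by +1).  Within each chromosome, genes are
sorted by (start, end, gene id) and given integer ranks 0..n−1.  All
positional rules downstream — chaining gaps, tandem adjacency, the
"< 10 gene distance" proximal rule — are defined on ranks, never on
base pairs: the *gene distance* between two genes on one chromosome is
|rank_a − rank_b|.  The simulator emits gene i of a chromosome at
[1000·rank+1, 1000·rank+500]; nothing downstream consumes base-pair
spacing.

Homology input is the 12-column BLAST tabular layout.  Filtering
removes self-hits, deduplicates ordered (query, subject) pairs keeping
the highest bitscore (ties: lower e-value), then keeps the top-k
(default 5) hits per query and subject species.  The per-species
filter needs a gene→species map, which the 12 columns do not carry, so
it is an optional argument; without it the filter treats all subjects
as one pool.  Filtering is idempotent.

## Collinear chaining

Anchors of one chromosome pair are chained by dynamic programming:
anchor j may follow i iff 0 < rank_a(j) − rank_a(i) ≤ max_gap and
0 < s·(rank_b(j) − rank_b(i)) ≤ max_gap for a chain-wide sign s
(forward/inverted).  Chains are scored by anchor count — unit scores
keep the optimum exactly checkable against exhaustive subsequence
search, which the tests do on every run — and extracted greedily
(best chain, remove, repeat) down to min_anchors.  Ties prefer the
smaller start rank, then forward orientation.  Strand is stored but
ignored: with rank geometry the orientation is fully determined.
Defaults min_anchors = 5, max_gap = 25 follow the conventions of the
standard collinearity tools; the published analysis this mirrors
reported no parameter values, so both are exposed.

Intra-genome anchoring excludes same-chromosome pairs at rank distance
≤ 1 (tandem signal, not collinearity) and the self-diagonal.  The
tandem exclusion stays at 1 so proximal pairs remain visible to the
duplication classifier.

A consequence of min_anchors worth knowing: a segment shorter than
min_anchors that was inverted in one lineage produces no cross-lineage
anchors (its mini-chain is dropped), so its genes can appear
lineage-specific in cluster space.  This is the dominant false-positive
mode in clade-specific mining and is a resolution limit shared with
the standard tools, not a bug.

## Clustering

The synteny network has one node per anchored gene and one unweighted
edge per distinct anchored pair.  Communities are found with the
map-equation (Infomap) algorithm via igraph, with the RNG seeded per
call so identical inputs give identical partitions.  Infomap was
chosen as the default after label propagation — attractive for its
simplicity — proved unstable in two ways: a smallest-label tie-break
deterministically floods whole components from the symmetric start
(every tie resolves to the globally smallest label), and even the
standard keep-if-maximal variant splits well-connected gene lineages
along clade boundaries, inflating spurious clade-specific clusters.
Both alternatives (`label_propagation`, `connected_components`) remain
available behind the same interface.  Edges are unweighted: anchors
are presence evidence and no principled weights are reported for this
analysis type.

## Profiling

`M[c,s]` counts species-s genes in cluster c; `B = 1{M > 0}`.
Species correlations are Pearson on the binary columns (the phi
coefficient) by default, with counts as an option, because the
upstream analyses specify only a default correlation; zero-variance
species yield missing values with a warning.  Sharing counts assign
each cluster to the exact set of clades reaching their `min_presence`
(so the table partitions qualifying clusters), optionally after
removing species-specific clusters.  "Specific to clade X" means
≥ min_presence species inside and ≤ max_outside (default 0) outside —
the only reading under which "specific" is well defined; the bound is
configurable.

Clade presence thresholds default to the proportional rule used for
the real 16-species analysis (≥ 4 of 6, ≥ 4 of 6, ≥ 3 of 4 ≈ two
thirds, rounded up): for the demo clades of 6/4/2 species this gives
4/3/2.

## Mk model and tree search

The binary matrix is treated as character data under a two-state
Markov model with free stationary frequencies (π₀, π₁) and k free rate
categories (default 2) with Σwⱼ = 1 and mean rate Σwⱼrⱼ = 1.  The
rate matrix has off-diagonals (π₁, π₀) scaled to unit mean rate,
giving P(same→same, t) = π_same + π_other·e^(−μrt), μ = 1/(2π₀π₁).
Likelihoods use Felsenstein pruning over unique site patterns; the
pruning core is verified against brute-force summation over all
interior-state assignments (15 five-taxon topologies, |Δ| < 1e−9).

Search: neighbor joining on profile Hamming distances (implemented
in-house for strict determinism; negative branches clamped to 0),
then alternating per-branch Brent optimization (bounds [1e−8, 10],
xatol 1e−6), joint Nelder–Mead over (logit π₀, logit w₁, log rate
ratio), and full NNI sweeps accepting improvements > 1e−6 log units,
until a sweep accepts nothing.  Everything is deterministic given the
input.  Bootstrap support is the standard nonparametric bootstrap
(characters resampled with replacement, reduced NNI budget per
replicate) rather than an ultrafast approximation — a deliberate,
simpler substitute at desk scale.

No ascertainment-bias correction is applied (matching the model
string of the source analysis, which also lacked one; cluster-derived
matrices cannot contain all-zero characters by construction).  On
invariant-heavy matrices this has a visible consequence: the free-rate
mixture can push internal branch lengths to the upper bound while a
near-zero rate category absorbs invariant characters.  Topology and
support are unaffected — recovery is exercised by the tests — but
branch lengths from cluster matrices should not be interpreted as
evolutionary distances.

## Duplication classification

The cascade (WGD → TD → PD → TRD → DSD, first match wins) mirrors
DupGen_finder's resolution order.  "Less than 10 gene distance" is
read exclusively: PD covers rank distances 2..9, distance 1 is TD, and
the bound (`pd_max`) is a parameter.  TRD requires a caller-designated
outgroup: a pair is transposed when exactly one gene sits inside an
inter-genome block with the outgroup (the ancestral locus).  Without
outgroup blocks, TRD detection is disabled with a warning and those
pairs fall to DSD.  Gene-level modes take the highest-priority mode
among a gene's pairs.  Note the simulator has no separate transposed
event: its dispersed duplications leave one copy at the ancestral
locus, which the classifier legitimately reports as TRD; confusion
matrices in the tests show this mapping rather than hiding it.

## Enrichment

Upper-tail hypergeometric p-values are summed in log space
(logsumexp over log-pmf terms) and verified against exact rational
arithmetic on every instance with population ≤ 60.  Multiple testing
uses Benjamini–Hochberg step-up (via statsmodels) across all terms
with at least one study gene; only over-representation is tested.
The default significance threshold is FDR < 0.05 (the source analysis
states none).

## Simulator: what it emulates, and what not

The simulator is a stated world, not a fitting device.  Events are a
Poisson process along branches: counts per branch are Poisson with
mean rate × branch length × gene count at branch start, applied in
random order.  Default per-gene rates (loss 0.15, tandem 0.05,
inversion 0.02, proximal 0.02, dispersed 0.02 per branch-length unit)
were fixed a priori to give a realistic regime for the demo tree:
roughly 1.5–6% gene loss per branch — enough presence/absence signal
for every bipartition without eroding synteny.  Tandem copies insert
at rank offset 1, proximal at a uniform offset in [2, 9], dispersed
anywhere; inversions reverse a contiguous segment of geometric length
(mean 5) and flip strands; WGD copies each chromosome to a new
homeolog and deletes each copy with probability 1 − retention
(instantaneous fractionation).  Planted clade-specific blocks insert
runs of brand-new single-copy families at homologous positions
(after a shared host gene) in every clade member.

Homology bitscores follow a documented monotone scheme, 100·e^(−d)
plus unit Gaussian noise, where d is the patristic distance between
the species plus 0.25 per duplication in either gene's history;
e-value and identity are monotone transforms.  Noise corrupts the
table by dropping a false-negative fraction of true pairs and adding
false-positive random pairs.  Every event is logged as a fully
resolved record; replaying the log on the root genome reproduces each
leaf genome exactly (tested).

Orthologous genes share a *lineage id* (duplications mint new ones),
so the ground truth can be queried at two granularities: families
(all descendants of a root gene) and lineages (one syntenic context).
Microsyntenic clusters resolve lineages, not families — a tandem copy
shares its parent's neighborhood and correctly co-clusters with it —
so cluster-level claims are validated against lineage presence
patterns.

Not emulated: sequence evolution (homology quality is distance-based,
not alignment-based), realistic intergenic spacing, segmental
duplications as a separate class (they fold into dispersed events),
and gene conversion.  A green end-to-end test therefore establishes
that the pipeline recovers rank-order structure and presence/absence
signal under noisy homology — not that it would be robust to, e.g.,
alignment artifacts in real proteomes.

## Degenerate inputs and numerical conventions

Empty networks cluster to an empty list; events on empty genomes are
logged no-ops; an empty matrix refuses to serialize; zero-length
branches are valid (likelihood uses e^0); site likelihoods are floored
at 1e−300 before logs; branch lengths live in [1e−8, 10]; π₀ and
mixture weights are clamped away from {0, 1} during optimization.
All randomness flows from named substreams of one root seed
(SHA-256 of "seed:stage", reduced below 2³¹), so stages can be rerun
independently yet reproducibly.
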