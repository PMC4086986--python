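# Methods

## Problem and model

`barcodegap` proposes primary species hypotheses (PSHs) from a single
aligned barcode locus (typically a 658-bp COI fragment). The underlying
model is the *barcode gap*: within a species, pairwise genetic distances
are small and unimodally distributed; between species they are larger,
so the pooled distance distribution is bimodal with a low-density region
— the gap — separating the two modes. A partition of specimens is
obtained by single linkage below the gap: two specimens share a PSH iff
they are connected by a chain of sub-gap distances. Because the gap
position depends on an assumed ceiling for intraspecific divergence, the
scan is repeated over a geometric series of priors, and the most and
least inclusive partitions (lumper/splitter) bracket the plausible
taxonomies. Conflicts between the two are then adjudicated with an
indicator-vector correlation map and corroboration from tree-based
delimitations supplied as input tables.

## Distances

Pairwise distances use pairwise deletion: a column counts for a pair only
when both sequences have an unambiguous A/C/G/T there; gaps, `N` and
IUPAC ambiguity codes are excluded for that pair (fractional matching of
ambiguity codes is deliberately not attempted — exclusion matches common
distance implementations and keeps the brute-force oracle trivial).
Models: uncorrected p; JC69 `-(3/4)·ln(1-(4/3)p)`; K2P
`-(1/2)·ln((1-2P-Q)·sqrt(1-2Q))` with transition proportion P and
transversion proportion Q. K2P is the default, the conventional choice
for COI barcoding. Saturated pairs (non-positive log argument) are
flagged and set to 1.01 × the largest finite distance so that rank-based
gap scanning and single linkage stay well defined; pairs with zero
comparable sites are flagged missing (NaN) and never connect clusters.
Transversion proportion is computed from integer mismatch/transition
counts (not as `p − P`) so that boundary-saturated pairs are classified
identically to exact rational arithmetic.

## Gap detection

Let `d_1 ≤ … ≤ d_m` be the sorted pairwise distances and
`w_i = d_{i+1} − d_i` the consecutive gaps. For a prior intraspecific
ceiling `P`, gap `w_i` is **eligible** when

1. `d_{i+1} ≥ P` — a gap closing below the prior cannot be the boundary
   between intra- and interspecific distances (this convention, rather
   than requiring `d_i ≥ P`, lets the gap *start* inside the prior range,
   which is necessary when all intraspecific distances are small); and
2. at least 0.5 % of the distances lie on each side — a species boundary
   separates distance mass, whereas the extreme tails of any continuous
   sample contain large spacings with negligible mass beyond them.

The first eligible gap with `w_i > X · max(mean of the preceding
`window` gaps, P)` is reported, and the partition threshold is its
midpoint (any threshold inside the gap produces the same single-linkage
components; the midpoint is deterministic). `window` defaults to
`ceil(0.05·m)` clamped to `[10, 1000]`.

`X` (relative gap width, default **10**) controls the detector's
specificity. The floor at `P` (instead of a vanishing `P/window`-style
floor) is essential: sorted distances from finite alignments are
quantised in steps of `1/L`, and without an absolute floor a
one-quantum spacing next to a run of ties always dominates the local
mean, producing hair-trigger false gaps. Calibration (star-tree
simulations and sorted samples from a single continuous unimodal
distribution) shows that with `X = 10`: unimodal clouds of 500 distances
yield a false gap in ≤ 2 % of seeds; a 10× inter/intra divergence ratio
is recovered exactly (splitter = truth, ARI 1.0) in 100/100 seeds; and at
ratio 1 the scan correctly reports no structure in 95/100 seeds. Values
of `X` near 1.5 make every unimodal tail spacing a "gap" (normalised
spacings are approximately Exp(1), so a threshold of 1.5 local means
fires at rate ~e^-1.5 per rank) and are unusable.

Recursion: each cluster of an initial partition with ≥ `min_group`
(default 4) members is re-scanned using only within-cluster distances and
the same prior, iterating until nothing splits, with depth capped at 10
as a guard against oscillation. The lumper (splitter) is the gap-detected
partition with the fewest (most) clusters over all priors, both initial
and recursive partitions competing; ties break toward the larger prior
for the lumper and the smaller prior for the splitter.

Default prior series: geometric, `pmin = 0.001`, `pmax = 0.2`,
`steps = 10` (substitutions/site, compared on the scale of the chosen
distance model). The upper bound is deliberately above the usual 0.1:
for the ≥ 0.90 correlation merge rule ever to *reject* a proposed split,
within-PSH divergence must be able to exceed ~0.10 (correlation of
gap-free representatives ≈ 1 − p-distance), and the lumper partition is
only reachable when some prior exceeds that level.

## Klee diagrams and the merge rule

An indicator vector one-hot encodes a sequence over four channels per
column (gaps/ambiguities are zero in all channels) and is scaled to unit
Euclidean norm; the correlation of two vectors is their inner product, a
cosine in [0, 1] that for gap-free equal-length sequences equals the
fraction of matching columns. Vectors are not centred before correlating;
cosine on the non-negative one-hot signal keeps the quantity
interpretable as sequence identity (centring would change absolute
values but not the ordering of high vs low blocks). Each splitter PSH is
represented by its medoid (minimum mean within-cluster distance, ties by
input order) — deterministic and robust to outlier haplotypes. Rows and
columns are ordered so splitter PSHs within one lumper PSH are adjacent.
"≥ 90 % similarity" is implemented as correlation ≥ 0.90, evaluated only
within lumper blocks (conflicts are audited inside each lumper PSH, not
globally — globally, moderately divergent congeners can exceed 0.90 and
would produce spurious cross-species proposals). Merge proposals are
connected components of the thresholded correlation graph, so a chain
a~b, b~c joins {a,b,c} even when a~c falls below the threshold.

## Congruence and consensus

One conflict case per lumper PSH containing > 1 splitter PSH (splitter
PSHs spanning several lumper PSHs violate refinement and are reported as
exceptions, never silently fixed). Resolution per case:

* one Klee component → `keep_lumper`;
* several components → every component pair stays split only if at
  least one tree-based partition (by default the GMYC single-threshold
  and PTP columns of the specimen table) separates it, i.e. no tree
  cluster mixes specimens of both components; unseparated pairs merge
  back transitively. GMYC multiple-threshold output is excluded from
  corroboration because multi-threshold delimitation systematically
  over-splits.
* labels: `accept_split` when the final clusters equal the splitter
  sub-PSHs, otherwise `partial_split` (including the case of a Klee-split
  pair merged back entirely for lack of tree support).

The consensus partition assembles non-conflicted lumper PSHs plus the
per-case resolutions; by construction every consensus cluster is a union
of splitter clusters and a subset of one lumper cluster. With no tree
columns available the Klee components are accepted as-is and the run is
flagged `klee_only`. Cryptic-species accounting reports both the
sum-of-(k−1) count over split morphospecies and the difference
`n_consensus − n_morphospecies`, which coincide exactly when no
morphospecies is merged across consensus PSHs (merges are reported
separately rather than assumed absent). Sympatry uses exact matching of
case-folded, trimmed locality labels: two same-morphospecies PSHs are
sympatric iff their locality sets intersect, allopatric iff both
non-empty and disjoint, unknown otherwise. 28S (or any second locus) is
not an input to the automated rule; the pipeline is single-locus by
design and second-locus evidence can be attached as annotation.

## Synthetic data

`simulate` draws a star tree: a uniform random root, species ancestors
mutated from it with per-site probability `inter/2` (Jukes–Cantor
symmetric substitution), individuals mutated from their ancestor with
probability `intra/2`. The star topology gives closed-form binomial
expectations for every pairwise divergence — exactly the quantity the
gap scan consumes — at the cost of realism: no coalescent genealogy, no
rate heterogeneity, no indels, no codon structure. Defaults (5 species ×
10 individuals, 658 columns, intra 0.005, inter 0.1) represent a clean
barcode study with a 20× gap; the recovery experiments vary the ratio.
Localities come from a small fixed vocabulary with a configurable
sympatric fraction of species sharing a common area. Passing recovery
tests on this generator demonstrates correctness of the gap/linkage/Klee
machinery, not robustness to introgression, uneven sampling or rate
variation in real data.

`synthetic_benchmark` is a SYNTHETIC stand-in for a published terebrid
COI case study whose supplementary data are not redistributable. It
generates a 454 × 658 COI-like alignment (with a 195 × 758 28S-like
companion that is only parsed and counted) and a five-method assignment
table engineered so that the study's printed summary structure emerges
from computation: 87 morphospecies; lumper/splitter 98/125; method
cluster counts 98/125/110/130/112; 63 clusters shared by all five
methods and 83 excluding multi-threshold GMYC; ten conflict cases
resolving to 104 consensus PSHs and 17 cryptic species; 8 morphospecies
split identically in both gap-scan partitions. Within-cluster
substructure is placed by disjoint-site *transition* substitutions, so
each engineered divergence is an exact mismatch count (26/658 between
sub-PSHs the Klee rule must re-merge, correlation 0.9605; 78–80/658
between components it must keep apart, correlation < 0.89) and — because
transitions are an involution and K2P is then a monotone function of the
mismatch count — the distance distribution has exactly four tie-degenerate
levels plus a far interspecific cloud. The sequences themselves (root,
ancestor draws, substitution positions, specimen order, 28S content)
vary freely with the seed; the combinatorial structure does not. One of
the ten conflict cases is a two-component Klee split corroborated by no
tree method, exercising the merge-back branch of the consensus rule.

## Numerical and engineering choices

* Input order is canonical everywhere: matrices, Klee block order,
  cluster labels (`psh_001…` by first member) and consensus labels are
  deterministic functions of it; re-running a configuration is bitwise
  reproducible for CSV/JSON outputs.
* Distance matrices are computed by one-hot matrix products (exact
  integer counts in float64), O(n²L) with small constants: the 454 × 658
  benchmark takes ~0.2 s, the full pipeline under a second.
* Single linkage is implemented as connected components of the
  thresholded distance graph (scipy `csgraph`), checked in tests against
  a brute-force transitive-closure oracle.
* `partition_similarity` is the adjusted Rand index
  (scikit-learn's implementation).
* Degenerate inputs: empty alignments, ragged rows, duplicate ids,
  all-gap sequences, zero-comparable-site pairs, inverted prior bounds
  and non-refining splitters all raise typed errors (`errors.py`);
  priors with no detected gap yield a flagged single-cluster partition,
  and a scan with no gap anywhere raises `NoStructureError` rather than
  inventing structure.
* Test problem sizes (100-seed recovery experiments at n = 50, 200
  random 20-specimen matrices for the linkage oracle) keep the full
  suite under ~10 s while leaving the statistical assertions
  (≥ 95 %/≥ 90 % seed fractions) meaningful.

## Known limitations

Single-locus by design: mitochondrial introgression, incomplete lineage
sorting and Wolbachia-style sweeps can mislead any COI-only partition,
and the workflow's output is explicitly a *primary* hypothesis set to be
tested integratively. The gap detector assumes distances are globally
comparable (no per-lineage rate shifts). The ≥ 0.90 merge rule is a
fixed identity threshold, appropriate for COI-scale divergences but not
automatically for other loci. GMYC/PTP partitions are consumed as given;
their model fitting is out of scope.
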