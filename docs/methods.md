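# Methods

This note records the models implemented in `chromnet`, the defaults and why,
the design choices made where the procedure was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Coordinates and interval arithmetic

All coordinates are 0-based half-open (BED convention) internally; 1-based
inputs (SNP tables) are converted at the reader boundary. Genomic distance
between two intervals or nodes is the absolute difference of their midpoints —
symmetric and robust to unequal peak lengths. Overlap joins go through a
per-chromosome interval tree; anchor→peak assignment takes the peak with the
largest base-pair overlap of the *extended* anchor, with ties broken to the
leftmost peak so results are order-independent.

## Loop calling

**Hypergeometric caller (HiChIP-style).** Valid pairs with either end not
overlapping an open-chromatin peak (after boundary extension, default 250 bp)
are discarded. With N surviving pairs, n_i and n_j pairs touching peaks i and
j, and k pairs linking them, the p-value is the upper tail
P(X ≥ k), X ~ Hypergeom(N, n_i, n_j) — the chance of seeing k or more links
if the n_j pair-ends choosing peak j were drawn at random from the N. N is the
total of peak-overlapping pairs, a self-consistent universe. BH correction is
applied across peak pairs (FDR 0.05) and calls additionally require at least
4 supporting pairs; pairs whose two ends map to the same peak are dropped.

**Four-filter Poisson caller (Hi-C-style).** For each candidate bin pair
(i, j), four local-background expectations are the mean counts under the
donut (square annulus of half-widths P..W), vertical (3-wide column band),
horizontal (3-wide row band) and lower-left (quadrant between P and W
below-left) footprints, each excluding the (2P+1)² peak box and clipped to
bounds and to the strict upper triangle. Observed counts are tested against
each expectation with an upper-tail Poisson p-value; BH is applied separately
within each filter, genome-wide, and a call must pass all four at q ≤ 0.025.
Defaults P = 20, W = 40 in bin units. Candidates are restricted to
2·resolution < distance ≤ 1 Mb: the near-diagonal violates the local
background model and the network stage caps spans at 1 Mb anyway. Degenerate
corners: λ = 0 with a positive observation gives p = 0; both zero give p = 1.
No matrix balancing is applied before testing; balanced input can be supplied
if desired.

## Network construction and annotation

Nodes exist only through surviving calls, so every node has degree ≥ 1.
Duplicate peak-pair calls merge into one edge with PETs summed (the graphlet
stage requires a simple graph); self-loops, inter-chromosomal calls and spans
beyond 1 Mb (midpoint distance) are dropped with counts logged. Extension
defaults per assay reflect upstream read extension: 250 bp (ChIA-PET), 0
(HiChIP), 1250 (Hi-C).

State annotation uses the priority schema (1 enhancer/promoter, 2 insulator,
3 poised promoter, 4 repressed, 5 transcribed, 6 low signal); a node touching
both promoter and enhancer states is a promoter iff a TSS lies within 2 kb of
the nearest node boundary (0 if inside). Nodes touching no segment are
labeled `other` and retained — they participate in the enrichment
denominator. Broad-domain overlays crown, per domain, the promoter node(s)
with maximal bp overlap (exact ties crown all; no component restriction).
Super-enhancer overlays relabel every enhancer node overlapping an SE region;
a node inside several regions joins the one with the largest overlap. Merging
collapses each SE domain to one node (interval = union span), removes
within-domain edges and sums PETs over parallel edges.

## Interaction enrichment

Expected(A,B) = Σ_C |E_C| · adm_C(A,B)/adm_C(all), where adm_C counts
unordered same-chromosome node pairs within 1 Mb (within-class pairs j < k
when A = B). The distance gate is read as gd ≤ 1 Mb: an equality gate would
zero the formula almost surely, and the network caps edges at 1 Mb. Summed
over all label pairs the expectation equals the edge count exactly (labels
partition nodes); this is asserted at 1e-9 relative tolerance. Zero-observed
pairs are reported as −inf log2 ratios, never dropped.

## Centralities

Within each connected component with unweighted shortest-path distance nd:
closeness = 1/Σ_u nd(u,v); harmonic = Σ_{u≠v} 1/nd(u,v); betweenness =
Σ_{u≠v≠x} |sp(u,x,v)|/|sp(u,x)| over unordered pairs, endpoints excluded —
the standard shortest-path-fraction form. Normalized variants: degree/(n−1),
closeness·(n−1), harmonic/(n−1), betweenness/((n−1)(n−2)/2), with 0 when a
denominator vanishes.

## Graphlet orbits

The catalog enumerates all graphs on 2–5 labeled vertices, keeps connected
ones, deduplicates by isomorphism (canonical minimum-adjacency-mask over
vertex permutations) and computes vertex automorphism orbits: 30 graphlets,
73 orbits. Graphlets are ordered by (vertex count, edge count, descending
degree sequence, canonical mask) and orbits within a graphlet by member
degree, which reproduces the standard numbering at its anchor points (edge =
orbit 0, 3-path ends/middle = 1/2, triangle = 3, 4-path = 4/5, 4-star = 6/7,
4-cycle = 8, 4-clique = 14, 5-clique = 72). The full 5-vertex ordering
follows this deterministic rule; cluster semantics do not depend on the index
permutation.

Counting enumerates every connected induced subgraph of size 2–5 exactly once
(ESU-style extension by exclusive neighbors with larger root id) and
classifies each by a precomputed lookup from the labeled adjacency mask to
per-position orbits. Counts[0] equals the degree by construction. Signatures
are per-node proportions over all 73 orbit counts.

Orbit clustering excludes orbits 0 and 1, which are present with similar
scores for essentially all nodes and would otherwise let degree dominate;
orbits with zero variance across nodes go to a sentinel "degenerate" cluster.
Distance is 1 − Spearman ρ across nodes, average linkage (robust for
correlation distances; the linkage was an open choice), tree cut at distance
1 − cutoff (default cutoff 0.3), clusters numbered by first orbit index.
Because Spearman is rank-based, monotone transforms of the signatures do not
change the clustering. For the classifier, which needs a fixed-width score
block, the tree is cut into exactly 7 clusters (`n_clusters=7`); a saved
orbit→cluster map can be loaded instead for cross-dataset comparability.
Cluster scores are CS_k = max over the cluster's orbits of the per-orbit
z-score on proportions, with population (not sample) standard deviation over
all nodes; zero-variance orbits contribute z = 0.

## Specificity, targets, group tests

SPM for gene g in cell type c is x_c/‖x‖₂ — cosine similarity between the
expression vector and the single-type indicator; squares over types sum to 1.
All-zero genes are dropped. Node scores average over associated genes.

Enhancer targets: BFS from each enhancer/super-enhancer node; at the first
depth d ≤ 4 reaching any promoter or broad-domain node, *all* such nodes at
depth d are targets ("first promoter found" is ambiguous under ties; keeping
all minimal-depth targets makes the result independent of neighbor order).
Promoter-class nodes are never expanded through; all other classes are
traversable. A nearest-TSS fallback mode (≤ 10 kb) is provided.

Group comparisons use the Wilcoxon rank-sum test: exact null for small
untied samples, normal approximation with tie correction otherwise.

## Classification

Features (23): degree, closeness, harmonic, betweenness — raw and
component-normalized (8); component size; 7 orbit-cluster scores; node length;
node length over mean neighbor length; mean PET of incident edges; distance to
the closest upstream and downstream TSS (capped at 1 Mb, strand encoded ±1,
0 when absent). Pipelines standardize features inside training folds.
Stratified 5-fold cross-validation (the evaluation scheme was an open choice;
cross-validation is disclosed wherever reported); grid search over
C ∈ {0.1, 1, 10, 100} and gamma ∈ {1e-3, 1e-2, 1e-1, 1, scale} optimizing
MCC, which is robust to the class imbalance between super enhancers and
enhancers; no resampling. Probabilities come from Platt scaling (sigmoid
calibration) fitted within the training folds; pooled out-of-fold
probabilities give ROC/PR/AUC and accuracy at a 0.2 probability threshold.
Greedy forward selection adds, per round, the feature maximizing
cross-validated MCC under fixed hyper-parameters (C = 1, gamma = scale) so
rounds are comparable, and reports the full 23-step ranking and MCC
trajectory.

## SNP enrichment

Enhancer-class nodes with at least one broad-domain target form E-BD (an
enhancer targeting both classes counts as E-BD — positive-class priority);
nodes with only regular-promoter targets form E-P; untargeted enhancers are
excluded. The unit is node-level harboring: a node harbors a phenotype iff
any of its SNPs falls inside the node interval. The test statistic is the
harboring-fraction difference (E-BD minus E-P); the null redistributes the
pooled harboring indicators into sets of the original sizes. Because the
statistic is monotone in the number of harboring nodes landing in E-BD, the
permutation distribution is sampled exactly via the corresponding
hypergeometric urn — distributionally identical to shuffling labels and much
faster. P-values use the add-one estimator (b+1)/(n_perm+1) (never exactly
zero); BH corrects across phenotypes. SNP inputs are assumed pre-expanded for
LD (proxies at r² ≥ 0.7 are an upstream concern).

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, with
all randomness drawn from a single seeded generator in fixed order
(byte-identical output per seed). Defaults: 3 chromosomes × 600 nodes on
30 Mb (midpoints on a 2 kb grid, widths 200–1000 bp, so peaks never overlap);
label proportions promoter 0.20, broad domain 0.05, enhancer 0.40, super
enhancer 0.10, insulator 0.15, other 0.10. Super-enhancer domains are runs of
3 neighboring nodes, so constituent nodes sit close together and within-domain
contacts are geometrically possible; the domain region is the members' span.

Edges are independent Bernoulli per admissible pair (same chromosome,
≤ 1 Mb) with probability min(0.95, base · (d0/(d0+gd))^α · M), base = 0.19,
d0 = 50 kb, α = 0.3, a saturating distance decay. The gentle exponent and low
base rate are deliberate: they keep the largest multiplied probability below
the cap, so planted multipliers are the *effective* contact enrichments and
can be recovered downstream — a steeper decay would clip boosted close pairs
and bias recovery. Expected edge count (~4000 at defaults, computed
analytically from the configuration) keeps the full pipeline fast on one CPU.
Default multipliers: broad-domain↔super-enhancer 4, within-domain SE pairs 5,
promoter-promoter 2, plus broad-domain–promoter 2 and broad-domain–broad-
domain 3 to plant the hub behaviour of broad domains (their elevated
connectivity is a core observed property this pipeline is meant to detect);
everything else 1. PET counts are geometric with mean 4. Because the
enrichment expectation normalizes against the total (multiplier-inflated)
edge count, recovered log2 ratios sit slightly below log2(M) when several
multipliers are planted at once; parameter-recovery experiments therefore
plant a single multiplier.

Expression: one gene per promoter-class node, TSS at the node midpoint.
Genes on broad-domain nodes and genes of promoters directly contacting a
super-enhancer node are cell-specific (high expression in the query type,
exponential noise elsewhere → SPM near 1); the rest are near-uniform across
the 23-type panel (SPM ≈ 1/√23). SNPs: a disease phenotype with per-bp rate
8e-5 × fold (default 5) in E-BD nodes and baseline elsewhere, plus 3 control
phenotypes at baseline everywhere. Contact matrices: Poisson fields
(default 150 bins, λ = 10, optional power-law decay) with planted focal peaks
at fold × local background.

What the generator does *not* emulate: chromatin-state spatial structure
(segments coincide with nodes; real segmentations tile the genome), peak
width/signal correlations, genome-wide contact-decay calibration,
LD structure among SNPs, and replicate/batch noise in expression. Passing
tests therefore demonstrate correctness of the algorithms and recoverability
of planted effects at desk scale — not performance claims on real data, whose
printed headline numbers derive from external datasets and are out of scope.

## Numerical and degenerate-input conventions

BH on an empty p-value list returns empty output; enrichment ratios with zero
observed are −inf, with zero expected NaN; a component of two nodes has
betweenness normalization 0; footprints falling entirely outside the matrix
skip the bin pair (logged); SPM of all-zero genes is undefined (dropped,
logged); orbit clustering on fewer than two nodes is an error. On very small
networks fewer than 7 orbit clusters may exist; absent cluster-score columns
are zero-filled in the feature table.
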