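# Methods

## Problem and model

The pipeline contrasts two architectures by which genes influence many
ageing-related diseases (ARDs), grouped into higher-order clusters (ARCs):
direct GWAS pleiotropy across clusters versus indirect, network-mediated
reach through first-order interactors. All analyses operate on four
unweighted, undirected layers over gene symbols — a protein-interaction
layer (PPI), two coexpression layers thresholded at |r| ≥ 0.90 and ≥ 0.95
(COX90, COX95), and a pathway layer (KEGG), which additionally participates
as a directed acyclic graph in the hierarchy analysis.

### Direct and indirect association metrics

A SNP maps to every gene whose body ± flank (default 10 kb) contains its
position; boundaries are inclusive and all coordinates 1-based. This makes
the ±10 kb edge case unambiguous and keeps the mapping monotone in the
flank. Gene → ARD associations aggregate to ARCs through the cluster map;
ARD-/ARC-pleiotropy are the distinct-trait counts at each level, with
ARC-pleiotropy ≥ 4 classed *high*. ARD-/ARC-interactions count the distinct
traits carried by a gene's neighbours; a gene's own direct hits never
contribute, so the two families are genuinely complementary. Genes absent
from a layer are dropped from that layer's analysis rather than scored 0,
consistent with restricting each analysis to network members.

### Proximity

Distances are unweighted shortest paths (BFS). The bounded transform
`Proximity = 1/(d+1)` maps self-distance to 1 and disconnection to 0, so
proximities can be averaged across disease sets of any size and then
back-transformed (`Distance = 1/P − 1`) to readable units. Shortest-path
proximity is the maximum over the target set (a gene belonging to the set
scores 1 — self-inclusion is deliberate, and trivial to recompute
leave-self-out from the per-target tables); average-path proximity divides
by the full target-set size with disconnected members contributing 0.

### Random walk with restart

Monoplex: steady state of `p = (1−r) W p + r p₀`, `W` the column-normalised
adjacency, restart probability r = 0.7, restart mass shared equally over the
seeds present in the layer. Systems of dimension ≤ 2000 are solved exactly
(dense LU); larger ones by power iteration to an L1 tolerance of 1e−10
(max 1000 iterations). Probability is conserved at every step because the
(supra-)transition matrix is column-stochastic.

Multiplex: layers share the union gene universe; genes missing from a layer
enter as isolated replicas. The coupling is purely τ-driven: an exploring
walker first picks a layer with probability ∝ τ, then moves along that
layer's edges if it picked its current layer and otherwise jumps to its own
replica there. With τ = [1,1,1,1] the exploration mass is split equally
across the four layers. Columns with no edges (isolated replicas) receive a
self-loop before normalisation, so the walker waits there until restart or a
layer jump. Replica scores are aggregated per gene by summation (the
arithmetic mean rescaled back to a probability vector). Seed mass is shared
equally over all seed replicas. The exact coupling scheme and aggregation
are design choices — reference multiplex implementations differ in these
internals — and both are isolated behind `RwrConfig` so alternatives are a
local change. Scores are z-standardised within each seed set; a
zero-variance column yields zeros with a warning.

### Coexpression, Tau, hierarchy

Set coherence is the mean absolute correlation over unordered gene pairs:
the lower triangle of the set's submatrix within a set; between two possibly
overlapping sets, the union of (i) overlap-overlap upper-triangle pairs,
(ii) group-1-only × group-2 pairs and (iii) group-2-only × group-1 pairs,
which counts every pair exactly once (verified against exhaustive pair
enumeration). Self-pairs are always excluded since the diagonal is 1 by
construction. Tissue specificity uses the standard Yanai-style index
`τ = Σ(1 − xᵢ/x_max)/(N−1)`; raw expression by default with an optional
log2(x+1) transform, rows of zeros excluded. Pathway position is the mean of
*finite* directed distances to DAG leaves (out-paths) and roots (out-paths
on the reversed graph); unreachable targets are excluded, and a node that is
itself a root/leaf contributes its own zero distance — excluding it would
leave roots and leaves undefined. Betweenness is unweighted and
unnormalised, reported as a summary only.

### Permutation framework

Each observed set statistic is compared with its mean over 10,000
size-matched random sets drawn without replacement from a declared
background universe (the genes of the relevant layer or matrix). Two-tailed
empirical p-values use the add-one rule on absolute deviation from the null
mean, so p ∈ [1/(n+1), 1]; a directional option exists but the symmetric
two-tailed rule is the default. Bonferroni family sizes are always declared
by the caller (16 for four groups × four layers, 4 for the per-column
hierarchy and Tau families, 10 for pairwise tests among five groups) —
different analyses legitimately use different families, so nothing is
inferred. Group-versus-group comparisons use two-sided Wilcoxon rank-sum
tests (midranks for ties), appropriate for the strongly right-skewed
discrete interaction counts.

### Prediction

Feature tables hold per-gene connectivity to each target (8 ARC or 57 ARD
columns) for four metric families — shortest-path proximity, average-path
proximity, neighbour counts, RWR — per layer or aggregated. The configured
grid instantiates 47 datasets: 4 metrics × 4 networks × 2 modes (32),
per-network integrations across metrics (8), per-metric integrations across
networks for the three path/count metrics (6), and one multiplex-RWR
dataset; the across-network RWR integration is superseded by the multiplex
run. In aggregations, genes absent from a layer get the metric's
disconnected value (0); optional presence-indicator columns are off by
default so single-metric aggregate widths stay at 8 × layers.

The classifier is a balanced random forest: each of `n_trees` decision
trees trains on a bootstrap drawing `n_min` samples with replacement from
every class (`n_min` = minority count), which counters the few-percent
positive rate without reweighting tricks. Evaluation is nested stratified
cross-validation — 10 outer × 5 inner folds and 500 trees at full scale,
with the inner folds tuning depth {None, 10, 20} × features-per-split
{sqrt, log2} by AUC. Every gene's probability score is out-of-fold; AUC is
computed on the pooled scores. Candidates are non-positive genes scoring
above 0.5, ranked by score with lexicographic tie-break.

## Synthetic studies

The generator emulates every input of the real-data mode at desk scale and
is fully deterministic given the config (single `numpy` generator seeded
from `StudyConfig.seed`, default 42). Fixed study dimensions follow the
target design: 57 ARDs in 8 clusters, 30 tissues. Desk-scale choices, made
once: 1,200 genes on 22 chromosomes with inter-gene gaps above twice the
mapping flank (so planted SNPs map back exactly); 12 associated genes per
ARD drawn disjointly (one ARD per gene unless the pleiotropy rate, default
0.15, adds a second from another cluster); planted sets of 60 ageing-like
and 60 pleiotropic-like genes.

Planted structure: pleiotropic-like genes carry direct hits in ≥ 4 clusters,
attach to the interaction layer by a single edge, occupy the bottom level of
the pathway DAG (leaf distance 0), coexpress weakly (|r| ≈ 0.08) and express
in one dominant tissue (50-fold, τ ≈ 0.98). Ageing-like genes get extra
interaction-layer edges to disease genes of six distinct clusters, a tight
coexpression module (|r| ≈ 0.93), moderate coexpression with disease modules
(≈ 0.40), and near-uniform expression (3% CV, τ ≈ 0.06). Disease genes form
per-cluster coexpression modules at ≈ 0.915 so the 0.90 threshold keeps them
and the 0.95 threshold mostly removes them. The interaction layer is
preferential-attachment (m = 3) over non-peripheral genes, reproducing hub
structure without copying real topology; the pathway DAG is layered
(depth 6, edges only between consecutive levels), so acyclicity and the
depth bound hold by construction.

What the generator does *not* reproduce: real degree distributions or
edge densities, annotation bias, correlated noise between layers, or
partial overlap between ageing and disease sets (planted sets are disjoint
and the ageing set is never directly GWAS-associated). One known artifact:
because ageing-like genes connect to disease modules only below the
coexpression thresholds, they form their own component in the COX layers,
where an exactly-zero diffusion score becomes a perfect class marker —
per-layer AUC rankings on synthetic data therefore do not mirror real-data
rankings, and passing tests demonstrate correctness of the machinery and
recovery of planted directions, not real-data effect sizes.

## Numerical and runtime choices

Exact linear solves below dimension 2000 and a shared LU/sparse-LU
factorisation across seed sets make the 65-seed-set runs cheap; power
iteration covers larger graphs. Permutation draws loop a seeded generator
(identical seed ⇒ identical null). Default analysis and acceptance runs use
the 1,200-gene study, 10,000 permutations, and a light forest (200 trees,
single-cell grid, 5 outer folds) — the full 500-tree nested grid is
available through `evaluate_classifier` arguments. Degenerate inputs are
handled explicitly: empty target sets and sub-pair gene sets yield missing
values with warnings; unknown chromosomes are skipped with a warning;
cyclic "DAG" input raises naming a cycle; zero-variance score columns
standardise to zeros with a warning; ties at the candidate threshold break
by score then gene id.

## Limitations

SNP-to-gene assignment is proximity-only (no LD, eQTL or chromatin
contact); layers are unweighted; no degree-preserving edge-rewiring nulls
(nulls permute gene labels, matching the permutation design); the KEGG
hierarchy is analysed on the merged global DAG, not per pathway; the
synthetic coexpression matrix is block-structured rather than drawn from a
generative expression model.
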