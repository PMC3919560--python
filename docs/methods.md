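# Methods

This note records the models, defaults and design decisions behind
`mirmodules`, in the spirit of a statistical-software methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Association matrix

Correlations are Spearman's rank correlation (average ranks for ties)
between each miRNA and each mRNA over the intersection of sample ids;
fewer than 3 matched samples is an error. When expression contains missing
values, correlations fall back to pairwise-complete samples with a
configurable minimum (default 3); below the minimum, and for zero-variance
features, the cell is flagged missing and later integrates to 0. The fast
path (no missing data) rank-transforms rows once and computes the whole
correlation matrix as a product of standardized rank matrices.

Integration keeps negative correlations with a predicted site and positive
correlations without one; all other cells — conflicts, exact zeros,
missing — become 0. The rationale: seed-mediated binding predicts
repression, so a negative correlation with a site is direct evidence and a
positive correlation without a site is admissible downstream (indirect)
evidence, while the other two combinations contradict the binding model.
No magnitude threshold is applied at this stage; neutralized conflicts
simply contribute nothing to the bicluster objective. Identifiers are
whitespace-trimmed, matched case-sensitively, and duplicates are an error
rather than being averaged.

## Bicluster search

The objective is the arithmetic mean of association values over the
sub-matrix; with the sub-matrix area fixed, minimizing the mean maximizes
the count and magnitude of negative cells. Seeds are fixed-size
(default 5 miRNAs × 20 mRNAs — about half the miRNA budget and a small
fraction of the mRNA budget); module budgets default to 10 miRNAs and 250
mRNAs, approximating the mean number of miRNAs predicted to target an mRNA
and the mean number of targets per miRNA.

Simulated annealing uses a swap move (replace one random member row or
column, 50/50, with a random outside one — this keeps the area fixed),
Metropolis acceptance on the score change, and geometric cooling
(factor 0.95, 200 moves per temperature, stop at 1e-3 by default). The
initial temperature is calibrated from ~100 probe moves so that roughly
80% of early uphill moves are accepted. The best state visited is kept
and then *polished* by alternating exact refinement: for a fixed row set
the optimal column set is exactly the k columns with the smallest column
sums, and vice versa, so alternating the two updates descends to a
coordinate-wise optimum in a few sweeps. The polish step removes the
occasional leftover junk row/column that annealing freezes in. Each
discovery round takes the best of `n_restarts` (default 3) independent
anneals.

Expansion is deterministic: candidate miRNAs are ranked by mean
association to the seed mRNAs and added while strictly negative (up to the
miRNA budget); mRNAs are then admitted best-first from either arm — most
negative mean association to the module miRNAs for the direct arm, most
positive for the indirect arm — until the shared mRNA budget is reached.
The budget is shared between arms because the source description is
ambiguous about whether the 250-row threshold covers the indirect arm;
interleaved best-first admission makes the split data-driven. Candidates
of the wrong sign are never admitted, and an optional magnitude floor
(`min_mean_association`, default 0 = unthresholded) guards against
chance-level admissions in noisy data. All ties break lexicographically by
feature id, so expansion — and with fixed seeds the entire discovery run —
is bitwise reproducible.

Between rounds the default `seed-exclusion` mask sets previously seeded
cells to +1 in a search-only copy of the matrix (maximally repulsive to a
minimizer); expansion always reads the unmasked matrix, so modules may
overlap, which the visualization assumes. A `value-damping` policy
(multiply used cells by 0.5) is available. Discovery stops early with a
warning once the best remaining seed has a non-negative score. The number
of rounds defaults to 100 independent seed+expansion rounds; returned
modules are sorted by ascending score.

## Cooperativity

For a miRNA family or genomic cluster, every mRNA with ≥1 predicted site
for a member receives its target count `k` and the *maximum inverse*
correlation — read as the minimum signed correlation over targeting
members, applied uniformly even when all candidates are positive.
Correlations default to the raw (pre-integration) matrix restricted to
predicted-target pairs; a flag switches to the conflict-zeroed matrix.

The trend statistic ρ is Spearman's rank correlation over **all**
(k, aggregated correlation) points, with average ranks over the heavily
tied counts. Per-level medians are also computed — they are the red trend
points of the scatter display — but ρ is deliberately not computed on the
medians: for a 3-member class the median-based ρ could only take the
values ±1, ±0.5, 0, which is far too coarse to rank against a permutation
null (ties would make the empirical p grossly conservative). ρ is flagged
undefined with fewer than 3 populated levels or fully tied correlations.

Significance: 100 (configurable) uniform random miRNA subsets of the same
size, drawn from all matrix miRNAs (including members of other real
groups), each re-profiled; `p = (1 + #{ρ_null ≤ ρ_obs}) / (1 + n_perm)`
(the add-one estimator avoids p = 0; zero exceedances at 100 permutations
reports as 1/101 ≈ 0.0099). Null draws with undefined ρ never count as
≤ observed, which is conservative. Note the min-aggregation itself induces
a negative trend under the null (a minimum over more draws is smaller);
the same-size permutation null absorbs exactly this bias.

Genomic clusters are built by single-linkage: two loci link when on the
same chromosome within a 10 kb window (gap measured between interval
boundaries, strand ignored) or when they share a host gene; transitive
closure via union-find; only clusters of ≥2 members are kept, named after
the member first in genomic order.

## Enrichment and evaluation

Term p-values are upper-tail hypergeometric probabilities via
`scipy.stats.hypergeom.sf(n-1, U, N, S)`. The universe is the association
matrix's mRNA set (respectively miRNA set for family/cluster enrichment),
not the genome — enrichment is relative to what the analysis could have
selected. Raw p-values are reported by default, matching the convention of
listing per-module top terms; Benjamini–Hochberg q-values are optional.
Modules are labelled by the top term of the combined direct + indirect
mRNA sample (the indirect arm carries downstream functional signal);
modules with no annotated members are labelled `unannotated`, and the
top-10 term list is retained per module.

The permuted-label baseline shuffles the association matrix's row and
column labels (value grid untouched), reruns discovery with identical
configuration, and compares top-term p-value distributions by a one-sided
Mann–Whitney U on −log10 p (the comparison test is a package choice).
Note that label permutation of the *association matrix* leaves bicluster
scores unchanged by construction — only the mapping from cells to
identifiers (and hence annotation coherence) is destroyed. Degrading the
scores themselves requires permuting upstream of integration, so that
correlations misalign with target flags; the test suite exercises both.

Validated-pair density = unique validated (miRNA, mRNA) pairs falling
inside modules divided by the total cell area the modules cover (sum of
per-module |miRNAs| × |mRNAs|); the fold is the ratio of real to
permuted-baseline density.

## Visualization

Overlap similarity uses the max-size denominator; the min denominator
would inflate the similarity of a small module nested in a large one, and
`1 − s` under the max denominator satisfies the triangle inequality, which
the MDS projection needs (the union/Jaccard denominator is available as an
option). The mRNA side uses direct ∪ indirect arms. Classical (Torgerson)
MDS double-centers squared distances, eigendecomposes, clips negative
eigenvalues (non-Euclidean residue) to zero, and takes one dimension per
side — miRNA overlap on X, mRNA overlap on Y. Sign convention: the entry
of largest magnitude on each axis is made positive, so coordinates are
reflection-stable and independent of input order.

Bubble radius maps the top-term enriched fraction linearly onto
`(r_min, r_max]` (defaults 0 and 1, i.e. radius = fraction, with a tiny
positive floor so every bubble is drawable); a palette of `k` colours
yields `k²` (perimeter, area) pairs, assigned to terms in order of first
appearance, with overflow terms sharing an "other" colour under a logged
warning. Z-order ranks modules by decreasing total size so small modules
draw on top. Module graphs export to GraphML with edge sign class
(direct = negative/red, indirect = positive/green), weight = |association|
and sign-specific magnitude thresholds standing in for the interactive
sliders of a GUI.

## Synthetic data

The generator uses a latent-activity linear-Gaussian model: each planted
module has a per-sample activity `a ~ N(0,1)`; member miRNAs follow
`+a + σε`, direct mRNAs `−e·a + σε`, indirect mRNAs `+e·a + σε`
(effect `e` = 1, noise σ = 0.1 by default); background features are
independent `N(0,1)`. A linear-Gaussian signal was chosen over copula
alternatives because its Spearman correlation is analytically predictable
from the Pearson value, easing oracle checks. Target flags are TRUE for
planted direct pairs minus a false-negative rate (default 0.1) plus
background pairs at a false-positive rate (default 0.02), echoing the
error profile of real prediction databases. Planted categories cover each
module's arms at configurable purity (default 0.8); validated pairs are
sampled inside planted modules at 10× the background rate (0.05 vs
0.005). Cooperative groups share a latent activity; a target with `k`
targeting members is generated at correlation `c_k = min(0.95, |e|·k)`
to it, so the per-level median trend is linear with slope ≈ the per-miRNA
effect `e`.

What the generator does *not* emulate: platform/batch effects, non-linear
regulation, mRNA–mRNA co-expression outside modules, realistic GO term
size distributions, or overlap between modules. Passing tests therefore
demonstrate correctness and recoverability of the method under its own
model assumptions — not performance on real tumour or immune-cell data.

## Benchmark problem sizes

Chosen as the package's standard test-bed:

* default module benchmark: 200 miRNAs × 2000 mRNAs × 40 samples, 5
  planted modules (6 miRNAs, 30 direct + 10 indirect mRNAs, noise 0.1),
  discovered with the 0.2 admission floor appropriate for this noise
  level;
* evaluation benchmark (permuted baseline, validated pairs): 120 × 800,
  8 planted modules, discovered with an mRNA budget of 60 matched to the
  planted arm sizes — with unthresholded expansion a much larger budget
  admits chance-level positive background columns that dilute
  density-based evaluation;
* cooperativity benchmark: one 8-member group with per-miRNA effect 0.1
  and 500 targets among 100 miRNAs × 800 mRNAs; background predicted-
  target density 0.1 ≈ 10.6/n_mirnas, the mean number of predicted
  targeting miRNAs per mRNA reported for human — at much sparser
  densities random same-size groups populate fewer than 3 target-count
  levels and the permutation null degenerates;
* calibration: 200 random groups of 8 on a structure-free 150 × 1500
  matrix at the same target density.

## Known limitations

* The SA schedule guarantees only local optimality (plus coordinate-wise
  optimality from the polish step); the exhaustive-agreement rate is
  measured, not proven.
* The empirical p-value resolution is bounded by 1/(n_perm+1); "<0.01"
  style reporting at 100 permutations means zero exceedances.
* Overlapping planted modules and correlated background are outside the
  generator's model; recovery metrics on such structure are untested.
* GO terms are flat sets: no ancestor propagation or evidence filtering.
* The bubble chart is static; interactive querying is out of scope.
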