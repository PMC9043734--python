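# Methods

This note documents the models behind each `yartsa` module, the assumptions
of the synthetic-data generator, the numerical choices that matter, and the
problem sizes the test suite and `scripts/acceptance.py` use.

## The study system the package targets

Caterpillar fungus is harvested across four regions of the
Himalaya–Hengduan–Tibetan-Plateau arc (labelled QTP, Hengduan, Himalaya and
Transition throughout). The host moths carry strong geographic genetic
structure — region-endemic monophyletic clades and isolation-by-distance —
while the fungal parasite is comparatively uniform (about 1% mean pairwise
divergence versus about 5% in the hosts). Origin authentication therefore
works on the host: build a multi-locus reference phylogeny of samples with
known provenance, place an unknown sample onto it by maximum likelihood,
and read origin off the placement.

## Synthetic-data generator

Every analysis in the package is exercised end-to-end on data from
`yartsa.synthdata`, whose defaults encode the study scale: 90 samples, 14
loci of 600 bp each, 5% target host divergence, parasite branch lengths at
0.2x the host's (≈1% divergence), locus dropout at 0.057 per sample-locus
(≈13.2 of 14 loci retained on average, with a floor of one locus per
sample), and a host-switch probability of 0.1 per parasite cladogenesis.

**Host tree.** Forward birth–death simulation from a crown pair
(λ=1, μ=0.2, arbitrary time units), conditioned on 90 surviving tips; when
the extant count first reaches n, pendant branches are extended by the
waiting time to the next (never realized) event, which makes the expected
Yule crown height exactly Σ_{k=2..n} 1/(λk) — the property the tests check.

**Geography.** Tip coordinates evolve along the tree as a *valley
stepping-stone* process: the landscape is a set of discrete habitat patches
(4 per region, scattered 1.6° around the region centroids, drawn once per
seed), a lineage diffuses within its current patch (σ²=0.2 deg²/time with
mean reversion 0.35/time toward the nearest patch), and colonizes another
patch at rate 0.4/time with an exponential distance kernel (scale 400 km).
Region labels are nearest-centroid (Voronoi) assignments; the centroids
span the real ~2000 km collection arc. Setting the reversion and jump rate
to zero recovers plain Brownian motion.

This dispersal model was chosen over pure Brownian motion deliberately:
under BM, genetic and geographic distances co-scale at *every* radius, so
the within-cluster Mantel correlation can never exceed the global one. The
real system's signature — IBD strongest among samples within a few hundred
km, diluted globally — requires geographic distance to saturate at the
landscape scale while divergence keeps accruing, which is exactly what
bounded patches plus rare colonization produce. The parameters were
calibrated once, structurally, so the generator reproduces the qualitative
regime of the study (all four regions occupied, region-endemic monophyla,
a significant but modest global IBD signal, local dominance of the radius
sweep); they are not per-analysis knobs. Note the inherent trade-off: the
more concentrated the local signal, the weaker the global Mantel — a
property the real data share (the study's own global geographic Mantel was
weak). What passing tests show is that the *methods* recover the signals
the generator plants; they do not certify effect sizes on real data, where
sampling design, marker choice and real landscape resistance all differ.

**Climate** is linear in latitude (20 − 0.8·lat °C, Gaussian noise 0.5) —
a deliberate confound with geography, as in real mountains; the slope is
configurable so tests can decouple the two.

**Parasite system.** The parasite tree starts as a copy of the host
topology. Each host cladogenesis event (oldest first) triggers, with
probability `p_switch`, a host switch implemented as a time-constrained
SPR: one daughter lineage is pruned and re-grafted at the same age onto a
uniformly chosen contemporary lineage. Switches therefore erase recent
codivergence first, leaving congruence concentrated in deep branches —
the pattern the cophylogeny sweeps are designed to localize. The
association stays one-to-one (each mummified sample yields one moth and
one fungus), and branch lengths are finally scaled by 0.2.

**Sequences.** Sites are i.i.d. per locus under JC69 (HKY85 with κ=2 and
unequal frequencies available), evolved down the tree from stationary root
draws. A global rate scaler is found by bisection on the closed-form
expected pairwise p-distance so the realized mean divergence lands on the
target; the same scaler converts the time tree into the
substitutions/site "molecular" tree that placement uses (the analog of the
ML reference tree a real analysis would estimate). No indels, selection or
among-site rate variation are simulated.

## Distances

Genetic distances are uncorrected p-distances (JC correction optional)
over concatenated loci with *pairwise* deletion of '-'/'N' sites — market
samples are degraded, and column deletion would discard most sites. JC
correction at p ≥ 0.75 is an error rather than ∞, forcing an explicit
choice of uncorrected distances for saturated data. Geographic distance is
great-circle (haversine, R = 6371.0088 km): at the 2000-km scale a planar
reading of lat/lon is ill-defined; an equirectangular planar option exists
behind a flag for fidelity checks. Landscape resistance is a least-cost
path on an 8-connected raster lattice (edge weight = mean endpoint cell
cost × great-circle center distance, Dijkstra) — a stand-in for
circuit-theory resistance, which needs a published cost model the synthetic
setting does not have.

## Mantel tests and the two sweeps

The Mantel statistic is the Pearson correlation of upper-triangle entries;
the null simultaneously permutes rows and columns of the second matrix
only. The estimator is (1+k)/(1+N) so p is never 0; for n ≤ 7 with enough
requested permutations all n! orderings are enumerated and the p-value is
exact. The default tail is one-sided "greater" because the IBD and
codivergence predictions are directional. Degenerate (zero-variance)
matrices raise an error rather than returning NaN.

The **radius sweep** cuts a complete-linkage clustering of the geographic
matrix at 100..2000 km (complete linkage so a cut at h bounds cluster
*diameter* by h — the natural reading of "samples within 500 km of each
other"), re-running the Mantel test inside each cluster with ≥5 members
(below that the test is degenerate: fewer than 10 distance pairs) and
reporting mean/min/max r per radius, averaging r across clusters.
Degenerate clusters are skipped and counted rather than erroring the curve.

The **time-slice sweep** cuts an ultrametric tree at increasing ages; the
branches crossing each age define the lineages alive then, each
represented by its medoid tip under the comparison matrix (ties broken
lexicographically), and the sliced-tree patristic matrix (2·(MRCA age − t))
is correlated with the comparison submatrix on the medoids. Ages with
fewer than 4 lineages are flagged and skipped. The medoid construction is
one defensible reading of a "time-sliced" statistic; the alternative
(aggregating full within-clade distance blocks) is deliberately not mixed
in.

## Cophylogeny tests

ParaFit keeps PCoA axes with eigenvalue > 1e-8 × the largest and computes
trace(DᵀD), D = Cᵀ A B; its null redraws each parasite's host links
independently (uniform over host subsets of the same size, preserving row
totals), with exact enumeration when all rows are single-link and the
assignment space fits in the permutation budget. Per-link F1 statistics
are leave-one-link-out drops, re-scored against the same permutations.
PACo instead applies the Cailliez additive constant before embedding
(the two original methods' conventions differ; following each avoids
hybrid behavior), replicates rows per link, and superimposes the parasite
configuration on the host's by closed-form least-squares Procrustes
(translation, scaling, rotation via SVD); its null shuffles the rows of A,
and small m² is evidence of congruence, so the p-value counts permutations
with m² ≤ observed. One-to-many associations are supported (shared fungal
haplotypes); both tests record which distance kind (sequence or patristic)
fed them.

## Placement and origin assignment

`tree_loglik` is Felsenstein pruning with site-pattern compression and
per-pattern rescaling; transition probabilities come from the spectral
decomposition of the symmetrized generator, exact for any branch length.
Placement computes, once per reference tree and query, "below" and
"outside" conditional likelihoods for every edge, after which each pendant
length evaluation is a 4-term spectral contraction — this is what makes
1400 leave-one-out placements affordable. The pendant branch is optimized
by golden-section search on [1e-8, 2.0] to tolerance 1e-6 at the edge
midpoint; the split halves are not re-optimized (a deliberate,
oracle-testable simplification of EPA-style placement; per-edge
log-likelihoods match a graft-and-rescore of the whole tree to 1e-8).
Loci absent from the query are excluded from the comparison for all taxa
rather than padded, so log-likelihoods are comparable across edges. Ties
in the best edge break toward the root, then by canonical edge id.

The leave-one-out "correct-placement confidence" is the LWR mass on the
merged edge created by pruning the tip plus that node's child edges (the
original attachment edge no longer exists after pruning; its neighborhood
inherits correctness). The assignment rule is: below an LWR floor of 0.5
the query is unassigned; otherwise nested (best edge strictly inside a
labelled clade) or sister (best edge is the clade's root edge) placements
assign the clade's label, the innermost containing clade deciding the
relation; conflicting labels on the best edge raise an ambiguity error.
With a known truth label, a wrong assignment is a false positive and an
unassigned query whose truth is an assignable label is a false negative.

## Biogeography

DEC's state space is the non-empty region subsets of size ≤ K (default
K=2 — configurable up to all four regions; real analyses should set K from
prior range knowledge). Anagenesis gains area a at rate d × |range| (all
region pairs equal: the four regions are pairwise adjacent along the arc)
and loses a non-last area at rate e; cladogenesis allows narrow sympatry,
subset sympatry and 1-vs-rest vicariance at weight 1 each, plus founder
jumps at weight j ∈ [0,3] under +J (j=0 reduces exactly to DEC). The root
prior is uniform over states. Fitting is Nelder–Mead from 5 jittered
starts in log space (j through a logistic transform), simplex tolerance
1e-6, AIC = 2k − 2lnL. A forward simulator (Gillespie anagenesis +
weighted cladogenetic draws) generates test data.

Stochastic character mapping uses the sample-level single-region chain: an
equal-rates Mk model (closed-form transition probabilities, ML rate by
bounded scalar optimization, uniform root prior), node states drawn from
pruning partials, and branch histories by uniformization at rate kq with
cached jump-count and step distributions. The default of 3000 maps keeps
the Monte-Carlo s.e. of mean transition counts small; the mean directional
count matrix is reported in full, with any display thresholding left to
presentation.

## Problem sizes and tolerances

The test suite generates everything it needs at run time. The heavier
checks use: 500 replicates for Mantel null calibration (n=30, 199
permutations); 50 generator seeds for IBD recovery; 50 power +
300 type-I replicates per cophylogeny condition (n=10, 199 permutations);
100 leave-one-out replicates per locus count for the sensitivity curve on
the default 90-sample data; 20 founder-heavy simulations (25 tips) for the
DEC/DEC+J comparison; and 3000 endpoint-conditioned branch histories
against the exact uniformization expectation (5% relative tolerance).
Exact oracles (Mantel enumeration, ParaFit enumeration, graft-and-score,
ancestral-state enumeration, DEC state/event enumeration) are matched at
1e-8 to 1e-12. `scripts/acceptance.py` runs the full default study plus a
30-tip placement-sensitivity subsample and 20 leave-one-out assignments.

## Known limitations

- The generator plants clean signals: no sequencing error, contamination,
  alignment error, within-locus rate variation or missing-at-random
  violations; real market samples are messier in all these ways.
- Placement fixes reference branch lengths and model parameters; no
  re-optimization, heuristic preselection or Γ rate categories.
- Resistance distance is least-cost-path, not circuit theory.
- DEC-based stochastic mapping (counting range-change events under the
  fitted DEC model itself) is not implemented; the mapping analog uses the
  Mk single-region chain.
- The time-slice statistic is one defensible construction among several;
  results at deep slices rest on few lineages and are flagged accordingly.
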