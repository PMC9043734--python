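# yartsa

Origin authentication and cophylogeography toolkit for caterpillar-fungus
host moths.

Caterpillar fungus ("yartsa gunbu") is the mummified larva of a *Thitarodes*
ghost moth parasitized by *Ophiocordyceps sinensis*. It is one of the most
valuable wildlife commodities in the world, and its price and sustainability
depend on where a sample was collected — yet traded samples carry no
provenance. Because the host moths show strong geographic genetic structure
(regional endemic clades and isolation-by-distance across the
Himalaya–Hengduan–Tibetan-Plateau arc) while their fungal parasite is nearly
uniform, the *host* genome is the natural substrate for tracing origin.

`yartsa` implements the computational side of that programme as a tested,
reusable library:

- **Likelihood placement** of query samples on a fixed multi-locus reference
  tree: exhaustive per-edge maximum likelihood with an optimized pendant
  branch, likelihood weight ratios (LWRs), jplace-compatible output, and the
  monophyly/sister **origin-assignment rule** (a query is called "Himalayan"
  if its best placement is nested within, or sister to, a labelled Himalayan
  clade).
- **Loci-sensitivity experiment**: leave-one-out re-placement using 1..L
  loci, measuring how placement confidence grows with locus count.
- **Isolation-by-distance** machinery: genetic (p/JC), great-circle,
  climatic, least-cost (resistance) and patristic distance matrices; Mantel
  tests with exact enumeration for small n; signal-localization sweeps
  across geographic cluster radius (100–2000 km) and phylogenetic time
  slices.
- **Cophylogeny tests**: ParaFit (global + per-link) and PACo (Procrustes
  m²), each with its original permutation null.
- **Discrete-range biogeography**: DEC and DEC+J likelihoods with ML
  fitting and AIC comparison, plus equal-rates Mk stochastic character
  mapping with mean region-to-region transition counts.
- A seeded **synthetic-data generator** that emulates the study system
  (~90 samples, 4 regions, 14 loci with dropout, ~5% host vs ~1% fungal
  divergence, host switching on deep branches) so the entire pipeline is
  exercisable and testable without any data download.

## The core statistics

For a query with sequences at a subset of loci and a reference tree T with
fixed branch lengths, the placement engine computes for every edge e the
maximized log-likelihood `lnL_e = max_λ ln P(data | T + query attached at
the midpoint of e with pendant length λ)` under JC69/HKY85, and reports
likelihood weight ratios

    LWR_e = exp(lnL_e − max_e' lnL_e') / Σ_e' exp(lnL_e' − max_e' lnL_e')

The Mantel statistic is the Pearson correlation r of the off-diagonal
entries of two distance matrices, with a permutation null that relabels one
matrix; ParaFit's global statistic is trace(DᵀD) with D = Cᵀ A B linking
parasite (C) and host (B) principal coordinates through the association
matrix A; PACo's m² is the residual sum of squares after least-squares
Procrustes superimposition of the parasite configuration on the host's. The
DEC(+J) model evolves geographic ranges by per-area dispersal (d),
extirpation (e) and — under +J — founder-event jumps (j) at cladogenesis,
compared by AIC.

## Worked example

```python
from yartsa import synthdata, distances, ibd, placement

bundle = synthdata.simulate_bundle(synthdata.SimConfig(seed=42))
D_gen = distances.genetic_distance(bundle.alignment)
D_geo = distances.haversine_matrix(bundle.samples).submatrix(D_gen.labels)
res = ibd.mantel_test(D_gen, D_geo, n_perm=999, seed=0)
print(f"IBD Mantel r = {res.r:.2f}, p = {res.p:.3f}")

tip = "s050"
pruned, _ = bundle.host_molecular_tree.prune_tip(tip)
query = {l: bundle.alignment.data[l][tip] for l in bundle.alignment.loci_of(tip)}
placed = placement.place_query(
    pruned, bundle.alignment.subset_samples(pruned.tip_labels), tip, query
)
print(f"best edge LWR = {placed.best_lwr:.3f}")
```

prints

```
IBD Mantel r = 0.05, p = 0.031
best edge LWR = 1.000
```

— the simulated system shows a modest but significant global
isolation-by-distance signal (locally it is much stronger; see the radius
sweep), and a withheld sample is re-placed on its original edge with
essentially complete confidence.

The same analyses are available from the shell:

```bash
yartsa simulate --out data --seed 42
yartsa distances --kind genetic --loci-dir data/loci --out gen.csv
yartsa distances --kind geo --samples data/samples.csv --out geo.csv
yartsa mantel --d1 gen.csv --d2 geo.csv --perms 999 --seed 0
yartsa pipeline --config cfg.yaml --out run1   # the full study in one call
```

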