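# ecophylo

Comparative analysis of ecological niche evolution on phylogenies, with a
matched synthetic data generator for end-to-end validation.

## The scientific problem

Given a time-calibrated phylogeny for a clade and, per species,
habitat-suitability rasters, occurrence records, trait measurements, and
protein-coding sequences, a standard comparative study asks:

1. **How much do species' niches overlap?** Suitability rasters are
   normalized to probability surfaces *p* and compared with Schoener's
   statistic, *D* = 1 − ½ Σ|p_A − p_B|, which is 1 for identical niches
   and 0 for niches with no shared habitat.
2. **Does overlap decay or grow with divergence time?** For each internal
   node of the tree, the mean *D* over all cross-clade tip pairs whose most
   recent common ancestor is that node is regressed on node age. The
   intercept (overlap at the moment of speciation) and slope are tested
   against a Monte Carlo null that permutes species across the tips, and the
   fitted line classifies the dominant geographic mode of speciation:
   intercept > 0.5 → sympatric; otherwise slope ≤ 0 → parapatric, slope >
   0 → allopatric.
3. **Do traits carry phylogenetic signal?** Blomberg's *K* compares the
   observed trait variance structure to Brownian-motion expectation on the
   same tree (*K* ≈ 1 under Brownian motion, → 0 with no signal), with a
   tip-shuffling permutation test. Multivariate trait tables are summarized
   by PCA before testing.
4. **How did discrete states evolve?** A one-parameter Mk model
   (all transitions at rate *q*) is fitted by maximum likelihood with
   Felsenstein pruning; marginal ancestral states and stochastic character
   maps (exact endpoint-conditioned sampling by uniformization) give
   posterior node states and the number of independent origins of a focal
   state.
5. **What selective regime do the genes show?** Pairwise Ka/Ks by the
   Nei–Gojobori (1986) pathway-counting method with Jukes–Cantor
   correction, aggregated to gene level, classifies genes as purifying
   (Ka/Ks < 1), neutral (≈ 1), or positive (> 1). Genes shorter than
   300 bp and pseudogenes are excluded.

The package implements all five analyses plus a generator that simulates
a birth–death chronogram, spatially autocorrelated environmental layers,
Brownian niche evolution over those layers, occurrence sampling, discrete
and continuous traits, and codon sequences under a GY94-style process — so
every estimator can be checked against known ground truth.

## Worked example

```python
import ecophylo as ep
from ecophylo.simulate import (SimConfig, simulate_tree, simulate_landscape,
                               simulate_trait, simulate_codon_alignment)
from ecophylo.niche import SuitabilityGrid, overlap_matrix
from ecophylo.molevol import gene_kaks_summary

cfg = SimConfig(seed=42, n_species=12, n_codons=400)
tree = simulate_tree(cfg)
env, truth, rasters = simulate_landscape(tree, cfg)
grids = [SuitabilityGrid(sp, vals) for sp, vals in rasters.items()]

d = overlap_matrix(grids, basis="range")
print("D(sp1, sp2) =", round(d.get("sp1", "sp2"), 4))

res = ep.AgeOverlapModel(tree, d).fit(n_perm=999, seed=1)
print(f"intercept = {res.intercept:.4f} (perm. p = {res.p_intercept:.4f})")
print(f"slope     = {res.slope:.4f} (perm. p = {res.p_slope:.4f})")
print("inferred mode:", res.mode)

x = simulate_trait(tree, "continuous", cfg, seed=7)
kr = ep.k_permutation_test(tree, x, n_perm=999, seed=2)
print(f"Blomberg's K = {kr.k_stat:.4f}, p = {kr.p_value:.4f}")

states = simulate_trait(tree, "discrete",
                        SimConfig(seed=42, n_species=12, mk_rate=0.15), seed=8)
fit = ep.Mk1Model(tree, states).fit()
maps = fit.stochastic_maps(n_maps=1000, seed=3, focal_state=1)
print(f"Mk1 rate q-hat = {fit.q:.4f}")
print(f"mean origins of state 1 = {maps.origin_counts.mean():.2f}")

aln = simulate_codon_alignment(tree, cfg, seed=9)
g = gene_kaks_summary(aln)
print(f"gene Ka/Ks = {g.ratio:.4f} ({g.selection_class})")
```

Output:

```
D(sp1, sp2) = 0.8769
intercept = 0.9528 (perm. p = 0.0010)
slope     = -0.0406 (perm. p = 0.0010)
inferred mode: sympatric
Blomberg's K = 0.5045, p = 0.0450
Mk1 rate q-hat = 0.1764
mean origins of state 1 = 1.26
gene Ka/Ks = 0.1521 (purifying)
```

With the default narrow niche-evolution rate the simulated clade keeps
highly overlapping niches, so the regression recovers a high intercept —
the sympatric signature — from its own generator.

## Command-line pipeline

Every analysis stage is also a subcommand of the `ecophylo` CLI, driven by
a YAML config (see `ecophylo.pipeline.RunConfig`); stages can run
individually or end-to-end, from either a synthetic config or on-disk
inputs (Newick tree, raster CSVs, occurrence and trait tables, FASTA):

```bash
ecophylo simulate --seed 5 --out data/          # write a synthetic dataset
ecophylo run-all --config config.yaml --out results/
ecophylo kaks    --config config.yaml --out results/
```

Outputs are plain CSV/JSON plus a `summary.txt`; a config hash and
per-stage seeds make every run reproducible byte-for-byte.

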