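# Methods

Models, assumptions, numerical choices, and the realism and limits of the
synthetic data generator. Nothing here is an empirical claim about any
real clade; all quantitative statements refer to quantities computed by
this package on simulated data.

## Niche overlap

**Statistic.** Schoener's D between probability surfaces,
D = 1 − ½ Σ_cells |p_A − p_B|, after normalizing each suitability raster
to sum to 1. D is invariant to any common positive rescaling of a raster
(such as the generator's per-species max rescaling), symmetric, and
bounded in [0, 1].

**Numerical choice.** D is evaluated through the exact identity
1 − ½ Σ|a − b| = Σ min(a, b) (valid for unit-sum surfaces), divided by the
mean total mass ½(Σa + Σb) to absorb the ~1e-16 residual left by floating
point normalization. This makes the estimator exact at its defined
endpoints — exactly 1 for identical surfaces and exactly 0 for surfaces
with disjoint support — and changes nothing else beyond the 1e-16 level.
Inputs are validated to sum to 1 within 1e-6.

**Bases.** `range`: D over the full normalized rasters. `point`: for each
pair, suitabilities restricted to the union of the two species' occupied
cells and renormalized over that union; this reduces to the range basis
when both species occupy every cell. The point basis is this package's
concrete, exactly computable rendering of occurrence-anchored overlap.

**Filters.** Occurrence thinning collapses records to one per
`block × block` cell window (deterministic: the record nearest the block
center, ties to the lowest index), an idempotent analogue of distance
thinning on a grid. Suitability models are retained only when AUC is
strictly above the threshold (default 0.8); grids without an AUC are an
error, not silently retained.

## Age–overlap regression and speciation mode

For every internal node of a binary ultrametric tree, the response is the
mean D over all cross-clade tip pairs whose MRCA is that node; the
predictor is node age. Ordinary least squares gives intercept (expected
overlap at speciation time zero) and slope. Significance comes from a
Monte Carlo permutation null: species identities are permuted jointly
across rows and columns of the overlap matrix (equivalently, shuffled
across tips), node means are recomputed, and
p = (1 + #{|stat_perm| ≥ |stat_obs|}) / (n_perm + 1), two-sided, for the
slope against 0 and the intercept against 0.5. The classification rule is
intercept > 0.5 → sympatric; otherwise slope ≤ slope_tol → parapatric,
else allopatric (strict inequality at 0.5; `slope_tol ≥ 0` widens "no
trend", default 0).

Assumptions: the tree is binary and ultrametric within tolerance (node
ages come from tip depths; violations raise with the offending tips
named); node means are treated as exchangeable observations, ignoring
their shared-pair covariance — the permutation null, not the Gaussian OLS
machinery, carries the inference.

## Phylogenetic signal

**Blomberg's K.** With C the Brownian variance–covariance implied by the
tree (shared path length to the root), the phylogenetically corrected mean
is the GLS mean â = (1'C⁻¹x)/(1'C⁻¹1), and
K = [(x−â)'(x−â) / (x−â)'C⁻¹(x−â)] / [(tr C − n/(1'C⁻¹1)) / (n − 1)].
The implementation factors C once per tree and evaluates all permutations
of the tip-shuffling null vectorized; it matches a dense GLS oracle and
`phytools::phylosig` to ~1e-12. The permutation p-value is one-sided for
high K by default, p = (1 + #{K_perm ≥ K_obs}) / (n_perm + 1).

**PCA.** Trait tables are standardized per column (ddof = 1) and
decomposed by SVD; component signs follow the convention that the largest
absolute loading is positive. Zero-variance columns are an error naming
the column.

## Mk1 model, ancestral states, stochastic mapping

**Model.** k states, all transitions at one rate q. The transition
probability has the closed form
P(t) = 1/k + (1 − 1/k)·e^(−kqt) on the diagonal and
1/k − (1/k)·e^(−kqt) off it, avoiding matrix exponentials.

**Likelihood and fitting.** Felsenstein pruning with a uniform root prior
(states are averaged at the root; `ape::ace` sums instead, so its
log-likelihood is exactly log k higher — verified in the test suite). The
rate is fitted by bounded scalar maximization over log q on
[1e-8, 100/tree height]; a monomorphic trait returns the q = 0 boundary
with a flag rather than a spurious interior optimum.

**Marginal ancestral states.** Standard up–down (outside) pass; node
posteriors match exhaustive enumeration over all internal-state
assignments to 1e-10 on small trees.

**Stochastic maps.** Joint node states are sampled exactly from the
conditional distribution (root to tips, conditioning on the sampled
parent), then each branch path is sampled conditional on its endpoints by
uniformization with rate Λ = (k−1)q; the uniformized jump chain has the
closed form R^m[x,y] = 1/k ± (1/k or 1/k·(k−1))·(−1/(k−1))^m, so
endpoint-conditioned jump counts are drawn without matrix powers.
Self-transitions are discarded when counting real substitutions. Origins
of a focal state on one map = transitions into that state plus one if the
root is in it.

## Ka/Ks (NG86)

Universal genetic code (from Biopython's table 1). Per codon, the
synonymous site count is Σ_positions (synonymous one-step changes)/3;
changes to stop codons are not synonymous, and the denominator stays 3, so
S + N = 3 per codon. Differences between two codons are resolved by
averaging substitution pathways over all orderings of the differing
positions, excluding any pathway through a stop codon (if all pathways are
blocked the codon pair is skipped and counted). S̄ is the mean of the two
sequences' site totals; pS = Sd/S̄, pN = Nd/N̄; distances are
Jukes–Cantor corrected, d = −¾ ln(1 − 4p/3), undefined at p ≥ 0.75.
Gap-containing codon pairs are skipped (pairwise deletion) and reported;
internal stops are an error; a terminal stop is skipped. Gene-level Ka and
Ks are means over all defined pairwise values; the gene ratio is
mean(Ka)/mean(Ks). Genes under 300 bp and pseudogenes are excluded with an
explicit reason. Selection classes: ratio > 1 positive, < 1 purifying,
within 1e-6 of 1 neutral, undefined otherwise.

**Neutral anchor.** Under simulation with equal synonymous and
nonsynonymous rates per site — ω = 1 *and* no transition/transversion
bias (κ = 1) — the mean NG86 Ka/Ks over replicates sits slightly below 1
(≈ 0.95 at 0.1 substitutions/codon): the stop-exclusion asymmetry removes
more synonymous than nonsynonymous opportunity, a documented small-sample
property of pathway counting, not a bug. With κ = 2, NG86's unweighted
site counting misclassifies the transition excess and the ratio drops to
≈ 0.83; neutrality checks therefore use κ = 1, where the estimator's own
assumptions hold. The default simulation κ remains 2 because real
sequences are transition-biased.

## Synthetic data generator

All parameters live on the frozen `SimConfig` dataclass; defaults below.

| Parameter | Default | Units / meaning |
|---|---|---|
| `seed` | 0 | master RNG seed; stage seeds are derived deterministically |
| `n_species` | 20 | extant tips |
| `birth`, `death` | 1.0, 0.2 | birth–death rates (events / lineage / time) |
| `grid_shape` | (40, 40) | raster rows × cols (abstract lattice, no CRS) |
| `n_env_layers` | 19 | environmental axes (as in standard bioclim sets) |
| `env_smooth_sigma` | 3.0 | Gaussian smoothing radius, in cells |
| `bm_rate_niche` | 0.05 | Brownian rate of niche optima (env SD² / time) |
| `niche_breadth` | 2.0 | Gaussian niche SD per axis (env SD units) |
| `n_occurrences` | 200 | occurrence draws per species |
| `mk_states`, `mk_rate` | 2, 0.5 | discrete trait states and Mk1 rate (/time) |
| `bm_rate_trait` | 1.0 | continuous trait Brownian rate (/time) |
| `omega`, `kappa` | 0.2, 2.0 | dN/dS and transition bias of the codon process |
| `n_codons` | 300 | alignment length in codons |

**Tree.** Birth–death from a root split of two lineages, run until the
(n+1)-th birth; that event is discarded and its time taken as the present,
so exactly n tips are extant and the age distribution is correct for
n-conditioned processes (pure-birth root age matches the harmonic-sum
expectation in tests). Extinct lineages are pruned and unifurcations
suppressed; extinction of the whole clade triggers rejection (capped at
1000 draws). Branch lengths are time; the tree is ultrametric by
construction.

**Landscape and niches.** Layers are white noise convolved with an
isotropic Gaussian kernel (wrap mode) and standardized — spatially
autocorrelated like bioclim surfaces, but stationary and independent
across axes, which real climate variables are not. Niche optima evolve by
Brownian motion from each layer's mean; suitability is a product of
per-axis Gaussian responses computed in log space and rescaled per species
so the best cell is 1 (prevents underflow with 19 axes; D is invariant to
it). Occurrences are drawn with probability proportional to suitability —
no sampling bias, detection error, or spatial clustering beyond the
landscape's own autocorrelation.

**Sequences.** GY94-style codon process: rate ∝ κ^[transition] ×
ω^[nonsynonymous], stop codons forbidden, uniform sense-codon frequencies,
Q normalized so branch lengths are expected substitutions per codon.
Simulation is exact (Gillespie per codon site), not an approximation.
Limits: no rate variation among sites or branches, no codon-usage bias,
no indels.

**Realism summary.** The generator reproduces the *structure* a
comparative study consumes (ultrametric tree, autocorrelated rasters,
heritable niches, state-dependent sequences) with known ground truth, and
is deliberately free of the observational noise (georeferencing error,
uneven sampling, alignment error) that real datasets carry. Conclusions
about estimator behaviour transfer; absolute effect sizes do not.

## Numerics, determinism, and problem sizes

- All randomness flows through `numpy.random.default_rng`; pipeline stages
  derive independent seeds as sha256(master:stage) mod 2³¹, so stage
  results do not change when other stages are toggled.
- Permutation p-values always use the add-one estimator
  (1 + #extreme)/(n_perm + 1), which is never 0 and is exact for the
  discrete null.
- Defaults of 1000 permutations / 1000 stochastic maps balance Monte Carlo
  error (~0.007 SD on a p ≈ 0.05) against runtime; tests use smaller
  values where only correctness, not resolution, is at stake.
- Validation sizes (enumeration oracles on ≤ 5–8 tips, 200-replicate
  recovery studies, 500-dataset calibration checks at n_perm = 199) are
  this package's own choices, sized so the whole suite runs in well under
  a minute on one CPU.

## Limitations

- The age–overlap regression inherits the method's known caveats: node
  means are correlated, extinction erases old low-overlap nodes, and the
  0.5-intercept rule is a convention, not a derived threshold.
- Blomberg's K assumes Brownian motion as the reference model and a
  correctly measured ultrametric tree; measurement error inflates
  apparent signal loss.
- The Mk1 model forces equal rates among all state pairs; the fitted q is
  a boundary value for monomorphic traits and weakly identified near
  saturation (q·height ≫ 1).
- NG86 is a counting method: it ignores transition bias and codon
  frequencies by design and is conservative for highly diverged pairs
  (JC correction undefined at p ≥ 0.75).
- The point-basis overlap and the thinning rule are exact grid analogues
  of field procedures that are usually defined in continuous geographic
  space; absolute values are not comparable across grid resolutions.
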