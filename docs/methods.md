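# Methods

This note records the models, conventions and design choices behind
`divnull`, in the order the pipeline applies them.

## Data model and reconciliation

The analysis joins four artifacts: a two-season site × species
presence/absence table, a species × trait table with *declared* trait types,
a rooted branch-length phylogeny, and an optional replacement map routing
species that could not be placed in the tree to a proxy tip from the same
clade. Trait types are never inferred from the data — a numeric column can
be a categorical code, and Gower semantics differ — so they come from a
`#type` header row or an explicit argument. Every site must have at least
one wet-season species (the change statistic divides by wet-season values);
an empty dry assemblage is legal and gives change −1.

Proxy placement is many-to-one: when two species share a proxy tip they
contribute a single tip to PD. Branch length cannot be attributed twice, and
treating the pair as two tips would double-count the proxy's terminal
branch. All substitutions are reported in a `substitutions.csv` audit table.

## Functional diversity

Gower dissimilarity averages per-trait terms: 0/1 mismatch for categorical
traits, `|xi − xj| / range` for continuous ones. Two conventions matter:

- the range is the **full species pool's** range, not the assemblage's, so
  FD values are comparable across sites and seasons;
- missing values drop out of the per-pair mean (pairwise-complete
  reweighting); a pair with no jointly observed trait is an error rather
  than a silent zero.

UPGMA merges at half the average inter-cluster distance, so tip-to-tip
cophenetic distance equals the average distance itself. Ties are broken
deterministically (the pair whose lexicographically smallest member is
smallest merges first) so dendrograms are identical across platforms. The
implementation is cross-checked in the tests against an independent
agglomeration (scipy's average linkage) on tie-free inputs.

The dendrogram is built **once** from the full pool; assemblage FD is the
branch-length sum of the induced subtree, never a re-clustering of the
assemblage's own submatrix. Pruning makes FD monotone under species addition
by construction; re-clustering does not, and per-assemblage dendrograms are
read as subtrees of the pool dendrogram (the convention of the standard
dendrogram-diversity routine in vegetation-analysis software). A
re-clustering variant (`recluster=True` / `--recluster`) is retained for
sensitivity analysis only.

## Phylogenetic diversity

PD is the same induced-subtree branch-length sum on the phylogeny. Both
kernels share one convention: the subtree is rooted at the assemblage's most
recent common ancestor and the path above it is excluded, so a singleton has
zero diversity and FD and PD are directly comparable statistics. The exact
root convention of the packaged routines used historically for such analyses
is not fixed in the literature, so an `include_root` switch exposes the
alternative; all shipped results use the MRCA convention.

Pruning collapses pass-through (degree-2) nodes and sums their incident edge
lengths, preserving patristic distances exactly; PD is invariant under
pruning (property-tested).

Internally both statistics evaluate through one edge × tip incidence matrix:
an edge belongs to the MRCA-rooted induced subtree of a k-tip assemblage
exactly when its below-edge tip count c satisfies 0 < c < k. A whole null
ensemble then evaluates as a single matrix product, which is what makes
1000-replicate ensembles on 12 sites a sub-second operation.

## The null model

Per site, the pool is wet ∪ dry. One replicate is one uniform shuffle of the
pool: wet null = first x species (x = observed wet SR); the remaining y
species (y = observed dry-only count) are forced into the dry null; the dry
null is completed to the observed dry SR with species from the wet null.
Taking the leading entries of the shuffled wet prefix implements "sample
without replacement from the wet null" exactly — the prefix's internal order
is itself uniform — and lets the whole ensemble vectorise. "Reordered 1000
times" is read as 1000 independent shuffles; duplicate permutations are
permitted (astronomically unlikely for realistic pools, harmless for small
ones).

Each site draws from its own RNG stream, seeded by the master seed plus a
CRC32 of the site identifier, so adding or removing a site never perturbs
other sites' draws. Identical seed and inputs give a bit-identical ensemble.

## Inference

Paired comparisons use the classical one-sample t on per-site differences
(df = n − 1, two-sided). A Welch correction is undefined for a paired
design; where a source describes seasonal comparisons as both "paired" and
"Welch", the paired reading is the mathematically coherent one, and an
unpaired Welch variant (`welch_test`) is provided separately. Observed
values are paired with the per-site null **mean**; the per-site null median,
the SES `(observed − null mean)/null SD`, and the observed value's quantile
within the null distribution are reported alongside, so a rank-based reading
is always available.

Redundancy regressions fit `response ~ SR + SR²` and `response ~ SR` by OLS
and delete the quadratic term first. The comparison statistic is **AICc**
(Gaussian likelihood, error variance counted as a parameter), and the
quadratic term is retained only when it improves AICc by more than 2 units —
the conventional "substantial support" threshold. Two deliberate departures
from plain minimum-AIC selection, both driven by the n ≈ 12 regime: plain
AIC retains a spurious quadratic in roughly a fifth of pure-noise fits at
this sample size (the asymptotic P(χ²₁ > 2) ≈ 0.16 problem, worse under the
finite-sample F(1, 9) tail), and AICc alone still over-selects at ~7%;
with the evidence margin the false-curvature rate is ~3%, while strong true
curvature is still detected essentially always. Functional redundancy is
flagged only for a *retained, negative* quadratic coefficient. Leverage and
studentised-residual maxima are reported as the residual-diagnostics
summary.

Moran's I uses inverse-Euclidean-distance weights with a zero diagonal,
expectation −1/(n − 1), and the kurtosis-corrected randomisation variance
with a two-sided normal p-value. Weights are unstandardised by default; the
`row_standardise` switch reproduces the classical R implementation (tested
against `ape::Moran.I` to 1e-8).

## The synthetic-data generator

The generator emulates the *structure* of a two-season stream survey — not
any real taxon set: 12 sites, a 31-species pool on a unit-height Yule tree,
wet SR uniform on 5–15, dry SR uniform on 2–min(12, wet SR), a per-site
turnover count ~ Binomial(3, 0.3) of dry-season insertions (≈ one per site,
with roughly two-thirds of sites showing some turnover), and — by default —
no species that is dry-exclusive pool-wide: insertions are drawn from the
union of wet assemblages across sites.

Traits mix a Brownian-motion realisation on the tree with independent
Gaussian noise as `√w·BM + √(1−w)·ε`, both standardised; under this
square-root mixing the between-tip correlation scales linearly with the
signal weight `w`, like Pagel's λ rescaling a phylogenetic correlation
matrix. Categorical traits threshold an analogous latent variable into 2–3
quantile bins. The default `w = 0.5` encodes traits with appreciable but
imperfect phylogenetic signal (morpho-functional homoplasy is the norm in
the motivating system).

Assembly scenarios:

- **A (neutral)** — uniform wet draws, uniform dry-season survival. This is
  exactly the null model's generative process conditional on the richness
  and turnover counts, so observed-vs-null tests must reject at the nominal
  rate; the acceptance suite verifies 5% ± 3 points over 1000 datasets.
- **B (environmental filtering)** — wet membership weighted by
  `exp(−s·(trait − site optimum)²)` on the first continuous trait.
- **C (limiting similarity)** — wet assemblages built by sequential
  furthest-trait (maximin Gower) selection; dry-season removals strike the
  functionally most redundant member (log-odds falling in the species' min
  trait distance to the rest), one Gumbel-noise event at a time.
- **D (clustered loss)** — dry-season removals strike the species most
  distant from a randomly chosen focal clade member (log-odds rising in
  patristic distance).
- **CD (both)** — C-type and D-type removal events alternate at random, and
  the resulting dry set is then refined by stochastic member swaps —
  richness- and turnover-preserving — accepted when they raise
  `FD − 0.1·PD` of the assemblage. The refinement is the package's
  operationalisation of both mechanisms acting *on the assemblage at once*:
  with a realistic richness decline there are only ~4 removal events per
  site, and splitting them between two antagonistic greedy rules starves
  both signals, while jointly extreme dry sets (trait-overdispersed AND
  clade-concentrated) do exist in the subset space because trait and
  phylogenetic distances are nearly independent axes at moderate signal
  weights.

Effect-size knobs (`filter_strength`, `similarity_strength`,
`clustering_strength`, `cd_tradeoff`, `cd_refinement_steps`) are explicit
config scalars, calibrated once and frozen in the `ScenarioConfig` defaults;
at these defaults scenario C elevates dry FD with ~0.9 power, scenario D
depresses dry PD with ~0.97 power, and CD recovers the joint signature in
~0.97–0.98 of datasets (200-dataset batches, 1000-replicate nulls).

What the generator does **not** emulate: detection error (presence/absence
is taken as truth), abundance structure, phylogenetic uncertainty, real
trait distributions, or any specific taxon set. Passing tests therefore
demonstrate that the pipeline's statistics are calibrated and its planted
mechanisms recoverable under the study's data structure — not that any
particular field dataset will show these effects.

## Problem sizes and determinism

Default analysis size (12 sites × 31 species × 1000 replicates, FD + PD)
runs in about a second; the acceptance script's largest computation (1000
neutral datasets through the full chain) takes a few minutes on one CPU.
Every random choice flows from an explicit seed through
`numpy.random.Generator` streams; reports, CSVs and ensembles are
byte-identical across reruns with the same seed, and the JSON manifest
written with every run bundle suffices to reproduce it.

## Known limitations

- FD and PD conventions (MRCA-rooting, pool-range Gower normalisation,
  pruning-not-reclustering) are choices among defensible alternatives; the
  switches exist precisely because the historical literature is not explicit
  about them.
- The paired t on 12 sites assumes approximate normality of per-site
  differences; the reported SES and null quantiles support nonparametric
  cross-checks but no permutation-test variant is built in.
- AICc-with-margin selection trades a little power against curvature for a
  controlled false-curvature rate; with many more sites plain AICc would be
  adequate.
- Moran's I uses the normal approximation to the randomisation
  distribution, which is rough below ~10 sites.
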