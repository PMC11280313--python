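# Methods

## Study design emulated by the generator

`oatnp.synthdata` simulates a two-group serum metabolomics comparison:
knockout (KO) vs wildtype (WT) mice, by default 6 vs 6 animals (the smaller
4 vs 4 design is a parameter), with ~1000 annotated metabolites per panel.
Abundances follow

    abundance(m, s) = baseline_m × FC_m^[group(s)=KO] × exp(ε),   ε ~ N(0, σ²)

on the raw scale.  Baselines are log-uniform over 1e2–1e5 arbitrary counts
(three orders of magnitude, the dynamic range typical of untargeted panels;
no abundance scale is otherwise implied by the design).  The default noise
σ = 0.3 on the natural-log scale gives per-metabolite CVs around 30%,
representative of between-animal serum variation.  Planted fold changes
default to the four vitamin effects that motivate the downstream analyses:
biotin 4.55, thiamine 2.06, pyridoxal 1.86, pyridoxamine 2.32.  Missing
values can be injected at a configurable rate (default 0) as below-detection
truncation to zero; median scaling is available but off by default, since
vendor panels may arrive either way and the package does not assert one.

Named NP metabolites come from a packaged pool of 83 real natural-product
names with representative SMILES and chemical-class labels (flavonoids,
flavones, isoflavones, anthraquinones, hydroxybenzoates, cinnamates,
indoles, bile acids, steroid ketones, vitamins, small organic acids).  Some
structures are regiochemically approximate; downstream code relies only on
class-level similarity, never on exact regiochemistry.  Pathway annotations
map chemical classes onto Metabolon-style super/subpathways (vitamins into
"Cofactors and Vitamins" with per-vitamin subpathways); filler metabolites
draw superpathways from a fixed frequency table dominated by Amino Acid and
Lipid, as real panels are.

One global seed drives independent substreams (metabolome / databases /
plates) via `np.random.default_rng([seed, purpose])`, so each stage is
reproducible in isolation.

What the generator does **not** emulate: LC–MS acquisition artifacts
(retention-time drift, in-source fragmentation, peak-picking errors),
correlated metabolite blocks, batch effects, or heavy-tailed platform
noise.  Passing tests therefore demonstrate the correctness of the
computations under the stated sampling model, not robustness to platform
pathology.

## Database matching

Names are normalized by NFKC folding, lower-casing, punctuation and
whitespace collapse, and repeated stripping of trailing salt/counter-ion/
hydrate suffixes from a packaged editable list (`data/salts.txt`); the rule
exists so that e.g. "Thiamine hydrochloride" matches thiamine.  Matching is
exact on normalized primary names and synonyms; when both sides carry
SMILES, equality of the stereo-insensitive structure key (InChIKey first
block) is a fallback, because NP databases disagree on stereo annotation.
No fuzzy matching is performed by default — precision over recall, since a
false NP call propagates into every enrichment.  Union counts count each
metabolite once regardless of how many sources it matches.

The three-source overlap model has two modes: a sampled mode (an `overlap`
fraction interpolates between fully shared and mutually exclusive
membership, with per-source membership probabilities), and a pinned mode in
which exact per-source significant-match counts are realized by solving for
source-subset counts (triple overlap maximized, remainder into pairwise
overlaps, capacity-checked; infeasible targets raise).  Pinned scenarios
are generated noise-free: with zero within-group variance the Welch test
is deterministic (planted effects give p = 0, nulls give p = 1), so the
bookkeeping counts reproduce exactly rather than within a false-positive
coin flip.

## Preprocessing and differential statistics

The fixed order is quantile normalization → log transform → pareto scaling.

* Quantile normalization maps every sample column onto the vector of
  cross-sample rank means; ties receive the mean of the reference values at
  the tied ranks.  The transform is idempotent.
* The log transform (base 2 by default) imputes zeros with half the
  smallest positive value of the matrix; negative input is an error.
* Pareto scaling maps each metabolite row to (x − mean)/√sd with the
  sample (ddof = 1) standard deviation; constant rows map to zero.  Pareto
  scaling is *not* idempotent (rescaling changes the sd), which is expected
  and tested.

Significance uses Welch's unequal-variance t-test on log abundances —
untargeted panels are strongly heteroskedastic, and group sizes of 4–6 do
not justify pooling variances.  Two-sided p-values; the degenerate
zero-variance case returns p = 1 for equal means and p = 0 otherwise.
Fold changes are raw-scale ratios mean(KO)/mean(WT): reported effect sizes
like 4.55 are ratios, and computing them after log/pareto processing would
destroy that interpretation.  Volcano categories: elevated iff p < 0.05 and
FC ≥ 1.1; decreased iff p < 0.05 and FC ≤ 0.9.  The negative fold-change
line sometimes printed as "−0.9" is treated as a display convention for
decreased compounds; the cut points act on the ratio scale.  The p < 0.05
boundary is strict; p-values are not multiplicity-adjusted by default
(matching the plain p < 0.05 criterion the analysis is built around), with
Benjamini–Hochberg available behind `adjust="bh"`.

Heatmap sample ordering uses average-linkage agglomeration on Euclidean
distances between processed sample columns (scipy linkage; ties resolve by
column index, making leaf order deterministic).

## PLS-DA

A from-scratch NIPALS PLS2 with a one-hot two-column class response, both
blocks centered (no scaling — the input is already pareto-scaled).  Weight
vectors are unit norm; after convergence (tolerance 1e−10, max 500
iterations) the sign is fixed by making the largest-magnitude weight
coordinate positive, so runs are bit-reproducible.  X is deflated by t pᵀ
and Y by t cᵀ per component.

"Variance explained" is reported on **X**: the fraction of the centered X
sum of squares removed by each component's rank-one reconstruction,
fraction_c = (tᵀt)(pᵀp)/SSX.  This is the quantity metabolomics scores
plots annotate; because the design could equally be read as a PCA overlay,
`pca_variance_explained` provides the PCA fractions as a comparison view.
Requesting more components than the rank of centered X raises with advice
rather than silently returning degenerate components.

## Pathway enrichment

The fold-enrichment score (k/m)/((n−k)/(N−m)) compares the significant
fraction inside a pathway with the significant fraction outside it.
Conventions: k = 0 → 0; n = k → +∞ (kept, rather than capped, so ranking
semantics survive; the infinity is explicit in output); m = N is undefined
and raises.  The universe N is all panel metabolites annotated at the
chosen level by default, with restriction to NP matches available — both
modes are legitimate reads of the design, so both ship and the choice is
logged.  Direction filtering (elevated-only / decreased-only) restricts
which categories count as significant, used for elevated-compound
subpathway rankings.  No p-value is attached to the score; an optional
hypergeometric tail probability is provided behind a flag as a clearly
marked extension.  Ranking is score-descending with ties broken by k then
pathway name.

## Chemical space

Descriptors come from RDKit's full 2D descriptor list, pinned by an
explicit manifest committed at `src/oatnp/data/descriptor_manifest.txt`
(210 names for the toolkit version developed against); molecules are
canonically renumbered before computation because a few descriptors are
atom-order sensitive.  Unparseable SMILES become per-compound failure
records and the run continues.

Correlated-property pruning is greedy in manifest order: constant columns
drop first (undefined correlation), then any column with |Pearson r| ≥ 0.9
against an already-retained column drops.  Property importance is the
absolute standardized class-mean difference (pooled-sd denominator) — a
transparent surrogate for an otherwise unspecified dimensionality
reduction, chosen because it selects exactly what a two-class projection
can use; ties break by name.  The default retained-property count for the
projection is 6, matching the number of properties such diagrams typically
display; both the count and the ranking method are configurable.

The anchored projection places each property as an anchor in the unit disc
and embeds compound i at Σ_j z_ij · anchor_j over z-scored properties.
Anchors are optimized by gradient ascent on a force-field objective —
same-class pairs attract (negative mean squared distance), different-class
pairs repel (negative mean inverse distance, kernel 1/(d + 1e−3)) — with
backtracking line search and projection into the unit disc, so the
objective is non-decreasing; iteration stops below 1e−6 improvement or at
1000 steps.  The objective depends only on pairwise embedded distances and
is therefore rotation-invariant, which is tested.  This objective is this
package's documented interpretation of radial anchored-projection methods,
not a claim about any particular implementation's internals.

## Chemical-similarity enrichment

Fingerprints are RDKit path-based (substructure-hashed) binary
fingerprints of length 2048; Tanimoto similarity is |A∩B|/|A∪B| with the
both-empty case defined as 0.  Clustering is label-first: compounds with a
chemical-class (ontology) label group by label; unlabeled compounds attach
to the cluster with the highest mean Tanimoto similarity if that mean
reaches 0.5, else remain unclustered; clusters below the minimum size of 3
(the smallest chemically meaningful group) dissolve.  A pure-similarity
mode (average-linkage hierarchical clustering on 1 − Tanimoto, cut at 0.5)
serves label-free inputs.  Clusters are disjoint by construction.

Each cluster's member differential p-values are tested against
Uniform(0, 1) with a two-sided one-sample Kolmogorov–Smirnov test.  The D
statistic is computed directly from the ECDF sweep; the p-value uses the
exact small-sample distribution (scipy `kstwo`) for n ≤ 25 and the
Kolmogorov asymptotic (`kstwobign`) above.  A cluster is significant at
KS p < 0.05 (the default threshold, logged).  The summary reports, per
cluster, size, KS p, −log10 p, the exact median of member XLogP values
(members lacking the descriptor are excluded with a warning), and the key
compound — the member with minimum differential p, ties broken by larger
|log fold change| then name.  The coverage statistic counts compounds in
significant clusters.

## In vitro assays

Binding: normalized shift (test − control)/control; a compound is a binder
iff shift ≤ −0.05 — the boundary counts as a binder, since a downshift *of*
−0.05 is the significant displacement.  Calls are invariant to rescaling
both fluorescences by a common positive factor.

Uptake inhibition: percent inhibition = 100 × (1 − (uptake − background)/
(vehicle − background)); raw values are kept uncapped.  Dose–response
fitting uses a four-parameter logistic, bottom + (top − bottom)/(1 +
(IC50/c)^hill), by bounded least squares: bottom ∈ [−10, 30]%, top ∈
[70, 110]%, IC50 within the dosed range extended one dilution step either
side, hill ∈ [0.1, 5].  The default series is a 2 mM top dose diluted
2-fold across 10 points; the dilution factor and replicate handling are
explicit configuration, not assumptions.  A response spanning < 20
percentage points is flagged "not converged" instead of fitted — a 4PL on a
flat curve only launders noise into an IC50.

## Problem sizes and numerical choices

Simulation-backed checks use panels of 200–1000 metabolites, 100–200
replicate panels for power and calibration estimates, 100 random instances
per statistical-engine comparison, and 2000 simulations for KS type-I
calibration — sizes at which the Monte-Carlo error is well below the
margins being asserted while the whole suite stays interactive.  NIPALS
tolerance is 1e−10; engine-vs-oracle agreement is asserted at 1e−8;
exact-formula identities (enrichment score, fold-change recovery at zero
noise) at 1e−12 relative.

## Known limitations

* Synthetic panels have independent metabolites; real serum metabolomes are
  block-correlated, which inflates effective false-positive counts in ways
  these tests do not measure.
* Name matching is exact-after-normalization; typos or vendor-specific
  naming conventions in real annotation tables will reduce recall until the
  salt list or synonym tables are extended.
* The anchored-projection objective is non-convex; different seeds can
  reach different (rotationally inequivalent) optima.  The seed is part of
  the configuration and the objective trace is exposed.
* The 4PL fit assumes a monotone response; biphasic dose–response curves
  are flagged as non-converged rather than modeled.
* PLS-DA is restricted to two classes by design; multi-class extensions
  (and VIP scores, O-PLS) are out of scope.
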