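# Methods

This note documents the models and procedures saprocom implements, the
choices made where the design was genuinely open, what the synthetic
generator does and does not emulate, and the package's known
limitations. It states no result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Survey data model

A survey is a set of deadwood logs, each with a tree species (Norway
spruce, silver fir or European beech), projected coordinates (E, N in
metres) and an exposure-start calendar year. Emergence records are
`(log, calendar year, species, count)`; analyses run on *years since
exposure*, `calendar_year − exposure_start`. The one-year offset
between the spruce experiment (exposed spring 2013, first sample =
exposure year 0) and the beech/fir experiment (exposed autumn 2011,
first sample 2013 = exposure year 1) is therefore data carried by the
design table, not a special case in code. A calendar year with no
sampling at all is represented by absent rows; because the trend models
treat exposure year as numeric, the gap needs no imputation or
zero-filling.

## Trait handling

Traits are declared in a sidecar schema: type (`continuous`, `ordinal`,
`categorical`) plus two flags, *standardize by body length* and
*natural-log transform*. Standardization precedes the log transform, so
a doubly flagged trait becomes `log(x / body_length)`; the rationale is
that size-corrected ratios are the quantity for which a log transform
is meaningful. Collinearity is reported as pairwise Pearson r and
variance inflation factors, `VIF_j = 1/(1 − R²_j)` from regressing each
continuous trait on the others; constant traits are excluded and
perfect collinearity reported as infinite.

Gower distance handles the mixed types: continuous traits contribute
`|x_i − x_j| / range`, ordinal traits are first rank-scaled to [0, 1],
categorical traits contribute 0/1 mismatch, and the distance is the
mean over traits observed in both species (pairwise deletion). Ranges
are taken over the full species pool, never per assemblage, so
distances are comparable across assemblages and years.

## Phylogeny

Trees are handled through dendropy; polytomies and non-ultrametric
branch lengths are allowed. Community species missing from the
reference phylogeny are grafted as sisters of their closest known
relative: a new node is inserted ε above the relative's tip and both
tips hang from it with pendant length ε, preserving every pre-existing
tip depth and pairwise distance. The default ε = 0 places the grafted
species exactly at its relative's position (zero distance to it), which
is legitimate for mean-pairwise-distance work; a positive ε is
available for diagnostics that dislike zero distances. Cophenetic
distances are path lengths computed from tip and
lowest-common-ancestor depths and are cross-checked in the tests
against a brute-force path-enumeration oracle.

## Functional–phylogenetic blend and the SES null

The blended distance is
`d_ij(a, p) = (a·P_ij^p + (1 − a)·F_ij^p)^(1/p)` with both source
matrices rescaled by their own maxima, `a ∈ [0, 1]` the phylogenetic
weight and `p = 2` by default (the canonical quadratic form; `p` is
exposed because the blend family is defined for any positive exponent).
Assemblage dispersion is presence-based mean pairwise distance;
abundance weighting is deliberately not the default because the
upstream convention is unweighted.

The null model shuffles species labels on the distance matrix over the
full pool while keeping each assemblage's species count fixed. A
uniform label shuffle maps an assemblage of k species onto a uniformly
random k-subset of the pool, so the implementation draws null subsets
per distinct k — marginally identical to explicit relabeling and about
two orders of magnitude cheaper; an exhaustive mode enumerates all
k-subsets on small pools and is tested against the full permutation
enumeration. SES = (observed − null mean)/null sd; a null with zero
spread (e.g. the assemblage is the whole pool) yields a flagged
missing value rather than a number.

## Trend models

All four responses share one structure: tree-species fixed effect,
one penalized cubic P-spline smooth of exposure year per tree species
(basis size 10 by default, second-difference penalty, sum-to-zero
constrained, entered via group indicators), and a low-rank
thin-plate-type radial basis over standardized (E, N) (knots by
k-means, default 30, plus unpenalized linear terms; the bending-energy
penalty is the PSD part of the radial kernel matrix). Families:
negative binomial with log link for counts (θ by alternating profile
likelihood with the smoothing loop) and Gaussian identity for SES-MFPD.

Smoothing parameters (one per smooth) are chosen by minimizing a
Laplace-approximate REML of the working penalized fit; GCV is
available as an option. REML is the default because, in the package's
own calibration experiments, GCV-selected smooths made the Wald tests
visibly anti-conservative under the null, while REML selection brings
the per-smooth null non-significance rate close to nominal. The Wald
test for a smooth truncates the quadratic form to the edf-many
best-determined coefficient directions (rank-truncated pseudo-inverse)
and refers it to chi-square with that many degrees of freedom;
p-values are reported with the conventional star codes (·, *, **,
***). Adjusted R² is fixed on the response scale as
`1 − [Σ(y−μ̂)²/(n−edf_total)] / [Σ(y−ȳ)²/(n−1)]`; agreement with any
particular backend's "adjusted r-squared" is approximate for
non-Gaussian families. Predictions and 95% bands are computed on the
link scale and back-transformed, so count bands are always positive.

The species-richness model adds natural-log abundance as a fixed
covariate (natural log chosen; the base is not identifiable from the
reported analysis) with species number as the response; a flat,
non-significant year smooth then means the species count is explained
by abundance alone. Residual spatial autocorrelation is checked with
Moran's I: residuals averaged per unique location, inverse-distance
weights row-standardized, analytic mean −1/(n−1) and normality
variance, two-sided test.

## Blend-weight scan and trait ablation

The scan re-runs blend → SES → trend model over a in steps of 0.025
(41 points) and selects the a with the highest adjusted R², ties
breaking toward the functional end. Two variance-reduction defaults
matter here, both switchable: the null subsets are drawn once and
reused across the grid, and the smoothing parameters are estimated
once (at a = 0.5) and fixed across the grid. Without them,
permutation and smoothing-selection jitter of order 0.01 in adjusted
R² dominates the between-a differences and makes the argmax unstable
run to run. When per-point draws are requested instead, sub-seeds are
derived from the master seed by counter, so the scan stays
reproducible.

Ablation removes one trait at a time from the Gower computation only
(the phylogenetic matrix is untouched), recomputes SES at the fixed
selected a and refits the trend model; ΔR² = reduced − full, and a
reduction of at least 0.03 is flagged as a substantial loss. The full
model's smoothing parameters are reused for the reduced fits for the
same variance-reduction reason.

### A structural caveat on recovering a purely phylogenetic signal

On simulated communities assembled purely by trait distance, the scan
recovers the functional end (a ≈ 0) essentially always. The mirrored
experiment — assembly purely by phylogenetic distance — behaves
asymmetrically: cophenetic distances on birth–death trees are
heavy-tailed (most pairs diverge near the root), while a Gower matrix
over many traits concentrates near a constant. Under the quadratic
blend, mixing 25–50% of a near-constant functional matrix acts as a
variance-stabilizing compression of the phylogenetic distances and can
*raise* the SES trend model's adjusted R² slightly above the pure
a = 1 model, so the selected a tends to sit at 0.5–0.8 rather than at
the phylogenetic end even when the generating process is purely
phylogenetic. This is a property of max-rescaled p-norm blends
combined with tree-shaped distance distributions, not an estimation
error; the corresponding recovery test documents it. Interpreting a
selected intermediate a as "both components matter" is therefore safe
in the functional direction but should be made cautiously in the
phylogenetic direction.

## Compositional succession

Bray–Curtis dissimilarities are computed on assemblages with at least
four species (spruce year-0 assemblages excluded, since the other tree
species enter the survey at exposure year 1). Non-metric MDS uses
SMACOF with isotonic regression (scikit-learn), best of 20 random
starts by default, no abundance pre-transformation (a Wisconsin/sqrt
option exists but silent auto-transforms would make runs
irreproducible); the winning configuration is centred and rotated to
principal axes so axis 1 carries the largest score variance. Stress is
Kruskal's stress-1.

PERMANOVA decomposes the Gower-centred inner-product matrix with
sequential sums of squares in the stated term order (tree species,
then exposure year), pseudo-F per term, and free permutation of rows
(no strata); p = (1 + #{F* ≥ F})/(1 + n_perm), 999 permutations by
default. The observed statistics are cross-checked against
scikit-bio's one-way PERMANOVA in the tests.

The year segmentation is a conditional-inference-style tree on the
first ordination axis: each node tests independence between score and
year factor with a quadratic form on level-wise score sums,
standardized by the exact permutation mean and covariance, referred to
chi-square at the covariance rank; splitting stops when p exceeds α
(default 0.05, minimum leaf 7). Because the reported year groups are
contiguous runs, the default split search scans cutpoints on the
ordered year axis; an unordered mode enumerating all level
bipartitions is provided for the strict treated-as-factor dialect.

## Temporal niches

Per species, the niche position is the abundance-weighted mean
exposure year over the whole survey and the breadth is the weighted
standard deviation around it, population-weighted (divide by Σn, no
−1 correction) because it describes the dispersion of the observed
individuals rather than estimating a sampling distribution. The ≥ 3
individuals-in-some-year filter only sets a display flag; summaries
are computed for every species.

## Synthetic generator

The generator emulates the survey's structure: 52 logs by default
(10 beech-only, 10 fir-only and 10 mixed beech–fir plots from one
experiment; 12 spruce plots exposed one year later), calendar years
2013–2024 with no sampling in 2020, and a 297-species pool. The
phylogeny is a pure-birth tree (dendropy). Continuous traits follow
Brownian motion with a shared-factor loading (default 0.3) plus an
optional tree-independent species effect; linear measurements are made
multiplicative in body size, so raw lengths correlate strongly through
size while size-corrected ratios stay nearly independent — which is
why the preprocessing standardizes by body length and the collinearity
check then sees moderate VIFs. Categorical traits (decay niche, wood
diameter niche, feeding type, host-tree association) follow a jump
process whose rate sets their phylogenetic signal.

Expected counts are
`λ = exp(β0 + host(s,l) − δ·t) · exp(−(t−μ_s)²/2σ_s²) · filter(s,t)`:
a log-scale host-mismatch penalty (default 4), exponential decay of
the resource pulse (δ = 0.35/yr), a Gaussian temporal niche whose
centre is exponential with mean 3 years and whose breadth grows with
the centre (0.6 + 0.25·μ_s — early species are narrow specialists),
and an early-colonizer filter `exp(−γ·d²)` active for t ≤ 3, where d
is the normalized distance (trait-Gower or cophenetic, configurable,
optionally restricted to named traits) to a randomly chosen
conifer-associated anchor species. Counts are negative binomial
(θ = 1.5). All parameters are returned as ground truth.

What the generator does **not** emulate: wood chemistry or fungal
succession, dispersal between logs, within-season phenology,
trap-level detection error, and species-abundance distributions with
realistic rarity tails. Passing recovery tests therefore show that the
estimators find planted signals of the stated kinds at these problem
sizes — not that the field data contain such signals.

## Problem sizes and numerical choices

Recovery and calibration experiments run at desk scale: 80–120 species
pools, 30 logs, 8 years, 99–149 null randomizations, 50 replicates for
recovery rates, 500 simulations for type-I calibration, 999 shuffles
for null-moment checks. The demo pipeline uses 60 species, 21 logs, 8
years, 199 randomizations. Degenerate inputs are flagged, not
silently dropped: SES with a zero-spread null is missing; assemblages
below two species propagate as excluded rows; an all-zero distance
matrix, a constant PERMANOVA term, or an empty assemblage filter raise
errors. IRLS adds a scale-aware ridge of 1e−8 times the mean squared
column norm for numerical solvability; smoothing parameters are
clamped to e^±18; argmax ties in the scan break toward smaller a.

## Known limitations

No plot-level random effects or temporal autocorrelation structure
(the modelled surveys contain neither); no PCoA/db-RDA or indicator
species analysis; no MNTD or independent-swap nulls (assemblage
membership is fixed by design); the conditional-inference tree
implements the single-covariate case needed here, not the general
multi-covariate framework; and the Wald smooth tests are approximate —
exact backend-specific p-values are not reproducible from any single
reference, which is why star categories, not raw p-values, are the
comparable surface.
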