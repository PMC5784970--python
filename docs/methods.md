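# Methods

## Generation length and the Rspan approximation

Generation length is the mean age of the parents of the current cohort.
The package computes it three ways: the life-table definition
GL = Σ x·l(x)·m(x) / Σ l(x)·m(x); the mortality approximation
GL = 1/(adult annual mortality) + AFR (valid only without reproductive
senescence); and the Rspan method GL = AFR + z·(ALR − AFR), which is the
workhorse because ages of first and last reproduction are often the only
data available.  z is the fraction of the adult lifespan elapsed before
half of the age-weighted lifetime reproduction is achieved; it is a single
global constant (default 0.29, the published cross-mammal value fitted
over 221 species) and is deliberately *not* re-estimated from data — the
point of the constant is comparability across species.  The test suite
verifies the underlying premise on synthetic schedules: with geometric
adult survival and constant fecundity, one shared z reproduces life-table
GL to within 10% provided ALR co-varies with survival, which is exactly
the cross-species situation.

## Database compilation rules

One record = one (species, parameter, source) estimate; point values or
ranges; days/months/years or g/kg; wild/captive/unknown provenance.

* **AFR**: direct estimates preferred; otherwise female maturity +
  gestation, paired within a source when a source reports both, else the
  median maturity plus median gestation as a single candidate.  Ranges
  resolve to the central value.  The median across candidates is converted
  to days and rounded *up* to an integer day.  Male maturity is never used
  alone (it ignores gestation and breeding access, which are what delay a
  female's first offspring).
* **ALR**: maximum longevity proxies ALR (no-senescence assumption); direct
  ALR records, where they exist, pre-empt longevity proxies within their
  provenance class.  Ranges resolve to the *upper* bound — reported
  longevity understates the true maximum, and lower bounds of ranges are
  often life-expectancy-like figures.  Records count as wild only when
  flagged wild; unknown provenance is pooled with captive (precautionary:
  mislabelling captive data as wild inflates GLw).  Wild and captive
  classes never mix.
* **Mass**: median across sources, in grams.

Numerical conventions: 1 year = 365.25 d, 1 month = 365.25/12 d; the AFR
ceiling subtracts a 10⁻⁶-day tolerance first so that a value entered in
months or years cannot gain a spurious day from floating-point round-trip.
Rounding is applied after unit conversion (the alternative — rounding in
the source unit — would make the result depend on the reporting unit).
Species names are normalised (underscores to spaces, case-folded binomial)
on every input path, including Newick tip labels, so trees and tables
join without manual cleaning.

## Phylogenetic eigenvector maps

The rooted ultrametric tree becomes a directed graph (vertices in
preorder; one edge per non-root vertex).  The influence matrix **B**
(tips × edges) has bᵢⱼ = 1 iff edge j lies on the root→tip-i path.
Columns are weighted by w(φ) = ψ·φ^((1−a)/2); a ∈ [0,1] is the steepness
(a → 0: change accrues along edges in proportion to their length,
Brownian-like; a → 1: every edge contributes equally, change concentrated
at divergences), and ψ is a pure scale fixed to 1 during construction (it
rescales all columns uniformly and can affect neither eigenvector
directions nor any downstream selection or prediction; the steepness fit
reports the residual scale under that name).  The weighted matrix is
column-centred and decomposed by SVD; the left singular vectors are the
tip scores: exactly n−1 orthonormal zero-mean eigenvectors for n tips,
ordered by decreasing singular value (early = basal divergences).
Singular values below max(n,m)·eps·s₁ are dropped and the drop logged.
Sign convention: the first element attaining the column's maximum
magnitude (within a 10⁻⁹ relative tie tolerance) is made positive; the tie
tolerance matters because contrast-like eigenvectors contain exact ±x
pairs whose float images differ by one ulp across platforms.

**Steepness fit.** Under the PEM model the trait is Gaussian with
covariance ∝ B_c B_cᵀ.  Projecting the trait onto the eigenbasis gives
independent components with variances σ²s_k², so the profile
log-likelihood is −r/2·ln(RSS_w/r) − Σ ln s_k with auxiliary covariates
(here log10 body mass) as fixed effects, profiled out in the whitened
basis; the intercept is annihilated by the zero-mean eigenvectors and
needs no column.  a is found by bounded one-dimensional search on [0,1]
(`xatol` 10⁻³ standalone, 10⁻² inside LOOCV loops where each evaluation
rebuilds the basis).  A constant trait has a flat likelihood; the fit
returns a = 0 with a warning rather than an arbitrary interior value.
Recovery checks: traits simulated with edge variance ∝ φ give â near 0,
equal-variance edges give â near 1.

**Model selection.** Forward stepwise over the n−1 eigenvectors plus
log10 mass (mass competes as an ordinary candidate; nothing in the
framework privileges it, and the data decide — in practice it enters
first).  AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1) with k the number of
regression coefficients including the intercept; selection stops when no
addition lowers AICc or the correction denominator would reach 1.
Rank-deficient additions are skipped and reported.

**Out-of-sample prediction.** `graph_locations` removes target tips,
collapses the resulting unifurcations by summing edge lengths (the root is
kept even if unifurcating; its constant influence column centres away),
and records each target's attachment edge, the distance from that edge's
rootward origin, and the pendant length.  A target's weighted influence
row carries full weights w(φⱼ) for edges from the root to the attachment
origin and w(d) for the partly traversed attachment edge; centring with
the training column means and projecting through V·S⁻¹ gives its scores.
The pendant branch has no counterpart among basis columns and contributes
nothing to the scores — its variance is unexplainable by construction,
one reason predictions use *prediction* intervals (t-based, residual df,
new-observation variance included) rather than confidence intervals.
These conventions are pinned by two oracles in the test suite: a dense
Gram-matrix eigendecomposition must reproduce basis and target scores,
and a from-scratch normal-equations pipeline must reproduce LOOCV
predictions exactly.  Two caveats document the convention's limits: when
several targets are removed together, each is located independently, so
structure private to a pair of removed sisters is not representable (their
mutual patristic distance is not preserved by re-attachment; everything
else is); and for a = 1 the partial-edge weight w(d) = ψ·d⁰ is
discontinuous at d = 0 — attachment exactly at a vertex (d = 0 or d = φ)
is treated as the vertex itself.

**Branch-length variants.** `point` (the dated tree as supplied), `lower`
/ `upper` (alternative trees built from divergence-time confidence
bounds, tip-set checked), and `equal` (all φ = 1, the
no-reliable-chronogram scenario).  All PEM properties (n−1 eigenvectors,
orthonormality) hold on every variant; scale equivariance — multiplying
all branch lengths by a constant changes nothing downstream — is tested.

## Binning predictors

Bins are half-open intervals on the log10-gram axis; default width 1.0,
origin 0.  The width is a config knob because the source studies never
state theirs; the level-assignment counts reported by the validation
output let a user match a published congeneric/confamilial split
empirically.  Predictions are unweighted means of reference GLw: (a)
congenerics in the focal species' bin, else confamilials in the bin;
(b) congenerics, else confamilials, ignoring mass; and the combined
four-level hierarchy (a then b) for true missing-data species, returning
the first level with ≥ 1 reference species.  A species without a mass is
simply ineligible for mass-aware levels, not an error.  The focal species
is forbidden from its own reference table (leakage guard for LOOCV).

## Validation design

LOOCV repeats the *entire* pipeline per fold — steepness refit, forward
re-selection — never just re-predicting from a fixed model; the held-out
species is asserted absent from every fitting structure.  Accuracy is
summarised by P² (cross-validated analogue of R²; 1 = perfect, 0 = no
better than the observed mean, negative = worse) and by the identity-line
regression of observed on predicted (that direction, matching how such
scatter is plotted) with classical two-sided t-tests of slope = 1 and
intercept = 0; a zero-residual fit is flagged degenerate instead of
fabricating p-values.  Relative importance uses the Genizi decomposition
λⱼ = Σ_k (S_jk c_k)², S = R^{1/2} (symmetric PSD root of the predictor
correlation matrix), c = S⁻¹r: shares are non-negative, reduce to squared
marginal correlations under orthogonality, and sum to the model R².  It
is computed on the *selected* model only, with eigenvector shares summed
into a single phylogeny number against the mass share, as percentages of
explained (not total) variance.

## Synthetic worlds

The generator's defaults are the study conditions and are not tuned per
test: 86 species, 34 genera, 4 families, pure-birth tree rescaled to
crown depth 15; log10 mass = 4.5 + Brownian (tip sd 0.45 split as 0.35
phylogenetic + 0.40 independent — antelope genera contain congeners of
very different sizes, and that non-phylogenetic mass spread is what makes
taxon-only extrapolation genuinely worse, as well as keeping the mass
share of explained variance dominant); GLw = −2.5 + 2.0·log10mass +
Brownian residual (tip sd 0.7) + iid noise (sd 0.25), giving 3–9-year
generation lengths over dik-dik-to-eland masses.  AFR and wild ALR are
back-solved from GLw and a uniform AFR/ALR fraction (0.15–0.35) with AFR
forced to an integer day, so the Rspan identity holds exactly and a
noiseless record table round-trips to the true GLw to machine precision.
Captive ALR = wild ALR + |offset| with offset ~ N(2200 d, 400 d).

Records: 1–5 sources per parameter (mean 3); AFR-type records carry
symmetric multiplicative noise (cv 4%) and central-value ranges;
longevity records understate the true maximum by an *additive*
half-normal deficit (sd 150 d) — a source reports the oldest individual
actually observed, and the unobserved tail of a lifespan is not
proportional to its length — with ranges whose upper bound is the point
estimate.  The additive form matters: it makes the compiled captive−wild
difference an unbiased estimator of the true offset, which the coverage
test (95% CI covers the truth in ≥ 90% of 50 worlds) verifies.  Units are
mixed (days/months/years, g/kg), 35% of captive records are relabelled
"unknown", and a fixed-size subset (round(32/86·n)) of species loses all
wild longevity records.  All randomness flows from one seed through
spawned generator streams; identical configs give byte-identical tables.

What the generator does *not* emulate — and hence what green tests do not
certify about real data: taxonomic mistakes and synonymy, non-random
missingness (real data gaps correlate with rarity and body size),
among-source correlation (real compilations copy each other), direct ALR
observations as a distinct record class, mass measurement structure
(single database lookup in practice), and any resemblance of the
simulated taxonomy to real antelope genera.

## Known limitations

* The PEM location convention for simultaneously removed sister tips
  ignores their private shared history (see above); predictions for such
  pairs are slightly over-smoothed toward the background.
* Forward selection is greedy; with n−1 candidate eigenvectors it can
  overfit modestly at small n, which is why accuracy claims rest on LOOCV
  rather than in-sample R².
* The identity-line test uses classical standard errors; heteroscedastic
  prediction errors (wider for poorly anchored species) are not modelled.
* `lower`/`upper` chronogram variants require externally supplied bound
  trees; the package does not propagate dating uncertainty itself.
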