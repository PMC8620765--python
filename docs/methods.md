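# Methods

## Data model

The pipeline consumes two tables. A **cover matrix** holds percent cover
(0–100) of every species in every 2 × 1 m plot, with per-plot metadata:
transect id, site type (two levels, distinguished by their subordinate
flora) and an integer position along the transect. Cover values are
independent visual estimates per species, so row sums may exceed 100
(vegetation layers overlap); this is deliberately not validated away. A
**trait table** holds species × trait values with a metadata sidecar per
trait: kind (`continuous` / `ordinal` / `categorical`), units, an optional
`log10` transform, and the ordered level set for non-continuous traits.
Missing trait values are preserved as missing and never imputed. Species
ids must match exactly between the two tables (taxonomic name resolution is
out of scope); cover-table species lacking *all* trait values are dropped
with a logged warning — a deliberate policy choice, since there is no
universally agreed treatment for species absent from trait databases.

The seven canonical traits are plant height (H), leaf dry matter content
(LDMC), leaf area (LA), seed mass (SM), lateral spread (LS), persistence of
the clonal growth organ (PCGO) and number of clonal offspring (NCO); the
nine canonical trait sets are the seven singletons, LHS = {LDMC, H, SM} and
"Multiple" = all seven.

## Trait dissimilarity

`d_ij` is a Gower coefficient averaged over the traits observed in *both*
species of a pair (pairwise deletion). Continuous traits contribute
`|x_i − x_j| / range` after the declared transform; the range is taken over
the **full species pool**, not per plot, so that `d_ij` is one matrix shared
by all plots — a requirement of the Rao formulation. Default transforms are
log10 for the right-skewed size traits (H, LA, SM) and none for LDMC and
the clonal traits; all are configurable per trait. Ordinal traits (the
clonal categories) use Podani's tie-corrected rank formulation rather than
treating category codes as measurements; categorical traits contribute a
0/1 mismatch. A zero-range trait contributes 0 to every pair (with a
warning); a pair sharing no observed trait is an error rather than a silent
hole. Whether the continuous scaling should be by range or by standard
deviation is a genuinely open choice; range scaling is used because it is
the variant that guarantees the stated `d_ij ∈ [0, 1]` bound.

The focal dominant never enters the trait pool: it is excluded from the
composition before abundances are renormalized, and from the ranges/ranks
behind `d_ij`, so its (often extreme) trait values cannot distort the
dissimilarity scale of the coexisting assemblage.

## Rao's Q and the Jost correction

`Q = p' D p` is computed as the full double sum with replacement
(`d_ii = 0`), giving `Q ∈ [0, 1)`. With all distances equal to 1, Q reduces
to the Simpson complement `1 − Σ p²`; merging species with identical trait
rows leaves Q unchanged (functional redundancy). The Jost correction
`1/(1 − Q)` expresses Q as an equivalent number of equally abundant,
maximally distinct species. The **Jost-corrected** value is what is
standardized by the null model (a config switch allows standardizing raw Q
instead; the choice is not decidable from the reference workflow alone, and
the SES sign pattern is insensitive to it since the map is monotone).
Plots whose coexisting assemblage has ≤ 1 species get Q = 0 but are
excluded from SES and modeling, where they carry no information.

## The trait-shuffle null and SES

The null permutes trait values among the pool species — by default one
single regional pool of all species (focal excluded) — while the
composition matrix stays untouched (asserted bit-identical). Two schemes
are provided: `rows_joint` permutes whole species rows (preserving
inter-trait correlation; the default for multi-trait sets) and
`per_column` permutes each trait independently (the default for singleton
sets, where the two coincide). One shuffled matrix per iteration is applied
to all plots; independent shuffles per plot would be equally defensible but
considerably more expensive, and the induced cross-plot correlation of the
nulls is benign for per-plot SES. 999 iterations is the default.

SES uses the sample standard deviation (n − 1) of the null draws; at 999
draws the alternative convention changes SES by well under 0.1%. A
zero-variance null (e.g. all species share identical trait values) sets a
`degenerate` flag instead of raising. Because a joint row relabelling
permutes the precomputed Gower matrix (`d'_ij = d_{π(i)π(j)}`, missing
pattern included), the null loop is pure index arithmetic; the Gower matrix
is rebuilt per iteration only in the per-column × multi-trait combination,
where the identity does not hold.

Calibration: under random assembly the observed assemblage is exchangeable
with its shuffled versions, so SES across plots is centred on zero and the
two-sided |SES| > 1.96 rule rejects at ≈ 5%. The test suite verifies both
at 500 plots / 999 shuffles.

## Gradient mixed models

For each trait set, SES is modeled as a function of focal percent cover
with `statsmodels` linear mixed models: random intercept and random cover
slope grouped by site type, a quadratic cover term in the nonlinear form,
ML-based AIC comparison between the linear and quadratic forms (the
simpler form wins when |ΔAIC| < 2), and REML refit of the chosen form for
the reported coefficients. Cover is centred and scaled to unit variance
before the quadratic term is formed, to tame collinearity; coefficients are
therefore on the standardized cover axis. Marginal and conditional R²
follow the Nakagawa–Schielzeth decomposition with
`σ²_fixed = Var(Xβ̂)` over the data and
`σ²_random = mean_i(z_i' Σ̂ z_i)` (which handles the random slope).

A two-level grouping factor is statistically fragile for variance
estimation. The random-slope fit therefore falls back to a random
intercept when singular (logged), and a fixed-effects robustness variant
(`SES ~ cover × site_type`, OLS) is exposed as a config option. With two
levels the random intercept/slope covariance cannot be richly structured;
the default unstructured 2 × 2 covariance plus the fallback chain is the
pragmatic resolution. Fixed-effect p-values use the normal approximation
on t-ratios; denominator-degrees-of-freedom corrections are out of scope.
Plots with degenerate or missing SES are dropped per model; plots where the
focal covers 0% or 100% participate like any other plot carrying a finite
SES.

## Composition comparison

ANOSIM ranks all n(n−1)/2 Bray–Curtis distances (mean ranks on ties) and
computes `R = (r̄_between − r̄_within)/(M/2)`. R's theoretical range is
[−1, 1]; negative observed values are reported as computed even though in
practice R is read on the 0 → 1 scale. The one-sided p-value uses the
add-one permutation estimator `p = (1 + #{R_perm ≥ R_obs})/(1 + n_perm)`,
so `p ≥ 1/(1 + n_perm)`. Bray–Curtis operates on untransformed percent
cover of the full composition (a pair of all-zero plots gets distance 0
with a warning). Plots are grouped by site type at plot level (grouping
transect aggregates instead would be defensible, but discards within-type
information). NMDS is a visualization aid: the SMACOF optimizer (scikit-
learn) under a nonmetric (isotonic) stress, started from classical scaling
plus random restarts, reporting Kruskal stress-1 and principal-axis-rotated
coordinates; the contract (monotone embedding, stress-1, best-of-starts) is
normative, the optimizer is not.

## Synthetic transect generator

The generator emulates the sampling design the pipeline targets: 6
transects × 20 plots (two site types, three transects each), a focal cover
ramp from ≈ 0% at the transect start to ≥ 90% (monodominance) at the end —
logistic by default, linear as an option, monotone by construction — and a
40-species pool of which 20% is unique to each site type. The type's own
subordinate species get a 4× selection prior (so the types stay
floristically distinct along the whole transect, yielding a clearly
positive ANOSIM R ≈ 0.2), and the type's marker species is forced into the
first plots of each transect with elevated cover.

Coexisting richness is drawn from a Poisson whose mean (12 at zero cover)
shrinks by 55% toward monodominance — richness declines mildly with
dominance, but the *trait composition* of the assemblage is what carries
the regime signal, and richness effects on raw Q are exactly what the SES
null absorbs. The assembly regime is the ground-truth knob:

* `random` — species drawn with the affinity prior only;
* `convergent` — selection probability `∝ exp(−λ d(·, anchor))` toward a
  random anchor species, with λ = 14 × effective strength;
* `divergent` — sequential selection with probability
  `∝ exp(+λ min distance to already-selected)` (limiting-similarity
  kernel).

Effective strength is `regime_strength × (0.15 + 0.85 c/100)`, so the
regime sharpens with focal cover `c` and the SES signal concentrates in
high-cover plots, as the limiting-similarity/filtering hypotheses predict.
The kernel scale (14) was chosen so that, on the 7-trait Gower scale
(typical pairwise d ≈ 0.1–0.5), strength 1 produces clearly detectable but
not saturated selectivity. Abundances are Dirichlet weights scaled to the
residual space `max(10, 100 − c)` with log-normal noise (sd 0.15).

Trait distributions are loose temperate-herb orders of magnitude
(log-normal H ~ 0.35 m, LA ~ 1500 mm², SM ~ 1 mg, LS ~ 0.08 m/yr; normal
LDMC ~ 250 mg/g; three ordered categories each for PCGO and NCO). They
exist to give Gower distances non-degenerate structure and make **no claim
of realism**: passing tests on these data demonstrate the statistical
machinery (calibration, sign recovery, model selection), not that any
field system behaves this way. Real data differ in ways the generator
deliberately ignores: spatial autocorrelation within transects,
intraspecific trait variation, trait–abundance correlations, database
missingness patterns, and abiotic gradients (held homogeneous here, as in
the sampling design the generator mirrors).

`inject_gradient_effect` turns a random-regime dataset into one whose
plug-in SES tracks `β₁c + β₂c²` (standardized cover axis) in expectation,
by redrawing each plot's assemblage until an internal 199-shuffle plug-in
SES lands within 0.4 of the plot's target (closest candidate kept after 80
tries; targets more than 3 SES units beyond what redrawing can reach raise
an error reporting the achievable range). Zero-target plots keep their
original assemblage, making a null injection the exact identity. Realized
SES is attenuated relative to the target (selection noise plus the
independent null used downstream), so the tool supports *shape* recovery
tests (sign of the quadratic term, hump detection) rather than exact
coefficient calibration.

## Pipeline, determinism, problem sizes

A single top-level seed spawns per-stage seeds through NumPy's
`SeedSequence`, making the full run a pure function of (inputs, config,
seed); reruns are bit-identical, and the manifest records seeds, stage
wall times, content hashes and the package version. With `resume=True`,
stages whose recorded input hash is unchanged are reloaded from disk.

Default problem sizes — 120 plots × 40 species × 999 shuffles × 9 trait
sets — run in seconds on one core thanks to the permutation identity above;
the heavier validation experiments in the test suite (500-plot calibration,
20-replicate regime recovery, 100-replicate mixed-model coverage) were
sized to keep the whole suite in the low minutes while leaving Monte-Carlo
error well below the effect sizes being checked.

## Known limitations

* Site type as a 2-level random grouping is at the edge of what mixed
  models support; variance components (hence conditional R²) for real
  2-level data should be read with caution. The fixed-interaction variant
  exists for exactly this reason.
* SES p-values are per plot; the 9 trait-set models are reported without
  multiplicity correction, mirroring standard practice for this design.
* Gower pairwise deletion can make `d_ij` non-metric under heavy
  missingness; Rao's Q does not require metricity, but ordination of such
  matrices would.
* The NMDS stress surface is multimodal; `n_starts` trades time for
  reliability of the global optimum.
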