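# fdgradient

Functional-diversity analysis of understory plant communities along the
cover gradient of a dominant species.

When a single species (the *focal dominant*, e.g. a monodominance-forming
forest herb) ramps from absence to near-100% cover along a transect, the
traits of the species that manage to coexist with it carry a signal about
the assembly process: **trait divergence** (limiting similarity — neighbours
must differ to coexist) or **trait convergence** (filtering / competitive
exclusion — only one trait profile survives). `fdgradient` implements the
full statistical pipeline for detecting that signal from plot × species
percent-cover tables and species × trait tables, and ships a synthetic
transect generator with ground-truth assembly regimes so every stage can be
validated.

It is aimed at community ecologists working with relevé/transect data and
mixed trait types (continuous, ordinal, categorical).

## The statistics at the core

* **Rao's quadratic entropy** per plot, the expected trait dissimilarity of
  two random individuals drawn with replacement:
  `Q = Σᵢ Σⱼ d_ij p_i p_j`, with `p` the relative abundances of the
  coexisting assemblage (the focal dominant is excluded *before* the
  proportions are taken) and `d_ij ∈ [0, 1]` a Gower dissimilarity computed
  over the full species pool (continuous traits range-scaled after optional
  log10 transform, ordinal traits via Podani's rank-based extension,
  categorical traits 0/1). Reported both raw and Jost-corrected as an
  equivalent number of maximally distinct species, `1/(1 − Q)`.
* **Standardized effect size (SES)** against a trait-shuffling null: trait
  values are permuted among the pool species 999 times while the
  composition matrix stays fixed, and
  `SES = (I_obs − mean I_sim) / sd I_sim`. SES > 0 → divergence,
  SES < 0 → convergence, ≈ 0 → random assembly. Nine trait sets are
  standardized: the seven single traits (H, LDMC, LA, SM, LS, PCGO, NCO),
  the leaf–height–seed triplet (LHS = LDMC, H, SM) and all seven pooled
  ("Multiple").
* **Gradient mixed models**: per trait set, `SES ~ cover` and
  `SES ~ cover + cover²` with a random intercept and random cover slope
  grouped by site type; the form is chosen by ML-AIC (parsimony tie-break
  at ΔAIC < 2), coefficients are reported from the REML refit, and
  explained variance as Nakagawa marginal/conditional R².
* **Composition comparison**: ANOSIM (rank-based R with a label-permutation
  p-value) on Bray–Curtis distances of untransformed cover, visualized by
  NMDS (Kruskal stress-1).

## Worked example

Run the whole pipeline on a synthetic dataset assembled under trait
divergence (6 transects × 20 plots, 40-species pool, 999-shuffle null):

```python
from fdgradient import RunConfig, SimConfig, run_pipeline

paths = run_pipeline(
    RunConfig(sim=SimConfig(assembly_regime="divergent"), out_dir="out", seed=17)
)
```

The model table (`out/model_table.csv`) then reads:

```
trait_set chosen_form  linear_term linear_sig  r2_marginal  r2_conditional  aic_ml
        H      linear        0.323          *        0.074           0.406 335.229
     LDMC      linear        0.087       n.s.        0.007           0.140 346.367
       LA      linear        0.312         **        0.100           0.117 332.475
       SM      linear        0.174          *        0.034           0.077 330.867
     PCGO      linear       -0.017       n.s.        0.000           0.101 364.623
       LS      linear        0.244          *        0.051           0.053 362.469
      NCO      linear        0.209       n.s.        0.037           0.191 349.693
      LHS      linear        0.335          *        0.102           0.172 344.229
 Multiple      linear        0.486        ***        0.178           0.362 335.536
```

with `ANOSIM R = 0.241 (p = 0.001)` and `NMDS stress = 0.168` in
`out/anosim.csv`. Reading: SES rises significantly with focal cover for
most trait sets (positive linear terms on the standardized cover axis) —
the imposed divergent assembly is detected, strongest for the pooled
"Multiple" trait set — while the two site types are floristically distinct
(positive, significant ANOSIM R). Under `assembly_regime="random"` the same
pipeline returns non-significant terms near zero.

The same analysis runs from the shell on real CSV inputs:

```bash
fdgradient simulate --out data --seed 3          # or bring your own tables
fdgradient all --config run.yaml --seed 3
```

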