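# Methods

This note records the modelling assumptions, the numerical conventions and
the genuinely open design choices behind `permsvr`.

## Model

The hierarchical model is a two-level regression.  Level one is a small
set (2–4) of ε- or ν-mode support vector regressors with RBF kernel, each
consuming a named descriptor subset that is autoscaled with statistics
fitted on the training partition only.  Level two (the meta learner) is
another RBF SVR whose inputs are the level-one predictions.  The intent is
to combine the reach of a global model with the accuracy of local models:
each base learner can specialise in one permeation regime (e.g. a
passive-diffusion surface versus transporter-mediated behaviour expressed
through hydrogen-bond donors), and the meta learner arbitrates.

Assumptions worth stating explicitly:

* the response is log10 of effective permeability (cm/s); all error
  statistics are in log units;
* descriptors are numeric and complete after filtration — no imputation is
  attempted;
* base-learner diversity comes from descriptor subsets, not from data
  resampling (no bagging).

## Pipeline conventions

* **Filtration** drops descriptors with any missing value or fewer than
  `min_distinct = 3` distinct values (the operational reading of "barely
  discriminates between compounds").
* **Intercorrelation pruning** works on Spearman rank correlations with
  threshold ρ² ≥ 0.64.  The pair with the largest ρ² is resolved first; the
  member with the smaller |ρ| against the response is removed, ties
  removing the later column.  This keeps the variable that carries more
  signal, which is the motivation for pruning in the first place.
* **Normalization** is the n−1-denominator z-score, fitted on the training
  partition and applied unchanged to every other table (no test-set
  re-centering; prevents leakage).
* **Ion classes** follow the printed pKa rule (one pKa → neutral; else
  zwitterion/acid/base by whether the extreme pKa values straddle, fall
  below, or exceed 7).  A pKa of exactly 7 counts as "above 7" so the rule
  is total.  The one-pKa-means-neutral convention is chemically unusual but
  is kept as the default; the boundary is configurable.
* **Applicability domain**: compounds are projected onto the top k = 3
  principal components of the normalized descriptor matrix.  For screening
  candidates against a reference set the perimeter is the axis-aligned
  bounding box of the reference scores (optionally a convex hull — closer
  to the visual notion but fragile in degenerate dimensions).  When
  outliers must be designated before any training set exists, Tukey fences
  (3 × IQR per component) provide a deterministic self-referential screen.
* **Split**: training size is round(ratio·n) (half-up), uniform at random
  under a mandatory seed.  66 in-domain compounds at ratio 0.803 give the
  reference 53/13 partition.
* **Subset selection**: the genetic search uses tournament selection
  (size 3), uniform crossover on membership masks, per-gene mutation 0.1,
  population 50, 100 generations, subset sizes 3–6.  Fitness is 5-fold
  CV-RMSE of a fixed moderate-hyperparameter SVR (C = 10, γ = 1/|subset|,
  ε = 0.1): selection is deliberately decoupled from hyperparameter tuning.
  RFE then discards, at each step, the descriptor whose removal least
  degrades (or most improves) CV-RMSE, stopping when the best removal
  degrades it by more than the tolerance.
* **Grid search** scores every (mode, C, γ, ε/ν) combination by seeded
  k-fold CV-RMSE on the training set only; ties break by smaller C, then
  smaller γ, making the ranking independent of evaluation order.  The
  default grid is the standard libsvm recipe (C = 2⁻⁵…2¹⁵, γ = 2⁻¹⁵…2³,
  powers of four).

## Stacking and ensemble growth

The meta learner is trained, by default, on the members' in-sample
training-set predictions — reproducing the published procedure.  Its
hyperparameters, however, are always selected by cross-validation on
out-of-fold member predictions: selecting them on in-sample predictions
would let the members leak every validation fold and systematically favour
overfit metas.  A fully out-of-fold stacking mode (`stacking="oof"`) is
available but not the default.  (Leave-one-out refits of the ensemble
always retrain members and meta with fixed hyperparameters.)

Ensemble growth follows Occam's razor: all two-member combinations are
tried in candidate-rank order (candidates ranked by external q², ties by
CV-RMSE) and the first whose statistics pass every applicable combined
criterion — external criteria first (cheap), then the training-set
criteria including LOO agreement (expensive) — is accepted.  Three- and
four-member combinations are attempted only if every smaller combination
fails; if nothing conforms, the combination with the highest test q² is
returned explicitly flagged non-conforming.

## Validation battery conventions

* `s` (reported alongside RMSE and MAE) is the sample standard deviation
  (n−1) of the absolute residuals.  This is the unique convention
  consistent with published (RMSE, MAE, s) triples:
  RMSE² = MAE² + ((n−1)/n)·s² holds identically.
* r²/q² is computed as 1 − Σ(ŷ−y)²/Σ(y−⟨ŷ⟩)² with the total sum of squares
  about the mean *predicted* value, exactly as the source formula prints
  it.  This is unconventional (the textbook definition uses ⟨y⟩); a
  `convention="classic"` flag provides the latter.  For any well-fitted
  model the two agree closely.
* Origin statistics: k = Σyŷ/Σŷ² (predicted-vs-observed fit through the
  origin), ro² = 1 − Σ(y−kŷ)²/Σ(y−⟨y⟩)²; the primed versions swap the two
  roles.  rm² = r²(1 − |r² − ro²|) as printed (the later square-root
  revision of rm² is deliberately not used).
* Y-scrambling permutes the response only, refits with unchanged
  hyperparameters and descriptors, and averages the training r² over 25
  rounds.
* Criteria applicability mirrors standard practice: the LOO-agreement
  criterion applies to the training set only, CCC to external sets only.

## Synthetic data generator

The generator emulates the statistical structure the model is designed
for, not any measured dataset — every constant is a simulator fixture.
Descriptors: logD ~ N(1.5, 1.5²), HBD ~ Poisson(2), MR ~ N(80, 20²),
shadow_v ~ U(1, 4), n_NO ~ Poisson(4), μ ~ |N(3, 2²)|, plus pure-noise
standard-normal columns (default 4).  Response:

    log Peff = −4.2 + 0.35·logD − 0.08·(logD − 2)² + 0.25·shadow_v
               − 0.012·max(0, MR − 90) − 0.05·n_NO + 0.15·t·HBD + ε

with latent transporter class t ∈ {−1, 0, +1} (efflux / none / influx,
default probabilities 0.4/0.2/0.4) and ε ~ N(0, 0.1²).  The resulting
log Peff concentrates in ≈[−6, −2.5], the rat-jejunum scale.  The t·HBD
term encodes the dual facilitate/hinder role of hydrogen-bond donors.

What the generator does *not* emulate: real descriptor covariance
(columns are independent), measurement-protocol heterogeneity, and —
importantly — an *observable* transporter signature: t is latent and
mean-zero, so the t·HBD term is irreducible noise (variance ≈ 0.11 log²
units) that caps attainable q² at roughly 0.8 under the default
conditions.  Passing tests on this generator therefore demonstrate
correct mechanics and honest statistics, not real-data performance.

The benchmark's two candidate subsets, (μ, logD, n_NO, shadow-ν) and
(μ, logD, HBD, MR), mirror the descriptor combinations of the published
base models A and B: both share the dominant lipophilicity descriptor,
and each carries a different secondary block (size/shape versus
hydrogen-bonding/refractivity).  The benchmark grid is a compact
sub-grid (C ∈ {1, 10, 100}, γ ∈ {0.03, 0.1, 0.3, 1}, ε = 0.1, ν = 0.5)
chosen so one replicate of the full build — grid search, meta selection,
criteria gating with a 320-fold LOO — runs in tens of seconds; the
replicate studies use 20 seeds at n = 400.

A caveat the replicate study itself quantifies: because the latent
transporter term is unlearnable and the two candidates share the dominant
descriptor, the stack's expected advantage over the *better* of the two
candidates is small (an oracle combiner with weights fitted on the test
set gains only ~0.003–0.01 q² in unfavourable seeds).  The ensemble
beats the best single candidate in only a modest majority of replicates,
while it beats a single grid-searched SVR on the full descriptor set far
more reliably.  Both fractions are reported by `scripts/acceptance.py`.

## Numerical details and degenerate inputs

* Division-by-zero guards raise informative errors (constant observed
  vectors, zero origin sums of squares, zero normalization scale).
* PCA component signs are fixed by making each component's
  largest-magnitude loading positive, so decompositions are reproducible.
* All stochastic steps (splits, CV folds, the genetic search, permutations)
  take explicit seeds; identical seeds reproduce results bit-for-bit.
* Model archives store hyperparameters, descriptor-subset names,
  normalization statistics and solver state; the round-trip contract is
  prediction equality (≤1e-10), not byte equality.

## Known limitations

* The strict r²/q² convention can differ noticeably from the classic one
  for poorly calibrated models; comparisons across software should state
  the convention.
* LOO cross-validation of the full ensemble is O(n) refits of every
  member and the meta; at n in the hundreds this dominates runtime.
* The GFA implementation explores membership masks only; it does not build
  spline terms the way the original commercial tool does.
* With `stacking="oof"`, LOO and Y-scrambling refits still use in-sample
  meta training (fixed hyperparameters), a deliberate simplification.
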