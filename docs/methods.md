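# Methods

## Problem and data model

The prediction target is the disintegration time (seconds) of directly
compressed orally disintegrating tablets. A formulation is a fixed-width
vector: excipient mass percentages under topological encoding (an absent
excipient is an exact 0 — this makes composition columns zero-inflated and
right-skewed by construction), the API mass fraction, manufacturing
parameters (tablet mass [mg], thickness [mm], punch-die diameter [mm],
hardness [N]), derived tablet geometry, and per-API 2-D molecular
descriptors. The packaged column registry pins 28 canonical composition
names and 9 manufacturing names (the four measured parameters plus the five
derived geometry columns); header matching is case-insensitive after
whitespace normalization.

Preprocessing rules and their rationale:

* **180 s exclusion.** "Exceeds 180 s" is interpreted strictly: a tablet
  disintegrating in exactly 180 s is within the 3-minute pharmacopoeial
  limit and is retained. The filter is idempotent and order-preserving, and
  is applied after any record merging (configurable).
* **Silica split.** Fumed silica (Aerosil) and other colloidal-silica
  grades behave differently as glidants; a single silica column with a
  grade annotation is split into two variables whose sum preserves the
  original content. Records carrying mass in both columns are warned about,
  not rejected.
* **Mass-balance validation is advisory.** Literature-derived rows may omit
  trace components, so a composition sum outside 100 ± tolerance (default
  2%) is a finding, not an error. Manufacturing parameters are checked
  against a configurable envelope (defaults: mass 67.13–1179.98 mg,
  thickness 1.86–6.5 mm, die 5.5–16 mm, hardness 2.4–155.43 N, time
  4.98–140 s).
* **Geometry.** The tablet is modelled as a flat-faced right circular
  cylinder with diameter equal to the punch-die bore: flat area 2π(d/2)²,
  lateral area πdh, volume π(d/2)²h, plus total area and SA/V. Convex faces
  are out of scope; the geometry columns are categorized as manufacturing
  parameters and are never dropped by the degeneracy filter.
* **Degenerate columns** (constant, or containing non-finite values — both
  common in descriptor exports) are dropped rather than imputed; the
  dropped list is always returned. Missing values are otherwise *refused*,
  never imputed: the curated table has none by construction.

## Metrics and the balanced splitter

RMSE is reported in seconds; NRMSE divides by the observed target range and
multiplies by 100 (invariant under joint affine rescaling of observed and
predicted values); R² = 1 − SS_res/SS_tot may be negative. Pooled
cross-validation metrics are always computed on concatenated out-of-fold
predictions, so each record contributes exactly once, predicted by a model
that never saw it.

"Balanced" k-fold means target-quantile stratification: records are ranked
by target, grouped into up to 10 quantile bins, shuffled within bins with
the plan seed, and dealt cyclically to folds (with a seeded starting
offset). This guarantees fold sizes within one record of each other — for
243 records and k = 10 that is test folds of 24 or 25 and training
partitions of 218 or 219 — while every fold samples the whole right-skewed
time distribution. Balancing on the target alone was chosen because
balancing several hundred input columns simultaneously is ill-posed; a
deposited fold assignment can be loaded verbatim (`CVPlan.from_csv`)
instead when replicating published splits.

## Model zoo and multistart search

Estimator internals are delegated to scikit-learn
(RandomForest/ExtraTrees/GradientBoostingRegressor, ElasticNet and
MLPRegressor behind a standardization pipeline); the package owns the
uniform `ModelSpec → fit → TrainedModel` contract, seeding, and the search.
The feedforward family uses relu ("rectifier") activations with two
100-neuron hidden layers by default; since the backend does not implement
dropout, stochastic regularization is replaced by an L2 penalty (`alpha`),
with early stopping on a seeded 10% validation split of the training fold.

The multistart search draws `n_starts` independent hyperparameter
configurations per family from fixed per-family distributions (tree counts,
learning rates, depths, penalties...), seeded via `SeedSequence(seed,
spawn_key=(family, start))` so results are exactly reproducible and
insensitive to family order. Each draw is evaluated by full k-fold CV;
the leaderboard sorts by mean per-fold RMSE and reports mean (SD) across
starts as the robustness summary. Budgets are expressed as iteration caps
by default (wall-clock caps are available but make runs hardware-
dependent). The stacked ensemble combines the best spec per family through
a non-negative least-squares meta-learner with free intercept fitted on
out-of-fold base predictions; exactly duplicated base columns share their
weight equally (symmetry tie rule).

## Feature selection

Permutation importance was fixed as the single importance definition for
every family: the importance of feature j is the mean increase of
out-of-fold RMSE over seeded shuffles of column j (floored at zero). It
needs only a predict function, treats trees, linear models and nets on the
same footing, and is checkable against synthetic ground truth. Mixing
model-specific importances (tree gain, coefficients, weight magnitudes)
would make the aggregate depend on which family happened to win each loop.

The short loop repeats `n_loops = 25` times: fresh seeded 5-fold plan,
best-of-budget model, per-loop importances scaled by their maximum. The
aggregate is the per-feature *mean* of scaled importances (median available
via config), rescaled so the top feature reads 1.0, and thresholded
inclusively at 0.1 — inclusive because observed importance tables retain
features right at the cut. Selection is monotone in the threshold, and an
empty selection raises an error suggesting a lower threshold rather than
returning an unusable model.

## Shapley values and partial dependence

Marginalization is *interventional*: the value of coalition S is the
weighted mean prediction with features in S pinned to the explained
instance and the rest overwritten by background points. This matches the
partial-dependence integral over P(X_C) and the usual background-summary
convention for kernel-style explainers; conditional marginalization is out
of scope.

* **Background.** Joint k-means (default k = 12) in standardized space,
  centroids returned in original units and weighted by cluster occupancy.
  Joint clustering of full feature vectors was chosen over per-feature
  clustering (the ambiguity is real in the field's informal descriptions)
  because coalition evaluation needs coherent background *vectors*. With k
  duplicated data rows the centroids reproduce the rows exactly and
  explanations agree with the full-data background to 1e-8.
* **Exact estimator.** Full enumeration of all 2^p coalitions (batched
  predictions), with the factorial weights |S|!(p−|S|−1)!/p!. Feasible to
  p = 15 by default (2^p coalition values); above that the caller is
  directed to the sampler.
* **Sampled estimator.** Permutation sampling with antithetic pairs (each
  drawn permutation is evaluated together with its reverse; the pair
  average is one sample). Each permutation costs p+1 coalition values,
  evaluated in one batched predict. Antithetic pairing cancels the
  sampling variance of additive and *pairwise-interaction* terms exactly —
  for such models the estimator is exact up to floating-point error — and
  per-feature Monte-Carlo standard errors are computed over pairs. The
  permutation estimator satisfies efficiency telescopically; the residual
  floating-point discrepancy is redistributed proportionally to |φ| and
  recorded in the explanation metadata. Kernel-weighted regression
  sampling was not used: permutation sampling has simpler variance
  accounting.
* **Partial dependence.** For each grid point (default: 20 equally spaced
  points between observed min and max; percentile limits optional) the
  feature(s) of interest are overwritten in every record and predictions
  averaged; two-feature subsets produce the surface used to study, e.g.,
  API lipophilicity against super-disintegrant level.

## Synthetic database

The generator emulates the *structure* of the curated database, not its
chemistry: per-excipient presence probabilities follow the database's
occupancy pattern (mannitol in ~85% of records, camphor in ~10%), present
amounts are right-skewed Beta draws bounded by the database maxima, fillers
absorb the mass balance to ~100%, tablet mass equals cylinder volume times
an apparent density (inducing the expected mass/punch-die correlation,
r ≈ 0.8), and manufacturing parameters are clipped to the database
envelope. 26 synthetic APIs carry an XLogP-like lipophilicity in
[1.14, 10.61]; the descriptor table adds proxies correlated with it
(population r = 0.9), one constant column (to exercise degeneracy
dropping) and independent noise descriptors.

The target mechanism (documented in `GroundTruth`, regenerable from the
seed) is: intercept 63 s; super-disintegrant coefficients −2.5 (CC-Na),
−3.0 (crospovidone), −3.0 (SSG) s per mass %; a hardness hinge of
+5 s per N above 100 N (very hard tablets disintegrate slowly — the kink
gives partial-dependence tests a known shape to detect); +9 s per XLogP
unit (lipophilic APIs wet slowly); a mild positive XLogP×disintegrant
interaction (+0.15, disintegrants less effective for lipophilic APIs);
Gaussian noise with SD 8 s; clipped below at 3 s. These values were chosen
once so that roughly 4–5% of records exceed the 180 s limit (exercising
the exclusion filter), the linear part is exactly recoverable by OLS on
noiseless data, and the signal-to-noise supports a pooled 10-fold R² ≥ 0.8
for a competent gradient-boosting model, verified by a brute-force
full-data fit.

What passing on synthetic data does **not** show: real excipient chemistry
(interactions among 28 excipients, grade effects), real descriptor
covariance (633 correlated descriptors vs. ~50 mostly independent ones
here), literature heterogeneity across source publications, or measurement
error in compendial disintegration testing. Results on the generator
validate the *machinery* — leakage-free CV, selection recovery, attribution
correctness — not pharmaceutical conclusions.

## Problem sizes and numerical choices

Default study sizes: n = 250 synthetic records, 25 selection loops × 5
folds, 10-fold final CV; the pipeline's explanation stage summarizes the
background to 12 centroids and explains a capped number of records
(default 50) with the sampled estimator. Acceptance runs use a 3-start
final search — enough to avoid a single unlucky hyperparameter draw while
staying desk-scale; the full reference configuration (30 starts, all
families, stacking) is available through `PipelineConfig`/CLI flags.

Tolerances: exact-Shapley efficiency and oracle agreement at 1e-8; sampled
estimator judged within 3 Monte-Carlo standard errors; flat-PDP closed
forms at 1e-8; OLS parameter recovery at 1e-6. Ties in the leaderboard are
broken by pooled RMSE then by the spec's canonical representation; NNLS
weight ties among identical bases are split uniformly. Degenerate inputs
(constant target, zero observed range, k > n, empty coalitions) raise
typed errors rather than returning NaN.

## Known limitations

* The neural family approximates the published architecture but not its
  training regime (no dropout, different epoch counts and stopping rule).
* Permutation importance dilutes across strongly correlated features; the
  synthetic descriptor proxies (r = 0.9 with XLogP) are occasionally
  co-selected — expected behaviour, counted against the noise-rejection
  rate.
* The sampled Shapley estimator reports near-zero standard errors for
  models with only pairwise interactions (antithetic cancellation); the
  reported 3·SE band is then essentially an exactness claim, which holds.
* Replication against the deposited real database requires a separate
  download and is stochastic across search runs; it is reported, not
  gated (`scripts/replicate_deposited.py`).
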