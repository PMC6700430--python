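# Methods

This note documents the statistical model behind `coatrophy`, the choices
made where the design was genuinely open, what the synthetic generator does
and does not emulate, and the package's numerical conventions.

## Data model

The unit of analysis is a subjects × features matrix of regional
morphometry per timepoint: 164 features — mean cortical thickness (mm) of
the 34 Desikan–Killiany regions per hemisphere (68), the volume (mm³) of
the corresponding parcellated cortical white matter (68), two unsegmented
white-matter volumes, and 26 further subcortical structures — plus total
intracranial volume (ICV) per subject. Cerebellar volumes are catalogued
but excluded from analysis (cerebellar atrophy is not an expected feature
of Alzheimer-type degeneration); exclusion is a schema flag, not a parse-
time name heuristic, so it is explicit and testable.

## Normalization

* Volumes are expressed as 100 × volume / ICV to remove head-size effects;
  thickness is not ICV-dependent and stays in mm.
* Robust *Z* against the CN cohort of the same timepoint:
  *Z* = (raw − median_CN) × 1.3489 / IQR_CN. The constant is the 25–75%
  spread of the standard normal (Φ⁻¹(0.75) − Φ⁻¹(0.25) = 1.34897…), fixed
  at the four-decimal value 1.3489 so the formula is bit-reproducible as
  written. Using the same-timepoint CN reference (rather than baseline CN
  for both) keeps the 36-month scores calibrated to a contemporaneous
  normal distribution.
* Quantiles use linear interpolation between order statistics (the default
  convention of the mainstream numerical stacks); the convention is
  recorded in the run manifest so alternatives are comparable.
* Degenerate features (CN IQR = 0) are dropped from all datasets rather
  than given infinite scores — a zero-spread reference leaves the score
  undefined.
* Missing raw values propagate as missing *Z*; subjects missing more than
  20% of features (configurable) are dropped with a warning. How partially
  missing regional values should be handled is not dictated by the method
  itself; strict-drop with logging is the least surprising default.
* Decline speed = (last cognitive score − baseline score) / months
  elapsed, a rate that tolerates unequal follow-up lengths.

Anchor property (asserted in tests): scoring the CN reference against
itself yields per-feature median exactly 0 and IQR exactly 1.3489.

## Univariate statistics

* Feature–trait association: Spearman correlation, two-sided p, pairwise-
  complete observations. Benjamini–Hochberg correction is applied per
  trait column across the 164 features (each heatmap column is one
  inference family); raw p-values are always reported alongside. Whether
  to correct per column or jointly across traits is an open choice; per
  column matches the way such heatmaps are read (one clinical question per
  column). BH is the literal step-up rule (adj_i = min_{j≥i} p_(j)·m/j,
  clipped at 1); perfect correlations produce p = 0, which is clamped to
  the smallest positive double before adjustment.
* Variable importance for a binary endpoint: per-feature ROC AUC via the
  rank / Mann–Whitney U identity with midrank ties, folded to
  max(AUC, 1 − AUC) so protective and deleterious features of equal
  strength rank equally. For a continuous endpoint: per-feature R², taken
  as the squared Pearson correlation. A tuned per-feature regressor (as in
  SVM-based importance screens) would be model- and tuning-dependent; the
  squared correlation is the model-free limit of that quantity, and a
  `predictor` hook accepts any per-feature statistic. Raw importances are
  min-max scaled to [0, 100] across features.

## Network construction

* Similarity: pairwise Spearman correlation of *Z* scores. Signed
  adjacency a = ((1 + s)/2)^β — the canonical signed transform: it maps
  [−1, 1] to [0, 1] so anti-correlated regions get near-zero adjacency
  instead of a spuriously strong link.
* Scale-free criterion: connectivity k_i = Σ_j a_ij is binned into 10
  equal-width bins; log₁₀(bin frequency) is regressed on log₁₀(bin mean
  k); the fit index is R² × (−sign(slope)), positive only for decaying
  degree distributions. β is the smallest grid value (default 1…20) with
  fit ≥ 0.80 in both datasets; if none qualifies the power maximising the
  worse fit is used with a prominent warning.
* TOM: the unsigned topological-overlap formula applied to the signed
  adjacency (whose entries are already non-negative):
  TOM_ij = (ℓ_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij). The denominator is
  ≥ 1 − a_ij + a_ij = 1 whenever k ≥ a, and is asserted positive.
* Cross-dataset scaling: each non-reference TOM is raised elementwise to
  log(q_ref)/log(q_s), where q are the 95th percentiles of the
  off-diagonal entries. A power transform preserves [0, 1] and ranks, and
  makes the two TOM distributions comparable before taking the minimum.
  The exact transform and quantile are design choices, recorded in the
  manifest.
* Consensus = elementwise minimum of the scaled TOMs: an edge survives
  only at the strength present in *every* dataset, so the resulting
  modules are preserved structures, not artifacts of one timepoint.

## Module detection

* Average-linkage hierarchical clustering on 1 − TOM_consensus
  (`scipy.cluster.hierarchy`; deterministic given the feature order).
* Branch cut: a *static* height cut at 0.99 × the maximum merge height
  (configurable). A dynamic hybrid cut is the common default in the
  co-expression toolchain, but it has many interacting knobs; the static
  cut is fully specified, deterministic, and — because background features
  coalesce just below the root while genuine modules join the tree last —
  separates planted structure from noise cleanly at this problem size.
* Minimum module size 2 (co-atrophy of even a bilateral pair is
  meaningful); smaller branches go to "grey", the expedient label for
  unclassified features, which is carried through all outputs but flagged
  as a non-module.
* Eigengene: first principal component (SVD) of the column-standardized
  member submatrix, sign-anchored to correlate non-negatively with the
  member-mean profile; explained-variance share reported. Missing cells
  are mean-imputed (logged); zero-variance members are dropped with a
  warning.
* Merging: iteratively merge the closest pair of modules whose consensus
  dissimilarity — the **maximum over datasets** of 1 − Pearson correlation
  of their eigengenes — is below 0.2 (i.e. similarity ≥ 0.8 in *both*
  datasets, the consensus reading of the merge rule). The loop strictly
  decreases the module count, so it terminates.
* Colors follow the standard module-color sequence (turquoise, blue,
  brown, …) by descending module size; ties break by first-member position.
* Module–trait tables report Spearman rho and raw two-sided p per module ×
  trait (BH across the table available behind a flag), for the baseline and
  subtracted datasets separately.
* Recovery against a known labelling is scored with the adjusted Rand
  index, treating grey as its own cluster.

## Synthetic cohort generator

The generator emulates the *statistical structure* of a two-timepoint
case/control morphometry study, not anatomy:

* Per-feature reference means and SDs at plausible adult scales (thickness
  ≈ 2.2–2.9 mm; volumes as fractions of ICV, e.g. a parcellated WM region
  ≈ 0.5–0.7 %ICV), fixed independently of the cohort seed.
* ICV ~ LogNormal(log 1.5 × 10⁶ mm³, 0.08); volumes are generated as
  ICV-fractions then multiplied by ICV, so head size is a fully removable
  confound (verified by simulation).
* Each planted module m has a per-MCI-subject latent factor f_m ~ N(0,1);
  member values lose loading λ · f_m reference-SDs (λ = 0.8 by default),
  plus N(0, 0.5 SD) residual noise; CN subjects and non-members are pure
  noise around the reference. Lower value = more atrophy, so members are
  positively inter-correlated after Z-scoring (within-module Spearman
  ≈ λ²/(λ² + σ²) ≈ 0.72 in expectation).
* Conversion ~ Bernoulli(logistic(α + Σ β_m f_m)) with α = 0 and
  β_temporal = 1.2 (≈ 50% converters, matching a late-MCI cohort over
  3 years); decline speed = 0.18 + 0.12 f_temporal + N(0, 0.08)
  score/month.
* At 36 months every module factor gains a fresh progression increment
  (SD 1) and converters' factors shift by +1, so the *change* (subtracted)
  dataset of a module is conversion-linked even when its baseline factor
  is independent of conversion. The default layout plants a temporal
  module with a baseline conversion link and a parietal module linked only
  through the 36-month shift — the temporal-to-parietal extension the
  consensus pipeline should expose. Both modules keep their correlation
  structure at both timepoints: a block uncorrelated at baseline would
  have near-zero baseline TOM and could not, by construction, survive an
  elementwise-minimum consensus, so "activation at 36 months" is a
  property of the trait link, not of the covariance. Literal
  one-timepoint loadings remain available via `timepoint_active`.
* Default sizes: 140 CN + 200 MCI, both retained at follow-up
  (configurable attrition fractions).

What passing tests on this generator do **not** show about real data:
there is no spatial smoothness or anatomical neighbourhood correlation, no
scanner/site effects, no heavy-tailed artefacts, no age/sex structure in
the morphometry, and the planted block-plus-noise covariance is far
cleaner than real structural covariance (where, e.g., strongly atrophic
medial-temporal structures can fail to modularize precisely because their
correlations are diffuse). Recovery of planted modules validates the
pipeline's correctness, not its sensitivity on real cohorts.

## Determinism and reproducibility

One integer seed drives every random draw; identical seed and config give
bitwise-identical outputs, including the written result files (floats
serialized with 17 significant digits, hence losslessly round-trippable).
The run manifest records the config hash, seed, chosen β, scaling
exponents, cut height, merge cut, dropped features/subjects, and the
quantile convention. The module assignment is invariant (as a partition)
under feature-order permutation and under swapping the dataset order in
the consensus.

## Problem sizes

Tests and the acceptance script run the full pipeline at the default study
conditions (340 subjects × 164 features, two timepoints); a complete run
takes a few seconds on one CPU. The implementation holds dense
features × features matrices in memory and is intended for feature counts
up to a few thousand, not for voxel-level data.

## Known limitations

* The static branch cut has a single global height; very heterogeneous
  module tightness may favour the dynamic cut (left as an option).
* No covariate adjustment (age/sex residualization) before network
  construction.
* The per-feature importance deliberately avoids model fitting; it will
  not capture feature-trait relationships that only a nonlinear regressor
  would see.
* With two datasets the consensus minimum is conservative: overlap absent
  from either dataset is discarded entirely rather than down-weighted.
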