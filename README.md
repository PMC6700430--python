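# coatrophy

Consensus co-atrophy network analysis of regional brain morphometry.

Neurodegeneration does not thin the cortex one region at a time: anatomically
and functionally connected regions atrophy together, and the *set* of regions
that co-atrophy — and how that set spreads over time — carries information
about the underlying pathological process that single-region statistics miss.
`coatrophy` applies the weighted correlation-network toolkit (originally
developed for gene co-expression, WGCNA) to regional morphometry: it finds
modules of brain regions whose atrophy is coordinated across subjects,
requires those modules to be *preserved* between a baseline and a
longitudinal-change dataset, and correlates each module's summary profile
with clinical progression (conversion from mild cognitive impairment to
dementia, and cognitive decline speed).

It is written for neuroimaging researchers working from FreeSurfer-style
regional stats tables (cortical thickness and regional/structural volumes)
plus a clinical table, and ships a seeded synthetic-cohort generator with
planted modules for validation and method development.

## Method

Given raw morphometry for subjects at baseline and at 36 months:

1. **Normalization.** Volumes become a percentage of each subject's
   intracranial volume (ICV); thickness stays in mm. Each feature is scored
   against the cognitively-normal (CN) cohort of the same timepoint:

   robust *Z* = (raw − median_CN) × 1.3489 / IQR_CN,

   where 1.3489 is the standard normal 25–75% spread, so robust *Z* matches
   (x − μ)/σ for normal data while resisting outliers. The *subtracted*
   dataset is *Z*₃₆ − *Z*_baseline per subject — net longitudinal change.

2. **Signed network.** Feature similarity is the pairwise Spearman
   correlation *s* of *Z* scores; the signed soft-thresholded adjacency is
   *a* = ((1 + *s*)/2)^β. β is the smallest power whose network satisfies
   the scale-free topology criterion (log-log connectivity fit R² ≥ 0.80)
   in **both** datasets.

3. **Topological overlap and consensus.** TOM_ij = (ℓ_ij + a_ij) /
   (min(k_i, k_j) + 1 − a_ij) with ℓ_ij = Σ_u a_iu a_uj and k_i = Σ_u a_iu.
   The per-dataset TOMs are quantile-matched (power transform equating the
   95th percentiles) and the consensus TOM is their elementwise minimum.

4. **Modules.** Average-linkage clustering on 1 − TOM_consensus; a static
   height cut with minimum module size 2; modules whose eigengenes
   correlate ≥ 0.8 in both datasets are merged (merge cut 0.2); modules get
   the standard color names by size, unclassified features go to "grey".

5. **Module–trait correlation.** Each module's eigengene (first principal
   component of its standardized member submatrix) is Spearman-correlated
   with clinical traits in each dataset.

Per-feature statistics (Spearman trait correlations with
Benjamini–Hochberg correction, ROC-AUC / R² variable importance) are
provided alongside the network analysis.

## Worked example

```python
from coatrophy import SimConfig, planted_truth, recovery_score, run_consensus_analysis

moduleset, manifest = run_consensus_analysis({"simulate": {"seed": 7}},
                                             outdir="coatrophy_results")
```

On the default synthetic cohort (140 CN + 200 MCI, 164 features, a planted
temporal module whose latent factor drives conversion from baseline and a
planted parietal module that becomes conversion-linked only through its
36-month change), `examples/04_consensus_modules.py` prints:

```
soft threshold power: 9 (scale-free criterion met)
2 consensus modules; 20/164 features assigned (12.20%)
planted-module recovery (adjusted Rand index): 1.000
  turquoise: 10 features (planted 'temporal' module)
  blue: 10 features (planted 'parietal' module)

module-conversion correlations, baseline dataset:
   module       rho            p
turquoise -0.456574 1.082596e-11
     blue  0.034295 6.297300e-01

module-conversion correlations, subtracted dataset:
   module       rho            p
turquoise -0.404785 2.763461e-09
     blue -0.427302 2.784773e-10
```

Both planted modules are recovered exactly. The temporal module's atrophy
correlates with conversion already at baseline (negative rho: thinner
cortex, more conversion); the parietal module is uncorrelated at baseline
but strongly conversion-linked in the longitudinal-change dataset — the
co-atrophy associated with progression *extends* from the first module to
the second over follow-up, which is the pattern this consensus design is
built to expose.

The `examples/` scripts walk through each capability (simulation,
normalization, univariate statistics, the full pipeline); a thin CLI is
also available: `coatrophy run --config cfg.yaml --outdir results`.

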