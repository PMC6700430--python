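"""The full consensus co-atrophy analysis in one call.

Runs simulation -> normalization -> soft-power selection -> TOM/consensus ->
module detection -> eigengene-trait correlation, then prints the recovered
modules and the conversion correlations that show the longitudinal
extension: the temporal module is conversion-linked already at baseline,
the parietal module only in the 36-month change (subtracted) dataset.
"""

from coatrophy import SimConfig, planted_truth, recovery_score, run_consensus_analysis

moduleset, manifest = run_consensus_analysis(
    {"simulate": {"seed": 7}}, outdir="coatrophy_results"
)

print(f"soft threshold power: {manifest.soft_power} "
      f"(scale-free criterion {'met' if manifest.sft_satisfied else 'NOT met'})")
print(f"{manifest.n_modules} consensus modules; "
      f"{manifest.n_assigned}/164 features assigned "
      f"({100 * manifest.n_assigned / 164:.2f}%)")

truth = planted_truth(SimConfig(seed=7))
print(f"planted-module recovery (adjusted Rand index): "
      f"{recovery_score(moduleset.assignment, truth):.3f}")

for label in moduleset.modules():
    members = moduleset.members(label)
    planted = truth.loc[members].mode().iloc[0]
    print(f"  {label}: {len(members)} features (planted '{planted}' module)")

for tag in ("baseline", "subtracted"):
    t = moduleset.trait_tables[tag]
    conv = t[(t.trait == "converted") & t.is_module]
    print(f"\nmodule-conversion correlations, {tag} dataset:")
    print(conv[["module", "rho", "p"]].to_string(index=False))
# Negative rho = module atrophy accompanies conversion.  Compare the
# parietal-module p-value between the two datasets: non-significant at
# baseline, strongly significant in the longitudinal change.
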