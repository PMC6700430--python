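"""Per-feature statistics: Spearman trait correlations and importance.

Correlates every regional Z score with conversion and decline speed
(BH-corrected per trait), then ranks features by direction-agnostic ROC AUC
(conversion) and R-squared (decline speed), and measures how well the two
rankings agree.
"""

from coatrophy import (
    SimConfig,
    adas_progression_speed,
    generate_cohort,
    importance_agreement,
    normalize_to_icv,
    reference_stats,
    robust_z,
    spearman_trait_correlations,
    variable_importance,
)
import pandas as pd

baseline, _, clinical = generate_cohort(SimConfig(seed=7))
pct = normalize_to_icv(baseline)
z = robust_z(pct, reference_stats(pct))

traits = pd.DataFrame(
    {
        "converted": clinical.data["converted"],
        "adas_speed": adas_progression_speed(clinical),
    }
).reindex(z.values.index)

table = spearman_trait_correlations(z, traits)
sig = table[(table.trait == "converted") & (table.fdr < 0.05)]
print(f"{len(sig)} / 164 features significantly correlated with conversion (FDR < .05)")
top = sig.reindex(sig.rho.abs().sort_values(ascending=False).index).head(5)
print(top[["feature", "rho", "fdr"]].to_string(index=False))
# The strongest correlates are the planted temporal-lobe members; rho < 0
# because lower thickness (more atrophy) accompanies conversion.

imp_conv = variable_importance(z, traits["converted"], kind="binary")
imp_adas = variable_importance(z, traits["adas_speed"], kind="continuous")
print("\ntop conversion-importance features (scaled 0-100):")
print(imp_conv.sort_values("scaled", ascending=False).head(5).to_string())

rho, p = importance_agreement(imp_conv, imp_adas)
print(f"\nagreement between the two importance rankings: rho = {rho:.3f} (p = {p:.2g})")
# Positive agreement: both endpoints are driven by the same latent atrophy factor.
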