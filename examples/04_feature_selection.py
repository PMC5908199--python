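"""Screen 29 candidate features against bNAb outcome at FDR 5%."""

from fcserology import CohortConfig, generate_cohort, select_features
from fcserology.pipeline import assemble_features, score_stage

table = generate_cohort(CohortConfig(seed=1))
feats = assemble_features(table, score_stage(table))
labels = table[table.group != "negative"].set_index("subject_id")["group"]

sel = select_features(feats.join(labels), fdr=0.05)
kept = sel[sel.selected].sort_values("adjusted_p")
print(kept[["feature", "rho", "adjusted_p"]].round(4).to_string(index=False))
print(f"{len(kept)} of {len(sel)} candidates pass the 5% FDR screen")
# Each feature is Spearman-correlated with the 0/1 group label and the
# p-values Benjamini-Hochberg adjusted; negative rho for CD4 reflects
# the lower CD4 counts of bNAb developers.
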