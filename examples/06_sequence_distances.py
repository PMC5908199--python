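"""Viral divergence and diversity as uncorrected p-distances."""

from fcserology import (
    divergence_report,
    generate_sequences,
    mean_pairwise_distance,
    percent_divergence,
)
from fcserology.synthetic import SyntheticSequenceConfig, random_reference

# Gap columns are excluded pairwise before counting differences:
r = percent_divergence("AC-GT", "ACAGA")
print(f"{r.differing_sites} differences over {r.compared_sites} "
      f"comparable sites = {r.percent_difference:.1f}%")   # -> 25.0%

# Simulated autologous sequences at a 3% per-site substitution rate
# diverge from the antigen reference by ~3%:
ref = random_reference(600, seed=4)
seqs = generate_sequences(SyntheticSequenceConfig(
    reference_length=600, n_sequences=20,
    per_site_substitution_prob=0.03, seed=4), ref)
rep = divergence_report({"donor": seqs}, {"antigen": ref})
print(rep.round(3).to_string(index=False))
print(f"intra-host diversity: "
      f"{100 * mean_pairwise_distance(seqs):.3f}% mean pairwise distance")
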