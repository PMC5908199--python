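"""Score raw effector readouts and apply the negative-control threshold."""

from fcserology import adcp_score, adcc_activity, negative_threshold

# A phagocytic score is the bead geometric MFI times the % bead uptake:
print("ADCP score:", adcp_score(37.5, 2400.0))        # -> 90000.0

# ADCC is % granzyme-B activity net of the no-IgG background wells:
print("ADCC activity:", adcc_activity(35.5, 5.5), "%")  # -> 30.0 %

# HIV-negative controls define a positivity threshold of mean + 3 SD;
# scores below it are treated as background.
thr = negative_threshold([5.0, 7.0, 9.0])
print("negative threshold:", thr)                      # -> 13.0
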