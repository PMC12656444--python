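"""Urban-vs-control effect sizes from the published group means.

Percent and fold changes between group means quantify how strongly each
stress marker shifted under urban conditions at the August stress peak.
"""

import thri

means = thri.published_group_means()


def m(species, condition, timepoint, trait):
    row = means[
        (means.species == species)
        & (means.condition == condition)
        & (means.timepoint == timepoint)
        & (means.trait == trait)
    ]
    return float(row["mean"].iloc[0])


pairs = [
    ("Platanus TBARS, August urban vs control",
     thri.percent_change(m("Platanus", "control", "August", "TBARS"),
                         m("Platanus", "urban", "August", "TBARS")), "%"),
    ("Celtis TBARS, August urban vs control",
     thri.percent_change(m("Celtis", "control", "August", "TBARS"),
                         m("Celtis", "urban", "August", "TBARS")), "%"),
    ("Celtis LEF, August urban vs control",
     thri.percent_change(m("Celtis", "control", "August", "LEF"),
                         m("Celtis", "urban", "August", "LEF")), "%"),
    ("Tilia proline, August urban vs control",
     thri.fold_change(m("Tilia", "control", "August", "Proline"),
                      m("Tilia", "urban", "August", "Proline")), "x"),
    ("Tilia TBARS, June control -> August urban",
     thri.fold_change(m("Tilia", "control", "June", "TBARS"),
                      m("Tilia", "urban", "August", "TBARS")), "x"),
]

for label, value, unit in pairs:
    print(f"{label}: {value:+.2f}{unit}" if unit == "%" else f"{label}: {value:.2f}{unit}")

print(
    "\nPositive % = increase under urban stress (oxidative damage markers rise);"
    "\nnegative % = decline (photosynthetic electron transport falls)."
)
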