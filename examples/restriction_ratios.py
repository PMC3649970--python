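"""Restriction-factor assay statistics and normalised titres.

The two-colour assay measures the infection rate (% EGFP+) separately in
restriction-factor-positive (EYFP+) and factor-negative cells; the ratio
classifies each virus/factor pair: < 0.3 restricted, > 0.7 not restricted.
Particle infectivity is reported as a percentage of the wild-type titre
within each experiment.
"""

import numpy as np

from gagntd import RestrictionMeasurement, restriction_ratio, titre_summary

ASSAYS = [
    # (label, % infected factor+, % infected factor-) per replicate
    ("factor wt  vs PFV", [25.8, 24.2, 26.1], [25.0, 23.9, 25.5]),
    ("factor wt  vs SFV", [2.0, 1.7, 2.4], [25.0, 24.1, 26.0]),
    ("RING mutant vs SFV", [23.5, 25.0, 24.4], [24.9, 25.3, 24.0]),
]

print(f"{'pair':<20} {'ratio':>12} {'class':>16}")
for label, pos, neg in ASSAYS:
    res = restriction_ratio(RestrictionMeasurement(pos, neg))
    print(f"{label:<20} {res.ratio:6.2f} +/- {res.sd:4.2f} "
          f"{res.classification:>16}")

titres = np.array([
    [8.7e6, 2.9e6, 4.3e4, 8.7e2],  # one experiment: wt, three mutants
    [1.2e7, 4.1e6, 6.5e4, 1.5e3],
    [5.9e6, 2.1e6, 2.8e4, 4.4e2],
])
mean, sd = titre_summary(titres, wt_index=0)
print("\ninfectivity, % of wild type (mean +/- sd over experiments):")
for name, m, s in zip(["wt", "mutant A", "mutant B", "mutant C"], mean, sd):
    print(f"  {name:<9} {m:8.2f} +/- {s:.2f}")
print()
print("Only the intact factor against the susceptible virus restricts")
print("(ratio << 0.3); titres show per-mutant infectivity losses.")
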