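"""Locate the KMD region from a Km posterior — the published worked example.

Uses the published posterior for the alcohol example (Km mean 11.97 mg/dL,
95% CI [11, 13]) and anchors the kneedle windows at the 90%/95%-of-Vmax
concentrations computed from the true Km = 11.8 (106.2 and 224.2 mg/dL).
"""

import kmdkit as kk

summary = kk.PosteriorSummary.from_intervals(km_mean=11.97, km_ci=(11.0, 13.0))
region = kk.compute_kmd_region(summary, smax_km=11.8)
report = kk.kmd_report(region, summary)
print(kk.format_report(report))
# Expected output: lower bound 25 mg/dL (raw 24.90), midpoint 34 mg/dL
# (raw 34.08) and upper bound raw 42.53 mg/dL — doses below ~25 mg/dL keep
# the study on the unsaturated side of the elimination kinetics.
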