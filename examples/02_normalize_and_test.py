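"""Normalize prediction scores and call differentially active kinases.

Raw kinase-substrate prediction scores live on kinase-specific scales. This
example normalizes them against each kinase's proteome-wide background
(s = -log10 of the add-one exceedance fraction), then compares each
kinase's scores on regulated sites against its background scores with a
two-sample KS test, adjusts with Benjamini-Hochberg, and calls direction
from the dominant one-sided statistic.

Run from the repository root:  python examples/02_normalize_and_test.py
"""

from kinact import (
    SyntheticSpec,
    differential_kinase_activity,
    generate_background,
    generate_regulated,
    results_to_frame,
)

# A synthetic study: 20 kinases scored over a 9500-site background; three
# kinases carry planted activity shifts in normalized-score units.
spec = SyntheticSpec(
    n_kinases=20,
    n_background_sites=9500,
    n_regulated_sites_per_kinase=25,
    shifted_kinases={"KIN001": 1.0, "KIN002": 0.8, "KIN003": -1.0},
    seed=7,
)
background_dist, background = generate_background(spec)
regulated, truth = generate_regulated(spec, background_dist)

# The normalized-score column obeys P(s >= t) = 10^(-t) under the null:
frac_above_1 = (background["score"] >= 1.0).mean()
print(f"background fraction with score >= 1: {frac_above_1:.4f} (expect ~0.1)")

results = differential_kinase_activity(
    regulated, background, min_sites=5, alpha=0.005
)
frame = results_to_frame(results)
print(frame.head(5)[["kinase", "n_regulated", "D", "p_two_sided", "q", "call"]]
      .to_string(index=False))

calls = frame.set_index("kinase")["call"]
print(f"\nKIN001: {calls['KIN001']}, KIN002: {calls['KIN002']}, "
      f"KIN003: {calls['KIN003']}")
# -> the two up-shifted kinases are called activated, the down-shifted one
#    inhibited; the 17 null kinases stay unchanged at alpha = 0.005.
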