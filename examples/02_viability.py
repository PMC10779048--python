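"""Trypan-blue viability metrics with Dunnett many-to-one testing.

Simulates count tables for four compounds, computes percent viability and
percent viable-cell density, and tests exposed groups against the
time-matched control.
"""

import numpy as np

from toxpod import dunnett_many_to_one, percent_viability
from toxpod.synthetic import default_design, default_truth, simulate_viability

design = default_design(timepoints=(24,), replicates=4)
truth = default_truth(design, n_genes=100, n_sets=4, hub_size=20, seed=0)
counts = simulate_viability(design, truth, seed=1)

counts["percent_viability"] = [
    percent_viability(w, b)
    for w, b in zip(counts["white_count"], counts["blue_count"])
]
print(counts.head(6).to_string(index=False))

stats_in = counts.assign(
    condition=[f"{c}@{k:g}" for c, k in zip(counts["compound"],
                                            counts["concentration"])],
    value=np.sqrt(counts["density_viable"]),  # square-root transform
)
result = dunnett_many_to_one(stats_in, control_label="control@0", seed=0)
print(result.to_string(index=False))
# p_adj is the familywise-adjusted probability that an exposure's
# viable-cell density equals the control's; small values flag cytotoxicity.
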