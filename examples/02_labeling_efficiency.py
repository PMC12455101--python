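"""Estimate ¹⁵N incorporation from simulated M−1/M0 observations.

Predicted ratios over a 95-100% incorporation grid are fitted with a
line; observed ratios are inverted through it. The protein-level value is
the median over precursors.
"""

import numpy as np

from prmkit import labeling, simulate
from prmkit.chem import PeptideSpecies

rng = np.random.default_rng(0)
sequences = simulate.random_tryptic_peptides(rng, 8)
peptides = [(f"P{i}", s, 2) for i, s in enumerate(sequences)]

# standards expressed at 99.4% incorporation, measured with 2% envelope noise
table = simulate.sim_envelopes(peptides, p=0.994, noise_cv=0.02, seed=1)
table["protein"] = "SERPINC1"

result = labeling.efficiency_table(table)
print(result.to_string(index=False))
print()
print(result.attrs["precursors"].to_string(index=False))

# The protein-level efficiency should land within ~0.1% of the simulated
# 99.4%; per-precursor estimates scatter with the envelope noise.
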