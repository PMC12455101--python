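"""Absolute quantification from light/heavy fragment areas.

The heavy standard's monoisotopic signal under-represents its true amount
because only a fraction p̂ⁿ of molecules is fully labeled; the mean heavy
intensity is divided by p̂ⁿ before forming the light/heavy ratio.
"""

import numpy as np

from prmkit import quant

# three clean fragments, L = 1000, H = 2000 summed, 1 ng heavy spike
fragments = {
    f"y{i}": (np.full(3, 1000.0 / 3), np.full(3, 2000.0 / 3)) for i in range(3)
}

uncorrected = quant.precursor_quant(
    fragments, spike_amount=1.0, efficiency=0.99, n_nitrogen=15,
    correct_efficiency=False,
)
corrected = quant.precursor_quant(
    fragments, spike_amount=1.0, efficiency=0.99, n_nitrogen=15,
)

print(f"mean light            : {corrected.mean_light:.0f}")
print(f"mean heavy (raw)      : {corrected.mean_heavy_raw:.0f}")
print(f"mean heavy / 0.99^15  : {corrected.mean_heavy_corrected:.1f}")
print(f"amount, uncorrected   : {uncorrected.amount:.3f} ng")
print(f"amount, corrected     : {corrected.amount:.3f} ng")

protein = quant.protein_quant([corrected], "TTR", molecular_weight_kda=13.8)
print(f"protein amount        : {protein.amount:.3f} ng-equivalent units")
print(f"plasma concentration  : {protein.concentration_mg_l:.2f} mg/L")

# With p = 0.99 and n = 15 the correction factor is 0.99^15 = 0.860: the
# corrected light amount (0.430 ng) is 14% lower than the naive 0.500 ng.
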