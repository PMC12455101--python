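"""Predict the isotope envelope of a ¹⁵N-labeled tryptic peptide.

The mass shift of a metabolically labeled peptide depends on its nitrogen
content; incomplete labeling leaves an M−1 peak (one residual ¹⁴N) whose
size relative to the fully labeled monoisotopic peak M0 encodes the
incorporation fraction p.
"""

from prmkit import chem
from prmkit.chem import PeptideSpecies

peptide = PeptideSpecies("AADDTWEPFASGK", charge=2, label="heavy15N")
comp = chem.peptide_composition(peptide)

print(f"peptide      : {peptide.sequence} ({peptide.charge}+)")
print(f"nitrogens    : {comp.n}")
print(f"heavy shift  : {chem.delta_mz_15n(peptide):.4f} Th")

for p in (1.0, 0.99, 0.97):
    env = chem.predict_envelope(comp, p)
    ratio = chem.m1_m0_ratio(env)
    print(f"p = {p:.2f}  ->  M-1/M0 = {ratio:.4f}")

# A ratio of 0.1515 at p = 0.99 is the binomial value n(1-p)/p for n = 15:
# with 15 labeled sites, ~15% of fully-labeled-minus-one molecules remain.
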