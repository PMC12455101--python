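"""Peptide and fragment mass arithmetic for light and ¹⁵N-labeled species.

Full-length ¹⁵N-labeled protein standards produce tryptic peptides whose
mass shift relative to the endogenous (light) form depends on the nitrogen
content of the sequence: Δm/z = n·δ/z, where n is the number of labeled
nitrogen atoms and δ = m(¹⁵N) − m(¹⁴N). The same holds for every b/y
fragment, with n counted over the fragment's residues. Because metabolic
labeling is never perfectly complete, the isotope envelope of a heavy
precursor contains an M−1 peak (exactly one residual ¹⁴N) whose abundance
relative to the fully labeled monoisotopic peak M0 encodes the
incorporation fraction p. This module predicts those envelopes at
arbitrary p by convolving per-element isotopologue distributions, with the
nitrogen sites treated as a two-state (¹⁴N/¹⁵N) = (1−p, p) distribution.

Conventions
-----------
* M0 is the fully labeled monoisotopic species: every labeled nitrogen is
  ¹⁵N and every other atom is its lightest isotope. Envelope peak offsets
  are nominal-mass differences from M0, so residual ¹⁴N shows up at
  negative offsets and natural ¹³C/¹⁵N/¹⁸O... at positive ones.
* Carbamidomethylation of cysteine is treated as a fixed modification.
  Standards are alkylated after expression, so its nitrogen is light by
  default (``label_modification_nitrogen=False``).
* Monoisotopic masses and natural abundances come from the NIST table
  shipped with :mod:`pyteomics`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal

import numpy as np
from pyteomics import mass as _pmass

__all__ = [
    "PROTON_MASS",
    "DELTA_15N",
    "AminoAcidTable",
    "PeptideSpecies",
    "ElementalComposition",
    "IsotopeEnvelope",
    "nitrogen_count",
    "peptide_composition",
    "precursor_mz",
    "delta_mz_15n",
    "fragment_mz",
    "predict_envelope",
    "m1_m0_ratio",
]

PROTON_MASS = 1.00727646688
#: m(15N) - m(14N) in Da
DELTA_15N = 0.9970349

_STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_ELEMENTS = ("C", "H", "N", "O", "S")

# carbamidomethyl adds C2H3NO to cysteine; Met oxidation adds one O
_MOD_COMPOSITIONS = {
    "cam": {"C": 2, "H": 3, "N": 1, "O": 1},
    "ox": {"O": 1},
}


def _default_residue_table() -> dict[str, dict[str, int]]:
    table = {}
    for aa in _STANDARD_RESIDUES:
        comp = _pmass.std_aa_comp[aa]
        table[aa] = {el: int(comp.get(el, 0)) for el in _ELEMENTS}
    return table


@dataclass(frozen=True)
class AminoAcidTable:
    """Elemental compositions of the 20 standard residues plus fixed mods.

    ``residues`` maps a one-letter code to CHNOS counts of the residue
    (peptide-bond form, i.e. without the terminal water); ``water`` is the
    composition added once per peptide; ``modifications`` holds the
    fixed/optional modification compositions keyed by id.
    """

    residues: dict[str, dict[str, int]] = field(default_factory=_default_residue_table)
    water: dict[str, int] = field(default_factory=lambda: {"H": 2, "O": 1})
    modifications: dict[str, dict[str, int]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _MOD_COMPOSITIONS.items()}
    )

    def __post_init__(self) -> None:
        for aa, comp in self.residues.items():
            if any(c < 0 for c in comp.values()):
                raise ValueError(f"negative element count for residue {aa!r}")
            if comp.get("N", 0) < 1:
                raise ValueError(f"residue {aa!r} must contain at least one nitrogen")
        for aa in "KR":
            if aa in self.residues and self.residues[aa]["N"] < 2:
                raise ValueError(f"residue {aa!r} must contain at least two nitrogens")


_DEFAULT_TABLE = AminoAcidTable()

LabelState = Literal["light", "heavy15N"]


@dataclass(frozen=True)
class PeptideSpecies:
    """A peptide in a specific charge and label state.

    ``modifications`` is a list of ``(position, mod_id)`` with 1-based
    residue positions; carbamidomethyl-C is implied on every cysteine and
    does not need to be listed.
    """

    sequence: str
    charge: int
    label: LabelState = "light"
    modifications: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        for aa in self.sequence:
            if aa not in _STANDARD_RESIDUES:
                raise ValueError(f"unknown residue symbol {aa!r} in {self.sequence!r}")
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")
        if self.label not in ("light", "heavy15N"):
            raise ValueError(f"unknown label state {self.label!r}")
        for pos, mod in self.modifications:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(f"modification position {pos} outside sequence")
            if mod not in _MOD_COMPOSITIONS:
                raise ValueError(f"unknown modification id {mod!r}")


@dataclass(frozen=True)
class ElementalComposition:
    """CHNOS counts plus the number n of metabolically labeled N sites.

    ``n`` may be smaller than the total nitrogen count when a modification
    introduced after expression (e.g. carbamidomethyl) carries unlabeled
    nitrogen.
    """

    counts: dict[str, int]
    n: int

    def __post_init__(self) -> None:
        for el, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for element {el}")
        if not 0 <= self.n <= self.counts.get("N", 0):
            raise ValueError("labeled nitrogen count n must lie within the N entry")

    def monoisotopic_mass(self) -> float:
        """Neutral monoisotopic mass with all atoms at their lightest isotope."""
        m = 0.0
        for el, c in self.counts.items():
            m += c * _lightest_mass(el)
        return m


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Relative isotopologue abundances around the fully labeled M0 peak.

    ``offsets``/``abundances`` give the unit-resolution (nominal-mass-binned)
    envelope, which is what an MS1 extraction at typical resolving power
    measures. ``m0_species``/``m1_species`` are the abundances of the two
    exact isotopologue species the labeling-efficiency ratio is defined on:
    all labeled N heavy with every other atom lightest (M0), and exactly one
    residual ¹⁴N (M−1). The nominal bins at offsets 0 and −1 additionally
    contain cross terms such as (one ¹⁴N + one ¹³C), so the binned ratio is
    slightly larger than the species ratio for carbon-rich peptides.
    """

    p: float
    offsets: np.ndarray
    abundances: np.ndarray
    mode: Literal["m0", "sum"] = "m0"
    m0_species: float | None = None
    m1_species: float | None = None

    def __post_init__(self) -> None:
        offsets = np.asarray(self.offsets, dtype=int)
        abundances = np.asarray(self.abundances, dtype=float)
        object.__setattr__(self, "offsets", offsets)
        object.__setattr__(self, "abundances", abundances)
        if offsets.shape != abundances.shape:
            raise ValueError("offsets and abundances must have equal length")
        if np.any(np.diff(offsets) <= 0):
            raise ValueError("offsets must be strictly increasing")
        if 0 not in offsets:
            raise ValueError("envelope must contain the M0 peak (offset 0)")
        if np.any(abundances < 0):
            raise ValueError("abundances must be non-negative")

    def abundance_at(self, offset: int) -> float:
        idx = np.flatnonzero(self.offsets == offset)
        if idx.size == 0:
            raise ValueError(f"offset {offset} not present in envelope")
        return float(self.abundances[idx[0]])


@lru_cache(maxsize=None)
def _lightest_mass(element: str) -> float:
    """Monoisotopic mass of the lightest naturally occurring isotope."""
    iso = _pmass.nist_mass[element]
    lightest = min(k for k in iso if k != 0 and iso[k][1] > 0)
    return iso[lightest][0]


def _check_sequence(sequence: str, table: AminoAcidTable) -> None:
    if not sequence:
        raise ValueError("sequence must be non-empty")
    for aa in sequence:
        if aa not in table.residues:
            raise ValueError(f"unknown residue symbol {aa!r}")


def nitrogen_count(sequence: str, table: AminoAcidTable = _DEFAULT_TABLE) -> int:
    """Number of backbone plus side-chain nitrogen atoms in ``sequence``.

    Independent of charge state and of the terminal water; modification
    nitrogen (carbamidomethyl) is not counted because it is introduced
    after metabolic labeling.
    """
    _check_sequence(sequence, table)
    return sum(table.residues[aa]["N"] for aa in sequence)


def peptide_composition(
    peptide: PeptideSpecies,
    table: AminoAcidTable = _DEFAULT_TABLE,
    label_modification_nitrogen: bool = False,
) -> ElementalComposition:
    """Elemental composition of the intact peptide (water included).

    Carbamidomethyl is applied to every cysteine; additional modifications
    come from ``peptide.modifications``. With the default
    ``label_modification_nitrogen=False`` the carbamidomethyl nitrogen is
    excluded from the labeled-site count n.
    """
    counts = {el: 0 for el in _ELEMENTS}
    for aa in peptide.sequence:
        for el, c in table.residues[aa].items():
            counts[el] += c
    for el, c in table.water.items():
        counts[el] += c
    n_labeled = sum(table.residues[aa]["N"] for aa in peptide.sequence)
    n_cam = peptide.sequence.count("C")
    for _ in range(n_cam):
        for el, c in table.modifications["cam"].items():
            counts[el] += c
    if label_modification_nitrogen:
        n_labeled += n_cam * table.modifications["cam"].get("N", 0)
    for _pos, mod in peptide.modifications:
        for el, c in table.modifications[mod].items():
            counts[el] += c
    return ElementalComposition(counts=counts, n=n_labeled)


def precursor_mz(
    peptide: PeptideSpecies,
    table: AminoAcidTable = _DEFAULT_TABLE,
    label_modification_nitrogen: bool = False,
) -> float:
    """Monoisotopic precursor m/z; heavy species shifted by n·δ/z."""
    comp = peptide_composition(peptide, table, label_modification_nitrogen)
    mass = comp.monoisotopic_mass()
    if peptide.label == "heavy15N":
        mass += comp.n * DELTA_15N
    return (mass + peptide.charge * PROTON_MASS) / peptide.charge


def delta_mz_15n(peptide: PeptideSpecies, table: AminoAcidTable = _DEFAULT_TABLE) -> float:
    """Heavy-minus-light precursor m/z shift, n·δ/z (Th)."""
    if peptide.label != "heavy15N":
        raise ValueError("delta_mz_15n is defined for heavy15N species")
    if peptide.charge < 1:
        raise ValueError("charge must be >= 1")
    return nitrogen_count(peptide.sequence, table) * DELTA_15N / peptide.charge


def fragment_mz(
    peptide: PeptideSpecies,
    ion: Literal["b", "y"],
    index: int,
    fragment_charge: int = 1,
    table: AminoAcidTable = _DEFAULT_TABLE,
) -> float:
    """Monoisotopic m/z of the b- or y-ion at 1-based cleavage ordinal ``index``.

    For heavy15N peptides the fragment is shifted by (N atoms in the
    fragment's residues)·δ/z. Carbamidomethyl-C mass is included for
    cysteines falling in the fragment; its nitrogen is never label-shifted.
    """
    n_res = len(peptide.sequence)
    if not 1 <= index < n_res:
        raise ValueError(
            f"cleavage index {index} out of range for length-{n_res} sequence"
        )
    if fragment_charge < 1:
        raise ValueError("fragment charge must be >= 1")
    if ion == "b":
        frag_seq = peptide.sequence[:index]
        extra_mass = 0.0
    elif ion == "y":
        frag_seq = peptide.sequence[n_res - index:]
        extra_mass = sum(c * _lightest_mass(el) for el, c in table.water.items())
    else:
        raise ValueError(f"unknown ion series {ion!r}")
    mass = extra_mass
    for aa in frag_seq:
        for el, c in table.residues[aa].items():
            mass += c * _lightest_mass(el)
        if aa == "C":
            for el, c in table.modifications["cam"].items():
                mass += c * _lightest_mass(el)
    if peptide.label == "heavy15N":
        mass += nitrogen_count(frag_seq, table) * DELTA_15N
    return (mass + fragment_charge * PROTON_MASS) / fragment_charge


@lru_cache(maxsize=None)
def _natural_offset_dist(element: str) -> tuple[tuple[int, ...], tuple[float, ...]]:
    """Nominal-mass-offset distribution of one atom at natural abundance."""
    iso = _pmass.nist_mass[element]
    keys = [k for k in iso if k != 0 and iso[k][1] > 0]
    base = min(keys)
    pairs = sorted((k - base, iso[k][1]) for k in keys)
    offsets, probs = zip(*pairs)
    total = sum(probs)
    return offsets, tuple(pr / total for pr in probs)


def _convolve(
    a: np.ndarray, a0: int, b: np.ndarray, b0: int
) -> tuple[np.ndarray, int]:
    """Convolve two offset distributions; origins add."""
    return np.convolve(a, b), a0 + b0


def _element_dist(offsets: tuple[int, ...], probs: tuple[float, ...], count: int) -> tuple[np.ndarray, int]:
    """Distribution of the summed offset of ``count`` i.i.d. atoms."""
    span = offsets[-1] - offsets[0]
    single = np.zeros(span + 1)
    for off, pr in zip(offsets, probs):
        single[off - offsets[0]] = pr
    # exponentiation by squaring on the convolution semiring
    result = np.array([1.0])
    origin = 0
    base, base0 = single, offsets[0]
    k = count
    while k:
        if k & 1:
            result, origin = _convolve(result, origin, base, base0)
        k >>= 1
        if k:
            base, base0 = _convolve(base, base0, base, base0)
    return result, origin


def predict_envelope(
    composition: ElementalComposition,
    p: float,
    mode: Literal["m0", "sum"] = "m0",
    min_span: tuple[int, int] = (-2, 3),
) -> IsotopeEnvelope:
    """Isotope envelope of a ¹⁵N-labeled molecule at incorporation ``p``.

    Each of the ``composition.n`` labeled nitrogen sites is ¹⁵N with
    probability p and ¹⁴N with probability 1−p; all other atoms (including
    unlabeled modification nitrogen) follow natural isotope abundances.
    Offsets are nominal-mass differences from the fully labeled
    monoisotopic peak M0. The returned envelope always covers at least
    ``min_span`` around M0 (zero-padded where nothing contributes).
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"incorporation p must be in (0, 1], got {p}")
    dist = np.array([1.0])
    origin = 0
    for el, count in composition.counts.items():
        if count == 0:
            continue
        natural_count = count - composition.n if el == "N" else count
        if natural_count:
            offs, probs = _natural_offset_dist(el)
            d, o = _element_dist(offs, probs, natural_count)
            dist, origin = _convolve(dist, origin, d, o)
    if composition.n:
        # labeled site: offset 0 = 15N (prob p), offset -1 = residual 14N
        d, o = _element_dist((-1, 0), (1.0 - p, p), composition.n)
        dist, origin = _convolve(dist, origin, d, o)
    offsets = np.arange(origin, origin + dist.size)
    lo = min(offsets[0], min_span[0])
    hi = max(offsets[-1], min_span[1])
    full = np.zeros(hi - lo + 1)
    full[offsets[0] - lo : offsets[0] - lo + dist.size] = dist
    offsets = np.arange(lo, hi + 1)
    # exact-species abundances: all natural atoms at their lightest isotope
    p_nat0 = 1.0
    for el, count in composition.counts.items():
        natural_count = count - composition.n if el == "N" else count
        if natural_count:
            offs, probs = _natural_offset_dist(el)
            p_nat0 *= probs[offs.index(0)] ** natural_count
    n = composition.n
    m0_species = p**n * p_nat0
    m1_species = n * (1.0 - p) * p ** (n - 1) * p_nat0 if n else 0.0
    m0 = full[np.flatnonzero(offsets == 0)[0]]
    if mode == "m0":
        if m0 <= 0:
            raise ValueError("M0 abundance is zero; cannot normalize to M0")
        scale = 1.0 / m0
    elif mode == "sum":
        scale = 1.0 / full.sum()
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return IsotopeEnvelope(
        p=p,
        offsets=offsets,
        abundances=full * scale,
        mode=mode,
        m0_species=m0_species * scale,
        m1_species=m1_species * scale,
    )


def m1_m0_ratio(envelope: IsotopeEnvelope) -> float:
    """Abundance ratio of the M−1 species (one residual ¹⁴N) to M0.

    Invariant to the envelope's normalization mode. Defined on the exact
    isotopologue species, so for n labeled nitrogens it equals n(1−p)/p
    (no other element contributes a −1 Da species). Falls back to the
    nominal-bin abundances for envelopes built without species bookkeeping.
    """
    # precondition per contract: both peaks must exist in the envelope
    envelope.abundance_at(-1)
    m0_bin = envelope.abundance_at(0)
    if envelope.m0_species is not None and envelope.m1_species is not None:
        if envelope.m0_species <= 0:
            raise ValueError("M0 abundance must be positive")
        return envelope.m1_species / envelope.m0_species
    if m0_bin <= 0:
        raise ValueError("M0 abundance must be positive")
    return envelope.abundance_at(-1) / m0_bin
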