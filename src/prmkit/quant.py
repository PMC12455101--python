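"""Calibration and absolute quantification with ¹⁵N protein standards.

A dilution series of the heavy standard in a constant matrix is fitted
with a bilinear (hockey-stick) model: a constant noise floor below a
turning point and a straight line above it, fitted by 1/x-weighted least
squares over a continuous grid of candidate turning points. The turning
point is the limit of detection (LOD); the limit of quantification (LOQ)
is the lowest level at or above the LOD whose replicate CV — and the CV of
every higher level — stays within 20%.

Absolute amounts come from light/heavy ratios of summed fragment areas.
Because metabolic labeling is incomplete (incorporation p̂ < 1), only a
fraction p̂ⁿ of heavy molecules with n nitrogen atoms is fully labeled and
contributes to the monoisotopic heavy signal; the mean heavy intensity is
therefore divided by p̂ⁿ before ratio formation. Precursors are excluded
— with machine-readable flags — when the computed amount falls below the
LOQ, the heavy signal-to-noise ratio is below 5, or fewer than three
interference-free fragments survive the per-fragment CV filter. Protein
amounts are the mean over included precursor amounts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DilutionLevel",
    "DilutionSeries",
    "CalibrationResult",
    "PrecursorQuant",
    "ProteinQuant",
    "DEFAULT_SAMPLE_PREP",
    "tic_normalize",
    "bilinear_fit",
    "loq_from_cv",
    "fragment_cv_filter",
    "interference_free_fragments",
    "precursor_quant",
    "protein_quant",
]

#: Sample-prep volume accounting used to express amounts as plasma
#: concentrations: 5 µl plasma tenfold-diluted, 10 µl of the dilution
#: (= 1 µl plasma) digested in 40 µl, quenched to 100 µl, 1 µl injected.
DEFAULT_SAMPLE_PREP = {
    "plasma_ul": 5.0,
    "dilution_factor": 10.0,
    "digested_dilution_ul": 10.0,
    "digest_volume_ul": 100.0,
    "injected_ul": 1.0,
    # plasma volume equivalent per injection, in liters:
    # (10/50)*5 µl = 1 µl plasma in 100 µl digest; 1 µl injected -> 0.01 µl
    "plasma_equivalent_l": 1e-8,
}


@dataclass(frozen=True)
class DilutionLevel:
    amount: float  # nominal spike amount at this level
    areas: np.ndarray  # replicate areas
    tics: np.ndarray | None = None  # per-run total ion current

    def __post_init__(self) -> None:
        object.__setattr__(self, "areas", np.asarray(self.areas, dtype=float))
        if self.tics is not None:
            object.__setattr__(self, "tics", np.asarray(self.tics, dtype=float))
        if self.areas.size < 2:
            raise ValueError("each level needs at least two replicates")


@dataclass(frozen=True)
class DilutionSeries:
    """A dilution series for one precursor (amounts strictly decreasing)."""

    precursor_id: str
    levels: tuple[DilutionLevel, ...]
    unit: str = "ng"
    dilution_factor: float = 4.0

    def __post_init__(self) -> None:
        if len(self.levels) < 4:
            raise ValueError("a dilution series needs at least four levels")
        amounts = [lv.amount for lv in self.levels]
        if any(b >= a for a, b in zip(amounts, amounts[1:])):
            raise ValueError("level amounts must be strictly decreasing")

    def amounts(self) -> np.ndarray:
        return np.array([lv.amount for lv in self.levels])

    def normalized_areas(self) -> list[np.ndarray]:
        """Replicate areas per level, TIC-normalized when TICs are present."""
        all_tics = np.concatenate(
            [lv.tics for lv in self.levels if lv.tics is not None]
        ) if any(lv.tics is not None for lv in self.levels) else None
        out = []
        for lv in self.levels:
            if lv.tics is None or all_tics is None:
                out.append(lv.areas.copy())
            else:
                out.append(lv.areas / lv.tics * all_tics.mean())
        return out


@dataclass(frozen=True)
class CalibrationResult:
    """Bilinear fit: noise floor below the turning point, line above."""

    precursor_id: str
    turning_point: float  # = LOD, in series units
    noise_floor: float
    slope: float
    intercept: float
    level_cv_percent: np.ndarray
    weighting: str = "1/x"
    valid: bool = True

    @property
    def lod(self) -> float:
        return self.turning_point


@dataclass(frozen=True)
class PrecursorQuant:
    """Light/heavy quantification of one precursor pair."""

    precursor_id: str
    n_nitrogen: int
    efficiency: float
    mean_light: float
    mean_heavy_raw: float
    mean_heavy_corrected: float
    light_heavy_ratio: float
    amount: float
    n_fragments_used: int
    flags: tuple[str, ...] = ()

    @property
    def included(self) -> bool:
        return not self.flags


@dataclass(frozen=True)
class ProteinQuant:
    protein_id: str
    amount: float  # mean over included precursors, spike units (e.g. pmol)
    concentration_mg_l: float
    n_peptides: int
    sd: float
    sd_percent: float
    best_loq: float
    excluded: tuple[PrecursorQuant, ...] = ()


def tic_normalize(areas, tic_per_run) -> np.ndarray:
    """Scale each run's areas by mean(TIC)/run TIC."""
    areas = np.asarray(areas, dtype=float)
    tics = np.asarray(tic_per_run, dtype=float)
    if areas.shape != tics.shape:
        raise ValueError("areas and TICs must align")
    if np.any(tics <= 0):
        raise ValueError("TIC must be positive for every run")
    return areas / tics * tics.mean()


def _fit_at_turning_point(
    x: np.ndarray, y: np.ndarray, w: np.ndarray, c_t: float
) -> tuple[float, float, float]:
    """Weighted LSQ of y = floor + slope*max(x - c_t, 0); returns (floor, slope, sse)."""
    ramp = np.maximum(x - c_t, 0.0)
    design = np.column_stack([np.ones_like(x), ramp])
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
    resid = y - design @ coef
    return float(coef[0]), float(coef[1]), float(np.sum(w * resid**2))


def bilinear_fit(series: DilutionSeries, n_grid: int = 200) -> CalibrationResult:
    """Fit the two-segment calibration model; the turning point is the LOD.

    Candidate turning points are scanned on a log-spaced continuous grid
    between the lowest and highest level amounts; at each candidate the
    floor and slope follow from 1/x-weighted least squares on the
    replicate-level data. Fits with a non-positive slope or fewer than two
    levels above the turning point are rejected; if no candidate is
    acceptable the result is flagged invalid.
    """
    amounts = series.amounts()
    norm = series.normalized_areas()
    x = np.concatenate([np.full(a.size, amt) for amt, a in zip(amounts, norm)])
    y = np.concatenate(norm)
    w = 1.0 / np.maximum(x, amounts.min() * 1e-3)
    cvs = np.array(
        [a.std(ddof=1) / a.mean() * 100.0 if a.mean() > 0 else math.nan for a in norm]
    )
    grid = np.geomspace(amounts.min(), amounts.max(), n_grid)
    best = None
    for c_t in grid:
        if np.sum(amounts > c_t) < 2:
            continue
        floor, slope, sse = _fit_at_turning_point(x, y, w, c_t)
        # the linear segment must rise meaningfully above the floor
        if slope <= 0 or slope * (x.max() - c_t) < 1e-6 * max(abs(y).max(), 1e-12):
            continue
        if best is None or sse < best[3]:
            best = (c_t, floor, slope, sse)
    if best is None:
        return CalibrationResult(
            precursor_id=series.precursor_id,
            turning_point=math.nan,
            noise_floor=float(np.median(y)),
            slope=0.0,
            intercept=0.0,
            level_cv_percent=cvs,
            valid=False,
        )
    c_t, floor, slope, _ = best
    return CalibrationResult(
        precursor_id=series.precursor_id,
        turning_point=float(c_t),
        noise_floor=floor,
        slope=slope,
        intercept=float(floor - slope * c_t),
        level_cv_percent=cvs,
        valid=True,
    )


def loq_from_cv(
    series: DilutionSeries, calib: CalibrationResult, max_cv_percent: float = 20.0
) -> float:
    """Lowest level >= LOD whose CV, and every higher level's CV, is in bound.

    Returns ``inf`` when no level qualifies.
    """
    if not calib.valid:
        return math.inf
    amounts = series.amounts()  # strictly decreasing
    cvs = calib.level_cv_percent
    loq = math.inf
    # walk from the top level down; stop at the first failure
    for amount, cv in zip(amounts, cvs):
        if not cv <= max_cv_percent:
            break
        if amount >= calib.lod:
            loq = amount
    return loq


def fragment_cv_filter(
    fragments: dict[str, tuple[np.ndarray, np.ndarray]],
    max_cv_percent: float = 20.0,
) -> list[str]:
    """Fragments whose light and heavy replicate CVs both stay within bound.

    ``fragments`` maps fragment id to (light replicate areas, heavy
    replicate areas).
    """
    kept = []
    for frag, (light, heavy) in fragments.items():
        light = np.asarray(light, dtype=float)
        heavy = np.asarray(heavy, dtype=float)
        if light.size < 2 or heavy.size < 2:
            raise ValueError(f"fragment {frag!r} needs at least two replicates")
        ok = True
        for areas in (light, heavy):
            mean = areas.mean()
            if mean <= 0 or areas.std(ddof=1) / mean * 100.0 > max_cv_percent:
                ok = False
        if ok:
            kept.append(frag)
    return kept


def interference_free_fragments(
    fragments: dict[str, tuple[np.ndarray, np.ndarray]],
    correlations: dict[str, float] | None = None,
    min_correlation: float = 0.9,
    max_ratio_fold: float = 2.0,
) -> list[str]:
    """Fragments considered free of co-eluting interference.

    A fragment qualifies when its chromatographic correlation to the
    precursor median trace (if supplied) is at least ``min_correlation``
    and its light/heavy ratio lies within ``max_ratio_fold`` of the median
    fragment ratio — an interfered fragment inflates one channel only.
    """
    ratios = {}
    for frag, (light, heavy) in fragments.items():
        h = float(np.mean(heavy))
        ratios[frag] = float(np.mean(light)) / h if h > 0 else math.inf
    finite = [r for r in ratios.values() if math.isfinite(r) and r > 0]
    med = float(np.median(finite)) if finite else math.nan
    out = []
    for frag, ratio in ratios.items():
        if correlations is not None:
            corr = correlations.get(frag, math.nan)
            if not corr >= min_correlation:
                continue
        if math.isfinite(med) and med > 0:
            if not (med / max_ratio_fold <= ratio <= med * max_ratio_fold):
                continue
        out.append(frag)
    return out


def precursor_quant(
    fragments: dict[str, tuple[np.ndarray, np.ndarray]],
    spike_amount: float,
    efficiency: float,
    n_nitrogen: int,
    precursor_id: str = "",
    loq: float | None = None,
    heavy_s_over_n: float | None = None,
    correlations: dict[str, float] | None = None,
    correct_efficiency: bool = True,
    min_clean_fragments: int = 3,
    max_fragment_cv_percent: float = 20.0,
    min_heavy_s_over_n: float = 5.0,
) -> PrecursorQuant:
    """Absolute light amount of one precursor pair from fragment areas.

    The precursor intensity per replicate is the sum of the retained
    fragment areas; replicate means give the light and heavy intensities.
    The heavy mean is divided by p̂ⁿ (fraction of fully labeled molecules)
    before the light/heavy ratio and the absolute amount
    ``spike_amount x light / heavy_corrected`` are formed. Exclusion flags
    follow the assay's rules; an excluded precursor always carries at
    least one flag.
    """
    if not fragments:
        raise ValueError("no fragment areas supplied")
    if not 0 < efficiency <= 1:
        raise ValueError("efficiency must be in (0, 1]")
    flags: list[str] = []
    cv_kept = fragment_cv_filter(fragments, max_fragment_cv_percent)
    clean = interference_free_fragments(
        {f: fragments[f] for f in cv_kept} if cv_kept else fragments,
        correlations=correlations,
    )
    retained = [f for f in cv_kept if f in clean]
    if len(cv_kept) < len(fragments) and len(retained) < min_clean_fragments:
        flags.append("fragment_CV_above_20")
    if len(retained) < min_clean_fragments:
        flags.append("fewer_than_3_clean_fragments")
        retained = retained or list(fragments)
    light_sum = np.sum([fragments[f][0] for f in retained], axis=0)
    heavy_sum = np.sum([fragments[f][1] for f in retained], axis=0)
    mean_light = float(np.mean(light_sum))
    mean_heavy = float(np.mean(heavy_sum))
    if mean_heavy <= 0:
        raise ValueError("zero heavy signal; cannot form light/heavy ratio")
    correction = efficiency**n_nitrogen if correct_efficiency else 1.0
    heavy_corrected = mean_heavy / correction
    ratio = mean_light / heavy_corrected
    amount = spike_amount * ratio
    if heavy_s_over_n is not None and heavy_s_over_n < min_heavy_s_over_n:
        flags.append("heavy_SN_below_5")
    if loq is not None and amount < loq:
        flags.append("below_LOQ")
    return PrecursorQuant(
        precursor_id=precursor_id,
        n_nitrogen=n_nitrogen,
        efficiency=efficiency,
        mean_light=mean_light,
        mean_heavy_raw=mean_heavy,
        mean_heavy_corrected=heavy_corrected,
        light_heavy_ratio=ratio,
        amount=float(amount),
        n_fragments_used=len(retained),
        flags=tuple(dict.fromkeys(flags)),
    )


def protein_quant(
    precursors: list[PrecursorQuant],
    protein_id: str,
    molecular_weight_kda: float,
    plasma_equivalent_l: float = DEFAULT_SAMPLE_PREP["plasma_equivalent_l"],
    precursor_loqs: dict[str, float] | None = None,
) -> ProteinQuant:
    """Protein amount as the mean over included precursor amounts.

    Concentration converts pmol to mg/L through the molecular weight
    (1 pmol x 1 kDa = 1 ng) and the plasma volume equivalent injected.
    Raises when every precursor is excluded (reasons are in the flags).
    """
    included = [p for p in precursors if p.included]
    excluded = tuple(p for p in precursors if not p.included)
    if not included:
        reasons = sorted({f for p in excluded for f in p.flags})
        raise ValueError(f"all precursors of {protein_id} excluded: {reasons}")
    amounts = np.array([p.amount for p in included])
    amount = float(amounts.mean())
    sd = float(amounts.std(ddof=1)) if amounts.size > 1 else 0.0
    mass_ng = amount * molecular_weight_kda  # pmol * kDa = ng
    conc_mg_l = mass_ng * 1e-6 / plasma_equivalent_l
    best_loq = math.inf
    if precursor_loqs:
        candidate = [
            precursor_loqs[p.precursor_id]
            for p in included
            if p.precursor_id in precursor_loqs
        ]
        if candidate:
            best_loq = float(min(candidate))
    return ProteinQuant(
        protein_id=protein_id,
        amount=amount,
        concentration_mg_l=float(conc_mg_l),
        n_peptides=len(included),
        sd=sd,
        sd_percent=sd / amount * 100.0 if amount else math.nan,
        best_loq=best_loq,
        excluded=excluded,
    )
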