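"""¹⁵N incorporation estimation from observed M−1/M0 ratios.

The measured ratio of the M−1 isotopologue (exactly one residual ¹⁴N) to
the fully labeled monoisotopic peak M0 decreases monotonically with the
incorporation fraction p. For each precursor, predicted ratios are
computed on a grid of candidate incorporations (default 95%–100%), a
straight line is fitted to ratio-versus-p, and the observed ratio is
inverted through that line to give the precursor-level estimate p̂.
Protein-level incorporation is the median of the in-range precursor
estimates, with the median absolute deviation as a dispersion measure.

The linear inversion is justified by the near-linearity of the exact
relation n(1−p)/p over the narrow grid span; residual curvature keeps the
noise-free inversion error below 1e−3 in p for tryptic peptides
(n up to ~40).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import chem
from .chem import PeptideSpecies

__all__ = [
    "DEFAULT_P_GRID",
    "EfficiencyCurve",
    "PrecursorEfficiency",
    "ProteinEfficiency",
    "build_curve",
    "estimate_efficiency",
    "protein_efficiency",
    "efficiency_table",
]

#: default incorporation grid, spanning 95% to 100%
DEFAULT_P_GRID = (0.95, 0.96, 0.97, 0.98, 0.99, 0.995, 1.00)


@dataclass(frozen=True)
class EfficiencyCurve:
    """Predicted M−1/M0 ratio versus incorporation for one precursor."""

    precursor_id: str
    p_grid: np.ndarray
    ratios: np.ndarray
    slope: float
    intercept: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "p_grid", np.asarray(self.p_grid, dtype=float))
        object.__setattr__(self, "ratios", np.asarray(self.ratios, dtype=float))
        if np.any(np.diff(self.ratios) >= 0) and self.p_grid.size > 1:
            raise ValueError("predicted ratio must be strictly decreasing in p")


@dataclass(frozen=True)
class PrecursorEfficiency:
    precursor_id: str
    observed_ratio: float
    p_hat: float
    in_range: bool


@dataclass(frozen=True)
class ProteinEfficiency:
    protein_id: str
    p_hat: float
    dispersion: float
    precursors: tuple[PrecursorEfficiency, ...]


def build_curve(
    peptide: PeptideSpecies,
    p_grid=DEFAULT_P_GRID,
    precursor_id: str | None = None,
) -> EfficiencyCurve:
    """Predicted-ratio curve and fitted line for ``peptide``.

    Ratios come from :func:`prmkit.chem.predict_envelope` evaluated at each
    grid incorporation; the line is an ordinary least-squares fit of ratio
    against p over the grid.
    """
    grid = np.asarray(sorted(p_grid), dtype=float)
    if grid.size < 2:
        raise ValueError("incorporation grid needs at least two points")
    if grid[0] <= 0 or grid[-1] > 1:
        raise ValueError("incorporation grid must lie within (0, 1]")
    comp = chem.peptide_composition(peptide)
    ratios = np.array(
        [chem.m1_m0_ratio(chem.predict_envelope(comp, p)) for p in grid]
    )
    slope, intercept = np.polyfit(grid, ratios, 1)
    if precursor_id is None:
        precursor_id = f"{peptide.sequence}/{peptide.charge}"
    return EfficiencyCurve(
        precursor_id=precursor_id,
        p_grid=grid,
        ratios=ratios,
        slope=float(slope),
        intercept=float(intercept),
    )


def estimate_efficiency(curve: EfficiencyCurve, observed_ratio: float) -> PrecursorEfficiency:
    """Invert the fitted line at ``observed_ratio`` to estimate p̂.

    p̂ is clipped to (0, 1]; ``in_range`` is False whenever the raw
    inversion falls outside the curve's grid span (extrapolation).
    """
    if observed_ratio < 0:
        raise ValueError("observed ratio must be non-negative")
    if curve.slope == 0:
        raise ValueError("degenerate curve: zero slope")
    raw = (observed_ratio - curve.intercept) / curve.slope
    in_range = bool(curve.p_grid[0] <= raw <= curve.p_grid[-1])
    p_hat = float(np.clip(raw, np.nextafter(0.0, 1.0), 1.0))
    if not in_range:
        # extrapolated estimates are clipped to the grid edge on the low side
        p_hat = float(np.clip(p_hat, curve.p_grid[0], 1.0))
    return PrecursorEfficiency(
        precursor_id=curve.precursor_id,
        observed_ratio=float(observed_ratio),
        p_hat=p_hat,
        in_range=in_range,
    )


def protein_efficiency(
    estimates: list[PrecursorEfficiency], protein_id: str = ""
) -> ProteinEfficiency:
    """Aggregate precursor estimates: median p̂ with MAD dispersion.

    Only in-range estimates enter the aggregate; at least one is required.
    """
    if not estimates:
        raise ValueError("no precursor estimates supplied")
    in_range = [e for e in estimates if e.in_range]
    if not in_range:
        raise ValueError("no in-range precursor estimates to aggregate")
    values = np.array([e.p_hat for e in in_range])
    agg = float(np.median(values))
    mad = float(np.median(np.abs(values - agg)))
    return ProteinEfficiency(
        protein_id=protein_id,
        p_hat=agg,
        dispersion=mad,
        precursors=tuple(estimates),
    )


def efficiency_table(observations: pd.DataFrame, p_grid=DEFAULT_P_GRID) -> pd.DataFrame:
    """Per-protein labeling efficiency from a table of envelope areas.

    ``observations`` needs columns ``protein``, ``precursor``, ``sequence``,
    ``charge``, ``m1_area``, ``m0_area``. Returns one row per protein with
    the aggregate efficiency, dispersion and the number of precursors used,
    plus a per-precursor detail frame attached in ``attrs['precursors']``.
    """
    required = {"protein", "precursor", "sequence", "charge", "m1_area", "m0_area"}
    missing = required - set(observations.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    detail_rows = []
    protein_rows = []
    for protein, group in observations.groupby("protein", sort=True):
        estimates = []
        for row in group.itertuples(index=False):
            if row.m0_area <= 0:
                continue
            pep = PeptideSpecies(row.sequence, int(row.charge), "heavy15N")
            curve = build_curve(pep, p_grid, precursor_id=str(row.precursor))
            est = estimate_efficiency(curve, row.m1_area / row.m0_area)
            estimates.append(est)
            detail_rows.append(
                {
                    "protein": protein,
                    "precursor": est.precursor_id,
                    "observed_ratio": est.observed_ratio,
                    "p_hat": est.p_hat,
                    "in_range": est.in_range,
                }
            )
        agg = protein_efficiency(estimates, protein_id=str(protein))
        protein_rows.append(
            {
                "protein": protein,
                "efficiency": agg.p_hat,
                "dispersion": agg.dispersion,
                "n_precursors": sum(e.in_range for e in estimates),
            }
        )
    result = pd.DataFrame(protein_rows)
    result.attrs["precursors"] = pd.DataFrame(detail_rows)
    return result
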