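"""Offline retention-time realignment against a compressed DIA reference.

Scheduled acquisition windows tolerate chromatographic drift only if the
schedule is realigned while the run unfolds. The approach re-implemented
here builds a compressed reference map from wide-window DIA spectra
(narrow discovery windows are summed in silico into >= 50 Th windows,
binned to ~1 Th and intensity-quantized), then estimates the RT lag of a
new run by maximizing the mean cosine correlation between the run's
wide-window spectra and reference spectra over candidate lags within a
search band (default ±30 s), with parabolic sub-grid refinement. The
estimated lag series, median-smoothed, translates every scheduled window.

Scan tables are long-format frames with columns
``rt, window_low, window_high, mz, intensity`` (one row per non-empty
m/z bin of one wide-window scan).
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd

from .assaydesign import AssayMethod

__all__ = [
    "ReferenceMap",
    "ShiftEstimate",
    "build_reference",
    "bin_scans",
    "estimate_shift",
    "shift_series",
    "apply_shift",
    "normalized_rt_error",
]

SCAN_COLUMNS = ("rt", "window_low", "window_high", "mz", "intensity")


@dataclass(frozen=True)
class ReferenceMap:
    """Compressed wide-window reference spectra over the RT grid."""

    rt_grid: np.ndarray  # s, strictly increasing
    bin_edges: np.ndarray  # m/z bin edges shared by all grid points
    windows: tuple[tuple[float, float], ...]  # combined wide-window bounds
    spectra: np.ndarray  # (n_rt, n_bins) quantized intensities
    quant_max: float  # intensity mapped to the top quantization code
    quant_bits: int = 8
    source: str = "prmkit"

    def __post_init__(self) -> None:
        object.__setattr__(self, "rt_grid", np.asarray(self.rt_grid, dtype=float))
        object.__setattr__(self, "bin_edges", np.asarray(self.bin_edges, dtype=float))
        object.__setattr__(self, "spectra", np.asarray(self.spectra))
        if np.any(np.diff(self.rt_grid) <= 0):
            raise ValueError("RT grid must be strictly increasing")
        if self.spectra.shape != (self.rt_grid.size, self.bin_edges.size - 1):
            raise ValueError("spectra shape must match RT grid and bin scheme")

    @property
    def grid_step(self) -> float:
        return float(np.median(np.diff(self.rt_grid)))


@dataclass(frozen=True)
class ShiftEstimate:
    """An RT lag (positive = later elution than reference) with its score."""

    lag_s: float
    score: float
    band_s: float
    valid: bool

    def __post_init__(self) -> None:
        if self.valid and abs(self.lag_s) > self.band_s + 1e-9:
            raise ValueError("valid lag must lie within the search band")


def _quantize(x: np.ndarray, quant_max: float, bits: int) -> np.ndarray:
    """8-bit (default) logarithmic intensity compression."""
    levels = (1 << bits) - 1
    scaled = np.log1p(np.clip(x, 0.0, quant_max)) / np.log1p(quant_max)
    return np.rint(scaled * levels).astype(np.uint16 if bits > 8 else np.uint8)


def _validate_scans(scans: pd.DataFrame) -> None:
    missing = set(SCAN_COLUMNS) - set(scans.columns)
    if missing:
        raise ValueError(f"scan table missing columns: {sorted(missing)}")


def build_reference(
    dia_scans: pd.DataFrame,
    combine_to: float = 50.0,
    bin_width: float = 1.0,
    quant_bits: int = 8,
    source: str = "prmkit",
) -> ReferenceMap:
    """Combine narrow DIA windows into a wide-window reference map.

    Adjacent isolation windows are summed until each combined window spans
    at least ``combine_to`` Th; spectra are binned to ``bin_width`` Th and
    log-quantized. Gaps in the window coverage are rejected.
    """
    _validate_scans(dia_scans)
    native = (
        dia_scans[["window_low", "window_high"]]
        .drop_duplicates()
        .sort_values("window_low")
        .to_numpy()
    )
    widths = native[:, 1] - native[:, 0]
    if combine_to < widths.max():
        raise ValueError("combine_to must be at least the native window width")
    if np.any(np.abs(native[1:, 0] - native[:-1, 1]) > 1e-6):
        raise ValueError("gaps or overlaps in DIA window coverage")
    combined = []
    lo = native[0, 0]
    for w_lo, w_hi in native:
        if w_hi - lo >= combine_to:
            combined.append((float(lo), float(w_hi)))
            lo = w_hi
    if not combined or combined[-1][1] < native[-1, 1]:
        last_lo = combined[-1][1] if combined else native[0, 0]
        if native[-1, 1] > last_lo:
            combined.append((float(last_lo), float(native[-1, 1])))
    rt_grid = np.sort(dia_scans["rt"].unique())
    lo_mz, hi_mz = dia_scans["mz"].min(), dia_scans["mz"].max()
    bin_edges = np.arange(
        np.floor(lo_mz / bin_width) * bin_width,
        np.ceil(hi_mz / bin_width) * bin_width + bin_width,
        bin_width,
    )
    rt_idx = np.searchsorted(rt_grid, dia_scans["rt"].to_numpy())
    mz_idx = np.clip(
        np.digitize(dia_scans["mz"].to_numpy(), bin_edges) - 1, 0, bin_edges.size - 2
    )
    dense = np.zeros((rt_grid.size, bin_edges.size - 1))
    np.add.at(dense, (rt_idx, mz_idx), dia_scans["intensity"].to_numpy())
    quant_max = float(dense.max()) or 1.0
    return ReferenceMap(
        rt_grid=rt_grid,
        bin_edges=bin_edges,
        windows=tuple(combined),
        spectra=_quantize(dense, quant_max, quant_bits),
        quant_max=quant_max,
        quant_bits=quant_bits,
        source=source,
    )


def bin_scans(run_scans: pd.DataFrame, reference: ReferenceMap) -> tuple[np.ndarray, np.ndarray]:
    """Bin and quantize run scans onto the reference's bin scheme.

    Returns (run RT grid, quantized spectra matrix).
    """
    _validate_scans(run_scans)
    edges = reference.bin_edges
    inside = (run_scans["mz"] >= edges[0]) & (run_scans["mz"] < edges[-1])
    scans = run_scans[inside]
    rt_grid = np.sort(run_scans["rt"].unique())
    rt_idx = np.searchsorted(rt_grid, scans["rt"].to_numpy())
    mz_idx = np.digitize(scans["mz"].to_numpy(), edges) - 1
    dense = np.zeros((rt_grid.size, edges.size - 1))
    np.add.at(dense, (rt_idx, mz_idx), scans["intensity"].to_numpy())
    return rt_grid, _quantize(dense, reference.quant_max, reference.quant_bits)


def _mean_cosine(
    run_rts: np.ndarray,
    run_spec: np.ndarray,
    reference: ReferenceMap,
    lag: float,
) -> float:
    ref_rts = reference.rt_grid
    shifted = run_rts - lag
    keep = (shifted >= ref_rts[0]) & (shifted <= ref_rts[-1])
    if not keep.any():
        return float("nan")
    idx = np.clip(np.searchsorted(ref_rts, shifted[keep]), 0, ref_rts.size - 1)
    # mean-centered cosine: plain cosine of non-negative spectra is inflated
    # by the shared chemical-background pattern, masking mismatches
    a = run_spec[keep].astype(float)
    b = reference.spectra[idx].astype(float)
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    ok = (na > 0) & (nb > 0)
    if not ok.any():
        return float("nan")
    cos = np.einsum("ij,ij->i", a[ok], b[ok]) / (na[ok] * nb[ok])
    return float(cos.mean())


def estimate_shift(
    run_scans: pd.DataFrame,
    reference: ReferenceMap,
    band_s: float = 30.0,
    min_score: float = 0.5,
) -> ShiftEstimate:
    """RT lag of a block of run scans relative to the reference.

    The lag maximizing the mean cosine correlation over the candidate grid
    (one reference grid step) is refined by parabolic interpolation of the
    score around the peak. The estimate is invalid when the peak score is
    below ``min_score`` or no overlap exists.
    """
    run_rts, run_spec = bin_scans(run_scans, reference)
    if run_spec.sum() == 0:
        return ShiftEstimate(lag_s=0.0, score=0.0, band_s=band_s, valid=False)
    step = reference.grid_step
    lags = np.arange(-band_s, band_s + step / 2, step)
    scores = np.array([_mean_cosine(run_rts, run_spec, reference, lag) for lag in lags])
    if np.all(np.isnan(scores)):
        return ShiftEstimate(lag_s=0.0, score=0.0, band_s=band_s, valid=False)
    best = int(np.nanargmax(scores))
    lag, score = float(lags[best]), float(scores[best])
    if 0 < best < lags.size - 1 and not np.isnan(scores[best - 1] + scores[best + 1]):
        y0, y1, y2 = scores[best - 1], scores[best], scores[best + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            lag += float(0.5 * (y0 - y2) / denom) * step
    lag = float(np.clip(lag, -band_s, band_s))
    return ShiftEstimate(lag_s=lag, score=score, band_s=band_s, valid=score >= min_score)


def shift_series(
    run_scans: pd.DataFrame,
    reference: ReferenceMap,
    chunk_s: float = 30.0,
    band_s: float = 30.0,
    min_score: float = 0.5,
) -> list[tuple[float, ShiftEstimate]]:
    """Per-chunk shift estimates along the run (one per ``chunk_s`` of RT)."""
    _validate_scans(run_scans)
    rts = run_scans["rt"]
    edges = np.arange(rts.min(), rts.max() + chunk_s, chunk_s)
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        chunk = run_scans[(rts >= lo) & (rts < hi)]
        if chunk.empty:
            continue
        est = estimate_shift(chunk, reference, band_s=band_s, min_score=min_score)
        out.append((float((lo + hi) / 2), est))
    return out


def apply_shift(
    method: AssayMethod,
    shifts: list[tuple[float, ShiftEstimate]],
    smooth_window: int = 5,
) -> AssayMethod:
    """Translate every scheduled window by the interpolated lag at its RT.

    Only valid estimates contribute; the lag profile is smoothed with a
    rolling median over ``smooth_window`` estimates before interpolation.
    Window widths and the target count never change.
    """
    valid = [(rt, est.lag_s) for rt, est in shifts if est.valid]
    if not valid:
        return AssayMethod(list(method.targets), method.timing)
    rts, lags = map(np.asarray, zip(*valid))
    if smooth_window > 1 and lags.size >= smooth_window:
        lags = (
            pd.Series(lags)
            .rolling(smooth_window, center=True, min_periods=1)
            .median()
            .to_numpy()
        )
    new_targets = []
    for t in method.targets:
        lag = float(np.interp(t.expected_rt, rts, lags))
        new_targets.append(
            _dc_replace(
                t,
                window=(t.window[0] + lag, t.window[1] + lag),
                expected_rt=min(max(t.expected_rt, t.window[0] + lag), t.window[1] + lag),
            )
        )
    return AssayMethod(new_targets, method.timing)


def normalized_rt_error(
    observed: pd.DataFrame,
    gradient_span: float | dict | None = None,
) -> pd.DataFrame:
    """Per-replicate deviation of normalized RT from the precursor mean.

    ``observed`` needs columns ``precursor``, ``replicate``, ``rt``.
    RTs are normalized to [0, 1] by the per-replicate gradient span:
    ``gradient_span`` may be a scalar (shared), a mapping
    replicate -> (start, end), or None to use each replicate's observed
    RT range. Every precursor must appear in at least two replicates.
    """
    required = {"precursor", "replicate", "rt"}
    if missing := required - set(observed.columns):
        raise ValueError(f"missing required columns: {sorted(missing)}")
    counts = observed.groupby("precursor")["replicate"].nunique()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"precursors with a single replicate: {bad}")
    df = observed.copy()

    def _norm(group: pd.Series, rep) -> pd.Series:
        if gradient_span is None:
            lo, hi = group.min(), group.max()
        elif isinstance(gradient_span, dict):
            lo, hi = gradient_span[rep]
        else:
            lo, hi = 0.0, float(gradient_span)
        return (group - lo) / (hi - lo)

    df["normalized_rt"] = df.groupby("replicate")["rt"].transform(
        lambda g: _norm(g, g.name)
    )
    df["mean_normalized_rt"] = df.groupby("precursor")["normalized_rt"].transform("mean")
    df["error"] = df["normalized_rt"] - df["mean_normalized_rt"]
    return df[["precursor", "replicate", "normalized_rt", "mean_normalized_rt", "error"]]
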