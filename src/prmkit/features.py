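"""Per-transition chromatographic features from extracted-ion chromatograms.

Everything the transition filter operates on is computed here: integrated
peak area above a linear baseline, background, FWHM peak width, time
correlation to the precursor's median chromatogram, and the
square-root-transformed spectral dot product (dotp) against a reference
intensity pattern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Trace",
    "PeakIntegration",
    "TransitionFeatureSet",
    "SpectrumSimilarity",
    "integrate",
    "peak_width",
    "median_trace",
    "time_correlation",
    "dotp",
    "extract_features",
]


@dataclass(frozen=True)
class Trace:
    """One transition's extracted-ion chromatogram (times in seconds)."""

    transition_id: str
    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        intensities = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "intensities", intensities)
        if times.size < 5:
            raise ValueError("trace needs at least 5 points")
        if times.shape != intensities.shape:
            raise ValueError("times and intensities must have equal length")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(intensities < 0):
            raise ValueError("intensities must be non-negative")


@dataclass(frozen=True)
class PeakIntegration:
    """Trapezoidal integration above a linear boundary-to-boundary baseline."""

    start: float
    end: float
    area: float
    background: float
    apex_time: float
    floored: bool = False  # set when the raw net area was negative


@dataclass(frozen=True)
class TransitionFeatureSet:
    """The per-transition quantities all filtering criteria operate on."""

    transition_id: str
    area: float
    relative_area: float
    s_over_b: float
    width_s: float
    time_correlation: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.relative_area <= 1.0 + 1e-9:
            raise ValueError("relative area must lie in [0, 1]")


@dataclass(frozen=True)
class SpectrumSimilarity:
    dotp: float

    def __post_init__(self) -> None:
        if not -1e-9 <= self.dotp <= 1.0 + 1e-9:
            raise ValueError("dotp must lie in [0, 1]")


def _interp(trace: Trace, t: float) -> float:
    return float(np.interp(t, trace.times, trace.intensities))


def integrate(trace: Trace, boundaries: tuple[float, float]) -> PeakIntegration:
    """Net area above a linear baseline drawn between the boundary intensities.

    The baseline area is reported as ``background``; a negative raw net
    area is floored at zero and flagged.
    """
    start, end = boundaries
    if start >= end:
        raise ValueError("boundary start must precede end")
    if start < trace.times[0] or end > trace.times[-1]:
        raise ValueError("boundaries outside trace time span")
    inside = (trace.times > start) & (trace.times < end)
    t = np.concatenate(([start], trace.times[inside], [end]))
    y = np.concatenate(([_interp(trace, start)], trace.intensities[inside], [_interp(trace, end)]))
    baseline = y[0] + (y[-1] - y[0]) * (t - t[0]) / (t[-1] - t[0])
    total = float(np.trapezoid(y, t))
    background = float(np.trapezoid(baseline, t))
    net = total - background
    floored = net < 0
    subtracted = y - baseline
    apex_idx = int(np.argmax(subtracted))
    return PeakIntegration(
        start=start,
        end=end,
        area=max(net, 0.0),
        background=max(background, 0.0),
        apex_time=float(t[apex_idx]),
        floored=floored,
    )


def peak_width(
    trace: Trace, integration: PeakIntegration, at_fraction: float = 0.5
) -> float:
    """Full width at ``at_fraction`` of the baseline-subtracted apex (seconds).

    Crossing times are linearly interpolated. Returns NaN (degenerate) when
    the apex sits on a boundary or the trace is flat over the window.
    """
    if not 0 < at_fraction < 1:
        raise ValueError("at_fraction must lie in (0, 1)")
    start, end = integration.start, integration.end
    inside = (trace.times > start) & (trace.times < end)
    t = np.concatenate(([start], trace.times[inside], [end]))
    y = np.concatenate(([_interp(trace, start)], trace.intensities[inside], [_interp(trace, end)]))
    baseline = y[0] + (y[-1] - y[0]) * (t - t[0]) / (t[-1] - t[0])
    sub = y - baseline
    apex_idx = int(np.argmax(sub))
    apex = sub[apex_idx]
    if apex <= 0 or apex_idx in (0, t.size - 1):
        return math.nan
    half = apex * at_fraction
    # walk outward from the apex to the first crossings below `half`
    left = None
    for i in range(apex_idx, 0, -1):
        if sub[i - 1] <= half <= sub[i]:
            if sub[i] == sub[i - 1]:
                left = t[i - 1]
            else:
                left = t[i - 1] + (half - sub[i - 1]) / (sub[i] - sub[i - 1]) * (t[i] - t[i - 1])
            break
    right = None
    for i in range(apex_idx, t.size - 1):
        if sub[i + 1] <= half <= sub[i]:
            if sub[i] == sub[i + 1]:
                right = t[i + 1]
            else:
                right = t[i] + (sub[i] - half) / (sub[i] - sub[i + 1]) * (t[i + 1] - t[i])
            break
    if left is None or right is None:
        return math.nan
    return float(right - left)


def median_trace(traces: list[Trace], transition_id: str = "median") -> Trace:
    """Pointwise median of the traces of one precursor on a shared grid.

    Traces are resampled by linear interpolation to the densest input grid
    restricted to the overlap of all time spans.
    """
    if not traces:
        raise ValueError("no traces supplied")
    lo = max(tr.times[0] for tr in traces)
    hi = min(tr.times[-1] for tr in traces)
    if lo >= hi:
        raise ValueError("traces have disjoint time spans")
    densest = max(traces, key=lambda tr: tr.times.size)
    grid = densest.times[(densest.times >= lo) & (densest.times <= hi)]
    if grid.size < 5:
        grid = np.linspace(lo, hi, 5)
    stacked = np.vstack([np.interp(grid, tr.times, tr.intensities) for tr in traces])
    return Trace(transition_id, grid, np.median(stacked, axis=0))


def time_correlation(
    trace: Trace, median: Trace, window: tuple[float, float] | None = None
) -> float:
    """Pearson correlation of a transition trace with the precursor median.

    Evaluated over the integration ``window`` (or the shared span) on the
    median's grid. Returns NaN when either series has zero variance.
    """
    lo = max(trace.times[0], median.times[0])
    hi = min(trace.times[-1], median.times[-1])
    if window is not None:
        lo, hi = max(lo, window[0]), min(hi, window[1])
    grid = median.times[(median.times >= lo) & (median.times <= hi)]
    if grid.size < 5:
        raise ValueError("fewer than 5 shared grid points")
    a = np.interp(grid, trace.times, trace.intensities)
    b = np.interp(grid, median.times, median.intensities)
    if np.std(a) == 0 or np.std(b) == 0:
        return math.nan
    return float(np.corrcoef(a, b)[0, 1])


def dotp(measured, reference) -> SpectrumSimilarity:
    """Skyline-style spectral similarity: cosine of √-transformed intensities."""
    m = np.sqrt(np.asarray(measured, dtype=float))
    r = np.sqrt(np.asarray(reference, dtype=float))
    if m.shape != r.shape or m.size < 2:
        raise ValueError("vectors must share the same transition ordering (>= 2 entries)")
    nm, nr = np.linalg.norm(m), np.linalg.norm(r)
    if nm == 0 or nr == 0:
        raise ValueError("all-zero intensity vector")
    return SpectrumSimilarity(dotp=float(np.clip(m @ r / (nm * nr), 0.0, 1.0)))


def extract_features(
    traces: dict[str, Trace],
    boundaries: dict[str, tuple[float, float]] | tuple[float, float],
) -> list[TransitionFeatureSet]:
    """Full feature sets for all transitions of one precursor.

    ``boundaries`` is either a single (start, end) shared by all
    transitions or a per-transition mapping. Relative areas are shares of
    the summed net areas; S/B uses a floored background to stay finite.
    """
    if not traces:
        return []
    if isinstance(boundaries, tuple):
        boundaries = {tid: boundaries for tid in traces}
    med = median_trace(list(traces.values()))
    integrations = {tid: integrate(tr, boundaries[tid]) for tid, tr in traces.items()}
    total_area = sum(pi.area for pi in integrations.values())
    out = []
    for tid, tr in traces.items():
        pi = integrations[tid]
        width = peak_width(tr, pi)
        corr = time_correlation(tr, med, window=boundaries[tid])
        s_over_b = pi.area / max(pi.background, 1e-9)
        out.append(
            TransitionFeatureSet(
                transition_id=tid,
                area=pi.area,
                relative_area=pi.area / total_area if total_area > 0 else 0.0,
                s_over_b=s_over_b,
                width_s=width,
                time_correlation=corr,
            )
        )
    return out
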