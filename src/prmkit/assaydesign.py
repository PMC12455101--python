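"""Candidate filtering and scheduled PRM assay construction.

The design chain mirrors how targeted assays are refined from discovery
data: transitions are filtered on simple chromatographic criteria
(absolute/relative area, signal-to-background, time correlation, peak
width), precursors with enough qualifying transitions are accepted,
replicate CV pruning removes irreproducible targets, and the surviving
candidates are packed into one or more scheduled acquisition methods such
that every target keeps at least the requested number of data points per
chromatographic peak. A load balancer redistributes targets across methods
to lower the worst-case cycle time, and helpers produce gas-phase
fractionation (GPF) DIA plans and multiplexed MS3 product selections.

Cycle-time model: a linear ion trap scans out fragments at a fixed mass
scan rate while the next injection proceeds in parallel, so one target's
scan cost is ``scan_range / scan_rate + overhead`` and the cycle time at
any retention time is the summed scan cost of all concurrently scheduled
targets. Points per peak = peak FWHM / cycle time at the target's apex.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .features import TransitionFeatureSet

__all__ = [
    "FilterCriteria",
    "LABEL_FREE_PROFILE",
    "N15_PROFILE",
    "TargetCandidate",
    "TimingModel",
    "AssayMethod",
    "GPFPlan",
    "SplitResult",
    "filter_transitions",
    "accept_precursors",
    "cv_percent",
    "cv_filter",
    "schedule_windows",
    "split_assays",
    "balance_load",
    "points_per_peak",
    "gpf_plan",
    "select_ms3_products",
    "export_target_list",
    "read_target_list",
]


@dataclass(frozen=True)
class FilterCriteria:
    """Transition/precursor acceptance thresholds."""

    min_absolute_area: float = 100.0
    min_s_over_b: float = 2.0
    min_relative_area: float = 0.05
    min_time_correlation: float = 0.80
    width_range_s: tuple[float, float] = (4.0, 20.0)
    min_qualifying_transitions: int = 3
    max_cv_percent: float = 30.0

    def __post_init__(self) -> None:
        lo, hi = self.width_range_s
        if lo > hi:
            raise ValueError("width range must be ordered")
        for name in (
            "min_absolute_area",
            "min_s_over_b",
            "min_relative_area",
            "min_time_correlation",
            "max_cv_percent",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


#: criteria used for label-free assay refinement
LABEL_FREE_PROFILE = FilterCriteria()
#: criteria used for the ¹⁵N standard assay (2 min windows, 12 points/peak)
N15_PROFILE = FilterCriteria(
    min_absolute_area=100.0,
    min_s_over_b=2.0,
    min_relative_area=0.0,
    min_time_correlation=0.75,
    width_range_s=(0.0, float("inf")),
    min_qualifying_transitions=3,
    max_cv_percent=30.0,
)


@dataclass(frozen=True)
class TargetCandidate:
    """A precursor candidate with its scheduling geometry."""

    precursor_id: str
    sequence: str
    charge: int
    label: str
    precursor_mz: float
    expected_rt: float  # s
    peak_width: float  # s, FWHM
    window: tuple[float, float]  # scheduled acquisition window, s
    transitions: tuple[TransitionFeatureSet, ...] = ()
    replicate_areas: tuple[float, ...] = ()
    ms3_products: tuple[tuple[float, float], ...] = ()  # (m/z, isolation width)

    def __post_init__(self) -> None:
        lo, hi = self.window
        if hi <= lo:
            raise ValueError("window width must be positive")
        if not lo <= self.expected_rt <= hi:
            raise ValueError("window must contain the expected RT")


@dataclass(frozen=True)
class TimingModel:
    """Per-scan time accounting for scheduled targeted acquisition."""

    scan_rate: float = 125000.0  # Da/s
    scan_range: float = 800.0  # Da scanned out per MS2
    overhead: float = 0.005  # s fixed cost per scan
    points_per_peak_goal: float = 7.0
    ms3_extra_per_product: float = 0.002  # s per multiplexed MS3 product
    agc_target: float = 1e4
    injection_parallel: bool = True  # injection overlaps the previous scan-out

    def __post_init__(self) -> None:
        if self.scan_rate <= 0:
            raise ValueError("scan rate must be positive")
        if self.overhead < 0:
            raise ValueError("overhead must be >= 0")

    def scan_time(self, target: TargetCandidate | None = None) -> float:
        t = self.scan_range / self.scan_rate + self.overhead
        if target is not None and target.ms3_products:
            t += self.ms3_extra_per_product * len(target.ms3_products)
        return t


def _sort_key(c: TargetCandidate):
    return (c.expected_rt, c.precursor_mz, c.sequence, c.charge, c.label)


@dataclass
class AssayMethod:
    """An ordered set of scheduled targets plus its timing model."""

    targets: list[TargetCandidate]
    timing: TimingModel = field(default_factory=TimingModel)

    def __post_init__(self) -> None:
        self.targets = sorted(self.targets, key=_sort_key)

    def cycle_time_at(self, rt: float) -> float:
        """Summed scan cost of all targets whose window contains ``rt``."""
        return sum(
            self.timing.scan_time(t)
            for t in self.targets
            if t.window[0] <= rt <= t.window[1]
        )

    def worst_cycle_time(self) -> float:
        """Maximum cycle time over the gradient (event sweep on window edges)."""
        if not self.targets:
            return 0.0
        events = sorted(
            itertools.chain.from_iterable(
                ((t.window[0], self.timing.scan_time(t)), (t.window[1], -self.timing.scan_time(t)))
                for t in self.targets
            )
        )
        worst = load = 0.0
        for _rt, delta in events:
            load += delta
            worst = max(worst, load)
        return worst

    def concurrency_profile(self, step: float = 1.0) -> pd.DataFrame:
        """Concurrent-target count and cycle time on a regular RT grid."""
        if not self.targets:
            return pd.DataFrame(columns=["rt", "concurrency", "cycle_time"])
        lo = min(t.window[0] for t in self.targets)
        hi = max(t.window[1] for t in self.targets)
        rts = np.arange(lo, hi + step, step)
        rows = [
            {
                "rt": rt,
                "concurrency": sum(t.window[0] <= rt <= t.window[1] for t in self.targets),
                "cycle_time": self.cycle_time_at(rt),
            }
            for rt in rts
        ]
        return pd.DataFrame(rows)

    def feasible(self) -> bool:
        """True when every target keeps >= points_per_peak_goal at its apex."""
        return all(
            points_per_peak(self, t) >= self.timing.points_per_peak_goal
            for t in self.targets
        )


@dataclass(frozen=True)
class GPFPlan:
    """Gas-phase fractionation plan: one DIA method per precursor segment."""

    methods: tuple[tuple[tuple[float, float], tuple[tuple[float, float], ...]], ...]
    window_width: float

    @property
    def n_methods(self) -> int:
        return len(self.methods)


@dataclass(frozen=True)
class SplitResult:
    methods: tuple[AssayMethod, ...]
    unschedulable: tuple[TargetCandidate, ...] = ()


def filter_transitions(
    features: list[TransitionFeatureSet], criteria: FilterCriteria
) -> list[TransitionFeatureSet]:
    """Transitions of one precursor passing every threshold.

    NaN widths/correlations (degenerate peaks) fail their respective
    criteria unless the criterion is disabled (0 or infinite bound).
    """
    lo_w, hi_w = criteria.width_range_s
    out = []
    for f in features:
        if f.area < criteria.min_absolute_area:
            continue
        if f.s_over_b < criteria.min_s_over_b:
            continue
        if f.relative_area < criteria.min_relative_area:
            continue
        if criteria.min_time_correlation > 0 and not (
            f.time_correlation >= criteria.min_time_correlation
        ):
            continue
        if (lo_w, hi_w) != (0.0, float("inf")) and not (lo_w <= f.width_s <= hi_w):
            continue
        out.append(f)
    return out


def accept_precursors(
    candidates: list[TargetCandidate], criteria: FilterCriteria
) -> tuple[list[TargetCandidate], dict[str, str]]:
    """Keep candidates with enough qualifying transitions.

    Returns the accepted list (each with its transitions replaced by the
    qualifying subset) and a rejection-reason map for the rest.
    """
    accepted: list[TargetCandidate] = []
    rejected: dict[str, str] = {}
    for cand in candidates:
        qualifying = filter_transitions(list(cand.transitions), criteria)
        if len(qualifying) >= criteria.min_qualifying_transitions:
            accepted.append(replace(cand, transitions=tuple(qualifying)))
        else:
            rejected[cand.precursor_id] = (
                f"{len(qualifying)} qualifying transitions < "
                f"{criteria.min_qualifying_transitions}"
            )
    return accepted, rejected


def cv_percent(replicate_areas) -> float:
    """Sample coefficient of variation in percent (SD/mean x 100)."""
    areas = np.asarray(replicate_areas, dtype=float)
    if areas.size < 2:
        raise ValueError("CV needs at least two replicates")
    mean = areas.mean()
    if mean <= 0:
        return float("nan")
    return float(areas.std(ddof=1) / mean * 100.0)


def cv_filter(
    candidates: list[TargetCandidate], max_cv_percent: float = 30.0
) -> tuple[list[TargetCandidate], dict[str, str]]:
    """Remove candidates whose replicate-area CV exceeds the bound."""
    kept, rejected = [], {}
    for cand in candidates:
        if len(cand.replicate_areas) >= 2:
            cv = cv_percent(cand.replicate_areas)
            if not cv <= max_cv_percent:  # catches NaN too
                rejected[cand.precursor_id] = f"replicate CV {cv:.1f}% > {max_cv_percent}%"
                continue
        kept.append(cand)
    return kept, rejected


def schedule_windows(
    candidates: list[TargetCandidate], window_s: float = 120.0
) -> list[TargetCandidate]:
    """Center a fixed-width acquisition window on each expected RT."""
    if window_s <= 0:
        raise ValueError("window width must be positive")
    return [
        replace(c, window=(c.expected_rt - window_s / 2, c.expected_rt + window_s / 2))
        for c in candidates
    ]


def split_assays(
    candidates: list[TargetCandidate],
    timing: TimingModel | None = None,
    keep_all: bool = True,
) -> SplitResult:
    """Partition candidates into the fewest methods meeting the point budget.

    First-fit over RT-sorted candidates: each candidate goes into the first
    method where adding it keeps every already-scheduled target (and
    itself) at or above ``points_per_peak_goal`` at its apex. A candidate
    that cannot meet the budget even alone is reported as unschedulable;
    with ``keep_all`` it is never silently dropped.
    """
    timing = timing or TimingModel()
    methods: list[list[TargetCandidate]] = []
    unschedulable: list[TargetCandidate] = []
    for cand in sorted(candidates, key=_sort_key):
        solo = AssayMethod([cand], timing)
        if not solo.feasible():
            unschedulable.append(cand)
            continue
        placed = False
        for m in methods:
            trial = AssayMethod(m + [cand], timing)
            if trial.feasible():
                m.append(cand)
                placed = True
                break
        if not placed:
            methods.append([cand])
    if unschedulable and not keep_all:
        unschedulable = []
    return SplitResult(
        methods=tuple(AssayMethod(m, timing) for m in methods),
        unschedulable=tuple(unschedulable),
    )


def balance_load(methods: list[AssayMethod]) -> list[AssayMethod]:
    """Even out worst-case cycle time across methods.

    Longest-processing-time greedy: targets are pooled, sorted by
    decreasing scan cost (deterministic tie-break by RT, m/z, sequence) and
    each is assigned to the method whose worst-case cycle time would stay
    lowest. If the greedy assignment would raise the maximum worst-case
    cycle time, the input assignment is returned unchanged; target count is
    always conserved.
    """
    if len(methods) < 2:
        return list(methods)
    timing = methods[0].timing
    pool = [t for m in methods for t in m.targets]
    input_max = max(m.worst_cycle_time() for m in methods)
    order = sorted(pool, key=lambda t: (-timing.scan_time(t),) + _sort_key(t))
    bins: list[list[TargetCandidate]] = [[] for _ in methods]
    for cand in order:
        best, best_cost = 0, float("inf")
        for i, b in enumerate(bins):
            cost = AssayMethod(b + [cand], timing).worst_cycle_time()
            if cost < best_cost:
                best, best_cost = i, cost
        bins[best].append(cand)
    rebalanced = [AssayMethod(b, timing) for b in bins]
    if max(m.worst_cycle_time() for m in rebalanced) > input_max:
        return list(methods)
    return rebalanced


def points_per_peak(method: AssayMethod, target: TargetCandidate) -> float:
    """Predicted data points across the target's peak: FWHM / cycle time at apex."""
    cycle = method.cycle_time_at(target.expected_rt)
    if cycle <= 0:
        raise ValueError("target is not scheduled in this method")
    return target.peak_width / cycle


def gpf_plan(
    range_start: float = 380.0,
    range_end: float = 980.0,
    step: float = 100.0,
    window: float = 1.0,
) -> GPFPlan:
    """Gas-phase fractionation plan tiling the precursor range.

    The precursor range is split into ``step``-wide segments, one injection
    (method) per segment, each covered by contiguous ``window``-Th MS2
    isolation windows.
    """
    span = range_end - range_start
    n_methods = span / step
    if abs(n_methods - round(n_methods)) > 1e-9:
        raise ValueError(f"step {step} does not divide range {range_start}-{range_end}")
    n_methods = int(round(n_methods))
    n_windows = step / window
    if abs(n_windows - round(n_windows)) > 1e-9:
        raise ValueError(f"window {window} does not divide step {step}")
    n_windows = int(round(n_windows))
    methods = []
    for i in range(n_methods):
        lo = range_start + i * step
        windows = tuple(
            (lo + j * window, lo + (j + 1) * window) for j in range(n_windows)
        )
        methods.append(((lo, lo + step), windows))
    return GPFPlan(methods=tuple(methods), window_width=window)


def select_ms3_products(
    products: list[tuple[float, int, float]],
    precursor_mz: float,
    max_products: int = 5,
) -> list[tuple[float, float]]:
    """Choose multiplexed MS3 precursor ions and their isolation widths.

    A product qualifies when it is multiply charged, or singly charged with
    m/z above the intact precursor (so it cannot be a low-mass interference
    of the same nominal species). The highest-intensity qualifiers are
    taken, up to ``max_products``. Isolation widths follow the instrument's
    calibrated rule: 2 Th for the lowest-m/z selected product, growing
    linearly to 10 Th for products at 4x that m/z, clamped to [2, 10].

    Returns ``(product m/z, isolation width)`` pairs sorted by m/z.
    """
    if not products:
        raise ValueError("no product ions supplied")
    qualifying = [
        (mz, z, inten)
        for mz, z, inten in products
        if z >= 2 or (z == 1 and mz > precursor_mz)
    ]
    if not qualifying:
        return []
    chosen = sorted(qualifying, key=lambda t: -t[2])[:max_products]
    lowest = min(mz for mz, _z, _i in chosen)
    out = []
    for mz, _z, _i in sorted(chosen):
        ratio = mz / lowest
        width = 2.0 + 8.0 * (ratio - 1.0) / 3.0
        out.append((mz, float(np.clip(width, 2.0, 10.0))))
    return out


_TARGET_LIST_COLUMNS = [
    "compound",
    "precursor_mz",
    "charge",
    "start_min",
    "end_min",
    "label",
    "ms_level",
    "ms3_product_mz",
    "ms3_isolation_width",
]


def export_target_list(method: AssayMethod, path=None) -> pd.DataFrame:
    """Scheduled-target table for instrument import (times in minutes).

    MS2 targets occupy one row; targets with MS3 products get one row per
    multiplexed product. Written CSV round-trips losslessly through
    :func:`read_target_list`.
    """
    rows = []
    for t in method.targets:
        base = {
            "compound": t.precursor_id,
            "precursor_mz": round(t.precursor_mz, 6),
            "charge": t.charge,
            "start_min": round(t.window[0] / 60.0, 4),
            "end_min": round(t.window[1] / 60.0, 4),
            "label": t.label,
        }
        if t.ms3_products:
            for mz, width in t.ms3_products:
                rows.append(
                    base | {"ms_level": 3, "ms3_product_mz": round(mz, 6), "ms3_isolation_width": round(width, 4)}
                )
        else:
            rows.append(base | {"ms_level": 2, "ms3_product_mz": np.nan, "ms3_isolation_width": np.nan})
    df = pd.DataFrame(rows, columns=_TARGET_LIST_COLUMNS)
    if path is not None:
        df.to_csv(path, index=False, float_format="%.6f")
    return df


def candidates_from_report(report: pd.DataFrame) -> list[TargetCandidate]:
    """Build target candidates from a pre-integrated transition report.

    One candidate per (peptide, charge, label). Transition features come
    from the report's integrated columns: the area is the replicate mean,
    S/B uses the background column, and the peak width is approximated
    from the integration boundary span (boundaries are typically drawn
    near the peak base, so FWHM ~ span/2). A ``correlation`` column is
    used when present; otherwise pre-integrated reports carry no trace
    shape and the correlation criterion is treated as passing (1.0).
    """
    required = {"peptide", "charge", "label", "fragment", "replicate", "area"}
    if missing := required - set(report.columns):
        raise ValueError(f"report missing columns: {sorted(missing)}")
    candidates = []
    for (peptide, charge, label), grp in report.groupby(
        ["peptide", "charge", "label"], sort=True
    ):
        frag_means = grp.groupby("fragment")["area"].mean()
        total = float(frag_means.sum())
        feats = []
        for fragment, sub in grp.groupby("fragment"):
            area = float(sub["area"].mean())
            bg = float(sub["background"].mean()) if "background" in sub and sub["background"].notna().all() else 0.0
            if {"start_s", "end_s"} <= set(sub.columns) and sub["end_s"].notna().all():
                width = float((sub["end_s"] - sub["start_s"]).mean()) / 2.0
            else:
                width = float("nan")
            corr = float(sub["correlation"].mean()) if "correlation" in sub else 1.0
            feats.append(
                TransitionFeatureSet(
                    transition_id=str(fragment),
                    area=area,
                    relative_area=area / total if total > 0 else 0.0,
                    s_over_b=area / max(bg, 1e-9),
                    width_s=width,
                    time_correlation=corr,
                )
            )
        rep_areas = tuple(grp.groupby("replicate")["area"].sum())
        rt = float(grp["rt_s"].mean()) if "rt_s" in grp else 0.0
        widths = [f.width_s for f in feats if np.isfinite(f.width_s)]
        peak_w = float(np.median(widths)) if widths else 8.0
        candidates.append(
            TargetCandidate(
                precursor_id=f"{peptide}/{charge}/{label}",
                sequence=str(peptide),
                charge=int(charge),
                label=str(label),
                precursor_mz=float(grp["precursor_mz"].iloc[0]),
                expected_rt=rt,
                peak_width=peak_w,
                window=(rt - 60.0, rt + 60.0),
                transitions=tuple(feats),
                replicate_areas=rep_areas,
            )
        )
    return candidates


def read_target_list(path) -> pd.DataFrame:
    """Read a target-list CSV written by :func:`export_target_list`."""
    df = pd.read_csv(path)
    missing = set(_TARGET_LIST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"target list missing columns: {sorted(missing)}")
    return df[_TARGET_LIST_COLUMNS]
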