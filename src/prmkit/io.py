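"""File exchange: transition reports, dilution tables, reference maps, logs.

CSV is the lingua franca (Skyline-style report exports); times are stored
in minutes in files and converted to seconds internally. All writes are
atomic (temp file + rename) so a crashed run never leaves a torn table.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .adaptivert import ReferenceMap
from .quant import DilutionLevel, DilutionSeries

__all__ = [
    "TRANSITION_COLUMNS",
    "SKYLINE_ALIASES",
    "RunConfig",
    "read_transition_report",
    "write_transition_report",
    "read_dilution_series",
    "write_dilution_series",
    "save_reference",
    "load_reference",
    "write_run_log",
    "atomic_write_text",
]

#: canonical transition-report columns (internal names, times in minutes on disk)
TRANSITION_COLUMNS = [
    "protein",
    "peptide",
    "modifications",
    "precursor_mz",
    "charge",
    "label",
    "fragment",
    "fragment_charge",
    "replicate",
    "rt_min",
    "start_min",
    "end_min",
    "area",
    "background",
    "tic",
]

_REQUIRED = {
    "protein",
    "peptide",
    "precursor_mz",
    "charge",
    "label",
    "fragment",
    "replicate",
    "area",
}

#: default header mapping for Skyline report exports
SKYLINE_ALIASES = {
    "Protein Name": "protein",
    "Peptide Sequence": "peptide",
    "Peptide Modified Sequence": "modifications",
    "Precursor Mz": "precursor_mz",
    "Precursor Charge": "charge",
    "Isotope Label Type": "label",
    "Fragment Ion": "fragment",
    "Product Charge": "fragment_charge",
    "Replicate Name": "replicate",
    "Retention Time": "rt_min",
    "Min Start Time": "start_min",
    "Max End Time": "end_min",
    "Area": "area",
    "Background": "background",
    "Total Ion Current Area": "tic",
}


def atomic_write_text(path, text: str) -> None:
    """Write text via a temp file in the same directory, then rename."""
    directory = os.path.dirname(os.path.abspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_transition_report(
    path, column_mapping: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read and validate a transition-level report CSV/TSV.

    ``column_mapping`` maps file headers to canonical names; Skyline's
    default headers are always recognized. Duplicate
    (peptide, charge, label, fragment, replicate) keys and non-positive
    precursor m/z are rejected; an ``rt_s`` column (seconds) is derived
    from ``rt_min``.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    mapping = dict(SKYLINE_ALIASES)
    if column_mapping:
        mapping.update(column_mapping)
    df = df.rename(columns=mapping)
    missing = _REQUIRED - set(df.columns)
    if missing:
        raise ValueError(f"transition report missing required columns: {sorted(missing)}")
    key = ["peptide", "charge", "label", "fragment", "replicate"]
    dup = df.duplicated(subset=key)
    if dup.any():
        raise ValueError(
            f"duplicate transition keys in report: {df.loc[dup, key].iloc[0].tolist()}"
        )
    if (df["precursor_mz"] <= 0).any():
        raise ValueError("precursor m/z must be positive")
    for col in TRANSITION_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    for col in ("rt_min", "start_min", "end_min"):
        df[col.replace("_min", "_s")] = df[col] * 60.0
    return df[TRANSITION_COLUMNS + ["rt_s", "start_s", "end_s"]]


def write_transition_report(df: pd.DataFrame, path) -> None:
    cols = [c for c in TRANSITION_COLUMNS if c in df.columns]
    atomic_write_text(path, df[cols].to_csv(index=False))


def write_dilution_series(series_list: list[DilutionSeries], path) -> None:
    """Long-format dilution CSV: precursor, level amount, replicate, area, TIC."""
    rows = []
    for series in series_list:
        for lv in series.levels:
            for r, area in enumerate(lv.areas):
                rows.append(
                    {
                        "precursor": series.precursor_id,
                        "amount": lv.amount,
                        "unit": series.unit,
                        "replicate": r,
                        "area": area,
                        "tic": lv.tics[r] if lv.tics is not None else np.nan,
                    }
                )
    atomic_write_text(path, pd.DataFrame(rows).to_csv(index=False))


def read_dilution_series(path) -> list[DilutionSeries]:
    df = pd.read_csv(path)
    required = {"precursor", "amount", "replicate", "area"}
    if missing := required - set(df.columns):
        raise ValueError(f"dilution table missing columns: {sorted(missing)}")
    out = []
    for pid, group in df.groupby("precursor", sort=True):
        levels = []
        for amount, lv in sorted(group.groupby("amount"), key=lambda kv: -kv[0]):
            lv = lv.sort_values("replicate")
            tics = lv["tic"].to_numpy() if "tic" in lv and lv["tic"].notna().all() else None
            levels.append(
                DilutionLevel(amount=float(amount), areas=lv["area"].to_numpy(), tics=tics)
            )
        unit = str(group["unit"].iloc[0]) if "unit" in group else "ng"
        out.append(DilutionSeries(precursor_id=str(pid), levels=tuple(levels), unit=unit))
    return out


def save_reference(reference: ReferenceMap, path) -> None:
    """Serialize a reference map to a documented JSON container."""
    payload = {
        "format": "prmkit-reference-map",
        "version": 1,
        "source": reference.source,
        "rt_grid": reference.rt_grid.tolist(),
        "bin_edges": reference.bin_edges.tolist(),
        "windows": [list(w) for w in reference.windows],
        "quant_max": reference.quant_max,
        "quant_bits": reference.quant_bits,
        "spectra": reference.spectra.astype(int).tolist(),
    }
    atomic_write_text(path, json.dumps(payload))


def load_reference(path) -> ReferenceMap:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "prmkit-reference-map":
        raise ValueError("not a prmkit reference-map container")
    return ReferenceMap(
        rt_grid=np.asarray(payload["rt_grid"], dtype=float),
        bin_edges=np.asarray(payload["bin_edges"], dtype=float),
        windows=tuple(tuple(w) for w in payload["windows"]),
        spectra=np.asarray(payload["spectra"], dtype=np.uint8),
        quant_max=float(payload["quant_max"]),
        quant_bits=int(payload["quant_bits"]),
        source=payload.get("source", "unknown"),
    )


_CONFIG_FIELDS = {
    "profile": str,
    "seed": int,
    "window_s": float,
    "points_per_peak_goal": float,
    "scan_range": float,
    "scan_rate": float,
    "overhead_s": float,
    "band_s": float,
    "correct_efficiency": bool,
    "plasma_equivalent_l": float,
    "max_loq_cv_percent": float,
    "molecular_weights_kda": dict,
}


@dataclass(frozen=True)
class RunConfig:
    """Flat, schema-validated run configuration."""

    profile: str = "label-free"
    seed: int = 0
    window_s: float = 120.0
    points_per_peak_goal: float = 7.0
    scan_range: float = 800.0
    scan_rate: float = 125000.0
    overhead_s: float = 0.005
    band_s: float = 30.0
    correct_efficiency: bool = True
    plasma_equivalent_l: float = 1e-8
    max_loq_cv_percent: float = 20.0
    molecular_weights_kda: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(_CONFIG_FIELDS)
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        for key, value in raw.items():
            expected = _CONFIG_FIELDS[key]
            if expected is float and isinstance(value, int):
                continue
            if not isinstance(value, expected):
                raise ValueError(
                    f"configuration key {key!r} must be {expected.__name__}"
                )
        return cls(**raw)


def write_run_log(path, stage_counts: dict[str, int], seed: int | None = None, **extra) -> None:
    """JSON run log: package version, seed, and row counts per stage."""
    from . import __version__

    payload = {
        "tool": "prmkit",
        "version": __version__,
        "seed": seed,
        "stages": stage_counts,
    } | extra
    atomic_write_text(path, json.dumps(payload, indent=2, default=float))
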