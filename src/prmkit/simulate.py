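"""Seeded synthetic-data generator with known ground truth.

Every input the other modules consume can be produced here: Gaussian LC
peaks on noisy baselines (per-transition chromatograms), ¹⁵N isotope
envelopes at a chosen incorporation, 1:4 dilution series with a bilinear
response and level-dependent CV, and wide-window DIA scan sets with a
bounded retention-time drift between reference and run. Each generator is
deterministic under its seed and returns the emitted data together with a
ground-truth table.

Default scales emulate short-gradient plasma PRM: ~21 min gradients,
lognormal FWHM around 8 s, four decades of abundance, drift bounded by
±30 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import chem
from .chem import PeptideSpecies
from .features import Trace
from .quant import DilutionLevel, DilutionSeries

__all__ = [
    "SimConfig",
    "sim_chromatograms",
    "sim_envelopes",
    "sim_dilution",
    "sim_drifting_run",
    "random_tryptic_peptides",
]

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generators; the seed is mandatory."""

    seed: int
    n_peptides: int = 20
    n_fragments: int = 5
    n_replicates: int = 3
    gradient_s: float = 1260.0  # 21 min, 60-samples-per-day style gradient
    fwhm_median_s: float = 8.0
    fwhm_log_sigma: float = 0.25
    abundance_decades: float = 4.0
    abundance_floor: float = 100.0
    baseline_level: float = 5.0
    noise_cv: float = 0.05  # multiplicative replicate noise
    interference_rate: float = 0.0
    incorporation: float = 0.99
    dilution_factor: float = 4.0
    dilution_top: float = 25.0  # ng
    n_dilution_levels: int = 7
    drift_max_s: float = 30.0
    sample_interval_s: float = 0.5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("gradient_s", "fwhm_median_s", "dilution_top", "sample_interval_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if abs(self.drift_max_s) > 30.0 + 1e-9:
            raise ValueError("drift profile must stay within ±30 s")


def sim_chromatograms(
    config: SimConfig,
) -> tuple[dict[tuple[str, str, int], Trace], pd.DataFrame]:
    """Gaussian fragment chromatograms with shared per-peptide patterns.

    Returns a trace per (peptide, fragment, replicate) and a ground-truth
    frame with one row per peptide: true RT, FWHM, per-replicate amplitude
    scale, analytic peak area of the summed transitions, and whether an
    interfering peak was injected.
    """
    rng = np.random.default_rng(config.seed)
    traces: dict[tuple[str, str, int], Trace] = {}
    truth_rows = []
    for i in range(config.n_peptides):
        pid = f"PEP{i:04d}"
        rt = float(rng.uniform(0.1, 0.9) * config.gradient_s)
        fwhm = float(
            config.fwhm_median_s * rng.lognormal(0.0, config.fwhm_log_sigma)
        )
        sigma = fwhm / _FWHM_TO_SIGMA
        amplitude = float(
            config.abundance_floor * 10 ** rng.uniform(0.0, config.abundance_decades)
        )
        pattern = rng.dirichlet(np.full(config.n_fragments, 1.5))
        interfered = bool(rng.random() < config.interference_rate)
        interfered_frag = int(rng.integers(config.n_fragments)) if interfered else -1
        t = np.arange(rt - 5 * sigma, rt + 5 * sigma, config.sample_interval_s)
        for r in range(config.n_replicates):
            rep_scale = float(rng.lognormal(0.0, config.noise_cv))
            for j in range(config.n_fragments):
                amp = amplitude * pattern[j] * rep_scale
                y = amp * np.exp(-0.5 * ((t - rt) / sigma) ** 2)
                if j == interfered_frag:
                    y = y + 0.8 * amp * np.exp(
                        -0.5 * ((t - rt - 2.0 * sigma) / sigma) ** 2
                    )
                if config.baseline_level > 0:
                    y = y + np.abs(
                        rng.normal(config.baseline_level, config.baseline_level / 5, t.size)
                    )
                traces[(pid, f"y{j + 1}", r)] = Trace(f"{pid}/y{j + 1}/{r}", t, y)
            if r == 0:
                truth_rows.append(
                    {
                        "peptide": pid,
                        "rt": rt,
                        "fwhm": fwhm,
                        "amplitude": amplitude,
                        "area": amplitude * sigma * np.sqrt(2 * np.pi),
                        "pattern": pattern,
                        "interfered_fragment": interfered_frag,
                    }
                )
    return traces, pd.DataFrame(truth_rows)


def random_tryptic_peptides(rng: np.random.Generator, n: int) -> list[str]:
    """Random tryptic-looking sequences (end in K/R, 7-20 residues)."""
    alphabet = np.array(list("ACDEFGHILMNPQSTVWY"))
    out = []
    for _ in range(n):
        length = int(rng.integers(7, 21))
        body = "".join(rng.choice(alphabet, size=length - 1))
        out.append(body + ("K" if rng.random() < 0.5 else "R"))
    return out


def sim_envelopes(
    peptides: list[tuple[str, str, int]],
    p: float,
    noise_cv: float,
    seed: int,
    abundance: float = 1e6,
) -> pd.DataFrame:
    """Observed M0/M−1 areas for heavy precursors at incorporation ``p``.

    ``peptides`` rows are (precursor id, sequence, charge). Envelope
    abundances come from :func:`prmkit.chem.predict_envelope`; observed
    areas are the M0 and M−1 species abundances scaled by a lognormal
    abundance and independently degraded by multiplicative lognormal noise
    of coefficient ``noise_cv``.
    """
    if not 0 < p <= 1:
        raise ValueError("incorporation must be in (0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for pid, sequence, charge in peptides:
        species = PeptideSpecies(sequence, int(charge), "heavy15N")
        comp = chem.peptide_composition(species)
        env = chem.predict_envelope(comp, p)
        ratio = chem.m1_m0_ratio(env)
        scale = abundance * rng.lognormal(0.0, 0.5)
        m0 = scale * rng.lognormal(0.0, noise_cv) if noise_cv > 0 else scale
        m1 = (
            scale * ratio * rng.lognormal(0.0, noise_cv)
            if noise_cv > 0
            else scale * ratio
        )
        rows.append(
            {
                "precursor": pid,
                "sequence": sequence,
                "charge": charge,
                "m0_area": m0,
                "m1_area": m1,
                "true_p": p,
                "true_ratio": ratio,
                "n_nitrogen": comp.n,
            }
        )
    return pd.DataFrame(rows)


def sim_dilution(
    config: SimConfig,
    turning_point: float | None = None,
    slope: float = 5000.0,
    floor: float = 100.0,
    n_replicates: int = 4,
    base_cv: float = 0.04,
    floor_cv: float = 0.35,
    precursor_id: str = "SIM",
) -> tuple[DilutionSeries, dict]:
    """A 1:4 dilution series with bilinear response and floor-inflated CV.

    Levels follow ``dilution_top / factor**k``. The mean response is
    ``floor + slope * max(amount - turning_point, 0)``; replicate noise is
    lognormal with a CV that interpolates between ``base_cv`` (signal
    dominated) and ``floor_cv`` (floor dominated). TICs vary mildly run to
    run. Ground truth (turning point, slope, floor) is returned alongside.
    """
    rng = np.random.default_rng(config.seed)
    amounts = config.dilution_top / config.dilution_factor ** np.arange(
        config.n_dilution_levels
    )
    if turning_point is None:
        # default truth: two levels sit in the floor
        turning_point = float(amounts[-2])
    levels = []
    for amount in amounts:
        signal = slope * max(amount - turning_point, 0.0)
        mean = floor + signal
        cv = base_cv + (floor_cv - base_cv) * (floor / mean)
        areas = mean * rng.lognormal(0.0, cv, size=n_replicates)
        tics = 1e6 * rng.lognormal(0.0, 0.05, size=n_replicates)
        levels.append(DilutionLevel(amount=float(amount), areas=areas, tics=tics))
    series = DilutionSeries(
        precursor_id=precursor_id,
        levels=tuple(levels),
        dilution_factor=config.dilution_factor,
    )
    truth = {
        "turning_point": float(turning_point),
        "slope": slope,
        "floor": floor,
        "amounts": amounts,
    }
    return series, truth


def _drift_profile(config: SimConfig, rng: np.random.Generator, kind: str):
    """Piecewise-linear drift over the gradient, bounded by drift_max_s."""
    if kind == "none":
        return lambda rt: np.zeros_like(np.asarray(rt, dtype=float))
    if kind == "constant":
        return lambda rt: np.full_like(np.asarray(rt, dtype=float), config.drift_max_s)
    if kind == "linear":
        return lambda rt: np.asarray(rt, dtype=float) / config.gradient_s * config.drift_max_s
    raise ValueError(f"unknown drift kind {kind!r}")


def sim_drifting_run(
    config: SimConfig,
    drift: str | float = "linear",
    n_species: int = 60,
    mz_range: tuple[float, float] = (400.0, 600.0),
    native_window: float = 4.0,
    scan_period_s: float = 2.0,
    spectrum_noise: float = 0.02,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Reference and drift-displaced run scan sets sharing one bin scheme.

    Species elute as RT-Gaussians at fixed m/z positions; the run set
    displaces each species' elution by the drift profile evaluated at its
    reference RT. ``drift`` is "none" | "constant" | "linear" or a number
    (constant shift in seconds). Returns (reference scans, run scans,
    ground truth) in the long scan-table format of
    :mod:`prmkit.adaptivert`.
    """
    rng = np.random.default_rng(config.seed)
    if isinstance(drift, (int, float)):
        shift_value = float(drift)
        if abs(shift_value) > config.drift_max_s + 1e-9:
            raise ValueError("drift exceeds the configured bound")
        drift_fn = lambda rt: np.full_like(np.asarray(rt, dtype=float), shift_value)
    else:
        drift_fn = _drift_profile(config, rng, drift)
    mzs = rng.uniform(mz_range[0], mz_range[1], size=n_species)
    rts = rng.uniform(0.12, 0.88, size=n_species) * config.gradient_s
    sigmas = config.fwhm_median_s * rng.lognormal(0.0, config.fwhm_log_sigma, n_species) / _FWHM_TO_SIGMA
    intensities = 10 ** rng.uniform(3.0, 5.0, size=n_species)
    windows = np.arange(mz_range[0], mz_range[1], native_window)
    scan_rts = np.arange(0.0, config.gradient_s, scan_period_s)

    def _emit(drifted: bool) -> pd.DataFrame:
        rows = []
        species_rt = rts + drift_fn(rts) if drifted else rts
        for t in scan_rts:
            # chemical background keeps every window represented each cycle
            for w_lo in windows:
                rows.append(
                    {
                        "rt": t,
                        "window_low": w_lo,
                        "window_high": w_lo + native_window,
                        "mz": w_lo + native_window / 2,
                        "intensity": float(rng.lognormal(0.0, 0.3)),
                    }
                )
            active = np.abs(t - species_rt) < 4 * sigmas
            for k in np.flatnonzero(active):
                inten = intensities[k] * np.exp(
                    -0.5 * ((t - species_rt[k]) / sigmas[k]) ** 2
                )
                if spectrum_noise > 0:
                    inten *= rng.lognormal(0.0, spectrum_noise)
                w_lo = windows[min(
                    int((mzs[k] - mz_range[0]) // native_window), windows.size - 1
                )]
                rows.append(
                    {
                        "rt": t,
                        "window_low": w_lo,
                        "window_high": w_lo + native_window,
                        "mz": mzs[k],
                        "intensity": inten,
                    }
                )
        return pd.DataFrame(rows, columns=["rt", "window_low", "window_high", "mz", "intensity"])

    reference = _emit(drifted=False)
    run = _emit(drifted=True)
    truth = pd.DataFrame(
        {
            "species": np.arange(n_species),
            "mz": mzs,
            "rt_reference": rts,
            "rt_run": rts + drift_fn(rts),
            "drift": drift_fn(rts),
            "sigma": sigmas,
        }
    )
    return reference, run, truth
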