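"""Bilinear calibration, LOQ rules and light/heavy quantification."""

import math

import numpy as np
import pytest

from prmkit import quant, simulate
from prmkit.quant import (
    CalibrationResult,
    DilutionLevel,
    DilutionSeries,
    bilinear_fit,
    fragment_cv_filter,
    loq_from_cv,
    precursor_quant,
    protein_quant,
    tic_normalize,
)
from prmkit.simulate import SimConfig


def make_series(amounts, means, cvs=None, reps=4, seed=0):
    rng = np.random.default_rng(seed)
    levels = []
    for i, (amt, mean) in enumerate(zip(amounts, means)):
        cv = 0.0 if cvs is None else cvs[i]
        areas = mean * (1 + cv * rng.standard_normal(reps)) if cv else np.full(reps, mean)
        levels.append(DilutionLevel(amount=amt, areas=np.clip(areas, 1e-6, None)))
    return DilutionSeries("test", tuple(levels))


class TestTicNormalize:
    def test_equal_tics_identity(self):
        areas = np.array([10.0, 20.0, 30.0])
        np.testing.assert_allclose(tic_normalize(areas, [5e5] * 3), areas)

    def test_double_tic_halved_then_rescaled(self):
        out = tic_normalize([100.0, 100.0], [1e6, 2e6])
        assert out[0] / out[1] == pytest.approx(2.0)

    def test_preserves_within_run_ratios(self):
        a = tic_normalize([100.0, 50.0], [1e6, 1e6])
        assert a[0] / a[1] == pytest.approx(2.0)

    def test_zero_tic_rejected(self):
        with pytest.raises(ValueError):
            tic_normalize([1.0], [0.0])


class TestBilinearFit:
    def test_noise_free_recovery(self):
        """Floor 100 below 0.1, slope 5000 above -> turning point ~0.1."""
        amounts = [25.0, 6.25, 1.5625, 0.390625, 0.09765625, 0.0244140625]
        means = [100.0 + 5000.0 * max(a - 0.1, 0.0) for a in amounts]
        series = make_series(amounts, means)
        calib = bilinear_fit(series)
        assert calib.valid
        # within half the inter-level (log) grid step of the truth
        assert abs(math.log(calib.turning_point / 0.1)) <= 0.5 * math.log(4.0)
        assert calib.noise_floor == pytest.approx(100.0, rel=0.05)
        assert calib.slope == pytest.approx(5000.0, rel=0.05)

    def test_all_flat_series_invalid(self):
        series = make_series([8.0, 4.0, 2.0, 1.0], [100.0] * 4)
        assert not bilinear_fit(series).valid

    def test_scale_equivariance(self):
        amounts = [16.0, 4.0, 1.0, 0.25, 0.0625]
        means = [50.0 + 300.0 * max(a - 0.3, 0.0) for a in amounts]
        s1 = make_series(amounts, means)
        s2 = make_series(amounts, [m * 7.0 for m in means])
        c1, c2 = bilinear_fit(s1), bilinear_fit(s2)
        assert c2.turning_point == pytest.approx(c1.turning_point, rel=1e-6)
        assert c2.noise_floor == pytest.approx(7 * c1.noise_floor, rel=1e-6)
        assert c2.slope == pytest.approx(7 * c1.slope, rel=1e-6)

    def test_lod_equals_turning_point(self):
        amounts = [16.0, 4.0, 1.0, 0.25, 0.0625]
        means = [50.0 + 300.0 * max(a - 0.3, 0.0) for a in amounts]
        calib = bilinear_fit(make_series(amounts, means))
        assert calib.lod == calib.turning_point


class TestLoqFromCv:
    def _calib(self, lod):
        return CalibrationResult(
            precursor_id="t", turning_point=lod, noise_floor=100.0, slope=1000.0,
            intercept=0.0, level_cv_percent=np.array([]), valid=True,
        )

    def _series_with_cvs(self, amounts, cvs):
        levels = tuple(
            DilutionLevel(amount=a, areas=np.array([100.0, 100.0])) for a in amounts
        )
        series = DilutionSeries("t", levels)
        calib = self._calib(lod=0.0)
        object.__setattr__(calib, "level_cv_percent", np.asarray(cvs, dtype=float))
        return series, calib

    def test_worked_cv_ladder(self):
        """CVs low->high {40,25,15,8,5}% -> LOQ at the third-lowest level."""
        amounts = [16.0, 8.0, 4.0, 2.0, 1.0]  # decreasing
        cvs_high_to_low = [5.0, 8.0, 15.0, 25.0, 40.0]
        series, calib = self._series_with_cvs(amounts, cvs_high_to_low)
        assert loq_from_cv(series, calib) == 4.0

    def test_all_passing_gives_lowest_level(self):
        amounts = [16.0, 8.0, 4.0, 2.0]
        series, calib = self._series_with_cvs(amounts, [5.0, 6.0, 7.0, 8.0])
        assert loq_from_cv(series, calib) == 2.0

    def test_none_passing_gives_sentinel(self):
        amounts = [16.0, 8.0, 4.0, 2.0]
        series, calib = self._series_with_cvs(amounts, [30.0, 35.0, 40.0, 50.0])
        assert loq_from_cv(series, calib) == math.inf

    def test_loq_not_below_lod(self):
        amounts = [16.0, 8.0, 4.0, 2.0]
        series, calib = self._series_with_cvs(amounts, [5.0, 5.0, 5.0, 5.0])
        object.__setattr__(calib, "turning_point", 3.0)
        assert loq_from_cv(series, calib) == 4.0


class TestFragmentFilters:
    def test_high_heavy_cv_dropped(self):
        frags = {
            "y3": (np.array([100.0, 102.0, 98.0]), np.array([50.0, 51.0, 49.0])),
            "y4": (np.array([100.0, 101.0, 99.0]), np.array([50.0, 90.0, 20.0])),
        }
        assert fragment_cv_filter(frags) == ["y3"]

    def test_stable_fragments_identity(self):
        frags = {
            f"y{i}": (np.array([100.0, 101.0]), np.array([50.0, 50.5])) for i in range(4)
        }
        assert fragment_cv_filter(frags) == [f"y{i}" for i in range(4)]

    def test_interference_detected_by_ratio(self):
        clean = (np.array([100.0, 100.0]), np.array([50.0, 50.0]))  # L/H = 2
        interfered = (np.array([500.0, 500.0]), np.array([50.0, 50.0]))  # L/H = 10
        frags = {"y1": clean, "y2": clean, "y3": clean, "y4": interfered}
        kept = quant.interference_free_fragments(frags)
        assert kept == ["y1", "y2", "y3"]


class TestPrecursorQuant:
    def _frags(self, light=1000.0, heavy=2000.0, n=3, reps=3):
        return {
            f"y{i}": (np.full(reps, light / n), np.full(reps, heavy / n))
            for i in range(n)
        }

    def test_unit_efficiency_worked_example(self):
        pq = precursor_quant(self._frags(), spike_amount=1.0, efficiency=1.0, n_nitrogen=15)
        assert pq.amount == pytest.approx(0.500)

    def test_efficiency_corrected_worked_example(self):
        """L=1000, H=2000, 1 ng spike, p=0.99, n=15 -> 0.430 ng."""
        pq = precursor_quant(self._frags(), spike_amount=1.0, efficiency=0.99, n_nitrogen=15)
        assert pq.mean_heavy_corrected == pytest.approx(2000.0 / 0.99**15, rel=1e-9)
        assert pq.mean_heavy_corrected == pytest.approx(2325.4, abs=0.1)
        assert pq.amount == pytest.approx(0.430, abs=0.001)

    def test_correction_bias_is_exactly_p_to_n(self):
        on = precursor_quant(self._frags(), 1.0, 0.99, 15, correct_efficiency=True)
        off = precursor_quant(self._frags(), 1.0, 0.99, 15, correct_efficiency=False)
        assert on.amount / off.amount == pytest.approx(0.99**15, rel=1e-12)
        assert on.amount < off.amount  # correction lowers the light amount

    def test_low_heavy_sn_flagged(self):
        pq = precursor_quant(self._frags(), 1.0, 0.99, 15, heavy_s_over_n=4.0)
        assert "heavy_SN_below_5" in pq.flags
        assert not pq.included

    def test_below_loq_flagged(self):
        pq = precursor_quant(self._frags(), 1.0, 1.0, 15, loq=10.0)
        assert "below_LOQ" in pq.flags

    def test_too_few_clean_fragments_flagged(self):
        pq = precursor_quant(self._frags(n=2), 1.0, 1.0, 15)
        assert "fewer_than_3_clean_fragments" in pq.flags

    def test_every_excluded_precursor_carries_a_flag(self):
        bad = precursor_quant(self._frags(n=2), 1.0, 1.0, 15, heavy_s_over_n=2.0, loq=100.0)
        assert not bad.included and len(bad.flags) >= 1

    def test_relaxing_thresholds_is_monotone(self):
        frags = self._frags(n=3)
        strict = precursor_quant(frags, 1.0, 1.0, 15, min_clean_fragments=4)
        relaxed = precursor_quant(frags, 1.0, 1.0, 15, min_clean_fragments=3)
        assert set(relaxed.flags) <= set(strict.flags)

    def test_zero_heavy_rejected(self):
        frags = {f"y{i}": (np.full(3, 10.0), np.zeros(3)) for i in range(3)}
        with pytest.raises(ValueError):
            precursor_quant(frags, 1.0, 1.0, 15)


class TestProteinQuant:
    def _pq(self, pid, amount, flags=()):
        return quant.PrecursorQuant(
            precursor_id=pid, n_nitrogen=10, efficiency=0.99, mean_light=1.0,
            mean_heavy_raw=1.0, mean_heavy_corrected=1.0, light_heavy_ratio=1.0,
            amount=amount, n_fragments_used=3, flags=tuple(flags),
        )

    def test_single_precursor(self):
        res = protein_quant([self._pq("a", 0.5)], "P", molecular_weight_kda=30.0)
        assert res.amount == 0.5
        assert res.n_peptides == 1

    def test_mean_and_sd(self):
        quants = [self._pq(p, a) for p, a in zip("abc", (0.40, 0.44, 0.46))]
        res = protein_quant(quants, "P", molecular_weight_kda=30.0)
        assert res.amount == pytest.approx(0.4333, abs=1e-4)
        assert res.sd == pytest.approx(0.0306, abs=1e-4)

    def test_excluded_precursors_not_averaged(self):
        quants = [self._pq("a", 0.4), self._pq("b", 99.0, flags=("below_LOQ",))]
        res = protein_quant(quants, "P", molecular_weight_kda=30.0)
        assert res.amount == 0.4
        assert len(res.excluded) == 1

    def test_all_excluded_raises_with_reasons(self):
        quants = [self._pq("a", 1.0, flags=("heavy_SN_below_5",))]
        with pytest.raises(ValueError, match="heavy_SN_below_5"):
            protein_quant(quants, "P", molecular_weight_kda=30.0)

    def test_concentration_units(self):
        # 1 pmol of a 30 kDa protein = 30 ng; in 1e-8 l plasma -> 3000 mg/L
        res = protein_quant([self._pq("a", 1.0)], "P", molecular_weight_kda=30.0,
                            plasma_equivalent_l=1e-8)
        assert res.concentration_mg_l == pytest.approx(30.0 * 1e-6 / 1e-8)

    def test_chain_resolved_constructs_are_separate_rows(self):
        """Two construct segments of one protein quantify independently."""
        chain30 = protein_quant([self._pq("a", 0.3)], "ITIH4 (30 kDa)", 30.0)
        chain70 = protein_quant([self._pq("b", 0.2)], "ITIH4 (70 kDa)", 70.0)
        assert chain30.protein_id != chain70.protein_id
        assert chain30.amount != chain70.amount


class TestCalibrationRecoverySimulated:
    def test_seeded_series_recover_turning_point(self):
        """Median |log4 error| <= half a dilution step over seeded series."""
        errors, loq_ge_lod = [], []
        for seed in range(30):
            config = SimConfig(seed=seed)
            series, truth = simulate.sim_dilution(config)
            calib = bilinear_fit(series)
            if not calib.valid:
                continue
            errors.append(abs(math.log(calib.turning_point / truth["turning_point"], 4.0)))
            loq = loq_from_cv(series, calib)
            if math.isfinite(loq):
                loq_ge_lod.append(loq >= calib.lod)
        assert np.median(errors) <= 0.5
        assert all(loq_ge_lod)
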