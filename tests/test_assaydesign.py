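"""Transition filtering, scheduling, load balancing, GPF and MS3 selection."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prmkit import assaydesign as ad
from prmkit.features import TransitionFeatureSet


def feat(tid="t", area=500.0, rel=0.5, sb=5.0, width=8.0, corr=0.95):
    return TransitionFeatureSet(
        transition_id=tid,
        area=area,
        relative_area=rel,
        s_over_b=sb,
        width_s=width,
        time_correlation=corr,
    )


def make_candidate(pid, rt, width=8.0, window_half=60.0, n_transitions=0, **kw):
    transitions = tuple(
        feat(f"{pid}.y{i}", area=500 - 100 * i) for i in range(n_transitions)
    )
    defaults = dict(
        precursor_id=pid,
        sequence="PEPTIDEK",
        charge=2,
        label="light",
        precursor_mz=500.0,
        expected_rt=rt,
        peak_width=width,
        window=(rt - window_half, rt + window_half),
        transitions=transitions,
    )
    defaults.update(kw)
    return ad.TargetCandidate(**defaults)


class TestFilterTransitions:
    def test_worked_example(self):
        """Areas {500,120,90,50,5} of 765 with min area 100, min rel 0.05."""
        areas = [500.0, 120.0, 90.0, 50.0, 5.0]
        total = sum(areas)
        feats = [feat(f"t{i}", area=a, rel=a / total) for i, a in enumerate(areas)]
        out = ad.filter_transitions(feats, ad.FilterCriteria())
        assert [f.area for f in out] == [500.0, 120.0]

    def test_zero_criteria_identity(self):
        feats = [feat(f"t{i}", area=float(i)) for i in range(1, 5)]
        zero = ad.FilterCriteria(
            min_absolute_area=0,
            min_s_over_b=0,
            min_relative_area=0,
            min_time_correlation=0,
            width_range_s=(0.0, float("inf")),
        )
        assert ad.filter_transitions(feats, zero) == feats

    @given(
        areas=st.lists(st.floats(1, 1e5), min_size=2, max_size=8),
        bump=st.sampled_from(
            ["min_absolute_area", "min_s_over_b", "min_relative_area", "min_time_correlation"]
        ),
        factor=st.floats(1.0, 3.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_tightening_never_grows_subset(self, areas, bump, factor):
        total = sum(areas)
        feats = [
            feat(f"t{i}", area=a, rel=a / total, sb=a / 50, corr=min(a / 1e4, 1.0))
            for i, a in enumerate(areas)
        ]
        base = ad.FilterCriteria(min_absolute_area=50, min_s_over_b=1.0,
                                 min_relative_area=0.02, min_time_correlation=0.3)
        tightened = ad.FilterCriteria(**{
            **{f: getattr(base, f) for f in (
                "min_absolute_area", "min_s_over_b", "min_relative_area",
                "min_time_correlation", "width_range_s",
                "min_qualifying_transitions", "max_cv_percent")},
            bump: getattr(base, bump) * factor,
        })
        loose = {f.transition_id for f in ad.filter_transitions(feats, base)}
        tight = {f.transition_id for f in ad.filter_transitions(feats, tightened)}
        assert tight <= loose


class TestAcceptPrecursors:
    def test_min_three_qualifying(self):
        areas = [500.0, 120.0, 90.0, 50.0, 5.0]
        total = sum(areas)
        two_pass = make_candidate("p2", 100.0)
        two_pass = ad.TargetCandidate(
            **{**two_pass.__dict__, "transitions": tuple(
                feat(f"t{i}", area=a, rel=a / total) for i, a in enumerate(areas))}
        )
        three_pass = make_candidate("p3", 200.0, n_transitions=3)
        accepted, rejected = ad.accept_precursors([two_pass, three_pass], ad.FilterCriteria())
        assert [c.precursor_id for c in accepted] == ["p3"]
        assert "p2" in rejected

    def test_zero_minimum_accepts_all(self):
        c = make_candidate("p", 100.0)
        criteria = ad.FilterCriteria(min_qualifying_transitions=0)
        accepted, _ = ad.accept_precursors([c], criteria)
        assert len(accepted) == 1


class TestCv:
    def test_example(self):
        assert ad.cv_percent([100, 110, 90]) == pytest.approx(10.0)

    def test_identical_replicates(self):
        assert ad.cv_percent([5, 5, 5, 5]) == 0.0

    def test_scale_invariance(self):
        a = [120.0, 90.0, 100.0]
        assert ad.cv_percent(a) == pytest.approx(ad.cv_percent([x * 7.3 for x in a]))

    def test_cv_filter_removes_noisy(self):
        stable = make_candidate("s", 100.0, replicate_areas=(100.0, 101.0, 99.0))
        noisy = make_candidate("n", 200.0, replicate_areas=(100.0, 220.0, 40.0))
        kept, rejected = ad.cv_filter([stable, noisy], 30.0)
        assert [c.precursor_id for c in kept] == ["s"]
        assert "n" in rejected


class TestSplitAssays:
    def timing_10ms(self, goal=7.0):
        # 625 Da at 125 kDa/s + 5 ms overhead = 10 ms per target scan
        return ad.TimingModel(scan_range=625.0, overhead=0.005, points_per_peak_goal=goal)

    def test_non_overlapping_targets_single_method(self):
        cands = [make_candidate(f"p{i}", 200.0 * i + 100, window_half=30.0) for i in range(10)]
        result = ad.split_assays(cands, self.timing_10ms())
        assert len(result.methods) == 1
        assert not result.unschedulable

    def test_200_coeluting_targets_need_two_methods(self):
        """Budget 8 s / 7 points = 1.143 s -> 114 x 10 ms scans per method."""
        cands = [
            make_candidate(f"p{i:03d}", 500.0, width=8.0, window_half=60.0)
            for i in range(200)
        ]
        result = ad.split_assays(cands, self.timing_10ms())
        assert len(result.methods) == math.ceil(200 * 0.010 / (8.0 / 7.0))
        assert all(m.feasible() for m in result.methods)

    def test_empty_input(self):
        assert ad.split_assays([], self.timing_10ms()).methods == ()

    def test_unschedulable_target_reported(self):
        narrow = make_candidate("impossible", 100.0, width=0.005)
        result = ad.split_assays([narrow], self.timing_10ms())
        assert [c.precursor_id for c in result.unschedulable] == ["impossible"]

    def test_count_conserved(self):
        cands = [make_candidate(f"p{i}", 100 + 3.0 * i) for i in range(60)]
        result = ad.split_assays(cands, self.timing_10ms())
        total = sum(len(m.targets) for m in result.methods) + len(result.unschedulable)
        assert total == 60


class TestBalanceLoad:
    def _brute_force_optimum(self, targets, timing, k):
        best = math.inf
        for assignment in itertools.product(range(k), repeat=len(targets)):
            bins = [[] for _ in range(k)]
            for t, b in zip(targets, assignment):
                bins[b].append(t)
            worst = max(ad.AssayMethod(b, timing).worst_cycle_time() for b in bins)
            best = min(best, worst)
        return best

    def test_never_increases_max_and_conserves_count(self):
        timing = ad.TimingModel(scan_range=625.0, overhead=0.005)
        heavy = [make_candidate(f"h{i}", 100.0, window_half=50.0) for i in range(9)]
        light = [make_candidate("l0", 400.0, window_half=50.0)]
        methods = [ad.AssayMethod(heavy, timing), ad.AssayMethod(light, timing)]
        before = max(m.worst_cycle_time() for m in methods)
        balanced = ad.balance_load(methods)
        after = max(m.worst_cycle_time() for m in balanced)
        assert after <= before
        assert sum(len(m.targets) for m in balanced) == 10

    def test_matches_brute_force_on_small_instance(self, rng):
        timing = ad.TimingModel(scan_range=625.0, overhead=0.005)
        targets = [
            make_candidate(f"t{i}", float(rng.uniform(100, 300)), window_half=40.0)
            for i in range(10)
        ]
        methods = [ad.AssayMethod(targets[:8], timing), ad.AssayMethod(targets[8:], timing)]
        balanced = ad.balance_load(methods)
        after = max(m.worst_cycle_time() for m in balanced)
        optimum = self._brute_force_optimum(targets, timing, 2)
        before = max(m.worst_cycle_time() for m in methods)
        assert optimum <= after <= before

    def test_already_balanced_unchanged_max(self):
        # six co-eluting equal-cost targets split 3/3 cannot be improved
        timing = ad.TimingModel()
        a = [make_candidate(f"a{i}", 100.0) for i in range(3)]
        b = [make_candidate(f"b{i}", 100.0) for i in range(3)]
        methods = [ad.AssayMethod(a, timing), ad.AssayMethod(b, timing)]
        before = max(m.worst_cycle_time() for m in methods)
        after = max(m.worst_cycle_time() for m in ad.balance_load(methods))
        assert after == pytest.approx(before)


class TestPointsPerPeak:
    def test_direct_ratio(self):
        timing = ad.TimingModel(scan_range=625.0, overhead=0.005)  # 10 ms
        cands = [make_candidate(f"p{i}", 100.0, width=8.0) for i in range(100)]
        method = ad.AssayMethod(cands, timing)
        # 100 concurrent 10 ms scans -> 1.0 s cycle -> 8 points
        assert ad.points_per_peak(method, cands[0]) == pytest.approx(8.0)

    def test_halving_concurrency_doubles_points(self):
        timing = ad.TimingModel(scan_range=625.0, overhead=0.005)
        cands = [make_candidate(f"p{i}", 100.0, width=8.0) for i in range(100)]
        full = ad.AssayMethod(cands, timing)
        half = ad.AssayMethod(cands[:50], timing)
        assert ad.points_per_peak(half, cands[0]) == pytest.approx(
            2 * ad.points_per_peak(full, cands[0])
        )


class TestGpfPlan:
    def test_default_six_methods(self):
        plan = ad.gpf_plan()
        assert plan.n_methods == 6

    def test_hundred_windows_of_one_th(self):
        plan = ad.gpf_plan()
        for (lo, hi), windows in plan.methods:
            assert len(windows) == 100
            assert all(w_hi - w_lo == pytest.approx(1.0) for w_lo, w_hi in windows)

    def test_tiling_without_gaps_or_overlap(self):
        plan = ad.gpf_plan()
        edges = [w for _seg, windows in plan.methods for w in windows]
        edges.sort()
        assert edges[0][0] == 380.0 and edges[-1][1] == 980.0
        for (a_lo, a_hi), (b_lo, b_hi) in zip(edges, edges[1:]):
            assert a_hi == pytest.approx(b_lo)

    def test_non_divisible_step_rejected(self):
        with pytest.raises(ValueError):
            ad.gpf_plan(380, 980, 70)


class TestMs3Selection:
    def test_rule_application(self):
        products = [(450.0, 1, 100.0), (700.0, 1, 80.0), (500.0, 2, 90.0)]
        out = ad.select_ms3_products(products, precursor_mz=600.0)
        assert [mz for mz, _w in out] == [500.0, 700.0]

    def test_isolation_widths(self):
        products = [(700.0, 1, 80.0), (500.0, 2, 90.0)]
        out = dict(ad.select_ms3_products(products, precursor_mz=600.0))
        assert out[500.0] == pytest.approx(2.0)
        assert out[700.0] == pytest.approx(2.0 + 8.0 * 0.4 / 3.0, abs=1e-6)  # ~3.07

    def test_width_clamped_at_10(self):
        products = [(200.0, 2, 50.0), (900.0, 2, 50.0)]
        out = dict(ad.select_ms3_products(products, precursor_mz=500.0))
        assert out[900.0] == 10.0

    def test_no_qualifying_products_empty(self):
        products = [(300.0, 1, 50.0), (400.0, 1, 60.0)]
        assert ad.select_ms3_products(products, precursor_mz=600.0) == []


class TestExport:
    def test_roundtrip(self, tmp_path):
        cands = [
            make_candidate("light_pep", 300.0),
            make_candidate(
                "heavy_pep", 300.0, label="heavy15N",
                ms3_products=((500.0, 2.0), (700.0, 3.07)),
            ),
        ]
        method = ad.AssayMethod(cands)
        path = tmp_path / "targets.csv"
        written = ad.export_target_list(method, path)
        read = ad.read_target_list(path)
        assert len(read) == 3  # 1 MS2 row + 2 MS3 rows
        assert list(read["compound"]) == list(written["compound"])
        assert read["start_min"].iloc[0] == pytest.approx(4.0)  # (300-60)/60
        assert read["end_min"].iloc[0] == pytest.approx(6.0)

    def test_heavy_light_pair_mz_separation(self):
        from prmkit import chem

        seq = "AADDTWEPFASGK"
        light_mz = chem.precursor_mz(chem.PeptideSpecies(seq, 2, "light"))
        heavy_mz = chem.precursor_mz(chem.PeptideSpecies(seq, 2, "heavy15N"))
        cands = [
            make_candidate("l", 300.0, precursor_mz=light_mz),
            make_candidate("h", 300.0, label="heavy15N", precursor_mz=heavy_mz),
        ]
        df = ad.export_target_list(ad.AssayMethod(cands))
        shift = df["precursor_mz"].max() - df["precursor_mz"].min()
        assert shift == pytest.approx(
            chem.delta_mz_15n(chem.PeptideSpecies(seq, 2, "heavy15N")), abs=1e-5
        )
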