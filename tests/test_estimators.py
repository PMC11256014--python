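import numpy as np
import pytest

from lodie.calibration import detect_levels, determine_linear_range
from lodie.errors import EstimatorUnavailableError, NoDetectionError
from lodie.estimators import (
    EstimatorConfig,
    estimate_all,
    lod_cutoff,
    lod_residuals,
    lod_sd,
    lod_sn_extrapolation,
)
from lodie.simulate import SimConfig, TruthRecord, simulate_calibration

from conftest import GRID_16, make_series, noisy_series


def _ranged(series, **kw):
    detected = detect_levels(series, **{k: v for k, v in kw.items() if k in ("min_replicates", "min_area")})
    rr = determine_linear_range(series, detected=detected, **kw)
    return detected, rr


class TestCutoff:
    def test_lod_is_lowest_detected_level(self):
        # levels undetected, undetected, then detected from 2.74e-11 M up
        concs = np.array([2.74e-12, 5.48e-12, 2.74e-11, 5.48e-11, 2.74e-10])
        rf = 1e15
        areas = np.repeat((rf * concs)[:, None], 3, axis=1)
        s = make_series(concs, areas)
        detected = detect_levels(s, min_area=rf * 1e-11)
        assert detected.tolist() == [False, False, True, True, True]
        est = lod_cutoff(s, detected)
        assert est.lod == pytest.approx(2.74e-11)

    def test_all_detected_gives_grid_floor(self, exact_series):
        series, _ = exact_series
        detected = detect_levels(series, min_area=1.0)
        est = lod_cutoff(series, detected)
        assert est.lod == series.concentrations[0]
        assert est.lod in series.concentrations

    def test_non_monotone_level_mean_flagged(self):
        concs = np.array([1e-10, 2e-10, 1e-9])
        areas = np.array([[3e4, 3e4, 3e4], [2e4, 2e4, 2e4], [1e5, 1e5, 1e5]])
        s = make_series(concs, areas)
        est = lod_cutoff(s, detect_levels(s))
        assert est.diagnostics.get("flag_dynamic_range") is True

    def test_nothing_detected_raises(self):
        s = make_series([1e-10], [[10, 20, 30]])
        with pytest.raises(NoDetectionError):
            lod_cutoff(s, detect_levels(s))


class TestSnExtrapolation:
    def _series(self, sn_at_lowest):
        concs = np.array([1e-9, 1e-8, 1e-7, 1e-6])
        rf = 1e13
        areas = np.repeat((rf * concs)[:, None], 3, axis=1)
        sn = np.repeat((sn_at_lowest * concs / concs[0])[:, None], 3, axis=1)
        return make_series(concs, areas, sn=sn)

    @pytest.mark.parametrize(
        "sn0,expected_factor", [(30.0, 0.1), (3.0, 1.0), (1.5, 2.0)]
    )
    def test_linear_rescaling(self, sn0, expected_factor):
        s = self._series(sn0)
        detected, rr = _ranged(s, min_area=1.0)
        est = lod_sn_extrapolation(s, detected, rr)
        assert est.lod == pytest.approx(1e-9 * expected_factor, rel=1e-12)
        if sn0 < 3:
            assert est.diagnostics.get("flag_above_measured_floor") is True

    def test_missing_sn_is_unavailable_not_silent(self):
        s = self._series(30.0)
        s.sn = None
        detected, rr = _ranged(s, min_area=1.0)
        with pytest.raises(EstimatorUnavailableError):
            lod_sn_extrapolation(s, detected, rr)


class TestSdBased:
    def _series(self):
        concs = np.array([1e-9, 1e-8, 1e-7, 1e-6])
        rf = 1e11
        areas = np.repeat((rf * concs)[:, None], 3, axis=1)
        areas[0] = [90.0, 100.0, 110.0]
        return make_series(concs, areas)

    def test_arithmetic_example(self):
        s = self._series()
        detected, rr = _ranged(s, min_area=1.0, rel_tol=0.3)
        est = lod_sd(s, detected, rr)
        assert est.lod == pytest.approx(3.3 * 10.0 / rr.fit.slope, rel=1e-12)
        assert rr.fit.slope == pytest.approx(1e11, rel=1e-3)

    def test_identical_replicates_degenerate_zero(self, exact_series):
        series, _ = exact_series
        detected, rr = _ranged(series, min_area=1.0)
        est = lod_sd(series, detected, rr)
        assert est.lod == 0.0
        assert est.diagnostics.get("flag_degenerate") is True

    def test_scale_invariance_under_doubling(self):
        s = self._series()
        detected, rr = _ranged(s, min_area=1.0, rel_tol=0.3)
        lod1 = lod_sd(s, detected, rr).lod
        s2 = make_series(s.concentrations, s.areas * 2)
        detected2, rr2 = _ranged(s2, min_area=2.0, rel_tol=0.3)
        lod2 = lod_sd(s2, detected2, rr2).lod
        assert lod2 == pytest.approx(lod1, rel=1e-9)


class TestResiduals:
    def test_exact_line_degenerate_zero(self, exact_series):
        series, _ = exact_series
        detected, rr = _ranged(series, min_area=1.0)
        est = lod_residuals(series, rr)
        assert est.lod == 0.0
        assert est.diagnostics.get("flag_degenerate") is True

    def test_matches_independent_recomputation(self):
        s = noisy_series(seed=21, sigma=2000.0, cv=0.02)
        detected, rr = _ranged(s)
        assert rr.accepted
        est = lod_residuals(s, rr)
        # independent recomputation outside the pipeline
        resid = rr.fit.mean_areas[:3] - (
            rr.fit.intercept + rr.fit.slope * rr.fit.concentrations[:3]
        )
        expected = 3.3 * np.std(resid, ddof=1) / rr.fit.slope
        assert est.lod == pytest.approx(expected, rel=1e-12)

    def test_too_few_levels_unavailable(self):
        concs = np.array([1e-9, 1e-8, 1e-7, 1e-6])
        areas = np.repeat((1e13 * concs)[:, None], 3, axis=1)
        s = make_series(concs, areas)
        detected, rr = _ranged(s, min_area=1.0)
        with pytest.raises(EstimatorUnavailableError):
            lod_residuals(s, rr, EstimatorConfig(n_resid_levels=5))


class TestEstimateAll:
    def test_noisy_series_yields_four_positive_estimates(self):
        s = noisy_series(seed=0, sigma=2000.0, cv=0.02)
        res = estimate_all(s)
        methods = {e.method for e in res.estimates}
        assert methods == {"cutoff", "sn_extrapolation", "sd_based", "residuals"}
        assert all(e.lod > 0 for e in res.estimates)

    def test_missing_sn_reports_three_plus_unavailable(self):
        s = noisy_series(seed=0, sigma=2000.0, cv=0.02)
        s.sn = None
        res = estimate_all(s)
        assert len(res.estimates) == 3
        assert "sn_extrapolation" in res.unavailable

    def test_undetected_compound_excluded_with_reason(self):
        s = make_series(GRID_16, np.full((16, 3), 50.0))
        res = estimate_all(s)
        assert res.estimates == []
        assert res.excluded_reason == "no-detection"

    @pytest.mark.parametrize("lam", [1e-3, 1e3])
    def test_scale_invariance_of_all_lods(self, lam):
        s = noisy_series(seed=4, sigma=2000.0, cv=0.02)
        base = {e.method: e.lod for e in estimate_all(s).estimates}
        s2 = make_series(s.concentrations, s.areas * lam, sn=s.sn)
        scaled = {e.method: e.lod
                  for e in estimate_all(s2, min_area=10000 * lam).estimates}
        assert scaled.keys() == base.keys()
        assert scaled["cutoff"] == base["cutoff"]
        for m in ("sd_based", "residuals", "sn_extrapolation"):
            assert scaled[m] == pytest.approx(base[m], rel=1e-9)


class TestStochasticBehaviour:
    def test_mean_sd_lod_increases_with_noise(self):
        cfg_lo = SimConfig(n_compounds=1, seed=0)
        means = []
        for sigma in (1000.0, 4000.0):
            vals = []
            for seed in range(200):
                truth = TruthRecord("c", 1e14, sigma, 3 * sigma / 1e14, 3.0)
                s = simulate_calibration(truth, cfg_lo, seed)
                res = estimate_all(s)
                for e in res.estimates:
                    if e.method == "sd_based":
                        vals.append(e.lod)
            means.append(np.mean(vals))
        assert means[1] > means[0]

    def test_sn_extrapolation_tracks_true_lod(self):
        # true LoD = sn_target * sigma / RF by construction; the S/N
        # extrapolation should land within a factor of 2 at moderate noise
        cfg = SimConfig(n_compounds=40, seed=5)
        from lodie.simulate import simulate_study

        series, _, truths = simulate_study(cfg)
        ratios = []
        for s, t in zip(series, truths):
            res = estimate_all(s)
            for e in res.estimates:
                if e.method == "sn_extrapolation":
                    ratios.append(e.lod / t.lod_true)
        assert len(ratios) >= 10
        assert 0.5 <= np.median(ratios) <= 2.0

    def test_sn_extrapolation_below_cutoff_when_floor_far_above_lod(self):
        # grid floor far above the true LoD: cutoff is stuck at the floor
        # while S/N extrapolation reaches below it
        concs = GRID_16[-6:]
        rf = 1e13
        rng = np.random.default_rng(8)
        sigma = 100.0
        areas = np.maximum(
            (rf * concs)[:, None] * (1 + rng.normal(0, 0.02, (6, 3)))
            + rng.normal(0, sigma, (6, 3)),
            0,
        )
        s = make_series(concs, areas, sn=areas / sigma)
        res = estimate_all(s)
        lods = {e.method: e.lod for e in res.estimates}
        assert lods["sn_extrapolation"] < lods["cutoff"]
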