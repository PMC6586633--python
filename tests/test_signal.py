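"""XIC extraction, peak integration, spectral dot product and pair QC."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings
from hypothesis import strategies as st

from prmquant.errors import UndefinedSimilarityError
from prmquant.signal import (ChromatogramTrace, PeakEvaluation, QcThresholds,
                             detect_and_integrate, dot_product, evaluate_pair,
                             extract_xic, gaussian_shape_score, parameter_sweep)
from prmquant.simulator import (AcquisitionSettings, build_upr_panel,
                                default_truth, panel_pairs)

from conftest import make_acquisition


def _trace(rts, intensities, fragment="y4", mzs=None, theoretical=500.0):
    rts = np.asarray(rts, float)
    intensities = np.asarray(intensities, float)
    if mzs is None:
        mzs = np.where(intensities > 0, theoretical, 0.0)
    return ChromatogramTrace(peptide="PEPTIDEK", label="light", fragment=fragment,
                             rts=rts, intensities=intensities,
                             measured_mzs=np.asarray(mzs, float),
                             theoretical_mz=theoretical)


class TestExtractXic:
    def test_exact_centroid_returned(self):
        acq = make_acquisition([(1.0, "PEP", "light", [500.0], [42.0])])
        tr = extract_xic(acq, "PEP", "light", "y4", 500.0, tol_ppm=10)
        assert tr.intensities[0] == 42.0
        assert tr.measured_mzs[0] == 500.0

    def test_centroid_outside_tolerance_excluded(self):
        acq = make_acquisition([(1.0, "PEP", "light", [500.0 * (1 + 15e-6)], [42.0])])
        tr = extract_xic(acq, "PEP", "light", "y4", 500.0, tol_ppm=10)
        assert tr.intensities[0] == 0.0
        assert tr.measured_mzs[0] == 0.0

    def test_unknown_target_raises(self):
        acq = make_acquisition([(1.0, "PEP", "light", [500.0], [1.0])])
        with pytest.raises(KeyError):
            extract_xic(acq, "OTHER", "light", "y4", 500.0)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n_scans = rng.integers(1, 6)
            tuples = []
            for i in range(n_scans):
                n_cent = rng.integers(0, 8)
                mzs = 500.0 * (1 + rng.uniform(-40e-6, 40e-6, n_cent))
                ints = rng.uniform(1, 100, n_cent)
                tuples.append((float(i + 1), "PEP", "light", mzs, ints))
            acq = make_acquisition(tuples)
            tol = float(rng.uniform(1, 25))
            tr = extract_xic(acq, "PEP", "light", "y4", 500.0, tol_ppm=tol)
            for i, (_, _, _, mzs, ints) in enumerate(tuples):
                expected = sum(inten for mz, inten in zip(mzs, ints)
                               if abs(mz - 500.0) / 500.0 * 1e6 <= tol)
                assert tr.intensities[i] == pytest.approx(expected)


class TestDetectAndIntegrate:
    def test_noiseless_gaussian_matches_closed_form(self):
        rts = np.linspace(9.0, 11.0, 401)
        a, mu, sig = 1000.0, 10.0, 0.1
        y = a * np.exp(-0.5 * ((rts - mu) / sig) ** 2)
        ev = detect_and_integrate([_trace(rts, y)], expected_rt=10.0, window=2.0)
        closed = a * sig * np.sqrt(2 * np.pi)
        assert ev.areas["y4"] == pytest.approx(closed, rel=0.01)
        assert ev.apex_rt == pytest.approx(10.0, abs=0.02)

    def test_all_zero_trace_flagged(self):
        rts = np.linspace(0, 2, 50)
        ev = detect_and_integrate([_trace(rts, np.zeros(50))], 1.0, 2.0)
        assert not ev.detected
        assert ev.areas["y4"] == 0.0
        assert "not-detected" in ev.rejection_reasons

    def test_two_disjoint_peaks_selects_expected(self):
        rts = np.linspace(0.0, 10.0, 501)
        y = 500 * np.exp(-0.5 * ((rts - 2.0) / 0.1) ** 2) \
            + 800 * np.exp(-0.5 * ((rts - 8.0) / 0.1) ** 2)
        ev = detect_and_integrate([_trace(rts, y)], expected_rt=8.0, window=2.0)
        assert ev.apex_rt == pytest.approx(8.0, abs=0.05)
        assert ev.boundaries[0] > 4.0  # first peak not integrated
        assert ev.areas["y4"] == pytest.approx(800 * 0.1 * np.sqrt(2 * np.pi), rel=0.02)

    def test_integration_additivity_exact(self):
        rts = np.linspace(9.0, 11.0, 101)
        rng = np.random.default_rng(0)
        y1 = 100 * np.exp(-0.5 * ((rts - 10.0) / 0.1) ** 2) + rng.uniform(0, 5, 101)
        y2 = 300 * np.exp(-0.5 * ((rts - 10.0) / 0.1) ** 2) + rng.uniform(0, 5, 101)
        ev = detect_and_integrate([_trace(rts, y1, "y3"), _trace(rts, y2, "y4")],
                                  10.0, 2.0)
        lo, hi = ev.boundaries
        sl = (rts >= lo) & (rts <= hi)
        summed_area = float(np.trapezoid((y1 + y2)[sl], rts[sl]))
        assert ev.areas["y3"] + ev.areas["y4"] == pytest.approx(summed_area, rel=1e-12)

    def test_empty_traces_rejected(self):
        with pytest.raises(ValueError):
            detect_and_integrate([], 1.0, 2.0)


class TestDotProduct:
    @pytest.mark.parametrize("a,b,expected", [
        ((3, 4, 5), (3, 4, 5), 1.0),
        ((1, 0), (0, 1), 0.0),
        ((3, 4), (4, 3), 0.96),  # 24/25 by hand
    ])
    def test_reference_values(self, a, b, expected):
        assert dot_product(a, b) == pytest.approx(expected, abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(UndefinedSimilarityError):
            dot_product((0, 0), (1, 2))

    @pytest.mark.parametrize("a,b", [((1, 2), (1, 2, 3)), ((-1, 2), (1, 2))])
    def test_invalid_inputs_rejected(self, a, b):
        with pytest.raises(ValueError):
            dot_product(a, b)

    @given(st.lists(st.floats(0, 1e6), min_size=2, max_size=8),
           st.floats(1e-3, 1e3))
    @hyp_settings(max_examples=100, derandomize=True)
    def test_symmetry_scale_invariance_and_range(self, vals, c):
        a = np.asarray(vals) + 1.0  # ensure nonzero
        b = a[::-1].copy()
        dp = dot_product(a, b)
        assert 0.0 <= dp <= 1.0
        assert dp == pytest.approx(dot_product(b, a), abs=1e-12)
        assert dp == pytest.approx(dot_product(a, c * b), rel=1e-9)
        assert dot_product(a, a) == pytest.approx(1.0, abs=1e-12)


class TestGaussianShapeScore:
    def test_exact_gaussian_scores_high(self):
        t = np.linspace(-1, 1, 41)
        y = 100 * np.exp(-0.5 * (t / 0.3) ** 2)
        assert gaussian_shape_score(t, y) >= 0.999

    def test_uniform_noise_scores_low(self):
        scores = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            scores.append(gaussian_shape_score(np.linspace(0, 1, 50),
                                               rng.uniform(0, 1, 50)))
        assert np.mean(scores) < 0.5

    def test_flat_trace_scores_zero(self):
        assert gaussian_shape_score(np.linspace(0, 1, 20), np.full(20, 7.0)) == 0.0

    def test_too_few_points_not_evaluable(self):
        assert gaussian_shape_score(np.arange(4), np.arange(4.0)) is None


class TestEvaluatePair:
    @staticmethod
    def _clean_eval(apex=10.0, ppm=1.0, n=5, shape=0.99, areas=None):
        areas = areas or {"y3": 100.0, "y4": 200.0, "y5": 300.0}
        return PeakEvaluation(peptide="PEP", label="light", apex_rt=apex,
                              boundaries=(apex - 0.2, apex + 0.2), areas=areas,
                              mass_errors_ppm={f: ppm for f in areas},
                              n_detected_transitions=n, shape_r2=shape,
                              detected=True)

    LIBRARY = {"y3": 1.0, "y4": 2.0, "y5": 3.0}

    def test_clean_pair_accepted(self):
        ev = evaluate_pair(self._clean_eval(), self._clean_eval(), self.LIBRARY)
        assert ev.accepted and not ev.rejection_reasons

    def test_rt_shift_rejected_as_coelution_failure(self):
        heavy = self._clean_eval(apex=10.5)
        ev = evaluate_pair(self._clean_eval(), heavy, self.LIBRARY)
        assert not ev.accepted
        assert "rt-coelution" in ev.rejection_reasons

    def test_eight_ppm_mass_error_rejected(self):
        ev = evaluate_pair(self._clean_eval(ppm=8.0), self._clean_eval(),
                           self.LIBRARY)
        assert not ev.accepted
        assert "mass-error" in ev.rejection_reasons

    def test_single_transition_rejected(self):
        light = self._clean_eval(areas={"y3": 100.0})
        ev = evaluate_pair(light, self._clean_eval(), self.LIBRARY)
        assert "min-transitions" in ev.rejection_reasons

    def test_discordant_ratios_rejected(self):
        heavy = self._clean_eval(areas={"y3": 300.0, "y4": 100.0, "y5": 5.0})
        ev = evaluate_pair(self._clean_eval(), heavy, self.LIBRARY)
        assert "ratio-dotp" in ev.rejection_reasons

    def test_simulated_clean_pair_accepted_end_to_end(self, acquisition):
        from prmquant.signal import evaluate_acquisition
        table = evaluate_acquisition(acquisition)
        assert table["accepted"].all()

    def test_every_failure_is_named(self):
        bad = PeakEvaluation(peptide="PEP", label="light", detected=False)
        ev = evaluate_pair(bad, bad, self.LIBRARY)
        assert not ev.accepted and len(ev.rejection_reasons) >= 3


class TestParameterSweep:
    def test_single_grid_point_single_row(self, panel):
        truth = default_truth(panel, seed=1)
        table = parameter_sweep(panel[:4], truth, [AcquisitionSettings()])
        assert len(table) == 1

    def test_dotp_non_decreasing_in_injection_time(self, panel):
        sub = panel[:8]
        truth = default_truth(sub, seed=2, with_interference=False)
        grid = [AcquisitionSettings(injection_time=t) for t in (30, 500)]
        table = parameter_sweep(sub, truth, grid)
        dotp = dict(zip(table["injection_time"], table["mean_dotp"]))
        assert dotp[500] >= dotp[30]

    def test_empty_grid_rejected(self, panel):
        with pytest.raises(ValueError):
            parameter_sweep(panel, default_truth(panel, seed=1), [])
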