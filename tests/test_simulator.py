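"""Simulator: panel construction, the mass-error model, seeded acquisition
physics and the dilution/condition generators."""

import numpy as np
import pytest

from prmquant.errors import ConfigurationError
from prmquant.signal import detect_and_integrate, extract_precursor_traces, signal_to_noise
from prmquant.simulator import (AcquisitionSettings, Interferent, SimulationTruth,
                                build_upr_panel, mass_error_sigma, panel_pairs,
                                simulate_acquisition, simulate_condition_experiment,
                                simulate_dilution_series)

# Frozen oracle: independent residue-mass summation for GGFGVVFEAK, 2+.
GGFGVVFEAK_MZ_2PLUS = 505.76890


class TestPanel:
    def test_structure(self, panel):
        pairs = panel_pairs(panel)
        assert len(pairs) == 21
        assert len({p.protein for p in panel}) == 8
        for light, heavy in pairs:
            assert light.rt_true == heavy.rt_true
            assert light.fragment_rel_intensities == heavy.fragment_rel_intensities
            assert heavy.precursor_mz > light.precursor_mz

    @pytest.mark.parametrize("seed", [1, 7, 123])
    def test_known_assay_peptides_present(self, seed):
        by_seq = {p.sequence: p.protein for p in build_upr_panel(seed)}
        assert by_seq["GGFGVVFEAK"] == "PERK"
        assert by_seq["YLTDFEPIQCLGR"] == "PERK"
        assert by_seq["AEPQPLSPASSSYSVSSPR"] == "ATF6"
        assert "APLSPSLLIR" in by_seq

    def test_precursor_mz_matches_residue_mass_oracle(self, panel):
        spec = next(p for p in panel
                    if p.sequence == "GGFGVVFEAK" and p.label == "light")
        assert spec.charge == 2
        assert spec.precursor_mz == pytest.approx(GGFGVVFEAK_MZ_2PLUS, abs=2e-3)

    def test_ambiguous_attribution_flagged(self, panel):
        spec = next(p for p in panel if p.sequence == "APLSPSLLIR")
        assert spec.protein_ambiguous

    def test_rts_span_gradient(self, panel):
        rts = [p.rt_true for p in panel]
        assert min(rts) > 2 and max(rts) < 75


class TestMassErrorModel:
    def test_frozen_arithmetic_oracle(self):
        # C * (1e6 / (60000*sqrt(200/500))) / sqrt(1000) computed independently
        assert mass_error_sigma(60_000, 500.0, 1000) == pytest.approx(8.3333333, rel=1e-6)

    def test_doubling_resolution_halves_sigma(self):
        s1 = mass_error_sigma(60_000, 500.0, 1000)
        s2 = mass_error_sigma(120_000, 500.0, 1000)
        assert s2 == pytest.approx(s1 / 2, rel=1e-9)

    @pytest.mark.parametrize("mz,count", [(300.0, 50), (500.0, 1000), (1200.0, 2e5)])
    def test_monotone_in_resolution(self, mz, count):
        assert mass_error_sigma(240_000, mz, count) < mass_error_sigma(60_000, mz, count)

    def test_monotone_in_ion_count(self):
        assert mass_error_sigma(240_000, 500.0, 1e4) < mass_error_sigma(240_000, 500.0, 1e2)

    @pytest.mark.parametrize("bad", [(0, 500, 100), (240_000, -1, 100), (240_000, 500, 0)])
    def test_nonpositive_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            mass_error_sigma(*bad)

    def test_calibration_clause(self):
        # mean |error| = sigma * sqrt(2/pi): > 5 ppm at 60k, <= 2 ppm at 240k
        factor = np.sqrt(2 / np.pi)
        assert mass_error_sigma(60_000, 500.0, 1000) * factor > 5.0
        assert mass_error_sigma(240_000, 500.0, 1000) * factor <= 2.0


class TestAcquisition:
    def test_seeded_determinism(self, panel, settings):
        from prmquant.simulator import default_truth
        a = simulate_acquisition(panel, settings, default_truth(panel, seed=5))
        b = simulate_acquisition(panel, settings, default_truth(panel, seed=5))
        assert len(a.scans) == len(b.scans)
        for sa, sb in zip(a.scans, b.scans):
            assert sa.rt == sb.rt and sa.sequence == sb.sequence
            np.testing.assert_array_equal(sa.mz, sb.mz)
            np.testing.assert_array_equal(sa.intensity, sb.intensity)

    def test_scan_rts_increasing_per_precursor(self, acquisition):
        for spec in acquisition.panel[:4]:
            rts = [s.rt for s in acquisition.scans_for(spec.sequence, spec.label)]
            assert np.all(np.diff(rts) > 0)

    def test_zero_amount_gives_no_analyte_signal(self, pair, settings):
        light, heavy = pair
        truth = SimulationTruth(amounts={light.key: 0.0, heavy.key: 100.0}, seed=3)
        acq = simulate_acquisition([light, heavy], settings, truth)
        assert all(s.signal_total == 0 for s in acq.scans_for(light.sequence, "light"))
        assert any(s.signal_total > 0 for s in acq.scans_for(heavy.sequence, "heavy"))

    def test_missing_truth_raises(self, pair, settings):
        light, heavy = pair
        with pytest.raises(ConfigurationError):
            simulate_acquisition([light, heavy], settings,
                                 SimulationTruth(amounts={light.key: 1.0}))

    def test_fragment_counts_conserve_drawn_total(self, pair):
        # without baseline/interference, per-scan centroid intensities must
        # sum exactly to the drawn analyte ion count (merging preserves sums)
        light, heavy = pair
        truth = SimulationTruth(amounts={light.key: 50.0, heavy.key: 100.0},
                                seed=11, baseline_rate=0.0)
        acq = simulate_acquisition([light, heavy], AcquisitionSettings(), truth)
        for s in acq.scans:
            assert int(s.intensity.sum()) == s.signal_total

    def test_truth_linearity_of_signal(self, pair, settings):
        # doubling the light amount doubles the expected accumulated ion
        # count (the XIC area inherits this up to extraction-tolerance loss)
        light, heavy = pair
        totals = {}
        for amol in (20.0, 40.0):
            vals = []
            for seed in range(20):
                truth = SimulationTruth(amounts={light.key: amol, heavy.key: 100.0},
                                        seed=seed, baseline_rate=0.0)
                acq = simulate_acquisition([light, heavy], settings, truth)
                vals.append(sum(s.signal_total
                                for s in acq.scans_for(light.sequence, "light")))
            totals[amol] = (np.mean(vals), np.std(vals, ddof=1) / np.sqrt(len(vals)))
        ratio = totals[40.0][0] / totals[20.0][0]
        sd = ratio * np.hypot(totals[40.0][1] / totals[40.0][0],
                              totals[20.0][1] / totals[20.0][0])
        assert abs(ratio - 2.0) < 3 * max(sd, 1e-3)

    def test_narrow_isolation_improves_snr_with_interferent(self, pair):
        light, heavy = pair
        sn = {0.4: [], 1.6: []}
        for seed in range(20):
            # isobaric chemical noise: fragments 6 ppm from the targets,
            # inside the 10 ppm extraction tolerance
            itf = Interferent(target_sequence=light.sequence, mz_offset=0.6,
                              rt=light.rt_true, intensity=10.0,
                              fragment_mzs=tuple(m * (1 + 6e-6)
                                                 for m in light.fragment_mzs[:3]))
            for width in sn:
                st = AcquisitionSettings(isolation_width=width)
                truth = SimulationTruth(amounts={light.key: 50.0, heavy.key: 100.0},
                                        interferents=[itf], seed=seed)
                acq = simulate_acquisition([light, heavy], st, truth)
                tr = extract_precursor_traces(acq, light)
                ev = detect_and_integrate(tr, light.rt_true, st.rt_window)
                sn[width].append(signal_to_noise(tr, ev))
        assert np.mean(sn[0.4]) > np.mean(sn[1.6])


class TestDilutionSeries:
    def test_seven_step_twofold_endpoints(self, pair, settings):
        series = simulate_dilution_series(pair, 980.8, 2.0, 7, settings, seed=1,
                                          with_interference=False)
        nominals = [n for n, _ in series]
        assert len(nominals) == 8
        assert nominals[0] == pytest.approx(980.8)
        assert nominals[-1] == pytest.approx(7.6625)
        assert round(nominals[-1], 1) == 7.7

    def test_low_start_endpoint(self, pair, settings):
        series = simulate_dilution_series(pair, 59.0, 2.0, 7, settings, seed=1,
                                          with_interference=False)
        assert series[-1][0] == pytest.approx(0.4609375)
        assert round(series[-1][0], 1) == 0.5

    def test_constant_heavy_across_levels(self, pair, settings):
        light, heavy = pair
        series = simulate_dilution_series(pair, 100.0, 2.0, 3, settings, seed=1,
                                          heavy_amol=123.0)
        assert all(acq.truth.amounts[heavy.key] == 123.0 for _, acq in series)

    @pytest.mark.parametrize("kwargs", [dict(factor=1.0), dict(factor=0.5),
                                        dict(steps=0), dict(start_conc=-1.0)])
    def test_degenerate_inputs_rejected(self, pair, settings, kwargs):
        args = dict(start_conc=100.0, factor=2.0, steps=7)
        args.update(kwargs)
        with pytest.raises(ValueError):
            simulate_dilution_series(pair, args["start_conc"], args["factor"],
                                     args["steps"], settings, seed=1)


class TestConditionExperiment:
    def test_identity_folds_leave_truth_unchanged(self, panel, settings):
        sub = panel[:4]
        runs = simulate_condition_experiment(sub, {}, 1, settings, seed=2, cv=0.0)
        c = runs["control"][0].truth.amounts
        t = runs["treated"][0].truth.amounts
        assert c == t

    def test_programmed_fold_exact_in_truth(self, panel, settings):
        sub = [p for p in panel if p.protein in ("XBP1", "PERK")]
        runs = simulate_condition_experiment(sub, {"XBP1": 17.0}, 1, settings,
                                             seed=2, cv=0.0)
        c = runs["control"][0].truth.amounts
        t = runs["treated"][0].truth.amounts
        for key in c:
            seq, label = key
            protein = next(p.protein for p in sub if p.sequence == seq)
            expect = 17.0 if (label == "light" and protein == "XBP1") else 1.0
            assert t[key] / c[key] == pytest.approx(expect)

    def test_unknown_protein_rejected(self, panel, settings):
        with pytest.raises(ConfigurationError):
            simulate_condition_experiment(panel[:2], {"NOT_A_PROTEIN": 2.0}, 1,
                                          settings, seed=0)

    def test_replicate_noise_has_requested_scale(self, panel, settings):
        sub = panel[:2]
        runs = simulate_condition_experiment(sub, {}, 30, settings, seed=4, cv=0.10)
        key = sub[0].key
        vals = [acq.truth.amounts[key] for acq in runs["control"]]
        cv_obs = np.std(vals, ddof=1) / np.mean(vals)
        assert 0.04 < cv_obs < 0.2
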