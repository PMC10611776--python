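import math

import numpy as np
import pytest

from silacmrm import frataxin
from silacmrm.chromsim import (
    Chromatogram,
    SimulationConfig,
    simulate_sample,
    simulate_standard_series,
)
from silacmrm.quant import (
    PeakArea,
    back_calculate,
    backcalc_table,
    fit_calibration,
    group_summary,
    injected_amount,
    integrate_peak,
    light_heavy_ratio,
    measure_ratio,
    protein_amount,
    quantify_standard_series,
    tissue_concentration,
)


def _gaussian_chrom(amplitude=1000.0, sigma=0.03, center=5.0, baseline=0.0,
                    half=0.2, dt=0.002):
    t = np.arange(center - half, center + half + dt / 2, dt)
    y = baseline + amplitude * np.exp(-0.5 * ((t - center) / sigma) ** 2)
    return Chromatogram("t1", t, y)


def _area(a):
    return PeakArea("t", a, 1.0, 0.0)


class TestIntegratePeak:
    def test_gaussian_closed_form(self):
        amp, sigma = 1000.0, 0.03
        pa = integrate_peak(_gaussian_chrom(amp, sigma), 5.0, window=0.1,
                            baseline="none")
        assert pa.area == pytest.approx(amp * sigma * math.sqrt(2 * math.pi), rel=0.01)
        assert pa.rt_observed == pytest.approx(5.0, abs=1e-6)

    def test_flat_trace_integrates_to_zero(self):
        pa = integrate_peak(_gaussian_chrom(amplitude=0.0, baseline=120.0), 5.0)
        assert pa.area == 0.0
        assert pa.baseline_used == pytest.approx(120.0)

    def test_linearity_in_amplitude(self):
        a1 = integrate_peak(_gaussian_chrom(100.0), 5.0, baseline="none").area
        a10 = integrate_peak(_gaussian_chrom(1000.0), 5.0, baseline="none").area
        assert a10 == pytest.approx(10 * a1, rel=1e-9)

    def test_window_outside_trace_errors(self):
        with pytest.raises(ValueError):
            integrate_peak(_gaussian_chrom(), 5.5, window=0.1)

    def test_shifted_centroid_is_flagged_not_dropped(self):
        chrom = _gaussian_chrom(center=5.04, half=0.3)
        pa = integrate_peak(chrom, 5.0, window=0.1, rt_tolerance=0.02)
        assert "rt_out_of_tolerance" in pa.flags
        assert pa.area > 0


class TestLightHeavyRatio:
    def test_channelwise_double_gives_two(self):
        m = light_heavy_ratio([_area(20), _area(40), _area(60)],
                              [_area(10), _area(20), _area(30)])
        assert m.ratio == pytest.approx(2.0)

    def test_estimators_differ_on_uneven_triples(self):
        light = [_area(30), _area(20), _area(10)]
        heavy = [_area(10), _area(10), _area(10)]
        assert light_heavy_ratio(light, heavy).ratio == pytest.approx(2.0)
        assert light_heavy_ratio(light, heavy, "sum_of_ratios").ratio == pytest.approx(6.0)

    def test_global_scaling_invariance(self):
        light = [_area(30), _area(20), _area(10)]
        heavy = [_area(12), _area(9), _area(6)]
        base = light_heavy_ratio(light, heavy).ratio
        for c in (0.1, 3.7, 1000.0):
            scaled = light_heavy_ratio(
                [_area(a.area * c) for a in light],
                [_area(a.area * c) for a in heavy],
            ).ratio
            assert scaled == pytest.approx(base, rel=1e-12)

    def test_missing_internal_standard_errors(self):
        light = [_area(10)] * 3
        with pytest.raises(ZeroDivisionError):
            light_heavy_ratio(light, [_area(0)] * 3)
        with pytest.raises(ZeroDivisionError):
            light_heavy_ratio(light, [_area(0), _area(5), _area(5)],
                              "sum_of_ratios")


class TestCalibration:
    def test_noise_free_line_recovered(self):
        pts = [(x, 0.025 * x) for x in (4, 10, 40, 100, 200)]
        for weighting in ("none", "1/x", "1/x2"):
            curve = fit_calibration(pts, weighting=weighting)
            assert curve.slope == pytest.approx(0.025, abs=1e-12)
            assert curve.intercept == pytest.approx(0.0, abs=1e-12)
            assert curve.r_squared == pytest.approx(1.0)

    def test_degenerate_designs_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([(4, 0.1), (4, 0.1), (4, 0.11)])
        with pytest.raises(ValueError):
            fit_calibration([(4, 0.1), (10, 0.2)])

    def test_relative_weighting_improves_low_end_accuracy(self):
        # heteroscedastic multiplicative noise, as MRM areas show
        rng = np.random.default_rng(17)
        levels = [4, 10, 15, 20, 30, 40, 80, 100, 150, 200]
        pts = [
            (x, 0.025 * x * math.exp(rng.normal(0, 0.08)))
            for x in levels for _ in range(5)
        ]
        err = {}
        for weighting in ("none", "1/x2"):
            curve = fit_calibration(pts, weighting=weighting)
            # back-calculate the true 4-ng ratio: any deviation is fit bias
            err[weighting] = abs(back_calculate(curve, 0.025 * 4).ng - 4.0)
        assert err["1/x2"] <= err["none"]

    def test_back_calculate_closure_and_range_flags(self):
        pts = [(x, 0.025 * x) for x in (4, 10, 40, 100, 200)]
        curve = fit_calibration(pts)
        assert back_calculate(curve, 0.025 * 40).ng == pytest.approx(40.0)
        assert back_calculate(curve, 0.025 * 40).flag == "ok"
        assert back_calculate(curve, 0.025 * 2).flag == "below_range"
        assert back_calculate(curve, 0.025 * 500).flag == "above_range"

    def test_backcalc_table_arithmetic(self):
        pts = [(x, 0.025 * x) for x in (4, 10, 40, 100, 200)]
        curve = fit_calibration(pts)
        table = backcalc_table(curve, {
            4.0: [0.025 * 4.3] * 5,
            40.0: [0.025 * 40.0] * 5,
        })
        row4 = table[table["Theoretical (ng)"] == 4.0].iloc[0]
        assert row4["Calculated (ng)"] == pytest.approx(4.3)
        assert row4["CV (%)"] == pytest.approx(0.0)
        assert row4["Accuracy (%)"] == pytest.approx(107.5)
        row40 = table[table["Theoretical (ng)"] == 40.0].iloc[0]
        assert row40["Accuracy (%)"] == pytest.approx(100.0)

    def test_backcalc_table_requires_replicates(self):
        curve = fit_calibration([(x, 0.025 * x) for x in (4, 40, 200)])
        with pytest.raises(ValueError):
            backcalc_table(curve, {4.0: [0.1]})


class TestAggregation:
    def test_protein_mean_of_two_peptides(self):
        amt = protein_amount({"SGT": 38.0, "NWV": 42.0}, ["SGT", "NWV"])
        assert amt.ng == pytest.approx(40.0) and amt.n_peptides == 2

    def test_single_peptide_warns(self):
        with pytest.warns(UserWarning):
            amt = protein_amount({"SGT": 38.0}, ["SGT", "NWV"])
        assert amt.ng == pytest.approx(38.0)

    def test_no_peptides_errors(self):
        with pytest.raises(ValueError):
            protein_amount({}, ["SGT"])

    def test_permutation_invariance(self):
        ng = {"a": 10.0, "b": 20.0, "c": 60.0}
        assert protein_amount(ng, ["a", "b", "c"]).ng == pytest.approx(
            protein_amount(ng, ["c", "a", "b"]).ng)

    def test_tissue_concentration(self):
        assert tissue_concentration(120.0, 25.0) == pytest.approx(4.8)
        assert tissue_concentration(120.0, 12.5) == pytest.approx(9.6)
        with pytest.raises(ValueError):
            tissue_concentration(120.0, 0.0)

    def test_partial_injection_arithmetic(self):
        # 2 uL of a 50 uL digest carrying a 40 ng spike = 1.6 ng on column
        assert injected_amount(40.0, 50.0, 2.0) == pytest.approx(1.6)


class TestGroupSummary:
    def test_mid_dose_fold_change(self):
        s = group_summary([37.9, 37.9], reference_mean=4.3)
        assert s.fold_change == 8.8

    def test_high_dose_vs_control_fold_change(self):
        s = group_summary([67.7, 67.7], reference_mean=2.1)
        assert s.fold_change == 32.2

    def test_identical_values_and_self_reference(self):
        s = group_summary([5.0, 5.0, 5.0], reference_mean=5.0)
        assert s.sd == 0.0 and s.fold_change == 1.0

    def test_explicit_exclusion(self):
        s = group_summary([10.0, 10.0, 1000.0], exclude=[2])
        assert s.mean == pytest.approx(10.0) and s.n == 2

    def test_too_few_after_exclusion(self):
        with pytest.raises(ValueError):
            group_summary([10.0, 11.0], exclude=[0])


class TestEndToEnd:
    def test_noise_free_parameter_recovery(self, panel, noiseless_config):
        """Simulate -> integrate -> ratio -> fit -> back-calculate recovers
        every ground-truth amount to better than 0.5%."""
        series = simulate_standard_series(
            panel, standard_ng=[4, 20, 40, 100, 200], replicates=2,
            config=noiseless_config,
        )
        for seq in frataxin.HUMAN_QUANTIFIERS:
            curve, table = quantify_standard_series(series, panel, seq)
            assert np.abs(table["Accuracy (%)"] - 100.0).max() < 0.5
            assert curve.r_squared > 0.999999

    def test_detector_gain_invariance(self, panel):
        """Scaling every intensity by a constant leaves ratios unchanged."""
        cfg = SimulationConfig(seed=6, baseline_level=0.0, baseline_noise_sd=0.0)
        light = {p.sequence: 40.0 for p in panel.peptides() if p.label == "light"}
        heavy = {p.sequence: 40.0 for p in panel.peptides() if p.label == "heavy"}
        chroms, _ = simulate_sample(panel, light, heavy, cfg)
        seq = "SGTLGHPGSLDETTYER"
        base = measure_ratio(chroms, panel, seq).ratio
        scaled = [
            Chromatogram(c.transition_id, c.times, c.intensities * 250.0)
            for c in chroms
        ]
        assert measure_ratio(scaled, panel, seq).ratio == pytest.approx(
            base, rel=1e-9
        )

    def test_macaque_peptide_reads_off_human_curve(self, panel, noiseless_config):
        """A homolog peptide normalized against the partner's heavy channel
        back-calculates correctly when response factors are shared."""
        import dataclasses
        cfg = dataclasses.replace(
            noiseless_config,
            response_groups=frataxin.INTERNAL_STANDARD_OF,
        )
        series = simulate_standard_series(
            panel, standard_ng=[4, 40, 200], replicates=2, config=cfg,
        )
        curve, _ = quantify_standard_series(series, panel, "SGTLGHPGSLDETTYER")
        # a sample with 10 ng macaque protein, 40 ng human SILAC standard
        light = {p.sequence: 0.0 for p in panel.peptides() if p.label == "light"}
        light["SGTLGHPGSLDDTTYER"] = 10.0
        light["NWVYSHDGVSLHELLGAELTK"] = 10.0
        heavy = {p.sequence: 40.0 for p in panel.peptides() if p.label == "heavy"}
        chroms, _ = simulate_sample(panel, light, heavy, cfg)
        m = measure_ratio(chroms, panel, "SGTLGHPGSLDDTTYER",
                          heavy_seq="SGTLGHPGSLDETTYER")
        assert back_calculate(curve, m.ratio).ng == pytest.approx(10.0, rel=0.005)
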