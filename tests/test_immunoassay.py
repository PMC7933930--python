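"""Sandwich-assay hook model, peak calibration, deconvolution, and 4PL fits."""

import numpy as np
import pytest

from a1atkit import immunoassay as ia
from a1atkit import synthetic as syn


class TestSandwichSignal:
    def test_empty_mix_gives_background(self, total_assay):
        assert ia.sandwich_signal(ia.SpeciesMix(), total_assay) == total_assay.background

    def test_linear_regime_at_trace_analyte(self, total_assay):
        """Far below antibody totals the net signal is linear in analyte."""
        c = 1e-12
        s1 = ia.sandwich_signal(ia.SpeciesMix(monomer=c), total_assay)
        s2 = ia.sandwich_signal(ia.SpeciesMix(monomer=2 * c), total_assay)
        net1, net2 = s1 - total_assay.background, s2 - total_assay.background
        assert net2 / net1 == pytest.approx(2.0, rel=0.01)

    def test_hook_regime_inverse_scaling(self, total_assay):
        """Far above antibody totals the net signal falls as 1/analyte."""
        cs = np.logspace(-5, -3, 10)
        net = np.array(
            [
                ia.sandwich_signal(ia.SpeciesMix(monomer=c), total_assay)
                - total_assay.background
                for c in cs
            ]
        )
        slope = np.polyfit(np.log(cs), np.log(net), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.01)

    def test_unimodality_in_analyte(self, total_assay):
        """Noiseless signal vs total analyte has exactly one interior maximum."""
        cs = np.logspace(-11, -4, 300)
        sig = np.array(
            [ia.sandwich_signal(ia.SpeciesMix(monomer=c), total_assay) for c in cs]
        )
        d = np.diff(sig)
        sign_changes = np.sum(np.diff(np.sign(d[d != 0])) != 0)
        assert sign_changes == 1
        assert 0 < np.argmax(sig) < len(cs) - 1

    def test_monomer_invisible_to_polymer_assay(self, polymer_assay, dense_dilutions):
        series, _ = syn.gen_dilution_series(
            ia.SpeciesMix(monomer=5e-6),
            polymer_assay,
            dense_dilutions,
            syn.GeneratorConfig(seed=0, noise_cv=0.0),
        )
        np.testing.assert_allclose(series.fret_ratios, polymer_assay.background)


class TestHookPeak:
    def test_symmetric_bell_exact_center(self):
        d = np.logspace(0, 4, 41)
        x = np.log10(d)
        y = np.exp(-((x - 2.0) ** 2))
        pk = ia.find_hook_peak(ia.DilutionSeries(d, y))
        assert pk.peak_dilution == pytest.approx(100.0, rel=1e-9)
        assert pk.interior

    def test_generator_peak_matches_dense_oracle(
        self, polymer_assay, coarse_dilutions, dense_dilutions
    ):
        """Interpolated coarse-grid peak within 2% of the dense-grid position."""
        mix = ia.SpeciesMix(polymer=1.7e-6)
        cfg = syn.GeneratorConfig(seed=0, noise_cv=0.0)
        coarse, _ = syn.gen_dilution_series(mix, polymer_assay, coarse_dilutions, cfg)
        dense, _ = syn.gen_dilution_series(mix, polymer_assay, dense_dilutions, cfg)
        pk_c = ia.find_hook_peak(coarse)
        pk_d = ia.find_hook_peak(dense)
        assert pk_c.peak_dilution == pytest.approx(pk_d.peak_dilution, rel=0.02)

    def test_monotone_series_raises(self):
        d = np.logspace(0, 2, 10)
        with pytest.raises(ia.NoInteriorPeakError):
            ia.find_hook_peak(ia.DilutionSeries(d, np.linspace(0, 1, 10)))

    def test_bell_extremes_below_one_percent_of_peak(
        self, polymer_assay, dense_dilutions
    ):
        """Polymer-only bell: signal at extreme dilutions under 1% of peak."""
        mix = ia.SpeciesMix(polymer=2e-6)
        wide = np.logspace(0, 6, 200)
        net = ia.dilution_curve(mix, polymer_assay, wide) - polymer_assay.background
        assert net[0] < 0.01 * net.max()
        assert net[-1] < 0.01 * net.max()

    def test_doubling_mix_doubles_peak_dilution(self, total_assay, dense_dilutions):
        """Dilution invariance: scaling the sample scales the peak position."""
        mix = ia.SpeciesMix(monomer=1e-6, polymer=0.5e-6)
        y1 = ia.dilution_curve(mix, total_assay, dense_dilutions)
        y2 = ia.dilution_curve(mix.scaled(2.0), total_assay, dense_dilutions)
        p1 = ia.find_hook_peak(ia.DilutionSeries(dense_dilutions, y1))
        p2 = ia.find_hook_peak(ia.DilutionSeries(dense_dilutions, y2))
        assert p2.peak_dilution / p1.peak_dilution == pytest.approx(2.0, rel=0.01)

    @pytest.mark.parametrize("factor", [0.25, 0.5, 2.0, 4.0])
    def test_dilution_invariance_over_factor_range(
        self, total_assay, dense_dilutions, factor
    ):
        mix = ia.SpeciesMix(monomer=2e-6)
        base = ia.find_hook_peak(
            ia.DilutionSeries(dense_dilutions, ia.dilution_curve(mix, total_assay, dense_dilutions))
        )
        scaled = ia.find_hook_peak(
            ia.DilutionSeries(
                dense_dilutions, ia.dilution_curve(mix.scaled(factor), total_assay, dense_dilutions)
            )
        )
        assert scaled.peak_dilution / base.peak_dilution == pytest.approx(factor, rel=0.01)


class TestCalibration:
    def test_slope_minus_one(self, polymer_assay, dense_dilutions):
        """Standards at 0.5-4 uM give a log-log peak-fraction slope of -1.0 +/- 0.05."""
        stds = syn.gen_calibration_standards(
            polymer_assay,
            [0.5e-6, 1e-6, 2e-6, 4e-6],
            "polymer",
            dense_dilutions,
            syn.GeneratorConfig(seed=3, noise_cv=0.0),
        )
        cal = ia.calibrate_peaks(stds, background=polymer_assay.background)
        assert cal.slope == pytest.approx(-1.0, abs=0.05)

    def test_single_standard_insufficient(self, polymer_assay, dense_dilutions):
        stds = syn.gen_calibration_standards(
            polymer_assay, [1e-6], "polymer", dense_dilutions, syn.GeneratorConfig(seed=3)
        )
        with pytest.raises(ValueError):
            ia.calibrate_peaks(stds, background=polymer_assay.background)

    def test_predicted_peak_doubles_with_concentration(
        self, polymer_assay, dense_dilutions
    ):
        stds = syn.gen_calibration_standards(
            polymer_assay,
            [0.5e-6, 1e-6, 2e-6, 4e-6],
            "polymer",
            dense_dilutions,
            syn.GeneratorConfig(seed=3, noise_cv=0.0),
        )
        cal = ia.calibrate_peaks(stds, background=polymer_assay.background)
        assert cal.predict_peak_dilution(2e-6) / cal.predict_peak_dilution(1e-6) == pytest.approx(
            2.0, rel=0.01
        )


class TestQuantifyAndDeconvolve:
    def test_standard_self_recovery(self, polymer_assay, dense_dilutions, dense_cals):
        cal, _, _ = dense_cals
        series, _ = syn.gen_dilution_series(
            ia.SpeciesMix(polymer=2e-6),
            polymer_assay,
            dense_dilutions,
            syn.GeneratorConfig(seed=1, noise_cv=0.0),
        )
        conc, extrapolated = ia.quantify_polymer(series, cal)
        assert conc == pytest.approx(2e-6, rel=1e-3)
        assert not extrapolated

    def test_polymer_recovery_noisy(self, polymer_assay, coarse_dilutions, dense_dilutions, dense_cals):
        """1.7 uM polymer recovered within 10% at 3% noise (20 seeds)."""
        cal, _, _ = dense_cals
        errs = []
        for seed in range(20):
            series, _ = syn.gen_dilution_series(
                ia.SpeciesMix(polymer=1.7e-6),
                polymer_assay,
                coarse_dilutions,
                syn.GeneratorConfig(seed=700 + seed, noise_cv=0.03),
            )
            conc, _ = ia.quantify_polymer(series, cal, peak_window=3)
            errs.append(abs(conc - 1.7e-6) / 1.7e-6)
        assert np.median(errs) < 0.10

    def test_monomer_only_sample_in_polymer_assay_errors(
        self, polymer_assay, dense_dilutions
    , dense_cals):
        series, _ = syn.gen_dilution_series(
            ia.SpeciesMix(monomer=5e-6),
            polymer_assay,
            dense_dilutions,
            syn.GeneratorConfig(seed=1, noise_cv=0.0),
        )
        cal, _, _ = dense_cals
        with pytest.raises(ia.NoInteriorPeakError):
            ia.quantify_polymer(series, cal)

    def test_zero_noise_deconvolution_exact_over_grid(
        self, polymer_assay, total_assay, dense_dilutions
    , dense_cals):
        """End-to-end monomer recovery exact to 1e-3 over the 3x3 mix grid."""
        cal_pol, cal_tm, cal_tp = dense_cals
        cfg = syn.GeneratorConfig(seed=0, noise_cv=0.0)
        for monomer in (1e-6, 3e-6, 10e-6):
            for polymer in (0.3e-6, 1e-6, 3e-6):
                mix = ia.SpeciesMix(monomer=monomer, polymer=polymer)
                ps, _ = syn.gen_dilution_series(mix, polymer_assay, dense_dilutions, cfg)
                p_est, _ = ia.quantify_polymer(ps, cal_pol)
                ts, _ = syn.gen_dilution_series(mix, total_assay, dense_dilutions, cfg)
                m_est, clipped = ia.deconvolve_monomer(ts, p_est, cal_tp, cal_tm)
                assert not clipped
                assert m_est == pytest.approx(monomer, rel=1e-3)

    def test_noisy_deconvolution_grid_median_error(
        self, polymer_assay, total_assay, coarse_dilutions, dense_dilutions
    , dense_cals):
        """3% noise, 20 seeds: median monomer error within 15% over the mix grid."""
        cal_pol, cal_tm, cal_tp = dense_cals
        errs = []
        for seed in range(20):
            for monomer in (1e-6, 3e-6, 10e-6):
                for polymer in (0.3e-6, 1e-6, 3e-6):
                    mix = ia.SpeciesMix(monomer=monomer, polymer=polymer)
                    cfg = syn.GeneratorConfig(seed=5000 + seed, noise_cv=0.03)
                    ps, _ = syn.gen_dilution_series(
                        mix, polymer_assay, coarse_dilutions, cfg
                    )
                    cfg2 = syn.GeneratorConfig(seed=6000 + seed, noise_cv=0.03)
                    ts, _ = syn.gen_dilution_series(
                        mix, total_assay, coarse_dilutions, cfg2
                    )
                    try:
                        p_est, _ = ia.quantify_polymer(ps, cal_pol, peak_window=3)
                        m_est, _ = ia.deconvolve_monomer(
                            ts, p_est, cal_tp, cal_tm, peak_window=3
                        )
                    except (ia.NoInteriorPeakError, ValueError):
                        errs.append(1.0)
                        continue
                    errs.append(abs(m_est - monomer) / monomer)
        assert np.median(errs) < 0.15

    def test_sevenfold_treatment_effect_recovered(
        self, polymer_assay, total_assay, coarse_dilutions, dense_dilutions
    , dense_cals):
        """Pre/post pair with a 7x monomer rise at fixed polymer: fold within 20%."""
        cal_pol, cal_tm, cal_tp = dense_cals
        pre = ia.SpeciesMix(monomer=1e-6, polymer=2e-6)
        post = ia.SpeciesMix(monomer=7e-6, polymer=2e-6)
        folds = []
        for seed in range(10):
            est = {}
            for off, (name, mix) in enumerate((("pre", pre), ("post", post))):
                cfg = syn.GeneratorConfig(seed=8000 + 2 * seed + off, noise_cv=0.03)
                ps, _ = syn.gen_dilution_series(mix, polymer_assay, coarse_dilutions, cfg)
                cfg2 = syn.GeneratorConfig(seed=9000 + 2 * seed + off, noise_cv=0.03)
                ts, _ = syn.gen_dilution_series(mix, total_assay, coarse_dilutions, cfg2)
                p_est, _ = ia.quantify_polymer(ps, cal_pol, peak_window=3)
                m_est, _ = ia.deconvolve_monomer(
                    ts, p_est, cal_tp, cal_tm, peak_window=3
                )
                est[name] = m_est
            folds.append(est["post"] / est["pre"])
        assert np.mean(folds) == pytest.approx(7.0, rel=0.20)

    def test_zero_polymer_reduces_to_direct_inversion(
        self, total_assay, dense_dilutions
    , dense_cals):
        _, cal_tm, cal_tp = dense_cals
        mix = ia.SpeciesMix(monomer=4e-6)
        ts, _ = syn.gen_dilution_series(
            mix, total_assay, dense_dilutions, syn.GeneratorConfig(seed=2, noise_cv=0.0)
        )
        m_est, _ = ia.deconvolve_monomer(ts, 0.0, cal_tp, cal_tm)
        direct = cal_tm.concentration_from_peak(ia.find_hook_peak(ts).peak_dilution)
        assert m_est == pytest.approx(direct, rel=1e-12)

    def test_signal_subtraction_bias_is_negative_and_bounded(
        self, polymer_assay, total_assay, dense_dilutions
    , dense_cals):
        """The classical signal-subtraction recipe underestimates monomer.

        Antibody depletion couples the species, so single-species signal
        curves are sub-additive at the mixture peak; the resulting negative
        bias is documented here rather than hidden.
        """
        cal_pol, cal_tm, cal_tp = dense_cals
        mix = ia.SpeciesMix(monomer=10e-6, polymer=0.3e-6)
        cfg = syn.GeneratorConfig(seed=0, noise_cv=0.0)
        ps, _ = syn.gen_dilution_series(mix, polymer_assay, dense_dilutions, cfg)
        p_est, _ = ia.quantify_polymer(ps, cal_pol)
        ts, _ = syn.gen_dilution_series(mix, total_assay, dense_dilutions, cfg)
        m_sub, _ = ia.deconvolve_monomer(
            ts, p_est, cal_tp, cal_tm, method="signal_subtraction"
        )
        assert m_sub < 10e-6  # systematically low
        assert m_sub > 0


class TestFourPL:
    def test_midpoint_identity(self):
        y = ia.four_pl(np.array([10**-8.3]), 8.3, 1.0, 100.0, 0.0)
        assert y[0] == pytest.approx(50.0)

    def test_noiseless_roundtrip(self, noiseless_cfg):
        curve, truth = syn.gen_dose_response(
            {"pXC50": 8.3, "hill": 1.0, "top": 100.0, "bottom": 0.0}, cfg=noiseless_cfg
        )
        fit = ia.fit_4pl(curve)
        assert fit.pXC50 == pytest.approx(8.3, abs=1e-6)
        assert fit.hill == pytest.approx(1.0, rel=1e-6)
        assert fit.within_dosed_range

    def test_flat_curve_flagged(self):
        doses = np.logspace(-9, -5, 8)
        curve = ia.DoseResponseCurve(doses, np.full(8, 50.0))
        with pytest.raises(ia.FlatCurveError):
            ia.fit_4pl(curve)

    def test_monte_carlo_recovery(self):
        """100 seeds at 3% noise: mean pXC50 within 0.05 of the 6.3 truth."""
        vals = []
        for seed in range(100):
            cfg = syn.GeneratorConfig(seed=40000 + seed, noise_cv=0.03)
            curve, _ = syn.gen_dose_response(
                {"pXC50": 6.3, "hill": 1.0, "top": 100.0, "bottom": 0.0},
                doses=10e-6 / 3.0 ** np.arange(11),
                cfg=cfg,
            )
            vals.append(ia.fit_4pl(curve).pXC50)
        assert np.mean(vals) == pytest.approx(6.3, abs=0.05)

    def test_fold_change_of_ascending_curve(self, noiseless_cfg):
        """Secretion-style curve: plateau ratio reports the maximal fold effect."""
        curve, _ = syn.gen_dose_response(
            {"pXC50": 6.5, "hill": -1.0, "top": 3.0, "bottom": 1.0}, cfg=noiseless_cfg
        )
        fit = ia.fit_4pl(curve)
        assert fit.fold_change == pytest.approx(3.0, rel=1e-4)
        assert fit.plateau_high_dose > fit.plateau_low_dose

    def test_fixed_plateau_fit(self, noiseless_cfg):
        curve, _ = syn.gen_dose_response(
            {"pXC50": 4.7, "hill": 1.0, "top": 100.0, "bottom": 0.0}, cfg=noiseless_cfg
        )
        fit = ia.fit_4pl(curve, fix_top=100.0, fix_bottom=0.0)
        assert fit.pXC50 == pytest.approx(4.7, abs=1e-6)
        assert fit.top == 100.0 and fit.bottom == 0.0


class TestNormalize:
    def test_anchors_and_linearity(self):
        assert ia.normalize_response(2.0, 2.0, 12.0) == 0.0
        assert ia.normalize_response(12.0, 2.0, 12.0) == 100.0
        assert ia.normalize_response(7.0, 2.0, 12.0) == pytest.approx(50.0)

    def test_division_guard(self):
        with pytest.raises(ZeroDivisionError):
            ia.normalize_response(5.0, 3.0, 3.0)
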