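"""Offset assembly: decay, dispersion, parent fraction, BPR."""

import numpy as np
import pytest

from aifcount import (BloodSample, Examination, OffsetVector,
                      PFSigmoidParams, decay_factor,
                      volume_calibration_factor, dispersion_correct,
                      dispersion_offset_component, fit_bpr,
                      fit_parent_fraction, assemble_offsets,
                      build_dispersion_table, TriExpParams,
                      apply_forward_dispersion)
from aifcount.offsets import log_tau


class TestOffsetVector:
    def test_tau_is_product_of_components(self):
        o = OffsetVector(duration_s=60.0, volume_mL=2.0,
                         vol_calibration=1.1, decay=0.5,
                         dispersion_component=1.02, bpr=0.9,
                         inv_parent_fraction=4.0)
        expected = 60 * 2 * 1.1 * 0.5 * 1.02 * 0.9 * 4.0
        assert o.tau == pytest.approx(expected)
        assert o.log_tau_total == pytest.approx(np.log(expected))

    def test_nonpositive_component_rejected(self):
        with pytest.raises(ValueError):
            OffsetVector(duration_s=60.0, volume_mL=2.0,
                         vol_calibration=1.0, decay=0.0,
                         dispersion_component=1.0, bpr=1.0,
                         inv_parent_fraction=1.0)


class TestElementaryFactors:
    def test_decay_halves_at_half_life(self):
        assert decay_factor(20.36, 20.36) == pytest.approx(0.5)
        assert decay_factor(0.0, 20.36) == pytest.approx(1.0)

    def test_volume_calibration(self):
        assert volume_calibration_factor(2.0, 0.05) == pytest.approx(
            np.exp(0.1))
        assert volume_calibration_factor(2.0, 0.0) == 1.0


class TestDispersionCorrect:
    def test_round_trip_on_exact_convolution(self):
        t = np.arange(0, 600, 1.0)
        truth = TriExpParams(A=(4000.0, 800, 150),
                             gamma=(3.0, 0.3, 0.03))(t / 60.0)
        measured = apply_forward_dispersion(t, truth, 2.5)
        recovered = dispersion_correct(t, measured, 2.5)
        interior = slice(2, -2)
        rms = np.sqrt(np.mean((recovered - truth)[interior] ** 2))
        assert rms < 0.01 * truth.max()

    def test_kappa_zero_is_identity(self):
        t = np.arange(0, 10, 1.0)
        v = np.exp(-t / 3)
        np.testing.assert_allclose(dispersion_correct(t, v, 0.0), v)

    def test_nonuniform_grid_rejected(self):
        with pytest.raises(ValueError):
            dispersion_correct(np.array([0.0, 1.0, 3.0]),
                               np.ones(3), 2.5)

    def test_forward_kernel_conserves_mass(self):
        t = np.arange(0, 400, 1.0)
        v = np.zeros(400)
        v[10] = 7.0
        out = apply_forward_dispersion(t, v, 2.5)
        assert out.sum() == pytest.approx(7.0, rel=1e-6)
        assert np.all(out[:10] == 0.0)  # causal

    def test_forward_matches_explicit_discrete_convolution(self):
        rng = np.random.default_rng(4)
        t = np.arange(0, 50, 1.0)
        v = rng.uniform(0, 5, t.size)
        kappa = 3.0
        w = np.exp(-np.arange(200) / kappa)
        w /= w.sum()
        oracle = np.array([sum(v[i - j] * w[j]
                               for j in range(min(i + 1, 200)))
                           for i in range(t.size)])
        np.testing.assert_allclose(apply_forward_dispersion(t, v, kappa),
                                   oracle, rtol=1e-10)


class TestDispersionComponent:
    def test_manual_after_cutoff_bypasses_tubing(self):
        assert dispersion_offset_component(90.0, 100.0, "manual", 20.0) == 1.0

    def test_abss_and_early_manual_get_ratio(self):
        assert dispersion_offset_component(
            90.0, 100.0, "abss", 2.0) == pytest.approx(100 / 90)
        assert dispersion_offset_component(
            90.0, 100.0, "manual", 2.0) == pytest.approx(100 / 90)

    def test_table_tracks_true_factor_on_descent(self, poisson_exam):
        from aifcount.blood_data import subtract_background
        exam, truth = poisson_exam
        cfg = truth.config
        table = build_dispersion_table(subtract_background(exam))
        est = (table["uncorrected"] / table["corrected"]).to_numpy()
        t_min = table["time_s"].to_numpy() / 60.0
        grid = np.arange(0, 601) / 60.0
        wb = cfg.curve(grid) / cfg.pf(grid) * cfg.bpr_fn(grid) \
            * decay_factor(grid, cfg.half_life_min)
        disp = apply_forward_dispersion(grid * 60, wb, cfg.kappa_s)
        ratio = np.where(wb > 0, disp / np.maximum(wb, 1e-12), 1.0)
        true_at = np.interp(t_min, grid, ratio)
        mask = t_min >= 1.0  # descent region (minutes)
        rms = np.sqrt(np.mean((est[mask] - true_at[mask]) ** 2))
        assert rms < 0.05


class TestParentFraction:
    def test_sigmoid_shape(self):
        pf = PFSigmoidParams(a=0.05, t50_min=10.0, k=2.0)
        assert pf(1e-9) == pytest.approx(1.0, abs=1e-6)
        assert pf(10.0) == pytest.approx(0.05 + 0.95 / 2)
        t = np.linspace(0.1, 100, 200)
        assert np.all(np.diff(pf(t)) < 0)

    def test_fit_recovers_noiseless_sigmoid(self):
        pf = PFSigmoidParams(a=0.07, t50_min=12.0, k=2.5)
        times = [1.0, 3, 5, 10.5, 20, 40, 60, 90]
        meas = [(t, float(pf(t))) for t in times]
        hat = fit_parent_fraction(meas)
        grid = np.linspace(1, 90, 100)
        np.testing.assert_allclose(hat(grid), pf(grid), atol=5e-3)

    def test_too_few_measurements_rejected(self):
        with pytest.raises(ValueError):
            fit_parent_fraction([(1.0, 0.9), (60.0, 0.1)])


class TestBpr:
    def test_paired_samples_recover_ratio(self, poisson_exam):
        exam, truth = poisson_exam
        model = fit_bpr(exam)
        t = np.array([3.0, 9.0, 30.0, 70.0])
        np.testing.assert_allclose(model(t), truth.bpr_fn(t), rtol=0.05)

    def test_constant_fallback_with_few_pairs(self):
        samples = []
        for tm in (10.0, 60.0):
            samples.append(BloodSample(tm, 50_000, 60.0, 2.0, "manual",
                                       "whole_blood"))
            samples.append(BloodSample(tm, 40_000, 60.0, 2.0, "manual",
                                       "plasma"))
        exam = Examination(exam_id="e", samples=samples)
        with pytest.warns(UserWarning):
            model = fit_bpr(exam)
        assert model.constant
        assert model(30.0) > 0


class TestAssembleOffsets:
    def test_alignment_and_conventions(self, prepared):
        work, offsets, aux = prepared
        assert len(offsets) == len(work.post_samples)
        for s, o in zip(work.post_samples, offsets):
            assert o.duration_s == s.duration_s
            assert o.volume_mL == s.volume_mL
            if s.compartment == "plasma":
                assert o.bpr == 1.0
            if s.detector == "manual" and s.time_min > work.abss_cutoff_min:
                assert o.dispersion_component == 1.0
            assert o.inv_parent_fraction >= 1.0
        lt = log_tau(offsets)
        assert np.all(np.isfinite(lt))

    def test_offsets_match_generator_exposures(self, prepared, poisson_exam):
        # model-implied mean at the true curve should track observed counts
        work, offsets, aux = prepared
        _, truth = poisson_exam
        cfg = truth.config
        t = np.array([s.time_min for s in work.post_samples])
        y = np.array([float(s.counts) for s in work.post_samples])
        abss = np.array([s.detector == "abss" for s in work.post_samples])
        mu = cfg.curve(t) * np.exp(log_tau(offsets)) \
            * np.where(abss, truth.abss_bias, 1.0)
        # Poisson noise limits pointwise agreement; compare total exposure
        assert mu[abss].sum() / y[abss].sum() == pytest.approx(1.0, rel=0.05)
        assert mu[~abss].sum() / y[~abss].sum() == pytest.approx(1.0,
                                                                 rel=0.05)
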