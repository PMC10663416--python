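"""Model classes: parametric, smooth, hierarchical, AIC comparison."""

import numpy as np
import pytest

from aifcount import (ParametricAIFModel, SmoothAIFModel,
                      HierarchicalAIFModel, SimConfig, simulate_examination,
                      prepare_examination, compare_models_aic,
                      fit_parametric_aif, fit_gam_aif, predict_aif,
                      TriExpParams)


@pytest.fixture(scope="module")
def parametric_fit(prepared):
    work, offsets, _ = prepared
    return ParametricAIFModel(work, offsets).fit()


@pytest.fixture(scope="module")
def gam_fit(prepared):
    work, offsets, _ = prepared
    return SmoothAIFModel(work, offsets, family="poisson",
                          shape_constrained=False, log_time=True,
                          k=15).fit()


class TestParametric:
    def test_slow_components_recovered(self, parametric_fit, poisson_exam):
        _, truth = poisson_exam
        p = parametric_fit.params
        A, g = truth.config.truth.A, truth.config.truth.gamma
        # slow and intermediate components are well identified from the
        # manual samples; the fast component is noisier (ABSS counts)
        assert p.A[1] == pytest.approx(A[1], rel=0.15)
        assert p.A[2] == pytest.approx(A[2], rel=0.15)
        assert p.gamma[1] == pytest.approx(g[1], rel=0.15)
        assert p.gamma[2] == pytest.approx(g[2], rel=0.15)

    def test_abss_bias_coefficient(self, parametric_fit, poisson_exam):
        _, truth = poisson_exam
        assert np.exp(parametric_fit.abss_bias_coef()) == pytest.approx(
            truth.abss_bias, abs=0.06)

    def test_predict_frame(self, parametric_fit):
        t = np.array([2.0, 10.0, 60.0])
        df = parametric_fit.predict(t)
        assert list(df.columns) == ["time_min", "estimate", "lower95",
                                    "upper95"]
        assert np.all(df["lower95"] < df["estimate"])
        assert np.all(df["estimate"] < df["upper95"])
        assert np.all(df["estimate"] > 0)

    def test_wrapper(self, prepared):
        work, offsets, _ = prepared
        res = fit_parametric_aif(work, offsets)
        assert res.kind == "parametric"


class TestSmooth:
    def test_tracks_truth(self, gam_fit, poisson_exam):
        _, truth = poisson_exam
        t = np.linspace(*gam_fit.t_range, 200)
        pred = gam_fit.predict(t)["estimate"].to_numpy()
        ape = 100 * np.abs(pred - truth.descent(t)) / truth.descent(t)
        assert np.median(ape) < 10.0

    def test_interval_width_reasonable(self, gam_fit):
        # bands are conditional on the estimated offsets, so they reflect
        # counting noise only; check ordering and a sane relative width
        t = np.linspace(*gam_fit.t_range, 100)
        df = gam_fit.predict(t)
        assert np.all(df["lower95"] < df["estimate"])
        assert np.all(df["estimate"] < df["upper95"])
        rel = (df["upper95"] - df["lower95"]) / df["estimate"]
        assert 1e-4 < rel.median() < 0.5

    def test_scop_monotone_and_positive(self, prepared):
        work, offsets, _ = prepared
        res = SmoothAIFModel(work, offsets, family="poisson",
                             shape_constrained=True, log_time=False,
                             k=12).fit()
        t = np.linspace(*res.t_range, 500)
        pred = res.predict(t)["estimate"].to_numpy()
        assert np.all(np.diff(pred) <= 1e-10)
        assert np.all(pred > 0)

    def test_scop_converges_on_strongly_curved_transform(self):
        # regression test: Fisher scoring without the transform-curvature
        # Hessian term crawled (>200 iterations, |grad| stuck ~5.7) on
        # this configuration and the fit aborted with a FitError
        cfg = SimConfig(truth=TriExpParams(A=(6777.8, 437.7, 177.2),
                                           gamma=(2.52, 0.217, 0.024)),
                        seed=16154)
        exam, _ = simulate_examination(cfg, seed=16154)
        work, offsets, _ = prepare_examination(exam)
        res = SmoothAIFModel(work, offsets, family="poisson",
                             shape_constrained=True, log_time=False,
                             k=12).fit()
        t = np.linspace(*res.t_range, 500)
        assert np.all(np.diff(res.predict(t)["estimate"]) <= 1e-10)

    def test_fixed_smoothing_path(self, prepared):
        work, offsets, _ = prepared
        res = SmoothAIFModel(work, offsets, family="poisson",
                             shape_constrained=False, log_time=True,
                             k=12).fit(sp=10.0)
        assert res.fit.converged

    def test_negbin_on_poisson_data_collapses_to_poisson(self, prepared,
                                                         gam_fit):
        work, offsets, _ = prepared
        res = SmoothAIFModel(work, offsets, family="negbin",
                             shape_constrained=False, log_time=True,
                             k=15).fit()
        assert res.fit.psi < 1e-4
        # AIC pays exactly the one-parameter price for profiling psi
        assert res.fit.aic == pytest.approx(gam_fit.fit.aic + 2.0, abs=0.5)

    def test_wrapper_and_predict_aif(self, prepared):
        work, offsets, _ = prepared
        res = fit_gam_aif(work, offsets, family="poisson")
        est, lo, hi = predict_aif(res, np.array([5.0, 20.0]))
        assert est.shape == lo.shape == hi.shape == (2,)
        assert np.all((lo < est) & (est < hi))


class TestHierarchical:
    @pytest.fixture(scope="class")
    def hgam(self):
        exams, offs, truths = [], [], []
        for i in range(4):
            cfg = SimConfig(seed=60 + i)
            exam, truth = simulate_examination(cfg, seed=60 + i,
                                               exam_id=f"h{i}")
            work, o, _ = prepare_examination(exam)
            exams.append(work)
            offs.append(o)
            truths.append(truth)
        fit = HierarchicalAIFModel(exams, offs, k_global=15,
                                   k_exam=4).fit()
        return fit, truths

    def test_per_exam_predictions_track_truth(self, hgam):
        fit, truths = hgam
        t = np.array([2.0, 5.0, 20.0, 60.0])
        for i, ex in enumerate(fit.exam_ids):
            pred = fit.predict(t, exam_id=ex)["estimate"].to_numpy()
            tru = truths[i].descent(t)
            assert np.median(100 * np.abs(pred - tru) / tru) < 12.0

    def test_per_exam_abss_bias(self, hgam):
        fit, truths = hgam
        for ex in fit.exam_ids:
            assert np.exp(fit.abss_bias_coef(ex)) == pytest.approx(
                1.10, abs=0.08)

    def test_deviation_edf_partition(self, hgam):
        fit, _ = hgam
        assert set(fit.deviation_edf) == set(fit.exam_ids)
        assert all(v >= -0.05 for v in fit.deviation_edf.values())

    def test_unknown_exam_rejected(self, hgam):
        fit, _ = hgam
        with pytest.raises(ValueError):
            fit.predict(np.array([5.0]), exam_id="nope")


class TestCompareModels:
    def test_delta_sign_convention(self, prepared):
        work, offsets, _ = prepared
        fits = {
            "a": {"e": SmoothAIFModel(work, offsets, family="poisson",
                                      shape_constrained=False,
                                      log_time=True, k=8).fit()},
            "b": {"e": SmoothAIFModel(work, offsets, family="poisson",
                                      shape_constrained=False,
                                      log_time=True, k=15).fit()},
        }
        table = compare_models_aic(fits, reference="b")
        row = table.iloc[0]
        assert row["delta_b"] == 0.0
        assert row["delta_a"] == pytest.approx(
            row["aic_b"] - row["aic_a"])


class TestPrepare:
    def test_prepare_examination_outputs(self, poisson_exam):
        exam, _ = poisson_exam
        work, offsets, aux = prepare_examination(exam)
        assert len(offsets) == len(work.post_samples)
        assert {"bpr_model", "pf_params", "dispersion_table"} <= set(aux)
        # background removed and ascent dropped
        assert all(not s.pre_injection for s in work.samples)
        assert min(s.time_min for s in work.post_samples) > 0.5
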