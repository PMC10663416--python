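"""AIF model classes: parametric, penalized-spline and hierarchical fits.

Three model classes, statsmodels-style (construct from data, ``fit()``
returns a results object):

* :class:`ParametricAIFModel` — tri-exponential descent by nonlinear
  Poisson regression, initialized by curve stripping.
* :class:`SmoothAIFModel` — a penalized-spline smooth of (log-)time with
  intercept and an ABSS-bias fixed effect, Poisson or negative-binomial,
  optionally shape-constrained (monotone non-increasing); smoothing by
  Laplace-approximate REML, negative-binomial dispersion profiled.
* :class:`HierarchicalAIFModel` — a joint negative-binomial fit across
  examinations: per-exam intercepts and ABSS effects, one global smooth
  of log time, and per-exam deviation smooths penalized to zero (shared
  smoothing parameter, full-rank penalty).

All results expose ``predict(t)`` returning the decay-corrected
parent-plasma rate with pointwise 95% intervals; the ``manual`` reference
excludes the ABSS bias term (manual samples are treated as the gold
standard), the ``abss`` reference multiplies by ``exp(beta_abss)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .blood_data import Examination, subtract_background, select_descent
from .bases import BasisBlock, tps_design, scop_decreasing_design
from .offsets import (assemble_offsets, build_dispersion_table, fit_bpr,
                      fit_parent_fraction, log_tau)
from . import engine
from .engine import (Family, PenalizedFit, linear_block, pirls_solve,
                     reml_optimize, nls_poisson_fit, curve_strip_init,
                     triexp_logf, TriExpParams, FitError)

_Z95 = stats.norm.ppf(0.975)


def center_block(block: BasisBlock, drop_constant_col: Optional[int] = None
                 ) -> BasisBlock:
    """Centre a smooth for use next to an explicit intercept.

    Optionally drops one column (the constant null-space direction of a
    thin-plate basis), then removes column means; the same drop/shift is
    applied when evaluating at new covariate values.
    """
    design = block.design
    keep = np.arange(design.shape[1])
    if drop_constant_col is not None:
        keep = np.delete(keep, drop_constant_col)
    D = design[:, keep]
    means = D.mean(axis=0)
    S = block.penalty[np.ix_(keep, keep)]
    base_ev = block._evaluator

    def ev(xnew):
        return base_ev(xnew)[:, keep] - means

    rank = np.linalg.matrix_rank(S) if np.any(S) else 0
    return BasisBlock(design=D - means, penalty=S,
                      nullspace_dim=len(keep) - rank, kind=block.kind,
                      transform=block.transform, _evaluator=ev,
                      meta=dict(block.meta))


def _exam_arrays(exam: Examination, offsets):
    samples = exam.post_samples
    if len(samples) != len(offsets):
        raise ValueError("offsets are not aligned with the examination's "
                         "post-injection samples")
    y = np.array([s.counts for s in samples], float)
    t = np.array([s.time_min for s in samples], float)
    abss = np.array([1.0 if s.detector == "abss" else 0.0 for s in samples])
    return y, t, abss, log_tau(offsets)


# ---------------------------------------------------------------------------
# results object
# ---------------------------------------------------------------------------

@dataclass
class AIFModelFit:
    """A fitted AIF with prediction, uncertainty and ABSS-bias removal."""

    kind: str
    fit: PenalizedFit
    log_time: bool
    t_range: tuple
    exam_ids: tuple
    has_abss: dict
    y: np.ndarray = field(repr=False, default=None)
    t: np.ndarray = field(repr=False, default=None)
    log_offset: np.ndarray = field(repr=False, default=None)
    model: object = field(repr=False, default=None)

    # -- filled in by the model classes ---------------------------------
    _predict_rows: callable = field(repr=False, default=None)
    _abss_coef_index: dict = field(repr=False, default_factory=dict)

    @property
    def aic(self) -> float:
        return self.fit.aic

    @property
    def psi(self) -> float:
        return self.fit.psi

    @property
    def edf(self) -> float:
        return self.fit.edf

    def abss_bias_coef(self, exam_id=None) -> float:
        """Estimated log-scale ABSS bias (per exam for the hierarchy)."""
        key = exam_id if exam_id is not None else self.exam_ids[0]
        idx = self._abss_coef_index.get(key)
        if idx is None:
            raise ValueError(f"no ABSS data for exam {key!r}")
        return float(self.fit.working[idx])

    def predict(self, t_grid, reference: str = "manual",
                exam_id=None) -> pd.DataFrame:
        """Decay-corrected parent-plasma rate with pointwise 95% bands.

        ``reference='manual'`` excludes the ABSS bias term; ``'abss'``
        multiplies by ``exp(beta_abss)``.  Intervals come from the
        Bayesian coefficient covariance through the linear predictor
        (delta method on the log scale, then exponentiated).
        """
        t_grid = np.atleast_1d(np.asarray(t_grid, float))
        if reference not in ("manual", "abss"):
            raise ValueError("reference must be 'manual' or 'abss'")
        key = exam_id if exam_id is not None else self.exam_ids[0]
        if reference == "abss" and not self.has_abss.get(key, False):
            raise ValueError(f"exam {key!r} has no ABSS data: cannot "
                             f"predict on the ABSS reference")
        eta, L = self._predict_rows(t_grid, key, reference)
        var = np.einsum("ij,jk,ik->i", L, self.fit.cov_working, L)
        se = np.sqrt(np.maximum(var, 0.0))
        return pd.DataFrame({
            "time_min": t_grid,
            "estimate": np.exp(eta),
            "lower95": np.exp(eta - _Z95 * se),
            "upper95": np.exp(eta + _Z95 * se),
        })

    def fitted_counts(self) -> np.ndarray:
        """Expected counts mu_i at the observed samples."""
        return self.fit.mu

    def summary(self) -> str:
        f = self.fit
        lines = [
            f"AIF model: {self.kind}",
            f"  family: {f.family.name}"
            + (f" (psi = {f.psi:.4g})" if f.family.name == "negbin" else ""),
            f"  n obs: {f.y.size}   edf: {f.edf:.2f}   "
            f"loglik: {f.log_likelihood:.2f}   AIC: {f.aic:.2f}",
            f"  smoothing parameters: "
            f"{np.array2string(f.sp, precision=3)}",
        ]
        for ex in self.exam_ids:
            if self.has_abss.get(ex, False):
                b = self.abss_bias_coef(ex)
                lines.append(f"  ABSS bias [{ex}]: exp({b:.4f}) = "
                             f"{np.exp(b):.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# parametric model
# ---------------------------------------------------------------------------

class ParametricAIFModel:
    """Tri-exponential descent fitted by nonlinear Poisson regression."""

    def __init__(self, exam: Examination, offsets, n_exp: int = 3):
        self.exam = exam
        self.offsets = offsets
        self.n_exp = n_exp
        self.y, self.t, self.abss, self.log_off = _exam_arrays(exam, offsets)

    def fit(self, start: Optional[TriExpParams] = None) -> AIFModelFit:
        if start is None:
            rate = self.y / np.exp(self.log_off)
            start = curve_strip_init(self.t, rate, n_exp=self.n_exp)
        has_abss = bool(self.abss.any())
        linear_X = self.abss[:, None] if has_abss else None
        pf = nls_poisson_fit(
            lambda t, p: triexp_logf(t, p)[0],
            lambda t, p: triexp_logf(t, p)[1],
            start, self.y, self.t, self.log_off, linear_X=linear_X)
        n_curve = pf.extra["n_curve"]
        params = pf.extra["triexp"]
        ex = self.exam.exam_id
        res = AIFModelFit(
            kind="parametric", fit=pf, log_time=False,
            t_range=(float(self.t.min()), float(self.t.max())),
            exam_ids=(ex,), has_abss={ex: has_abss},
            y=self.y, t=self.t, log_offset=self.log_off, model=self)
        if has_abss:
            res._abss_coef_index[ex] = n_curve

        def predict_rows(t_grid, key, reference):
            logf, G = triexp_logf(t_grid, pf.coef[:n_curve])
            L = np.zeros((t_grid.size, pf.coef.size))
            L[:, :n_curve] = G
            eta = logf.copy()
            if reference == "abss":
                eta = eta + pf.coef[n_curve]
                L[:, n_curve] = 1.0
            return eta, L

        res._predict_rows = predict_rows
        res.params = params
        return res


# ---------------------------------------------------------------------------
# single-exam penalized smooth
# ---------------------------------------------------------------------------

class SmoothAIFModel:
    """Penalized-spline AIF for one examination.

    ``shape_constrained=True`` uses the monotone non-increasing B-spline
    construction (the intercept is absorbed into its level parameter);
    otherwise an intercept plus a centred thin-plate smooth.  ``log_time``
    places the smooth over the natural log of time.  The negative-binomial
    dispersion is selected jointly with the smoothing parameter by LAML.
    """

    def __init__(self, exam: Examination, offsets, family: str = "negbin",
                 shape_constrained: bool = False, log_time: bool = True,
                 k: int = 15):
        self.exam = exam
        self.offsets = offsets
        self.family_name = family
        self.shape_constrained = shape_constrained
        self.log_time = log_time
        self.k = k
        self.y, self.t, self.abss, self.log_off = _exam_arrays(exam, offsets)
        if np.any(self.t <= 0) and log_time:
            raise ValueError("log-time transform needs strictly positive "
                             "times")

    def _x(self, t):
        return np.log(t) if self.log_time else np.asarray(t, float)

    def fit(self, sp=None, psi: Optional[float] = None) -> AIFModelFit:
        x = self._x(self.t)
        has_abss = bool(self.abss.any())
        transforms = {}
        if self.shape_constrained:
            block, tr = scop_decreasing_design(x, self.k)
            blocks = [block]
            transforms[0] = tr
            smooth_idx, icpt_idx = 0, None
        else:
            raw = tps_design(x, self.k)
            block = center_block(raw, drop_constant_col=raw.k - 2)
            blocks = [linear_block(np.ones((self.y.size, 1)), "intercept"),
                      block]
            smooth_idx, icpt_idx = 1, 0
        if has_abss:
            blocks.append(linear_block(self.abss[:, None], "abss"))
            abss_block = len(blocks) - 1
        else:
            abss_block = None
        transforms = {smooth_idx: transforms[0]} if transforms else {}

        if psi is not None or sp is not None:
            fam = Family(self.family_name,
                         psi if psi is not None else 0.0)
            sp_vec = np.zeros(len(blocks))
            sp_vec[smooth_idx] = sp if sp is not None else 1.0
            pf = pirls_solve(blocks, self.y, self.log_off, fam, sp_vec,
                             transforms=transforms)
        elif self.family_name == "negbin":
            pf = reml_optimize(blocks, self.y, self.log_off,
                               Family("negbin", 0.1), transforms=transforms,
                               optimize_psi=True)
        else:
            pf = reml_optimize(blocks, self.y, self.log_off,
                               Family(self.family_name),
                               transforms=transforms)
        ex = self.exam.exam_id
        kind = ("gam_poisson_scop" if self.shape_constrained
                else f"gam_{self.family_name}_tps")
        res = AIFModelFit(
            kind=kind, fit=pf, log_time=self.log_time,
            t_range=(float(self.t.min()), float(self.t.max())),
            exam_ids=(ex,), has_abss={ex: has_abss},
            y=self.y, t=self.t, log_offset=self.log_off, model=self)
        if has_abss:
            res._abss_coef_index[ex] = pf.slices[abss_block].start
        slices = pf.slices
        cov_dim = pf.cov_working.shape[0]

        def predict_rows(t_grid, key, reference):
            xg = self._x(np.maximum(t_grid, 1e-9) if self.log_time
                         else t_grid)
            n = xg.size
            L = np.zeros((n, cov_dim))
            Xs = blocks[smooth_idx].evaluate(xg)
            if self.shape_constrained:
                tr = transforms[smooth_idx]
                J = tr.jacobian(pf.working[slices[smooth_idx]])
                eta = Xs @ pf.coef[slices[smooth_idx]]
                L[:, slices[smooth_idx]] = Xs @ J
            else:
                eta = (pf.coef[slices[icpt_idx]][0]
                       + Xs @ pf.coef[slices[smooth_idx]])
                L[:, slices[icpt_idx]] = 1.0
                L[:, slices[smooth_idx]] = Xs
            if reference == "abss":
                bidx = slices[abss_block].start
                eta = eta + pf.coef[bidx]
                L[:, bidx] = 1.0
            return eta, L

        res._predict_rows = predict_rows
        return res


# ---------------------------------------------------------------------------
# hierarchical model
# ---------------------------------------------------------------------------

class HierarchicalAIFModel:
    """Joint fit across examinations with penalized per-exam deviations.

    Per-exam intercepts and per-exam ABSS effects are unpenalized fixed
    effects; one global thin-plate smooth of log time (dimension
    ``k_global``) carries the mean curve; a factor-smooth block
    (dimension ``k_exam`` per exam, one shared smoothing parameter,
    full-rank penalty) carries the deviations, which vanish as the
    deviation smoothing parameter grows.
    """

    def __init__(self, exams: Sequence[Examination], offsets_per_exam,
                 family: str = "negbin", k_global: int = 20,
                 k_exam: int = 5):
        if len(exams) < 2:
            raise ValueError("hierarchical model needs >= 2 examinations")
        exams = list(exams)
        offsets_per_exam = list(offsets_per_exam)
        keep = [i for i, e in enumerate(exams) if e.post_samples]
        if len(keep) < len(exams):
            warnings.warn("dropping examination(s) with no data")
            exams = [exams[i] for i in keep]
            offsets_per_exam = [offsets_per_exam[i] for i in keep]
        self.exams = exams
        self.family_name = family
        self.k_global = k_global
        self.k_exam = k_exam

        ys, ts, abss, offs, gids = [], [], [], [], []
        for exam, offsets in zip(exams, offsets_per_exam):
            y, t, a, lo = _exam_arrays(exam, offsets)
            ys.append(y); ts.append(t); abss.append(a); offs.append(lo)
            gids.append(np.full(y.size, exam.exam_id, dtype=object))
        self.y = np.concatenate(ys)
        self.t = np.concatenate(ts)
        self.abss = np.concatenate(abss)
        self.log_off = np.concatenate(offs)
        self.group = np.concatenate(gids)
        self.exam_ids = tuple(e.exam_id for e in exams)

    def _design(self):
        x = np.log(self.t)
        G = len(self.exam_ids)
        n = self.y.size
        icpt = np.zeros((n, G))
        for j, g in enumerate(self.exam_ids):
            icpt[self.group == g, j] = 1.0
        abss_ids = [g for g in self.exam_ids
                    if self.abss[self.group == g].any()]
        A = np.zeros((n, len(abss_ids)))
        for j, g in enumerate(abss_ids):
            A[(self.group == g) & (self.abss > 0), j] = 1.0
        raw = tps_design(x, self.k_global)
        global_block = center_block(raw, drop_constant_col=raw.k - 2)
        from .bases import factor_smooth_design
        fs_block = factor_smooth_design(x, self.group, self.k_exam)
        blocks = [linear_block(icpt, "exam_intercepts")]
        abss_block_idx = None
        if abss_ids:
            blocks.append(linear_block(A, "exam_abss"))
            abss_block_idx = 1
        global_idx = len(blocks)
        blocks.append(global_block)
        fs_idx = len(blocks)
        blocks.append(fs_block)
        return (x, blocks, abss_ids, abss_block_idx, global_idx, fs_idx)

    def fit(self, sp=None, psi: Optional[float] = None,
            maxiter: int = 120) -> AIFModelFit:
        """REML fit; pass ``sp=(sp_global, sp_deviation)`` (and ``psi``)
        to fit at fixed smoothing instead."""
        x, blocks, abss_ids, abss_bidx, g_idx, fs_idx = self._design()
        if sp is not None:
            fam = Family(self.family_name, psi if psi is not None else 0.0)
            sp_vec = np.zeros(len(blocks))
            sp_vec[g_idx], sp_vec[fs_idx] = sp
            pf = pirls_solve(blocks, self.y, self.log_off, fam, sp_vec)
        elif self.family_name == "negbin":
            pf = reml_optimize(blocks, self.y, self.log_off,
                               Family("negbin", 0.1), optimize_psi=True,
                               maxiter=maxiter)
        else:
            pf = reml_optimize(blocks, self.y, self.log_off,
                               Family(self.family_name), maxiter=maxiter)
        has_abss = {g: g in abss_ids for g in self.exam_ids}
        res = AIFModelFit(
            kind="hgam", fit=pf, log_time=True,
            t_range=(float(self.t.min()), float(self.t.max())),
            exam_ids=self.exam_ids, has_abss=has_abss,
            y=self.y, t=self.t, log_offset=self.log_off, model=self)
        for j, g in enumerate(abss_ids):
            res._abss_coef_index[g] = pf.slices[abss_bidx].start + j
        fs_block = blocks[fs_idx]
        offs = fs_block.meta["offsets"]
        widths = fs_block.meta["widths"]
        cov_dim = pf.cov_working.shape[0]

        def predict_rows(t_grid, key, reference):
            if key not in self.exam_ids:
                raise ValueError(f"unknown exam {key!r}")
            xg = np.log(np.maximum(t_grid, 1e-9))
            n = xg.size
            L = np.zeros((n, cov_dim))
            j_exam = self.exam_ids.index(key)
            L[:, pf.slices[0].start + j_exam] = 1.0
            Xg = blocks[g_idx].evaluate(xg)
            L[:, pf.slices[g_idx]] = Xg
            Xf = fs_block.evaluate(xg, np.full(n, key, dtype=object))
            L[:, pf.slices[fs_idx]] = Xf
            eta = L @ pf.coef
            if reference == "abss":
                bidx = res._abss_coef_index[key]
                eta = eta + pf.coef[bidx]
                L = L.copy()
                L[:, bidx] = 1.0
            return eta, L

        res._predict_rows = predict_rows
        # per-exam deviation EDF: partition the factor-smooth block's edf
        sl = pf.slices[fs_idx]
        res.deviation_edf = _per_exam_deviation_edf(pf, sl, offs, widths)
        return res


def _per_exam_deviation_edf(pf: PenalizedFit, sl: slice, offs, widths):
    """Split the factor-smooth influence diagonal by examination."""
    asm_blocks = pf.blocks
    X = np.hstack([b.design for b in asm_blocks])
    w = pf.family.fisher_weight(pf.mu)
    XtWX = X.T @ (X * w[:, None])
    Fdiag = np.einsum("ij,ji->i", pf.cov_working, XtWX)
    out = {}
    for g, off in offs.items():
        cols = np.arange(sl.start + off, sl.start + off + widths[g])
        out[g] = float(np.sum(Fdiag[cols]))
    return out


# ---------------------------------------------------------------------------
# spec-level convenience functions
# ---------------------------------------------------------------------------

def fit_parametric_aif(exam: Examination, offsets) -> AIFModelFit:
    """Tri-exponential nonlinear Poisson fit with ABSS-bias effect."""
    return ParametricAIFModel(exam, offsets).fit()


def fit_gam_aif(exam: Examination, offsets, family: str = "negbin",
                shape_constrained: bool = False, log_time: bool = True,
                k: int = 15) -> AIFModelFit:
    """Penalized-spline AIF fit (the preferred configuration is
    negative-binomial, unconstrained thin-plate, log time)."""
    return SmoothAIFModel(exam, offsets, family=family,
                          shape_constrained=shape_constrained,
                          log_time=log_time, k=k).fit()


def fit_hgam_aif(exams, offsets_per_exam, k_global: int = 20,
                 k_exam: int = 5, family: str = "negbin") -> AIFModelFit:
    """Hierarchical negative-binomial fit across examinations."""
    return HierarchicalAIFModel(exams, offsets_per_exam, family=family,
                                k_global=k_global, k_exam=k_exam).fit()


def predict_aif(fit: AIFModelFit, t_grid, reference: str = "manual",
                exam_id=None):
    """(estimate, lower95, upper95) arrays on a time grid."""
    df = fit.predict(t_grid, reference=reference, exam_id=exam_id)
    return (df["estimate"].to_numpy(), df["lower95"].to_numpy(),
            df["upper95"].to_numpy())


def compare_models_aic(fits_by_model: dict, reference: str) -> pd.DataFrame:
    """Per-exam AIC table and differences vs a reference model.

    ``fits_by_model`` maps model name -> {exam_id -> AIFModelFit}; all
    models must be fitted to the same counts per exam.  The ``delta_*``
    columns are AIC(reference) - AIC(model): negative values mean the
    reference model is preferred.
    """
    if reference not in fits_by_model:
        raise ValueError(f"reference model {reference!r} not present")
    names = list(fits_by_model)
    exam_ids = sorted(fits_by_model[reference])
    rows = []
    for ex in exam_ids:
        ref_fit = fits_by_model[reference][ex]
        row = {"exam_id": ex}
        for name in names:
            f = fits_by_model[name].get(ex)
            if f is None:
                row[f"aic_{name}"] = np.nan
                continue
            if f.y.size != ref_fit.y.size or \
                    not np.array_equal(f.y, ref_fit.y):
                raise ValueError(
                    f"model {name!r} and reference were fitted to "
                    f"different data for exam {ex!r}")
            row[f"aic_{name}"] = f.aic
        for name in names:
            row[f"delta_{name}"] = (row[f"aic_{reference}"]
                                    - row[f"aic_{name}"])
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# preprocessing pipeline
# ---------------------------------------------------------------------------

def prepare_examination(exam: Examination, background: bool = True,
                        descent: bool = True, peak_window: int = 5):
    """Standard preprocessing: background, sub-models, descent, offsets.

    Fits the blood-to-plasma ratio and parent-fraction sub-models on the
    full examination, subtracts the ABSS background (when a pre-injection
    segment exists), builds the dispersion-correction table, restricts to
    the descent and assembles per-sample offsets.

    Returns ``(descent_exam, offsets, aux)`` where ``aux`` carries the
    fitted sub-models.
    """
    bpr_model = fit_bpr(exam)
    pf_params = (fit_parent_fraction(exam.pf_measurements)
                 if len(exam.pf_measurements) >= 3 else None)
    work = exam
    if background and any(s.pre_injection for s in exam.samples):
        work = subtract_background(work)
    table = build_dispersion_table(work)
    if descent:
        work = select_descent(work, window=peak_window)
    offsets = assemble_offsets(work, bpr_model, pf_params, table)
    aux = {"bpr_model": bpr_model, "pf_params": pf_params,
           "dispersion_table": table}
    return work, offsets, aux
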