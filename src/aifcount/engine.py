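"""Penalized count-regression engine.

Implements the likelihood machinery shared by all AIF models:

* Poisson and negative-binomial log-likelihoods with a log link.  The
  negative binomial uses the dispersion parameterization with variance
  ``mu + psi * mu**2``; ``psi = 0`` recovers the Poisson.
* Penalized iteratively reweighted least squares (PIRLS) for models that
  are linear in (possibly transformed) coefficients, with known offsets
  entering the linear predictor with coefficient fixed at one.
* Laplace-approximate REML (LAML) selection of smoothing parameters, and
  profile-likelihood estimation of the negative-binomial dispersion.
* Nonlinear Poisson regression for the tri-exponential parametric curve,
  initialized by classic curve stripping (exponential peeling).

Smoothing parameters are called ``sp`` throughout; ``lambda`` is reserved
for the Poisson rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import optimize, special, stats

from .bases import BasisBlock, ScopTransform

_LOG2PI = np.log(2.0 * np.pi)
_PSI_POISSON_LIMIT = 1e-7   # below this the negbin is numerically Poisson
_ETA_CLIP = 300.0


class FitError(RuntimeError):
    """The optimizer failed to produce a converged, identifiable fit."""


# ---------------------------------------------------------------------------
# families
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Family:
    """Count-data family with log link.

    ``negbin`` carries a dispersion ``psi`` >= 0 giving variance
    ``mu + psi * mu**2``; ``psi = 0`` is exactly Poisson.
    """

    name: str = "poisson"
    psi: float = 0.0

    def __post_init__(self):
        if self.name not in ("poisson", "negbin", "gaussian"):
            raise ValueError(f"unknown family {self.name!r}")
        if self.psi < 0:
            raise ValueError("psi must be >= 0")

    @property
    def effective_psi(self) -> float:
        return self.psi if self.name == "negbin" else 0.0

    def variance(self, mu):
        mu = np.asarray(mu, float)
        return mu + self.effective_psi * mu ** 2

    def loglik(self, y, mu) -> float:
        return family_loglik(self, y, mu)

    def score_eta(self, y, mu):
        """d loglik / d eta per observation (log link)."""
        psi = self.effective_psi
        if psi < _PSI_POISSON_LIMIT:
            return y - mu
        return (y - mu) / (1.0 + psi * mu)

    def fisher_weight(self, mu):
        """(dmu/deta)^2 / V(mu) for the log link."""
        psi = self.effective_psi
        if psi < _PSI_POISSON_LIMIT:
            return mu
        return mu / (1.0 + psi * mu)

    def cdf(self, y, mu):
        psi = self.effective_psi
        if psi < _PSI_POISSON_LIMIT:
            return stats.poisson.cdf(y, mu)
        r = 1.0 / psi
        return stats.nbinom.cdf(y, r, r / (r + mu))

    def rvs(self, mu, rng: np.random.Generator):
        mu = np.asarray(mu, float)
        psi = self.effective_psi
        if psi < _PSI_POISSON_LIMIT:
            return rng.poisson(mu)
        r = 1.0 / psi
        return rng.negative_binomial(r, r / (r + mu))


def family_loglik(family: Family, y, mu) -> float:
    """Exact log-likelihood (including all constants)."""
    y = np.asarray(y, float)
    mu = np.asarray(mu, float)
    if np.any(mu <= 0) or not np.all(np.isfinite(mu)):
        raise ValueError("mu must be positive and finite")
    psi = family.effective_psi
    if family.name == "gaussian":
        raise ValueError("gaussian family has no count log-likelihood")
    if psi < _PSI_POISSON_LIMIT:
        return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1.0)))
    r = 1.0 / psi
    return float(np.sum(
        special.gammaln(y + r) - special.gammaln(r)
        - special.gammaln(y + 1.0)
        + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))))


# ---------------------------------------------------------------------------
# fit container
# ---------------------------------------------------------------------------

@dataclass
class PenalizedFit:
    """A converged penalized (or unpenalized) count-regression fit.

    ``coef`` is on the natural (spline-coefficient) scale; for
    shape-constrained blocks ``working`` holds the unconstrained working
    parameters.  ``edf`` is the total effective degrees of freedom used in
    the AIC (it includes +1 for a profiled negative-binomial dispersion);
    ``edf_coef``/``edf_by_block`` is the coefficient breakdown.
    ``cov_working`` is the Bayesian posterior covariance
    ``(X'WX + sum sp_j S_j)^-1`` on the working scale.
    """

    coef: np.ndarray
    working: np.ndarray
    sp: np.ndarray
    psi: float
    edf: float
    edf_coef: float
    edf_by_block: np.ndarray
    log_likelihood: float
    aic: float
    cov_working: np.ndarray
    cov_coef: np.ndarray
    iterations: int
    grad_norm: float
    converged: bool
    family: Family
    mu: np.ndarray
    y: np.ndarray = field(repr=False, default=None)
    offset: np.ndarray = field(repr=False, default=None)
    blocks: Sequence[BasisBlock] = field(repr=False, default=None)
    slices: Sequence[slice] = field(repr=False, default=None)
    transforms: dict = field(repr=False, default_factory=dict)
    laml: float = np.nan
    psi_profiled: bool = False
    extra: dict = field(default_factory=dict, repr=False)

    def block_coef(self, j: int) -> np.ndarray:
        return self.coef[self.slices[j]]

    def to_dict(self) -> dict:
        return {
            "coef": self.coef.tolist(),
            "sp": self.sp.tolist(),
            "psi": self.psi,
            "edf": self.edf,
            "edf_by_block": self.edf_by_block.tolist(),
            "log_likelihood": self.log_likelihood,
            "aic": self.aic,
            "iterations": self.iterations,
            "grad_norm": self.grad_norm,
            "converged": self.converged,
            "family": self.family.name,
        }


def linear_block(X: np.ndarray, name: str = "linear") -> BasisBlock:
    """Wrap fixed-effect columns as an unpenalized basis block."""
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    k = X.shape[1]
    return BasisBlock(design=X, penalty=np.zeros((k, k)), nullspace_dim=k,
                      kind="linear", meta={"name": name})


# ---------------------------------------------------------------------------
# PIRLS
# ---------------------------------------------------------------------------

class _Assembled:
    """Concatenated design, per-block slices and penalty embedding."""

    def __init__(self, blocks: Sequence[BasisBlock]):
        self.blocks = list(blocks)
        widths = [b.design.shape[1] for b in self.blocks]
        edges = np.concatenate([[0], np.cumsum(widths)])
        self.slices = [slice(int(a), int(b))
                       for a, b in zip(edges[:-1], edges[1:])]
        self.p = int(edges[-1])
        self.X = np.hstack([b.design for b in self.blocks])
        self.penalized = [j for j, b in enumerate(self.blocks)
                          if np.any(b.penalty)]

    def S_total(self, sp: np.ndarray) -> np.ndarray:
        S = np.zeros((self.p, self.p))
        for j, b in enumerate(self.blocks):
            if np.any(b.penalty):
                sl = self.slices[j]
                S[sl, sl] += sp[j] * b.penalty
        return S

    def map_coef(self, theta: np.ndarray, transforms: dict):
        """theta -> (beta, block-diagonal Jacobian)."""
        if not transforms:
            return theta, None
        beta = theta.copy()
        J = np.eye(self.p)
        for j, tr in transforms.items():
            sl = self.slices[j]
            beta[sl] = tr.beta(theta[sl])
            J[sl, sl] = tr.jacobian(theta[sl])
        return beta, J


def _initial_theta(asm: _Assembled, y, offset, transforms: dict):
    mu0 = np.maximum(np.asarray(y, float), 0.25) + 0.25
    z = np.log(mu0) - offset
    theta = np.zeros(asm.p)
    if not transforms:
        A = asm.X.T @ asm.X + np.eye(asm.p)
        theta = np.linalg.solve(A, asm.X.T @ z)
        return theta
    # shape-constrained blocks start from a gently decreasing ramp at the
    # working level implied by the data; other blocks start at zero
    level = float(np.median(z))
    for j, tr in transforms.items():
        theta[asm.slices[j]] = tr.initial(level)
    return theta


def pirls_solve(design_blocks: Sequence[BasisBlock], y, log_offset,
                family: Family, sp, transforms: Optional[dict] = None,
                theta0: Optional[np.ndarray] = None,
                max_iter: int = 200, tol: float = 1e-9,
                _assembled: Optional[_Assembled] = None) -> PenalizedFit:
    """Penalized IRLS (Newton with Fisher weights and step halving).

    ``sp`` is one smoothing parameter per block (ignored for unpenalized
    blocks).  ``transforms`` maps block index -> ``ScopTransform`` for
    shape-constrained terms; the Jacobian of the transform is applied
    inside every iteration.
    """
    y = np.asarray(y, float)
    offset = np.zeros_like(y) if log_offset is None else \
        np.asarray(log_offset, float)
    transforms = transforms or {}
    asm = _assembled if _assembled is not None else _Assembled(design_blocks)
    sp = np.asarray(sp, float) * np.ones(len(asm.blocks))
    if np.any(sp < 0):
        raise ValueError("smoothing parameters must be >= 0")
    S = asm.S_total(sp)

    theta = (_initial_theta(asm, y, offset, transforms)
             if theta0 is None else np.asarray(theta0, float).copy())

    def eval_state(th):
        beta, J = asm.map_coef(th, transforms)
        eta = np.clip(asm.X @ beta + offset, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        ll = family.loglik(y, mu)
        pen = 0.5 * th @ S @ th
        return beta, J, mu, ll, ll - pen

    beta, J, mu, ll, obj = eval_state(theta)
    n_iter = 0
    grad_norm = np.inf
    converged = False
    for n_iter in range(1, max_iter + 1):
        u = family.score_eta(y, mu)
        w = family.fisher_weight(mu)
        XJ = asm.X if J is None else asm.X @ J
        g = XJ.T @ u - S @ theta
        grad_norm = float(np.max(np.abs(g)))
        H = XJ.T @ (XJ * w[:, None]) + S
        if transforms:
            # curvature of the coefficient transform: for SCOP working
            # parameters, d2(beta_j)/d(delta_l)^2 = -exp(delta_l), so the
            # exact Hessian gains a diagonal term -(J^T X^T u) on the
            # delta coordinates.  Without it, Fisher scoring can crawl
            # when the transform is strongly curved; the positive part is
            # kept so H stays positive definite.
            jtg = g + S @ theta
            for jdx in transforms:
                sl = asm.slices[jdx]
                idx = np.arange(sl.start + 1, sl.stop)
                H[idx, idx] += np.maximum(-jtg[idx], 0.0)
        ridge = 0.0
        for _ in range(8):
            try:
                c, low = _cho(H + ridge * np.eye(asm.p))
                break
            except np.linalg.LinAlgError:
                ridge = max(ridge * 10, 1e-8 * max(np.mean(np.diag(H)), 1.0))
        else:
            raise FitError("penalized Hessian is singular: model not "
                           "identifiable from these data")
        step = _cho_solve((c, low), g)
        # step halving on penalized log-likelihood decrease
        t = 1.0
        for _ in range(40):
            th_new = theta + t * step
            if np.max(np.abs(th_new)) > 1e6:
                t *= 0.5
                continue
            try:
                beta_n, J_n, mu_n, ll_n, obj_n = eval_state(th_new)
            except (ValueError, FloatingPointError):
                t *= 0.5
                continue
            if np.isfinite(obj_n) and obj_n >= obj - 1e-12:
                break
            t *= 0.5
        else:
            # no improving step: treat as converged if gradient small
            break
        delta = abs(obj_n - obj)
        theta, beta, J, mu, ll, obj = th_new, beta_n, J_n, mu_n, ll_n, obj_n
        if delta < tol * (abs(obj) + 1.0):
            converged = True
            break
    if not converged and grad_norm > 1e-4 * (abs(ll) + 1.0):
        raise FitError(
            f"PIRLS did not converge in {n_iter} iterations "
            f"(|grad| = {grad_norm:.3g}, obj = {obj:.6g})")
    if np.max(np.abs(beta)) > 1e5:
        raise FitError("coefficients diverged (possible separation)")

    # influence and covariance at convergence
    w = family.fisher_weight(mu)
    XJ = asm.X if J is None else asm.X @ J
    XtWX = XJ.T @ (XJ * w[:, None])
    H = XtWX + S
    Hinv = _safe_inv(H)
    Fdiag = np.einsum("ij,ji->i", Hinv, XtWX)
    edf_by_block = np.array([float(np.sum(Fdiag[asm.slices[j]]))
                             for j in range(len(asm.blocks))])
    edf_coef = float(np.sum(Fdiag))
    cov_working = Hinv
    cov_coef = Hinv if J is None else J @ Hinv @ J.T
    aic = -2.0 * ll + 2.0 * edf_coef
    return PenalizedFit(
        coef=beta, working=theta, sp=sp, psi=family.effective_psi,
        edf=edf_coef, edf_coef=edf_coef, edf_by_block=edf_by_block,
        log_likelihood=ll, aic=aic, cov_working=cov_working,
        cov_coef=cov_coef, iterations=n_iter, grad_norm=grad_norm,
        converged=True, family=family, mu=mu, y=y, offset=offset,
        blocks=asm.blocks, slices=asm.slices, transforms=transforms)


def _cho(A):
    from scipy.linalg import cho_factor
    return cho_factor(A, lower=True, check_finite=False)


def _cho_solve(cf, b):
    from scipy.linalg import cho_solve
    return cho_solve(cf, b, check_finite=False)


def _safe_inv(A):
    try:
        c = _cho(A)
        return _cho_solve(c, np.eye(A.shape[0]))
    except np.linalg.LinAlgError:
        return np.linalg.pinv(A)


# ---------------------------------------------------------------------------
# LAML / REML
# ---------------------------------------------------------------------------

def laml_criterion(fit: PenalizedFit, blocks, sp, family: Family) -> float:
    """Laplace-approximate restricted marginal likelihood at a fitted mode.

    LAML = l_p(theta_hat) + 1/2 log|S|_+ - 1/2 log|H| + (M_p/2) log(2 pi)
    with ``l_p`` the penalized log-likelihood, ``|S|_+`` the product of
    positive eigenvalues of the total penalty, ``H`` the penalized Fisher
    information at the mode and ``M_p`` the penalty null-space dimension.
    """
    asm = _Assembled(blocks)
    sp = np.asarray(sp, float) * np.ones(len(blocks))
    S = asm.S_total(sp)
    theta = fit.working
    lp = fit.log_likelihood - 0.5 * theta @ S @ theta
    # log|S|_+ blockwise: the penalty is block diagonal, and each block's
    # positive eigenvalues must be judged against that block's own scale;
    # a single threshold on the assembled matrix would misclassify a
    # lightly penalized block as null space whenever another block's
    # smoothing parameter is many orders of magnitude larger.
    logdet_S = 0.0
    rank_total = 0
    for j, b in enumerate(asm.blocks):
        if not np.any(b.penalty) or sp[j] <= 0:
            continue
        ew = np.linalg.eigvalsh(b.penalty)
        pos = ew[ew > max(ew.max(), 0.0) * 1e-10]
        logdet_S += pos.size * np.log(sp[j]) + float(np.sum(np.log(pos)))
        rank_total += pos.size
    Mp = asm.p - rank_total
    w = family.fisher_weight(fit.mu)
    beta, J = asm.map_coef(theta, fit.transforms)
    XJ = asm.X if J is None else asm.X @ J
    H = XJ.T @ (XJ * w[:, None]) + S
    sign, logdet_H = np.linalg.slogdet(H)
    if sign <= 0:
        return -np.inf
    return float(lp + 0.5 * logdet_S - 0.5 * logdet_H + 0.5 * Mp * _LOG2PI)


def reml_optimize(design_blocks: Sequence[BasisBlock], y, log_offset,
                  family: Family, transforms: Optional[dict] = None,
                  optimize_psi: bool = False,
                  log_sp0: float = 0.0, psi0: float = 0.1,
                  maxiter: int = 200) -> PenalizedFit:
    """Select smoothing parameters (and optionally psi) by maximizing LAML.

    The outer search is a Nelder-Mead walk over ``log(sp)`` (one per
    penalized block) starting from ``sp = 1``; for the negative binomial
    with ``optimize_psi=True`` the log-dispersion is searched jointly.
    Returns the fit at the optimum, with per-term EDFs.
    """
    y = np.asarray(y, float)
    offset = np.zeros_like(y) if log_offset is None else \
        np.asarray(log_offset, float)
    transforms = transforms or {}
    asm = _Assembled(design_blocks)
    pen_idx = asm.penalized
    if not pen_idx and not optimize_psi:
        raise ValueError("no penalized blocks: nothing to optimize")
    n_sp = len(pen_idx)
    state = {"theta": None, "best": None, "best_val": -np.inf}

    def unpack(par):
        sp = np.zeros(len(asm.blocks))
        for i, j in enumerate(pen_idx):
            sp[j] = np.exp(np.clip(par[i], -30.0, 30.0))
        if optimize_psi:
            psi = float(np.exp(np.clip(par[n_sp], -18.0, 4.0)))
            fam = Family("negbin", psi)
        else:
            fam = family
        return sp, fam

    def objective(par):
        sp, fam = unpack(par)
        try:
            fit = pirls_solve(asm.blocks, y, offset, fam, sp,
                              transforms=transforms, theta0=state["theta"],
                              _assembled=asm)
        except (FitError, np.linalg.LinAlgError, ValueError):
            try:
                fit = pirls_solve(asm.blocks, y, offset, fam, sp,
                                  transforms=transforms, _assembled=asm)
            except (FitError, np.linalg.LinAlgError, ValueError):
                return 1e10
        state["theta"] = fit.working
        val = laml_criterion(fit, asm.blocks, sp, fam)
        if not np.isfinite(val):
            return 1e10
        if val > state["best_val"]:
            state["best_val"] = val
            state["best"] = (par.copy(), fit)
        return -val

    x0 = np.full(n_sp + (1 if optimize_psi else 0), log_sp0)
    if optimize_psi:
        x0[n_sp] = np.log(max(psi0, 1e-6))
    res = optimize.minimize(objective, x0, method="Nelder-Mead",
                            options={"xatol": 1e-3, "fatol": 1e-6,
                                     "maxiter": maxiter * max(1, len(x0)),
                                     "maxfev": maxiter * max(1, len(x0))})
    if state["best"] is None:
        raise FitError("LAML criterion non-finite at every probed point")
    par, fit = state["best"]
    sp, fam = unpack(par)
    fit.laml = state["best_val"]
    if optimize_psi:
        fit.psi_profiled = True
        fit.edf = fit.edf_coef + 1.0
        fit.aic = -2.0 * fit.log_likelihood + 2.0 * fit.edf
    return fit


@dataclass
class DispersionEstimate:
    psi: float
    fit: PenalizedFit
    effectively_poisson: bool
    profile: list


def estimate_negbin_dispersion(fit_fn: Callable[[float], PenalizedFit],
                               y=None, lo: float = 1e-8, hi: float = 10.0,
                               xatol: float = 0.01) -> DispersionEstimate:
    """Profile maximum likelihood over log(psi).

    ``fit_fn(psi)`` must refit the coefficients at the given dispersion and
    return the fit; the profile log-likelihood is maximized by bounded
    scalar search on the log scale.  A solution at the lower boundary is
    flagged as effectively Poisson.
    """
    profile = []

    def neg_profile(logpsi):
        fit = fit_fn(float(np.exp(logpsi)))
        profile.append((float(np.exp(logpsi)), fit.log_likelihood))
        return -fit.log_likelihood

    res = optimize.minimize_scalar(
        neg_profile, bounds=(np.log(lo), np.log(hi)), method="bounded",
        options={"xatol": xatol})
    psi_hat = float(np.exp(res.x))
    fit = fit_fn(psi_hat)
    # bounded Brent stops a few ulp short of the bound; anything within a
    # decade of it is indistinguishable from Poisson at machine precision
    boundary = psi_hat <= lo * 10.0
    fit.psi_profiled = True
    fit.edf = fit.edf_coef + 1.0
    fit.aic = -2.0 * fit.log_likelihood + 2.0 * fit.edf
    return DispersionEstimate(psi=psi_hat, fit=fit,
                              effectively_poisson=boundary, profile=profile)


def model_aic(fit: PenalizedFit) -> float:
    """AIC = -2 loglik + 2 edf (edf = trace of the influence matrix;
    a profiled negative-binomial dispersion counts as one extra edf)."""
    return float(fit.aic)


# ---------------------------------------------------------------------------
# Gaussian working fits (for the blood-to-plasma ratio smooth)
# ---------------------------------------------------------------------------

def gaussian_reml_fit(design_blocks: Sequence[BasisBlock], y,
                      maxiter: int = 200) -> PenalizedFit:
    """Penalized least squares with REML smoothing for a Gaussian response.

    Used as the working family for smooth ratio curves (e.g. the
    whole-blood-to-plasma ratio).  The error variance is profiled as
    ``(RSS + penalty) / (n - M_p)``.
    """
    y = np.asarray(y, float)
    asm = _Assembled(design_blocks)
    n = y.size

    def fit_at(sp_full):
        S = asm.S_total(sp_full)
        A = asm.X.T @ asm.X + S
        beta = np.linalg.solve(A, asm.X.T @ y)
        resid = y - asm.X @ beta
        rss = float(resid @ resid)
        pen = float(beta @ S @ beta)
        ew = np.linalg.eigvalsh(S)
        pos = ew[ew > max(ew.max(), 0.0) * 1e-10]
        Mp = asm.p - pos.size
        sigma2 = max((rss + pen) / max(n - Mp, 1), 1e-12)
        logdet_S = float(np.sum(np.log(pos))) if pos.size else 0.0
        sign, logdet_A = np.linalg.slogdet(A)
        reml = (-0.5 * n * np.log(2 * np.pi * sigma2)
                - 0.5 * (rss + pen) / sigma2
                + 0.5 * (logdet_S - pos.size * np.log(sigma2))
                - 0.5 * (logdet_A - asm.p * np.log(sigma2))
                + 0.5 * Mp * _LOG2PI)
        return beta, A, S, sigma2, rss, float(reml)

    pen_idx = asm.penalized

    def objective(par):
        sp_full = np.zeros(len(asm.blocks))
        for i, j in enumerate(pen_idx):
            sp_full[j] = np.exp(np.clip(par[i], -30, 30))
        return -fit_at(sp_full)[-1]

    if pen_idx:
        res = optimize.minimize(objective, np.zeros(len(pen_idx)),
                                method="Nelder-Mead",
                                options={"xatol": 1e-3, "fatol": 1e-7,
                                         "maxiter": maxiter})
        par = res.x
    else:
        par = np.array([])
    sp_full = np.zeros(len(asm.blocks))
    for i, j in enumerate(pen_idx):
        sp_full[j] = np.exp(np.clip(par[i], -30, 30))
    beta, A, S, sigma2, rss, reml = fit_at(sp_full)
    Ainv = _safe_inv(A)
    F = Ainv @ (asm.X.T @ asm.X)
    edf = float(np.trace(F))
    ll = -0.5 * n * np.log(2 * np.pi * sigma2) - 0.5 * rss / sigma2
    return PenalizedFit(
        coef=beta, working=beta, sp=sp_full, psi=0.0, edf=edf, edf_coef=edf,
        edf_by_block=np.array([float(np.sum(np.einsum("ij,ji->i", Ainv,
                                asm.X.T @ asm.X)[asm.slices[j]]))
                               for j in range(len(asm.blocks))]),
        log_likelihood=float(ll), aic=float(-2 * ll + 2 * edf),
        cov_working=sigma2 * Ainv, cov_coef=sigma2 * Ainv,
        iterations=1, grad_norm=0.0, converged=True,
        family=Family("gaussian"), mu=asm.X @ beta, y=y,
        offset=np.zeros(n), blocks=asm.blocks, slices=asm.slices,
        laml=reml, extra={"sigma2": sigma2})


# ---------------------------------------------------------------------------
# parametric curve: tri-exponential
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TriExpParams:
    """Amplitudes and rate constants of a sum of decreasing exponentials.

    ``A`` in counts/s/mL-equivalent units, ``gamma`` in 1/min; components
    are ordered fastest first (gamma strictly decreasing, ties broken by
    amplitude descending).
    """

    A: tuple
    gamma: tuple

    def __post_init__(self):
        A = tuple(float(a) for a in self.A)
        g = tuple(float(x) for x in self.gamma)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "gamma", g)
        if len(A) != len(g):
            raise ValueError("A and gamma must have equal length")
        if any(a <= 0 for a in A) or any(x <= 0 for x in g):
            raise ValueError("amplitudes and rates must be positive")
        if any(g2 >= g1 for g1, g2 in zip(g, g[1:])):
            raise ValueError("rates must be strictly decreasing")

    @classmethod
    def from_arrays(cls, A, gamma) -> "TriExpParams":
        """Sort components by rate descending (ties: amplitude descending)
        and merge numerically tied rates by nudging them apart."""
        A = np.asarray(A, float).copy()
        g = np.asarray(gamma, float).copy()
        order = np.lexsort((-A, -g))
        A, g = A[order], g[order]
        for i in range(1, g.size):
            if g[i] >= g[i - 1]:
                g[i] = g[i - 1] * (1 - 1e-6)
        return cls(tuple(A), tuple(g))

    @property
    def n_exp(self) -> int:
        return len(self.A)

    def __call__(self, t):
        scalar = np.isscalar(t)
        t = np.atleast_1d(np.asarray(t, float))
        A = np.asarray(self.A)
        g = np.asarray(self.gamma)
        out = np.exp(-np.outer(t, g)) @ A
        return float(out[0]) if scalar else out

    def log_params(self) -> np.ndarray:
        return np.concatenate([np.log(self.A), np.log(self.gamma)])

    @classmethod
    def from_log_params(cls, p) -> "TriExpParams":
        p = np.asarray(p, float)
        m = p.size // 2
        return cls.from_arrays(np.exp(p[:m]), np.exp(p[m:]))


def triexp_logf(t: np.ndarray, p: np.ndarray):
    """log f and d(log f)/d(log-params) for a sum of exponentials.

    ``p = (log A_1..m, log gamma_1..m)``; returns ``(logf, G)`` with ``G``
    of shape (n, 2m).
    """
    t = np.asarray(t, float)
    m = p.size // 2
    A = np.exp(p[:m])
    g = np.exp(p[m:])
    terms = A[None, :] * np.exp(-np.outer(t, g))      # (n, m)
    f = terms.sum(axis=1)
    G = np.empty((t.size, 2 * m))
    G[:, :m] = terms / f[:, None]
    G[:, m:] = -(g[None, :] * t[:, None]) * terms / f[:, None]
    return np.log(f), G


def nls_poisson_fit(model_fn, grad_fn, start: TriExpParams, y, t,
                    log_offset, linear_X: Optional[np.ndarray] = None,
                    max_restarts: int = 4,
                    rng: Optional[np.random.Generator] = None
                    ) -> PenalizedFit:
    """Nonlinear Poisson regression with log-parameterized curve.

    Maximizes the Poisson log-likelihood of ``eta = log f(t, theta) +
    linear_X @ b + log tau`` over ``(log A_k, log gamma_k, b)`` with
    quasi-Newton (L-BFGS-B) and the analytic gradient.  ``model_fn(t, p)``
    returns ``log f``; ``grad_fn(t, p)`` its Jacobian w.r.t. the log
    parameters (use :func:`triexp_logf` for both).  Rates are re-sorted
    into decreasing order at output.
    """
    y = np.asarray(y, float)
    t = np.asarray(t, float)
    offset = np.zeros_like(y) if log_offset is None else \
        np.asarray(log_offset, float)
    if linear_X is not None:
        linear_X = np.atleast_2d(np.asarray(linear_X, float))
        if linear_X.shape[0] != y.size:
            linear_X = linear_X.T
    n_lin = 0 if linear_X is None else linear_X.shape[1]
    p_curve = start.log_params()
    n_curve = p_curve.size
    rng = rng or np.random.default_rng(20231121)

    def neg_ll_and_grad(par):
        logf = model_fn(t, par[:n_curve])
        G = grad_fn(t, par[:n_curve])
        eta = logf + offset
        if n_lin:
            eta = eta + linear_X @ par[n_curve:]
        eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        ll = np.sum(y * eta - mu - special.gammaln(y + 1.0))
        u = y - mu
        grad = np.empty(par.size)
        grad[:n_curve] = G.T @ u
        if n_lin:
            grad[n_curve:] = linear_X.T @ u
        return -ll, -grad

    x0 = np.concatenate([p_curve, np.zeros(n_lin)])
    best = None
    for attempt in range(max_restarts + 1):
        res = optimize.minimize(neg_ll_and_grad, x0, jac=True,
                                method="L-BFGS-B",
                                options={"maxiter": 2000, "ftol": 1e-12,
                                         "gtol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
        if res.success or np.max(np.abs(res.jac)) < 1e-4:
            break
        x0 = np.concatenate([p_curve, np.zeros(n_lin)]) + \
            0.2 * rng.standard_normal(n_curve + n_lin)
    res = best
    if not (res.success or np.max(np.abs(res.jac)) < 1e-3 * (abs(res.fun) + 1)):
        raise FitError(f"nonlinear Poisson fit did not converge: "
                       f"{res.message}; best loglik {-res.fun:.6g}")
    par = res.x
    params = TriExpParams.from_log_params(par[:n_curve])
    logf = model_fn(t, par[:n_curve])
    eta = logf + offset + (linear_X @ par[n_curve:] if n_lin else 0.0)
    mu = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
    ll = float(np.sum(y * np.clip(eta, -_ETA_CLIP, _ETA_CLIP) - mu
                      - special.gammaln(y + 1.0)))
    G = grad_fn(t, par[:n_curve])
    Gfull = np.hstack([G, linear_X]) if n_lin else G
    H = Gfull.T @ (Gfull * mu[:, None])
    cov = _safe_inv(H)
    n_par = par.size
    fit = PenalizedFit(
        coef=par, working=par, sp=np.array([]), psi=0.0,
        edf=float(n_par), edf_coef=float(n_par),
        edf_by_block=np.array([float(n_par)]),
        log_likelihood=ll, aic=float(-2 * ll + 2 * n_par),
        cov_working=cov, cov_coef=cov,
        iterations=int(res.nit), grad_norm=float(np.max(np.abs(res.jac))),
        converged=True, family=Family("poisson"), mu=mu, y=y, offset=offset,
        extra={"triexp": params, "n_curve": n_curve, "n_linear": n_lin})
    return fit


def curve_strip_init(t, rate_estimates, n_exp: int = 3) -> TriExpParams:
    """Exponential peeling starting values for a multi-exponential fit.

    Splits the time span into ``n_exp`` log-spaced segments, fits a
    log-linear regression to the slowest (latest) segment, subtracts the
    fitted component, and repeats on the residuals for progressively
    faster components.  Negative residuals are dropped before each log
    step.
    """
    t = np.asarray(t, float)
    r = np.asarray(rate_estimates, float)
    keep = r > 0
    t, r = t[keep], r[keep]
    if t.size < 2 * n_exp:
        raise ValueError("need at least 2 points per exponential stage")
    tmin, tmax = float(t.min()), float(t.max())
    if tmin <= 0:
        tmin = min(tmax / 100.0, np.min(t[t > 0], initial=tmax / 100.0))
    edges = np.geomspace(max(tmin, 1e-6), tmax, n_exp + 1)
    resid = r.copy()
    A_list, g_list = [], []
    m = n_exp
    for stage in range(n_exp - 1, -1, -1):
        lo = edges[stage]
        hi = edges[stage + 1] * (1 + 1e-12)
        mask = (t >= lo) & (t <= hi) & (resid > 0)
        if mask.sum() < 2:
            mask = (t >= lo) & (resid > 0)
        if mask.sum() < 2:
            warnings.warn(f"curve stripping: stage {stage} has fewer than "
                          f"2 usable points; reducing n_exp")
            m -= 1
            continue
        slope, intercept = np.polyfit(t[mask], np.log(resid[mask]), 1)
        gamma = max(-slope, 1e-4)
        A = float(np.exp(intercept))
        A_list.append(A)
        g_list.append(gamma)
        resid = resid - A * np.exp(-gamma * t)
    if not A_list:
        raise ValueError("curve stripping failed on every stage")
    return TriExpParams.from_arrays(A_list, g_list)
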