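"""Design and penalty matrices for the smooth terms.

Four constructions are provided:

* cubic B-splines with a second-order difference penalty,
* shape-constrained (monotone non-increasing) B-splines, in which working
  parameters map to non-increasing spline coefficients through an
  exponential transform,
* 1-d thin-plate regression splines (radial basis |x - x_j|^3,
  eigen-truncated, unpenalized {1, x} null space),
* factor-smooth blocks: one thin-plate basis per group sharing a single
  smoothing parameter, with a full-rank penalty so that every group
  deviation shrinks to zero exactly as the smoothing parameter grows.

All bases carry an evaluator so fitted smooths can be predicted at new
covariate values; covariates outside the training range are clamped to
the range boundary (constant extrapolation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.interpolate import BSpline


@dataclass
class BasisBlock:
    """A design matrix + penalty for one smooth term.

    Attributes
    ----------
    design : (n, k) ndarray
        Basis functions evaluated at the covariate values.
    penalty : (k, k) ndarray
        Symmetric positive-semidefinite penalty matrix.
    nullspace_dim : int
        k - rank(penalty): number of unpenalized directions.
    kind : {"bspline", "scop_decreasing", "tps", "factor_smooth"}
    transform : {"identity", "log"}
        Covariate transform applied before basis construction (a tag; the
        caller transforms the covariate).
    """

    design: np.ndarray
    penalty: np.ndarray
    nullspace_dim: int
    kind: str
    transform: str = "identity"
    _evaluator: Optional[Callable] = field(default=None, repr=False)
    meta: dict = field(default_factory=dict, repr=False)

    @property
    def k(self) -> int:
        return self.design.shape[1]

    def evaluate(self, x, group_ids=None) -> np.ndarray:
        """Evaluate the basis at new covariate values."""
        if self._evaluator is None:
            raise ValueError("this basis has no evaluator")
        if self.kind == "factor_smooth":
            return self._evaluator(np.asarray(x, float), group_ids)
        return self._evaluator(np.asarray(x, float))


def _project_psd(S: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Symmetrize and clip tiny negative eigenvalues to zero."""
    S = 0.5 * (S + S.T)
    w, V = np.linalg.eigh(S)
    w = np.clip(w, 0.0, None)
    return (V * w) @ V.T


def _quantile_knots(x: np.ndarray, k: int, degree: int) -> np.ndarray:
    """Clamped knot vector with interior knots at quantiles of x."""
    n_interior = k - degree - 1
    lo, hi = float(np.min(x)), float(np.max(x))
    pad = 1e-8 * max(hi - lo, 1.0)
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(np.unique(x), qs)
    else:
        interior = np.array([])
    return np.concatenate([
        np.full(degree + 1, lo - pad), interior,
        np.full(degree + 1, hi + pad)])


def _diff_penalty(k: int, order: int) -> np.ndarray:
    D = np.diff(np.eye(k), n=order, axis=0)
    return D.T @ D


def bspline_design(x, k: int, degree: int = 3) -> BasisBlock:
    """Cubic B-spline basis with a second-order difference penalty.

    Knots are placed at quantiles of ``x`` with clamped boundaries, so the
    basis is a partition of unity on the covariate range.
    """
    x = np.asarray(x, float)
    if k < degree + 1:
        raise ValueError(f"k must be >= degree + 1 = {degree + 1}")
    knots = _quantile_knots(x, k, degree)
    lo, hi = knots[degree], knots[-degree - 1]

    def ev(xnew):
        xc = np.clip(xnew, lo + 1e-12, hi - 1e-12)
        return BSpline.design_matrix(xc, knots, degree).toarray()

    S = _diff_penalty(k, 2)
    return BasisBlock(design=ev(x), penalty=S, nullspace_dim=2,
                      kind="bspline", _evaluator=ev,
                      meta={"knots": knots, "degree": degree})


class ScopTransform:
    """Map working parameters to non-increasing B-spline coefficients.

    Working parameters are ``(beta_1, delta_2, ..., delta_k)``; the spline
    coefficients are ``beta_j = beta_1 - sum_{l=2}^{j} exp(delta_l)``,
    which are strictly decreasing in ``j`` for any finite working value,
    so the fitted curve is non-increasing for every parameter value.
    """

    def __init__(self, k: int):
        self.k = k

    def beta(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, float)
        steps = np.concatenate([[0.0], np.exp(theta[1:])])
        return theta[0] - np.cumsum(steps)

    def jacobian(self, theta: np.ndarray) -> np.ndarray:
        """d beta / d theta, (k, k) lower-triangular-like."""
        theta = np.asarray(theta, float)
        k = self.k
        J = np.zeros((k, k))
        J[:, 0] = 1.0
        e = np.exp(theta[1:])
        for l in range(1, k):
            J[l:, l] = -e[l - 1]
        return J

    def initial(self, level: float = 0.0) -> np.ndarray:
        """A gently decreasing start at the given level."""
        th = np.full(self.k, np.log(0.1))
        th[0] = level
        return th


def scop_decreasing_design(x, k: int, degree: int = 3):
    """Shape-constrained (monotone non-increasing) B-spline basis.

    Returns a ``BasisBlock`` whose penalty acts on the *working* scale (a
    first-order difference penalty on the log-step parameters) together
    with the coefficient transform.
    """
    bb = bspline_design(x, k, degree)
    # first differences of the delta part; beta_1 and a common delta level
    # are unpenalized -> null space dimension 2
    D = np.zeros((k - 2, k))
    for i in range(k - 2):
        D[i, i + 1] = -1.0
        D[i, i + 2] = 1.0
    S = D.T @ D
    transform = ScopTransform(k)
    block = BasisBlock(design=bb.design, penalty=S, nullspace_dim=2,
                       kind="scop_decreasing", _evaluator=bb._evaluator,
                       meta=dict(bb.meta))
    return block, transform


def _tps_eta(r: np.ndarray) -> np.ndarray:
    """Radial basis for a 1-d thin-plate spline (cubic kernel)."""
    return np.abs(r) ** 3


def tps_design(x, k: int) -> BasisBlock:
    """1-d thin-plate regression spline of basis dimension ``k``.

    The radial basis ``|x - x_j|^3`` on the unique covariate values is
    eigen-truncated to its ``k - 2`` leading components; the unpenalized
    null space is {1, x}.  Column order: penalized columns first, then
    [1, x].
    """
    x = np.asarray(x, float)
    xu = np.unique(x)
    m = xu.size
    if m < 4:
        raise ValueError("thin-plate basis needs >= 4 unique covariates")
    if k > m:
        warnings.warn(f"tps basis dimension reduced from {k} to {m} "
                      f"(only {m} unique covariate values)")
        k = m
    if k < 3:
        raise ValueError("tps basis dimension must be >= 3")

    E = _tps_eta(xu[:, None] - xu[None, :])
    w, U = np.linalg.eigh(E)
    order = np.argsort(np.abs(w))[::-1]
    Uk = U[:, order[:k]]
    Dk = np.diag(w[order[:k]])
    T = np.column_stack([np.ones(m), xu])
    # absorb the side constraint T' delta = 0 (delta = Uk c)
    _, _, Vh = np.linalg.svd(T.T @ Uk)
    Z = Vh[2:].T                                   # (k, k-2)
    UZ = Uk @ Z                                    # (m, k-2)
    S_pen = _project_psd(Z.T @ Dk @ Z)
    lo, hi = xu[0], xu[-1]

    def ev(xnew):
        xc = np.clip(xnew, lo, hi)
        Xp = _tps_eta(xc[:, None] - xu[None, :]) @ UZ
        return np.column_stack([Xp, np.ones_like(xc), xc])

    S = np.zeros((k, k))
    S[:k - 2, :k - 2] = S_pen
    return BasisBlock(design=ev(x), penalty=S, nullspace_dim=2, kind="tps",
                      _evaluator=ev, meta={"x_unique": xu})


def factor_smooth_design(x, group_ids, k: int) -> BasisBlock:
    """Per-group thin-plate deviation smooths sharing one penalty.

    Builds a block-diagonal design of one thin-plate basis (dimension
    ``k``, including its {1, x} directions) per group.  The penalty is
    made full rank by placing a scaled identity (the mean positive
    penalty eigenvalue) on each group's null-space directions, so that
    as the shared smoothing parameter grows every group deviation —
    including its level and slope — shrinks to zero exactly.
    """
    x = np.asarray(x, float)
    group_ids = np.asarray(group_ids)
    groups = list(dict.fromkeys(group_ids.tolist()))   # preserve order
    if len(groups) < 2:
        raise ValueError("factor smooth needs >= 2 groups")

    sub_ev, sub_S, widths = {}, {}, {}
    for g in groups:
        xg = x[group_ids == g]
        if np.unique(xg).size < max(3, 4):
            warnings.warn(f"group {g!r} has too few points; reduced to an "
                          f"intercept-free shrinkage term")
            xg0 = xg if xg.size else np.array([0.0])
            scale = max(np.max(np.abs(xg0)), 1.0)

            def ev_small(xnew, _s=scale):
                return (xnew / _s)[:, None]

            sub_ev[g] = ev_small
            sub_S[g] = np.array([[1.0]])
            widths[g] = 1
        else:
            bb = tps_design(xg, k)
            pen = bb.penalty.copy()
            kk = bb.k
            ew = np.linalg.eigvalsh(pen)
            pos = ew[ew > 1e-10 * max(ew.max(), 1e-300)]
            sbar = float(pos.mean()) if pos.size else 1.0
            pen[kk - 2:, kk - 2:] = sbar * np.eye(2)
            sub_ev[g] = bb._evaluator
            sub_S[g] = pen
            widths[g] = kk

    total = sum(widths[g] for g in groups)
    S = np.zeros((total, total))
    offs = {}
    pos = 0
    for g in groups:
        offs[g] = pos
        w = widths[g]
        S[pos:pos + w, pos:pos + w] = sub_S[g]
        pos += w

    def ev(xnew, gnew):
        gnew = np.asarray(gnew)
        X = np.zeros((xnew.size, total))
        for g in groups:
            mask = gnew == g
            if mask.any():
                X[np.ix_(mask, range(offs[g], offs[g] + widths[g]))] = \
                    sub_ev[g](xnew[mask])
        return X

    return BasisBlock(design=ev(x, group_ids), penalty=S, nullspace_dim=0,
                      kind="factor_smooth", _evaluator=ev,
                      meta={"groups": groups, "widths": widths,
                            "offsets": offs})
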