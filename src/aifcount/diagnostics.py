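"""Residual-based model criticism for fitted count models.

Randomized quantile residuals are exactly standard normal under a
correctly specified discrete model, which turns the usual visual Q-Q
check for overdispersion into assertable numbers (Q-Q slope, KS
statistic, residual standard deviation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .engine import PenalizedFit


@dataclass
class ResidualSet:
    """Randomized quantile residuals plus summary statistics."""

    residuals: np.ndarray
    seed: int
    family: str
    mean: float
    sd: float
    ks_stat: float
    ks_pvalue: float
    qq_slope: float

    def __len__(self):
        return self.residuals.size


def _as_engine_fit(fit) -> PenalizedFit:
    return fit.fit if hasattr(fit, "fit") and \
        isinstance(fit.fit, PenalizedFit) else fit


def randomized_quantile_residuals(fit, seed: int) -> ResidualSet:
    """Dunn-Smyth residuals: r_i = Phi^-1(u_i), u_i ~ U(F(y_i - 1), F(y_i)).

    ``F`` is the fitted family's CDF at the fitted mean.  Deterministic
    given the seed.
    """
    pf = _as_engine_fit(fit)
    y = np.asarray(pf.y, float)
    mu = np.asarray(pf.mu, float)
    fam = pf.family
    rng = np.random.default_rng(seed)
    lo = fam.cdf(y - 1.0, mu)
    hi = fam.cdf(y, mu)
    u = rng.uniform(lo, np.maximum(hi, lo + 1e-300))
    u = np.clip(u, 1e-12, 1 - 1e-12)
    r = stats.norm.ppf(u)
    ks = stats.kstest(r, "norm")
    slope, _, _ = _qq_fit(r)
    return ResidualSet(residuals=r, seed=seed, family=fam.name,
                       mean=float(np.mean(r)), sd=float(np.std(r, ddof=1)),
                       ks_stat=float(ks.statistic),
                       ks_pvalue=float(ks.pvalue), qq_slope=slope)


def _qq_fit(residuals: np.ndarray):
    n = residuals.size
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    emp = np.sort(residuals)
    slope, intercept = np.polyfit(theo, emp, 1)
    return float(slope), float(intercept), (theo, emp)


def qq_summary(residual_set: ResidualSet):
    """(slope, intercept, ks_stat) of the normal Q-Q line, + plot data.

    Ordered residuals are regressed on standard-normal quantiles; the
    plot data (theoretical vs empirical quantiles) is returned as a
    DataFrame suitable for TSV export.
    """
    r = residual_set.residuals
    if r.size < 10:
        raise ValueError("need at least 10 residuals")
    slope, intercept, (theo, emp) = _qq_fit(r)
    plot = pd.DataFrame({"theoretical": theo, "empirical": emp})
    return slope, intercept, residual_set.ks_stat, plot


def pearson_dispersion(fit) -> float:
    """Pearson dispersion: sum (y - mu)^2 / V(mu) / (n - edf).

    Near 1 when the family's mean-variance relation matches the data;
    well above 1 under a Poisson fit to overdispersed counts.
    """
    pf = _as_engine_fit(fit)
    y = np.asarray(pf.y, float)
    mu = np.asarray(pf.mu, float)
    V = pf.family.variance(mu)
    n = y.size
    denom = max(n - pf.edf_coef, 1.0)
    return float(np.sum((y - mu) ** 2 / V) / denom)
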