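"""Exposure offsets: every known multiplicative factor between the
decay-corrected parent-plasma rate and the expected measured counts.

The model convention is fixed as

    expected counts = f(t_i) * tau_i,

where ``f`` is the decay-corrected parent-plasma concentration (counts
per second per mL, at injection-time calibration) and ``tau_i`` is the
product of: counting duration, sample volume, the gamma-counter volume
calibration ``exp(rho * vol)``, radioactive decay, the ABSS dispersion
component (measured / dispersion-corrected, mapping the true rate to the
measured expectation), the whole-blood-to-plasma ratio (for whole-blood
samples), and the reciprocal of the parent fraction.  The model offset is
``log(tau_i)``, the sum of the logs of all components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.integrate import cumulative_trapezoid

from .blood_data import Examination, BloodSample, moving_average
from . import engine
from .bases import tps_design

_COMPONENTS = ("duration_s", "volume_mL", "vol_calibration", "decay",
               "dispersion_component", "bpr", "inv_parent_fraction")


@dataclass(frozen=True)
class OffsetVector:
    """Per-sample multiplicative exposure components (each > 0)."""

    duration_s: float
    volume_mL: float
    vol_calibration: float
    decay: float
    dispersion_component: float
    bpr: float
    inv_parent_fraction: float

    def __post_init__(self):
        for name in _COMPONENTS:
            v = getattr(self, name)
            if not (v > 0 and np.isfinite(v)):
                raise ValueError(f"offset component {name} must be positive "
                                 f"and finite, got {v!r}")

    @property
    def tau(self) -> float:
        return float(np.prod([getattr(self, c) for c in _COMPONENTS]))

    @property
    def log_tau_total(self) -> float:
        return float(sum(np.log(getattr(self, c)) for c in _COMPONENTS))


def log_tau(offsets: Sequence[OffsetVector]) -> np.ndarray:
    return np.array([o.log_tau_total for o in offsets])


def offsets_to_frame(exam: Examination,
                     offsets: Sequence[OffsetVector]) -> pd.DataFrame:
    """Per-sample offset audit table."""
    rows = []
    for s, o in zip(exam.post_samples, offsets):
        row = {"time_min": s.time_min, "detector": s.detector,
               "compartment": s.compartment}
        row.update({c: getattr(o, c) for c in _COMPONENTS})
        row["log_tau_total"] = o.log_tau_total
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# elementary components
# ---------------------------------------------------------------------------

def decay_factor(t_min, half_life_min: float):
    """Fraction of activity remaining at the draw time: 2^(-t / T_half)."""
    if half_life_min <= 0:
        raise ValueError("half-life must be positive")
    t = np.asarray(t_min, float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    out = np.exp2(-t / half_life_min)
    return float(out) if np.isscalar(t_min) else out


def volume_calibration_factor(volume_mL, rho_per_mL: float):
    """Gamma-counter linearity calibration exp(rho * vol)."""
    v = np.asarray(volume_mL, float)
    out = np.exp(rho_per_mL * v)
    return float(out) if np.isscalar(volume_mL) else out


def _check_uniform(times_s: np.ndarray) -> float:
    dt = np.diff(times_s)
    if dt.size == 0 or np.any(dt <= 0):
        raise ValueError("need an increasing grid of at least 2 points")
    if np.max(np.abs(dt - dt[0])) > 1e-6 * dt[0]:
        raise ValueError("dispersion correction requires a uniform time "
                         "grid: resample first")
    return float(dt[0])


def dispersion_correct(times_s, values, kappa_s: float) -> np.ndarray:
    """Deconvolve external (tubing) dispersion from an ABSS series.

    The measured concentration lags the true one through an exponential
    sticking kernel with time constant ``kappa_s``; the cumulative
    relation  int_0^t C_true = kappa * C_meas(t) + int_0^t C_meas  is
    evaluated with trapezoidal integration on the uniform grid, then
    differentiated by central differences over 2*dt (one-sided at the
    endpoints) to recover the corrected series.
    """
    times_s = np.asarray(times_s, float)
    values = np.asarray(values, float)
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    if kappa_s < 0:
        raise ValueError("kappa must be >= 0")
    if kappa_s == 0:
        return values.copy()
    dt = _check_uniform(times_s)
    I_meas = cumulative_trapezoid(values, dx=dt, initial=0.0)
    I_true = kappa_s * values + I_meas
    out = np.empty_like(values)
    out[1:-1] = (I_true[2:] - I_true[:-2]) / (2 * dt)
    out[0] = (I_true[1] - I_true[0]) / dt
    out[-1] = (I_true[-1] - I_true[-2]) / dt
    return out


def dispersion_offset_component(corrected: float, uncorrected: float,
                                detector: str, time_min: float,
                                cutoff_min: float = 10.0) -> float:
    """Offset factor mapping the true rate to the measured expectation.

    ABSS samples (and manual samples drawn through the tubing, i.e. at or
    before the cutoff) get ``uncorrected / corrected``; manual samples
    after the cutoff bypass the tubing and get exactly 1.
    """
    if detector == "manual" and time_min > cutoff_min:
        return 1.0
    if corrected <= 0 or uncorrected <= 0:
        raise ValueError("corrected and uncorrected values must be positive")
    return float(uncorrected) / float(corrected)


def build_dispersion_table(exam: Examination,
                           window: int = 31) -> Optional[pd.DataFrame]:
    """Dispersion-correction table from the ABSS stream of one exam.

    The counts-per-second series is smoothed (moving average) before
    correction, and the resulting correction factor is smoothed again
    over the same window, because the deconvolution differentiates the
    series and therefore amplifies counting noise.  The corrected series
    is also bounded to within a factor of 5 of the measured one: the
    exponential tubing kernel can only redistribute signal on the kappa
    timescale, so larger excursions are amplified noise, not dispersion.
    The true factor varies slowly away from the bolus peak, so the heavy
    smoothing costs little bias on the descent while suppressing most of
    the variance.  Returns a frame with columns time_s, uncorrected,
    corrected, or None when there is no ABSS stream or kappa == 0.
    """
    abss = exam.stream("abss")
    if len(abss) < 3 or exam.kappa_s == 0:
        return None
    t_s = np.array([s.time_min * 60.0 for s in abss])
    cps = moving_average(np.array([s.cps for s in abss]), window)
    cps = np.maximum(cps, 1e-6 * max(cps.max(), 1.0))
    corrected = dispersion_correct(t_s, cps, exam.kappa_s)
    corrected = np.clip(corrected, cps / 5.0, cps * 5.0)
    factor = moving_average(cps / corrected, window)
    corrected = cps / np.clip(factor, 0.2, 5.0)
    return pd.DataFrame({"time_s": t_s, "uncorrected": cps,
                         "corrected": corrected})


def write_dispersion_table(table: pd.DataFrame, path):
    table.to_csv(path, sep="\t", index=False)


def read_dispersion_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# parent fraction sigmoid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PFSigmoidParams:
    """Hill-type parent-fraction sigmoid pf(t) = a + (1-a)/(1+(t/t50)^k).

    ``a`` is the late-time floor, ``t50_min`` the time at which the
    metabolized fraction is halfway to the floor, ``k`` the steepness.
    pf(0) = 1 and pf is non-increasing.
    """

    a: float
    t50_min: float
    k: float

    def __post_init__(self):
        if not (0 <= self.a < 1):
            raise ValueError("floor a must be in [0, 1)")
        if self.t50_min <= 0 or self.k <= 0:
            raise ValueError("t50 and k must be positive")

    def __call__(self, t):
        t = np.asarray(t, float)
        if np.any(t < 0):
            raise ValueError("time must be >= 0")
        out = self.a + (1 - self.a) / (1.0 + (t / self.t50_min) ** self.k)
        return float(out) if out.ndim == 0 else out


def fit_parent_fraction(pf_measurements,
                        n_starts: int = 6) -> PFSigmoidParams:
    """Bounded least-squares fit of the parent-fraction sigmoid.

    Multi-start over a log-grid of t50 candidates to avoid local optima.
    """
    pts = [(float(t), float(p)) for t, p in pf_measurements]
    if len(pts) < 3:
        raise ValueError("need at least 3 parent-fraction measurements")
    t = np.array([p[0] for p in pts])
    pf = np.array([p[1] for p in pts])
    if np.any(t <= 0) or np.any((pf < 0) | (pf > 1)):
        raise ValueError("times must be > 0 and fractions in [0, 1]")

    def resid(par):
        a, log_t50, log_k = par
        model = a + (1 - a) / (1.0 + (t / np.exp(log_t50)) ** np.exp(log_k))
        return model - pf

    a0 = float(np.clip(pf.min() * 0.8, 0.0, 0.9))
    best = None
    for t50 in np.geomspace(max(t.min(), 0.5), t.max(), n_starts):
        for k0 in (1.0, 2.0):
            try:
                res = optimize.least_squares(
                    resid, x0=[a0, np.log(t50), np.log(k0)],
                    bounds=([0.0, np.log(1e-3), np.log(1e-2)],
                            [1 - 1e-9, np.log(1e4), np.log(50.0)]))
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
    if best is None:
        raise engine.FitError("parent-fraction sigmoid fit failed from "
                              "every start")
    a, log_t50, log_k = best.x
    return PFSigmoidParams(a=float(a), t50_min=float(np.exp(log_t50)),
                           k=float(np.exp(log_k)))


# ---------------------------------------------------------------------------
# whole-blood-to-plasma ratio
# ---------------------------------------------------------------------------

@dataclass
class BPRModel:
    """Fitted whole-blood-to-plasma ratio r(t) (> 0 on the data range).

    Either a penalized thin-plate smooth or, with too few paired samples,
    a time-constant mean ratio.  Extrapolation beyond the sampled range is
    constant at the boundary value.
    """

    predictor: Callable
    constant: bool
    basis_dim: int
    sp: float
    n_pairs: int

    def __call__(self, t):
        t = np.asarray(t, float)
        scalar = t.ndim == 0
        r = self.predictor(np.atleast_1d(t))
        r = np.maximum(r, 1e-6)
        return float(r[0]) if scalar else r


def _paired_ratios(exam: Examination):
    """(time, wb/plasma cps-per-mL ratio) for paired manual samples.

    Whole-blood and plasma aliquots of the same draw share a draw time,
    so decay cancels in the ratio; the gamma-counter volume calibration
    is applied to each before the ratio is formed.
    """
    manual = exam.stream("manual")
    wb = {s.time_min: s for s in manual if s.compartment == "whole_blood"}
    pl = {s.time_min: s for s in manual if s.compartment == "plasma"}
    times, ratios = [], []
    for tm in sorted(set(wb) & set(pl)):
        sw, sp_ = wb[tm], pl[tm]
        num = sw.cps / (sw.volume_mL *
                        volume_calibration_factor(sw.volume_mL,
                                                  exam.rho_per_mL))
        den = sp_.cps / (sp_.volume_mL *
                         volume_calibration_factor(sp_.volume_mL,
                                                   exam.rho_per_mL))
        if den > 0:
            times.append(tm)
            ratios.append(num / den)
    return np.array(times), np.array(ratios)


def fit_bpr(exam: Examination, basis_dim: int = 10) -> BPRModel:
    """Penalized thin-plate smooth of the whole-blood/plasma ratio vs time.

    Needs >= 4 paired manual samples; with fewer, falls back to a
    time-constant mean ratio (with a warning).
    """
    times, ratios = _paired_ratios(exam)
    n = times.size
    if n < 4:
        warnings.warn(f"only {n} paired whole-blood/plasma samples: "
                      f"using a time-constant mean ratio")
        mean = float(np.mean(ratios)) if n else 1.0
        return BPRModel(predictor=lambda t: np.full(len(t), mean),
                        constant=True, basis_dim=0, sp=np.inf, n_pairs=n)
    k = min(basis_dim, n)
    block = tps_design(times, k)
    fit = engine.gaussian_reml_fit([block], ratios)
    beta = fit.coef

    def predictor(t):
        return block.evaluate(t) @ beta

    return BPRModel(predictor=predictor, constant=False, basis_dim=k,
                    sp=float(fit.sp[0]), n_pairs=n)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def assemble_offsets(exam: Examination,
                     bpr_model: Optional[BPRModel] = None,
                     pf_params: Optional[PFSigmoidParams] = None,
                     dispersion_table: Optional[pd.DataFrame] = None
                     ) -> list:
    """Per-sample offset vectors for every post-injection sample.

    ``tau_i = duration * volume * e^(rho vol) * 2^(-t/T_half) *
    dispersion_component * bpr_component / PF(t)``.  The blood-to-plasma
    ratio applies to whole-blood samples only (1 for plasma); the parent
    fraction divides every sample; the dispersion component applies to
    ABSS samples and to manual samples drawn through the tubing (at or
    before the cutoff).
    """
    if dispersion_table is not None:
        dt_t = dispersion_table["time_s"].to_numpy() / 60.0
        factor = (dispersion_table["uncorrected"].to_numpy()
                  / dispersion_table["corrected"].to_numpy())
        if np.any(~np.isfinite(factor)) or np.any(factor <= 0):
            raise ValueError("dispersion table yields non-positive "
                             "correction factors")
    out = []
    for i, s in enumerate(exam.post_samples):
        if dispersion_table is not None and (
                s.detector == "abss"
                or (s.detector == "manual"
                    and s.time_min <= exam.abss_cutoff_min)):
            disp = float(np.interp(s.time_min, dt_t, factor))
        else:
            disp = 1.0
        bpr = 1.0
        if s.compartment == "whole_blood" and bpr_model is not None:
            bpr = float(bpr_model(s.time_min))
        pf = 1.0 if pf_params is None else float(pf_params(s.time_min))
        try:
            out.append(OffsetVector(
                duration_s=s.duration_s,
                volume_mL=s.volume_mL,
                vol_calibration=float(volume_calibration_factor(
                    s.volume_mL, exam.rho_per_mL)),
                decay=float(decay_factor(s.time_min, exam.half_life_min)),
                dispersion_component=disp,
                bpr=bpr,
                inv_parent_fraction=1.0 / pf if pf > 0 else np.inf,
            ))
        except ValueError as err:
            raise ValueError(
                f"sample {i} (t = {s.time_min} min, {s.detector}, "
                f"{s.compartment}): {err}") from None
    return out
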