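"""Synthetic blood-count examinations with known ground truth.

Emulates a typical carbon-11 PET blood-sampling protocol: an automatic
blood sampling system (ABSS) recording whole-blood counts each second for
the first 10 minutes, manual whole-blood and plasma samples at 1, 3, 5,
7, 9, 10.5, 20, 30, 40, 50, 60, 70, 80 and 90 minutes, and parent-
fraction measurements at 1, 3, 5, 10.5, 20, 40, 60 and 90 minutes.  The
decay-corrected parent-plasma curve ascends linearly from injection to a
peak and then follows a tri-exponential descent; whole-blood and total-
plasma compartments are composed through the blood-to-plasma ratio and
the parent fraction; the ABSS stream is forward-dispersed through an
exponential tubing kernel, scaled by a multiplicative detector bias, and
receives Poisson background counts.  Counts are drawn from a Poisson or
negative-binomial family.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

from .blood_data import BloodSample, Examination, replace_samples
from .engine import Family, TriExpParams
from .offsets import PFSigmoidParams, decay_factor, \
    volume_calibration_factor

#: manual draw times (minutes post injection)
MANUAL_TIMES_MIN = (1.0, 3.0, 5.0, 7.0, 9.0, 10.5, 20.0, 30.0, 40.0,
                    50.0, 60.0, 70.0, 80.0, 90.0)
#: parent-fraction measurement times (minutes post injection)
PF_TIMES_MIN = (1.0, 3.0, 5.0, 10.5, 20.0, 40.0, 60.0, 90.0)

#: default tri-exponential descent, counts/s/mL at injection calibration;
#: chosen so the first manual whole-blood sample expects ~1e5 counts
DEFAULT_TRUTH = TriExpParams(A=(4000.0, 800.0, 150.0),
                             gamma=(3.0, 0.3, 0.03))


def default_bpr(t):
    """Whole-blood-to-plasma ratio drifting from 1.0 toward 0.8."""
    return 0.8 + 0.2 * np.exp(-np.asarray(t, float) / 20.0)


@dataclass
class SimConfig:
    """Generator configuration; defaults emulate the reference protocol."""

    truth: TriExpParams = DEFAULT_TRUTH
    peak_time_min: float = 0.7
    bpr_fn: Callable = default_bpr
    pf: PFSigmoidParams = PFSigmoidParams(a=0.05, t50_min=10.0, k=2.0)
    family: str = "poisson"
    psi: float = 0.0
    abss_bias: float = 1.10
    abss_rate_hz: float = 1.0
    abss_window_min: float = 10.0
    manual_times_min: tuple = MANUAL_TIMES_MIN
    pf_times_min: tuple = PF_TIMES_MIN
    manual_wb_volume_range: tuple = (1.0, 3.0)
    plasma_volume_range: tuple = (0.8, 1.5)
    abss_volume_mL: float = 0.01
    manual_duration_s: float = 60.0
    kappa_s: float = 2.5
    rho_per_mL: float = 0.0
    background_rate_cps: float = 1.0
    half_life_min: float = 20.36
    pre_injection_s: int = 30
    pf_noise_sd: float = 0.01
    abss_cutoff_min: float = 10.0
    seed: int = 0

    def __post_init__(self):
        for name in ("peak_time_min", "abss_rate_hz", "abss_window_min",
                     "abss_volume_mL", "manual_duration_s", "half_life_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("psi", "kappa_s", "background_rate_cps",
                     "pf_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.abss_bias <= 0:
            raise ValueError("abss_bias must be positive")
        if list(self.manual_times_min) != sorted(self.manual_times_min):
            raise ValueError("manual_times_min must be sorted")
        if list(self.pf_times_min) != sorted(self.pf_times_min):
            raise ValueError("pf_times_min must be sorted")
        if self.family not in ("poisson", "negbin"):
            raise ValueError("family must be poisson or negbin")

    def curve(self, t):
        """True decay-corrected parent-plasma rate, ascent included."""
        t = np.atleast_1d(np.asarray(t, float))
        peak = self.peak_time_min
        f_peak = float(self.truth(peak))
        out = np.where(t >= peak, self.truth(np.maximum(t, peak)),
                       f_peak * t / peak)
        return out

    def family_obj(self) -> Family:
        return Family(self.family, self.psi)


@dataclass
class GroundTruth:
    """Simulation ledger: the true quantities behind one examination."""

    config: SimConfig
    curve: Callable
    bpr_fn: Callable
    pf: PFSigmoidParams
    abss_bias: float
    psi: float
    peak_time_min: float
    lambda_by_sample: np.ndarray = field(repr=False, default=None)

    def descent(self, t):
        """True descent curve (the tri-exponential) at times >= the peak."""
        return self.config.truth(t)


def apply_forward_dispersion(times_s, values, kappa_s: float) -> np.ndarray:
    """Convolve a series with the exponential tubing kernel.

    The kernel ``(1/kappa) exp(-t/kappa)`` is discretized on the uniform
    grid and normalized to unit sum (mass conservation); ``kappa = 0`` is
    the identity.
    """
    times_s = np.asarray(times_s, float)
    values = np.asarray(values, float)
    if kappa_s < 0:
        raise ValueError("kappa must be >= 0")
    if kappa_s == 0:
        return values.copy()
    dt = np.diff(times_s)
    if dt.size and np.max(np.abs(dt - dt[0])) > 1e-6 * dt[0]:
        raise ValueError("forward dispersion requires a uniform grid")
    step = dt[0] if dt.size else 1.0
    n_kernel = int(np.ceil(-np.log(1e-12) * kappa_s / step)) + 1
    j = np.arange(n_kernel)
    w = np.exp(-j * step / kappa_s)
    w /= w.sum()
    return np.convolve(values, w)[:values.size]


def simulate_examination(config: SimConfig,
                         seed: Optional[int] = None,
                         exam_id: str = "sim"):
    """Generate one synthetic examination and its ground truth.

    Returns ``(Examination, GroundTruth)``; ``GroundTruth.lambda_by_sample``
    is aligned with ``exam.samples`` and includes the ABSS background mean.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    fam = config.family_obj()
    pf, bpr = config.pf, config.bpr_fn
    T = config.half_life_min

    samples = []
    lam_list = []

    # pre-injection ABSS background segment
    step_s = 1.0 / config.abss_rate_hz
    bg_per_sample = config.background_rate_cps * step_s
    for _ in range(config.pre_injection_s):
        lam = bg_per_sample
        counts = int(rng.poisson(lam))
        samples.append(BloodSample(0.0, counts, step_s, config.abss_volume_mL,
                                   "abss", "whole_blood", pre_injection=True))
        lam_list.append(lam)

    # ABSS stream: uniform grid from injection, sampled each step
    n_abss = int(round(config.abss_window_min * 60.0 / step_s))
    grid_s = np.arange(0, n_abss + 1) * step_s
    grid_min = grid_s / 60.0
    parent = config.curve(grid_min)
    wb_true = parent / pf(grid_min) * bpr(grid_min) \
        * decay_factor(grid_min, T)
    wb_disp = apply_forward_dispersion(grid_s, wb_true, config.kappa_s)
    disp_ratio = np.ones_like(wb_true)
    pos = wb_true > 0
    disp_ratio[pos] = wb_disp[pos] / wb_true[pos]

    abss_lam = (wb_disp[1:] * config.abss_bias * config.abss_volume_mL
                * step_s)
    abss_counts = fam.rvs(np.maximum(abss_lam, 1e-12), rng) \
        + rng.poisson(bg_per_sample, size=n_abss)
    for i in range(n_abss):
        samples.append(BloodSample(float(grid_min[i + 1]),
                                   int(abss_counts[i]), step_s,
                                   config.abss_volume_mL, "abss",
                                   "whole_blood"))
        lam_list.append(float(abss_lam[i] + bg_per_sample))

    # manual whole-blood + plasma pairs; samples drawn through the ABSS
    # tubing (t <= cutoff) inherit the dispersion time-profile
    for tm in config.manual_times_min:
        f_t = float(config.curve(tm)[0] if np.ndim(config.curve(tm))
                    else config.curve(tm))
        pf_t = float(pf(tm))
        dk = float(decay_factor(tm, T))
        if tm <= config.abss_cutoff_min:
            d_t = float(np.interp(tm, grid_min, disp_ratio))
        else:
            d_t = 1.0
        v_wb = rng.uniform(*config.manual_wb_volume_range)
        v_pl = rng.uniform(*config.plasma_volume_range)
        dur = config.manual_duration_s
        lam_wb = (f_t / pf_t * float(bpr(tm)) * dk * d_t * v_wb * dur
                  * volume_calibration_factor(v_wb, config.rho_per_mL))
        lam_pl = (f_t / pf_t * dk * d_t * v_pl * dur
                  * volume_calibration_factor(v_pl, config.rho_per_mL))
        for lam, vol, comp in ((lam_wb, v_wb, "whole_blood"),
                               (lam_pl, v_pl, "plasma")):
            counts = int(fam.rvs(np.array([max(lam, 1e-12)]), rng)[0])
            samples.append(BloodSample(tm, counts, dur, vol, "manual", comp))
            lam_list.append(lam)

    pf_meas = []
    for tm in config.pf_times_min:
        val = float(pf(tm)) + rng.normal(0.0, config.pf_noise_sd)
        pf_meas.append((tm, float(np.clip(val, 1e-4, 1.0))))

    exam = Examination(
        exam_id=exam_id, samples=samples, pf_measurements=pf_meas,
        half_life_min=T, kappa_s=config.kappa_s,
        rho_per_mL=config.rho_per_mL,
        abss_cutoff_min=config.abss_cutoff_min)
    truth = GroundTruth(
        config=config, curve=config.curve, bpr_fn=bpr, pf=pf,
        abss_bias=config.abss_bias, psi=fam.effective_psi,
        peak_time_min=config.peak_time_min,
        lambda_by_sample=np.array(lam_list))
    return exam, truth


def true_offsets(exam: Examination, truth: GroundTruth):
    """Exact per-sample offsets from the generator's own nuisance functions.

    Returns a list of :class:`~aifcount.offsets.OffsetVector` aligned with
    ``exam.samples`` (pre-injection samples excluded), built from the true
    parent fraction, blood-to-plasma ratio, decay and dispersion profile
    rather than from estimates.  Useful for studying an estimator in the
    known-offsets setting, where the only stochasticity is counting noise.
    """
    from .offsets import OffsetVector

    cfg = truth.config
    step_s = 1.0 / cfg.abss_rate_hz
    n_abss = int(round(cfg.abss_window_min * 60.0 / step_s))
    grid_s = np.arange(0, n_abss + 1) * step_s
    grid_min = grid_s / 60.0
    wb_true = cfg.curve(grid_min) / cfg.pf(grid_min) \
        * cfg.bpr_fn(grid_min) * decay_factor(grid_min, cfg.half_life_min)
    wb_disp = apply_forward_dispersion(grid_s, wb_true, cfg.kappa_s)
    ratio = np.ones_like(wb_true)
    pos = wb_true > 0
    ratio[pos] = wb_disp[pos] / wb_true[pos]

    out = []
    for s in exam.samples:
        if s.pre_injection:
            continue
        through_tubing = (s.detector == "abss"
                          or s.time_min <= exam.abss_cutoff_min)
        disp = float(np.interp(s.time_min, grid_min, ratio)) \
            if through_tubing else 1.0
        out.append(OffsetVector(
            duration_s=s.duration_s, volume_mL=s.volume_mL,
            vol_calibration=volume_calibration_factor(
                s.volume_mL, cfg.rho_per_mL),
            decay=float(decay_factor(s.time_min, cfg.half_life_min)),
            dispersion_component=disp,
            bpr=float(cfg.bpr_fn(s.time_min))
            if s.compartment == "whole_blood" else 1.0,
            inv_parent_fraction=1.0 / float(cfg.pf(s.time_min))))
    return out


def make_missing(exam: Examination, pattern: str,
                 drop_abss: bool = True) -> Examination:
    """Reduce an examination to two manual samples (a missing-data case).

    ``pattern`` selects which two manual draw times survive:
    ``first_last``, ``first_two`` or ``last_two``.  Both compartments of a
    surviving draw are kept; the ABSS stream is dropped by default;
    parent-fraction measurements are retained.  Idempotent.
    """
    manual_times = sorted({s.time_min for s in exam.stream("manual")})
    if len(manual_times) < 2:
        raise ValueError("need at least 2 manual draw times")
    if pattern == "first_last":
        keep = {manual_times[0], manual_times[-1]}
    elif pattern == "first_two":
        keep = set(manual_times[:2])
    elif pattern == "last_two":
        keep = set(manual_times[-2:])
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    kept = []
    for s in exam.samples:
        if s.detector == "abss":
            if not drop_abss:
                kept.append(s)
        elif s.time_min in keep:
            kept.append(s)
    return replace_samples(exam, kept)
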