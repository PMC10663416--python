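"""Per-sample blood count records: data model, table I/O and preprocessing.

An *examination* is the full series of blood samples recorded while a
participant is in the PET system; a *sample* is one blood draw (or one
second of the automatic sampling system, ABSS).  Counts are kept raw —
corrections are applied later as model offsets, not to the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

DETECTORS = ("abss", "manual")
COMPARTMENTS = ("whole_blood", "plasma")

TABLE_COLUMNS = [
    "time_min", "counts", "duration_s", "volume_mL",
    "detector", "compartment", "pre_injection",
]


class SchemaError(ValueError):
    """Input table does not conform to the expected column schema."""


class ValidationError(ValueError):
    """A row or field violates a data invariant."""


@dataclass(frozen=True)
class BloodSample:
    """One blood sample: raw gamma counts plus its exposure metadata.

    Parameters
    ----------
    time_min : float
        Draw time in minutes post injection (>= 0).
    counts : int
        Recorded gamma counts (non-negative integer).
    duration_s : float
        Counting duration in seconds (> 0).
    volume_mL : float
        Sample volume in millilitres (> 0).
    detector : {"abss", "manual"}
    compartment : {"whole_blood", "plasma"}
        ABSS samples are always whole blood.
    pre_injection : bool
        True for samples recorded before tracer injection; these are used
        only to estimate the detector background rate.
    """

    time_min: float
    counts: int
    duration_s: float
    volume_mL: float
    detector: str
    compartment: str
    pre_injection: bool = False

    def __post_init__(self):
        if self.detector not in DETECTORS:
            raise ValidationError(f"unknown detector {self.detector!r}")
        if self.compartment not in COMPARTMENTS:
            raise ValidationError(f"unknown compartment {self.compartment!r}")
        if not float(self.counts).is_integer() or self.counts < 0:
            raise ValidationError(
                f"counts must be a non-negative integer, got {self.counts!r}")
        if self.duration_s <= 0:
            raise ValidationError("duration_s must be > 0")
        if self.volume_mL <= 0:
            raise ValidationError("volume_mL must be > 0")
        if self.time_min < 0:
            raise ValidationError("time_min must be >= 0")
        if self.detector == "abss" and self.compartment != "whole_blood":
            raise ValidationError("ABSS samples must be whole blood")

    @property
    def cps(self) -> float:
        """Raw count rate (counts per second)."""
        return self.counts / self.duration_s


@dataclass
class Examination:
    """All blood samples and instrument constants for one PET examination.

    Attributes
    ----------
    exam_id : str
    samples : list of BloodSample
        Ordered; times must be non-decreasing within each detector stream.
    pf_measurements : list of (time_min, parent_fraction)
        Measured plasma parent fractions, values in [0, 1].
    half_life_min : float
        Radioisotope half-life in minutes.
    kappa_s : float
        External-dispersion constant of the ABSS tubing, seconds.
    rho_per_mL : float
        Gamma-counter volume-calibration factor (exponent per mL).
    abss_cutoff_min : float
        Time after which manual samples are drawn directly from the cannula
        and bypass the ABSS tubing (default 10 min).
    """

    exam_id: str
    samples: list = field(default_factory=list)
    pf_measurements: list = field(default_factory=list)
    half_life_min: float = 20.36
    kappa_s: float = 2.5
    rho_per_mL: float = 0.0
    abss_cutoff_min: float = 10.0

    def __post_init__(self):
        self.validate()

    def validate(self):
        if self.half_life_min <= 0:
            raise ValidationError("half_life_min must be > 0")
        if self.kappa_s < 0:
            raise ValidationError("kappa_s must be >= 0")
        for t, pf in self.pf_measurements:
            if not (0.0 <= pf <= 1.0):
                raise ValidationError(
                    f"parent fraction {pf} at t={t} outside [0, 1]")
        for det in DETECTORS:
            times = [s.time_min for s in self.samples
                     if s.detector == det and not s.pre_injection]
            if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
                raise ValidationError(
                    f"{det} sample times are not non-decreasing")
        if self.samples and not any(
                not s.pre_injection for s in self.samples):
            raise ValidationError("no post-injection samples")

    # -- convenience accessors -------------------------------------------
    def stream(self, detector: str, *, post_injection: bool = True):
        """Samples of one detector, optionally post-injection only."""
        return [s for s in self.samples if s.detector == detector
                and (not post_injection or not s.pre_injection)]

    @property
    def post_samples(self):
        return [s for s in self.samples if not s.pre_injection]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{c: getattr(s, c) for c in TABLE_COLUMNS} for s in self.samples]
        )

    def constants(self) -> dict:
        return {
            "exam_id": self.exam_id,
            "half_life_min": self.half_life_min,
            "kappa_s": self.kappa_s,
            "rho_per_mL": self.rho_per_mL,
            "abss_cutoff_min": self.abss_cutoff_min,
            "pf_measurements": [[float(t), float(p)]
                                for t, p in self.pf_measurements],
        }


def _samples_from_frame(df: pd.DataFrame):
    samples = []
    for idx, row in df.iterrows():
        c = row["counts"]
        cf = float(c)
        if not cf.is_integer():
            raise ValidationError(f"row {idx}: counts {c!r} is not integral")
        try:
            samples.append(BloodSample(
                time_min=float(row["time_min"]),
                counts=int(cf),
                duration_s=float(row["duration_s"]),
                volume_mL=float(row["volume_mL"]),
                detector=str(row["detector"]),
                compartment=str(row["compartment"]),
                pre_injection=bool(row["pre_injection"]),
            ))
        except ValidationError as err:
            raise ValidationError(f"row {idx}: {err}") from None
    return samples


def parse_blood_table(table_path, constants) -> Examination:
    """Read a per-sample blood table (CSV or TSV) into an ``Examination``.

    ``constants`` is a dict (or path to a JSON file) supplying at least
    ``half_life_min``, ``kappa_s`` and ``rho_per_mL``; it may also supply
    ``exam_id``, ``abss_cutoff_min`` and ``pf_measurements``.
    Row order is preserved within each detector stream.
    """
    path = Path(table_path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    if isinstance(constants, (str, Path)):
        constants = json.loads(Path(constants).read_text())
    for key in ("half_life_min", "kappa_s", "rho_per_mL"):
        if key not in constants:
            raise SchemaError(f"constants block missing {key!r}")
    return Examination(
        exam_id=str(constants.get("exam_id", path.stem)),
        samples=_samples_from_frame(df),
        pf_measurements=[tuple(x) for x in
                         constants.get("pf_measurements", [])],
        half_life_min=float(constants["half_life_min"]),
        kappa_s=float(constants["kappa_s"]),
        rho_per_mL=float(constants["rho_per_mL"]),
        abss_cutoff_min=float(constants.get("abss_cutoff_min", 10.0)),
    )


def write_examination(exam: Examination, table_path, constants_path=None):
    """Write an examination back to a table (+ optional JSON constants)."""
    path = Path(table_path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    exam.to_frame().to_csv(path, sep=sep, index=False)
    if constants_path is not None:
        Path(constants_path).write_text(
            json.dumps(exam.constants(), indent=2))


def subtract_background(exam: Examination) -> Examination:
    """Subtract the pre-injection ABSS background rate from ABSS counts.

    The background rate ``b`` is the mean counts-per-second over the
    pre-injection ABSS samples.  Each post-injection ABSS sample's counts
    are replaced by ``max(0, round(counts - b * duration))``; manual
    samples are untouched and pre-injection samples are dropped from the
    returned examination.
    """
    pre = [s for s in exam.samples
           if s.pre_injection and s.detector == "abss"]
    if not pre:
        raise ValidationError(
            "no pre-injection ABSS samples: if the recording has no "
            "background segment, skip background subtraction explicitly")
    b = float(np.mean([s.cps for s in pre]))
    out = []
    for s in exam.samples:
        if s.pre_injection:
            continue
        if s.detector == "abss":
            new = max(0, int(round(s.counts - b * s.duration_s)))
            s = replace(s, counts=new)
        out.append(s)
    return replace_samples(exam, out)


def replace_samples(exam: Examination, samples: Sequence[BloodSample],
                    **overrides) -> Examination:
    """Copy an examination with a new sample list (constants preserved)."""
    return Examination(
        exam_id=overrides.get("exam_id", exam.exam_id),
        samples=list(samples),
        pf_measurements=list(exam.pf_measurements),
        half_life_min=exam.half_life_min,
        kappa_s=exam.kappa_s,
        rho_per_mL=exam.rho_per_mL,
        abss_cutoff_min=exam.abss_cutoff_min,
    )


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with edge truncation (window may be even)."""
    if window <= 1:
        return np.asarray(x, dtype=float)
    kernel = np.ones(window)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x, dtype=float), kernel, mode="same")
    return num / den


def select_descent(exam: Examination, window: int = 5) -> Examination:
    """Restrict an examination to the descent of the curve.

    The peak time is located on a moving-average (default 5-point window)
    of the ABSS counts-per-second series; ties break to the earliest
    maximum.  All samples (both detector streams) drawn at or after the
    peak time are retained.  Without an ABSS stream, the peak of the
    manual whole-blood counts-per-second is used instead.
    """
    abss = exam.stream("abss")
    if abss:
        cps = np.array([s.cps for s in abss])
        sm = moving_average(cps, window)
        t_peak = abss[int(np.argmax(sm))].time_min
    else:
        wb = [s for s in exam.stream("manual")
              if s.compartment == "whole_blood"]
        if not wb:
            raise ValidationError(
                "no ABSS stream and no manual whole-blood samples: "
                "cannot locate the curve peak")
        cps = np.array([s.cps for s in wb])
        t_peak = wb[int(np.argmax(cps))].time_min
    kept = [s for s in exam.post_samples if s.time_min >= t_peak]
    return replace_samples(exam, kept)


def export_aif_tsv(times_min: np.ndarray, aif: np.ndarray, path):
    """Write a final interpolated AIF as a two-column TSV."""
    pd.DataFrame({"time_min": times_min, "aif": aif}).to_csv(
        path, sep="\t", index=False)
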