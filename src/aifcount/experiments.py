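"""Reproducible experiments: model-evolution AIC comparison and the
pseudo-leave-one-out missing-data study.

``run_model_evolution`` fits the four model classes (tri-exponential
Poisson, shape-constrained Poisson on linear time, thin-plate negative
binomial on linear time, thin-plate negative binomial on log time) to
each examination and tabulates AIC differences against the log-time
negative-binomial reference.

``run_pseudo_loo`` reduces one examination at a time to two manual
samples (keeping the other examinations complete), refits the
hierarchical model, and scores its predictions at the held-out manual
times against the full-data fit and, for synthetic data, the known
truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .blood_data import Examination
from .engine import FitError
from .models import (SmoothAIFModel, ParametricAIFModel,
                     HierarchicalAIFModel, compare_models_aic,
                     prepare_examination)
from .simulate import make_missing

logger = logging.getLogger("aifcount")

MODEL_SEQUENCE = ("parametric", "scop_poisson", "negbin_tps",
                  "negbin_tps_logtime")
REFERENCE_MODEL = "negbin_tps_logtime"


def _fit_one(name: str, exam, offsets, k: int = 15):
    if name == "parametric":
        return ParametricAIFModel(exam, offsets).fit()
    if name == "scop_poisson":
        return SmoothAIFModel(exam, offsets, family="poisson",
                              shape_constrained=True, log_time=False,
                              k=k).fit()
    if name == "negbin_tps":
        return SmoothAIFModel(exam, offsets, family="negbin",
                              shape_constrained=False, log_time=False,
                              k=k).fit()
    if name == "negbin_tps_logtime":
        return SmoothAIFModel(exam, offsets, family="negbin",
                              shape_constrained=False, log_time=True,
                              k=k).fit()
    raise ValueError(f"unknown model {name!r}")


@dataclass
class ModelEvolutionReport:
    """Per-exam AIC table plus mean/range summaries vs the reference."""

    table: pd.DataFrame
    summary: pd.DataFrame
    failures: list

    def __str__(self):
        head = ("AIC comparison (delta = AIC(reference) - AIC(model); "
                f"reference = {REFERENCE_MODEL}; negative delta means "
                "the reference is preferred)")
        return f"{head}\n{self.table}\n\n{self.summary}"


def run_model_evolution(prepared: Sequence, k: int = 15
                        ) -> ModelEvolutionReport:
    """Fit the four-model sequence to each prepared examination.

    ``prepared`` is a sequence of ``(exam, offsets)`` pairs (e.g. from
    :func:`aifcount.models.prepare_examination`).  Individual model
    failures are recorded, not fatal.
    """
    fits = {name: {} for name in MODEL_SEQUENCE}
    failures = []
    for exam, offsets in prepared:
        for name in MODEL_SEQUENCE:
            try:
                fits[name][exam.exam_id] = _fit_one(name, exam, offsets, k)
            except (FitError, ValueError, np.linalg.LinAlgError) as err:
                logger.warning("model %s failed on exam %s: %s",
                               name, exam.exam_id, err)
                failures.append((exam.exam_id, name, str(err)))
    table = compare_models_aic(fits, reference=REFERENCE_MODEL)
    rows = []
    for name in MODEL_SEQUENCE:
        col = table[f"delta_{name}"]
        rows.append({"model": name,
                     "mean_aic": float(table[f"aic_{name}"].mean()),
                     "mean_delta_aic": float(col.mean()),
                     "min_delta_aic": float(col.min()),
                     "max_delta_aic": float(col.max())})
    return ModelEvolutionReport(table=table, summary=pd.DataFrame(rows),
                                failures=failures)


@dataclass
class LooResult:
    """Pseudo-leave-one-out scores: one row per (exam, pattern)."""

    table: pd.DataFrame

    def median_ape(self, pattern: str, against: str = "truth") -> float:
        sub = self.table[self.table["pattern"] == pattern]
        return float(sub[f"median_ape_vs_{against}"].median())


def _ape(pred: np.ndarray, ref: np.ndarray) -> np.ndarray:
    return 100.0 * np.abs(pred - ref) / np.abs(ref)


def run_pseudo_loo(exams: Sequence[Examination],
                   patterns: Sequence[str] = ("first_last", "first_two",
                                              "last_two"),
                   ground_truths: Optional[dict] = None,
                   holdout_exams: Optional[Sequence[str]] = None,
                   k_global: int = 20, k_exam: int = 5) -> LooResult:
    """Missing-data resilience study for the hierarchical model.

    For each held-out examination and each missingness pattern, the
    examination is reduced to two manual samples (ABSS dropped), all
    other examinations stay complete, the hierarchical model is refitted,
    and the predictions at the held-out manual times are scored as
    absolute percentage error against the full-data hierarchical fit and
    (when ``ground_truths`` maps exam ids to ``GroundTruth``) against the
    true descent curve.
    """
    if len(exams) < 3:
        raise ValueError("pseudo-leave-one-out needs >= 3 examinations")
    prepared = [prepare_examination(e) for e in exams]
    ids = [e.exam_id for e in exams]
    full_fit = HierarchicalAIFModel(
        [p[0] for p in prepared], [p[1] for p in prepared],
        k_global=k_global, k_exam=k_exam).fit()
    holdout = list(holdout_exams) if holdout_exams is not None else ids
    rows = []
    for ex_id in holdout:
        i = ids.index(ex_id)
        manual_times = sorted({s.time_min
                               for s in exams[i].stream("manual")})
        for pattern in patterns:
            reduced_raw = make_missing(exams[i], pattern)
            kept = sorted({s.time_min for s in reduced_raw.stream("manual")})
            held_t = np.array([t for t in manual_times if t not in kept])
            row = {"exam_id": ex_id, "pattern": pattern,
                   "converged": True}
            try:
                red_exam, red_off, _ = prepare_examination(
                    reduced_raw, background=False)
                exs = [p[0] for p in prepared]
                offs = [p[1] for p in prepared]
                exs[i], offs[i] = red_exam, red_off
                fit = HierarchicalAIFModel(exs, offs, k_global=k_global,
                                           k_exam=k_exam).fit()
                pred = fit.predict(held_t, exam_id=ex_id)[
                    "estimate"].to_numpy()
                full_pred = full_fit.predict(held_t, exam_id=ex_id)[
                    "estimate"].to_numpy()
                ape_full = _ape(pred, full_pred)
                row["median_ape_vs_full"] = float(np.median(ape_full))
                row["max_ape_vs_full"] = float(np.max(ape_full))
                if ground_truths and ex_id in ground_truths:
                    truth = ground_truths[ex_id].descent(held_t)
                    ape_t = _ape(pred, truth)
                    row["median_ape_vs_truth"] = float(np.median(ape_t))
                    row["max_ape_vs_truth"] = float(np.max(ape_t))
            except (FitError, ValueError, np.linalg.LinAlgError) as err:
                logger.warning("HGAM failed for exam %s pattern %s: %s",
                               ex_id, pattern, err)
                row["converged"] = False
            rows.append(row)
    return LooResult(table=pd.DataFrame(rows))
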