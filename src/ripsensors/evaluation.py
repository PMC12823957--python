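"""Cross-validation and cohort-level evaluation of the software sensors.

Two complementary protocols are implemented:

* **pooled** — all subjects' valid epochs are concatenated and a seeded
  10-fold cross-validation is run on the pool; the report carries the mean
  and standard deviation of the Pearson correlation (PCC) and RMSE across
  the 10 folds.
* **per-subject** — each subject gets their own 10-fold cross-validation and
  their own full-data fit (for n_obs, error dof, R^2, adjusted R^2, F and
  p); the cohort report averages these per-subject values.

Fold assignment is a seeded uniform shuffle of epoch indices by default; a
``blocked`` option assigns contiguous time blocks instead, for checking
sensitivity to temporal leakage.  Subjects can additionally be stratified by
apnea-hypopnea index using the standard clinical cut points (normal < 5,
mild 5-15, moderate 15-30, severe >= 30 events/h).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyCohortError,
    InsufficientDataError,
    UndefinedStatisticError,
    ValidationError,
)
from .preprocessing import CleaningConfig, build_epoch_table, recording_passes_inclusion
from .sensor_models import MODEL_DESIGNS, ModelKind, fit_sensor_model, predict
from .signal_io import Recording
from .spectral_features import HR_BANDS, MODEL_CHANNELS, extract_features

__all__ = [
    "pearson",
    "rmse_vec",
    "FoldResult",
    "CVSummary",
    "kfold_cv",
    "SubjectResult",
    "EvaluationReport",
    "evaluate_cohort",
    "stratify_by_ahi",
    "AHI_CUTPOINTS",
]

#: clinical AHI severity cut points (events/hour).
AHI_CUTPOINTS: tuple[float, float, float] = (5.0, 15.0, 30.0)
_AHI_LABELS = ("normal", "mild", "moderate", "severe")


def pearson(y: Sequence[float] | np.ndarray, yhat: Sequence[float] | np.ndarray) -> float:
    """Sample Pearson correlation between observed and predicted values."""
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape or y.ndim != 1 or y.size < 2:
        raise ValidationError("pearson requires two equal-length vectors of length >= 2")
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        raise UndefinedStatisticError("Pearson correlation is undefined for constant input")
    yc = y - y.mean()
    pc = yhat - yhat.mean()
    return float(yc @ pc / np.sqrt((yc @ yc) * (pc @ pc)))


def rmse_vec(y: Sequence[float] | np.ndarray, yhat: Sequence[float] | np.ndarray) -> float:
    """Root mean squared error between observed and predicted values."""
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape or y.size < 1:
        raise ValidationError("rmse requires two equal-length non-empty vectors")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


@dataclass
class FoldResult:
    fold_index: int
    n_train: int
    n_test: int
    pcc: float
    rmse: float


@dataclass
class CVSummary:
    mean_pcc: float
    std_pcc: float
    mean_rmse: float
    std_rmse: float
    folds: list[FoldResult] = field(default_factory=list)


def kfold_cv(
    rows: pd.DataFrame,
    kind: ModelKind,
    k: int = 10,
    seed: int = 0,
    blocked: bool = False,
) -> CVSummary:
    """Seeded k-fold cross-validation of one model kind on a feature table.

    Rows are partitioned into k near-equal folds (shuffled by default,
    contiguous blocks when ``blocked``); for each fold the model is fit on
    the remainder and PCC/RMSE are computed on the held-out rows.  The same
    seed always yields the same partition and results.
    """
    kind = ModelKind(kind)
    n = len(rows)
    p_total = len(MODEL_DESIGNS[kind][0]) + 1
    minimum = k * p_total if k > 1 else p_total + 1
    if n < max(minimum, k):
        raise InsufficientDataError(
            f"{kind.value} {k}-fold CV needs at least {max(minimum, k)} rows, got {n}"
        )
    if blocked:
        order = np.arange(n)
    else:
        order = np.random.default_rng(seed).permutation(n)
    folds = np.array_split(order, k)

    results: list[FoldResult] = []
    for i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(order, test_idx)
        model = fit_sensor_model(rows.iloc[train_idx], kind)
        test_rows = rows.iloc[test_idx]
        yhat = predict(model, test_rows)
        y = test_rows[MODEL_DESIGNS[kind][1]].to_numpy(dtype=np.float64)
        try:
            r = pearson(y, yhat)
        except (UndefinedStatisticError, ValidationError):
            r = np.nan
        results.append(
            FoldResult(
                fold_index=i,
                n_train=int(train_idx.size),
                n_test=int(test_idx.size),
                pcc=r,
                rmse=rmse_vec(y, yhat),
            )
        )

    pccs = np.array([f.pcc for f in results], dtype=np.float64)
    rmses = np.array([f.rmse for f in results], dtype=np.float64)
    return CVSummary(
        mean_pcc=float(np.nanmean(pccs)),
        std_pcc=float(np.nanstd(pccs, ddof=1)) if len(results) > 1 else np.nan,
        mean_rmse=float(np.mean(rmses)),
        std_rmse=float(np.std(rmses, ddof=1)) if len(results) > 1 else np.nan,
        folds=results,
    )


@dataclass
class SubjectResult:
    subject_id: str
    cv: CVSummary
    n_obs: int
    error_dof: int
    r2: float
    adj_r2: float
    f_vs_constant: float
    f_p_value: float
    ahi: float | None = None


_COHORT_COLUMNS = [
    "mean_pcc",
    "std_pcc",
    "mean_rmse",
    "std_rmse",
    "mean_n_obs",
    "mean_error_dof",
    "mean_r2",
    "mean_adj_r2",
    "mean_f",
    "mean_p",
]


@dataclass
class EvaluationReport:
    """Per-subject results plus cohort summary for one model kind and scope."""

    model_kind: ModelKind
    scope: str
    subjects: list[SubjectResult]
    cohort: dict
    excluded: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def to_frame(self) -> pd.DataFrame:
        """One row per subject plus a trailing cohort row."""
        rows = []
        for s in self.subjects:
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "mean_pcc": s.cv.mean_pcc,
                    "std_pcc": s.cv.std_pcc,
                    "mean_rmse": s.cv.mean_rmse,
                    "std_rmse": s.cv.std_rmse,
                    "n_obs": s.n_obs,
                    "error_dof": s.error_dof,
                    "r2": s.r2,
                    "adj_r2": s.adj_r2,
                    "f_vs_constant": s.f_vs_constant,
                    "f_p_value": s.f_p_value,
                    "ahi": s.ahi,
                }
            )
        frame = pd.DataFrame(rows)
        cohort_row = {"subject_id": "COHORT", **self.cohort}
        return pd.concat([frame, pd.DataFrame([cohort_row])], ignore_index=True)


def _cohort_summary(subjects: list[SubjectResult]) -> dict:
    def agg(vals: list[float], fn) -> float:
        arr = np.asarray(vals, dtype=np.float64)
        return float(fn(arr)) if arr.size else np.nan

    many = len(subjects) > 1
    return {
        "n_subjects": len(subjects),
        "mean_pcc": agg([s.cv.mean_pcc for s in subjects], np.nanmean),
        "std_pcc": agg([s.cv.mean_pcc for s in subjects], lambda a: np.nanstd(a, ddof=1))
        if many
        else np.nan,
        "mean_rmse": agg([s.cv.mean_rmse for s in subjects], np.nanmean),
        "std_rmse": agg([s.cv.mean_rmse for s in subjects], lambda a: np.nanstd(a, ddof=1))
        if many
        else np.nan,
        "mean_n_obs": agg([s.n_obs for s in subjects], np.mean),
        "mean_error_dof": agg([s.error_dof for s in subjects], np.mean),
        "mean_r2": agg([s.r2 for s in subjects], np.mean),
        "mean_adj_r2": agg([s.adj_r2 for s in subjects], np.mean),
        "mean_f": agg([s.f_vs_constant for s in subjects], np.nanmean),
        "mean_p": agg([s.f_p_value for s in subjects], np.nanmean),
    }


def evaluate_cohort(
    recordings: Sequence[Recording],
    kind: ModelKind,
    scope: str = "per_subject",
    cleaning: CleaningConfig | None = None,
    k: int = 10,
    seed: int = 0,
    blocked: bool = False,
    bands=HR_BANDS,
) -> EvaluationReport:
    """Run preprocessing, feature extraction and CV over a cohort.

    Recordings failing the minimum-valid-duration inclusion rule (or with too
    few valid epochs for the CV layout) are listed in ``report.excluded``
    with a reason.  ``scope`` is ``"per_subject"`` or ``"pooled"``.
    """
    kind = ModelKind(kind)
    if scope not in {"per_subject", "pooled"}:
        raise ValidationError(f"unknown scope {scope!r}")
    cleaning = cleaning or CleaningConfig()
    required = MODEL_CHANNELS[kind]

    tables: list[pd.DataFrame] = []
    per_subject_meta: list[tuple[str, float | None]] = []
    excluded: list[tuple[str, str]] = []
    for rec in recordings:
        epochs = build_epoch_table(rec, required, cleaning)
        passes, summary = recording_passes_inclusion(epochs, cleaning)
        if not passes:
            excluded.append(
                (rec.subject_id, f"below {cleaning.min_valid_hours} valid hours "
                                 f"({summary.valid_hours:.2f} h)")
            )
            continue
        rates = {ch: rec.channels[ch].sampling_rate_hz for ch in required}
        rows = extract_features(epochs, kind, rates, subject_id=rec.subject_id, bands=bands)
        tables.append(rows)
        per_subject_meta.append((rec.subject_id, rec.metadata.get("ahi")))

    if not tables:
        raise EmptyCohortError("no recording passed the inclusion criteria")

    subjects: list[SubjectResult] = []
    if scope == "per_subject":
        for (sid, ahi), rows in zip(per_subject_meta, tables):
            try:
                cv = kfold_cv(rows, kind, k=k, seed=seed, blocked=blocked)
            except InsufficientDataError as exc:
                excluded.append((sid, str(exc)))
                continue
            model = fit_sensor_model(rows, kind)
            fs = model.fit_stats
            subjects.append(
                SubjectResult(
                    subject_id=sid,
                    cv=cv,
                    n_obs=fs.n_obs,
                    error_dof=fs.error_dof,
                    r2=fs.r2,
                    adj_r2=fs.adj_r2,
                    f_vs_constant=fs.f_vs_constant,
                    f_p_value=fs.f_p_value,
                    ahi=ahi,
                )
            )
        if not subjects:
            raise EmptyCohortError("no subject had enough valid epochs for cross-validation")
        cohort = _cohort_summary(subjects)
    else:
        pooled = pd.concat(tables, ignore_index=True)
        cv = kfold_cv(pooled, kind, k=k, seed=seed, blocked=blocked)
        model = fit_sensor_model(pooled, kind)
        fs = model.fit_stats
        cohort = {
            "n_subjects": len(tables),
            "mean_pcc": cv.mean_pcc,
            "std_pcc": cv.std_pcc,
            "mean_rmse": cv.mean_rmse,
            "std_rmse": cv.std_rmse,
            "mean_n_obs": fs.n_obs,
            "mean_error_dof": fs.error_dof,
            "mean_r2": fs.r2,
            "mean_adj_r2": fs.adj_r2,
            "mean_f": fs.f_vs_constant,
            "mean_p": fs.f_p_value,
        }
        subjects = []

    return EvaluationReport(
        model_kind=kind, scope=scope, subjects=subjects, cohort=cohort, excluded=excluded
    )


def ahi_stratum(ahi: float) -> str:
    """Clinical severity label for one AHI value."""
    lo, mid, hi = AHI_CUTPOINTS
    if ahi < lo:
        return _AHI_LABELS[0]
    if ahi < mid:
        return _AHI_LABELS[1]
    if ahi < hi:
        return _AHI_LABELS[2]
    return _AHI_LABELS[3]


def stratify_by_ahi(
    report: EvaluationReport,
    metadata: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-AHI-stratum PCC summaries for a per-subject report.

    AHI comes from ``metadata`` (subject_id -> events/hour) or, failing that,
    from each subject's own stored AHI.  Subjects without an AHI are dropped
    with a warning.
    """
    rows = []
    for s in report.subjects:
        ahi = (metadata or {}).get(s.subject_id, s.ahi)
        if ahi is None or (isinstance(ahi, float) and np.isnan(ahi)):
            warnings.warn(f"subject {s.subject_id} has no AHI; excluded from stratification")
            continue
        rows.append({"subject_id": s.subject_id, "ahi": float(ahi),
                     "stratum": ahi_stratum(float(ahi)), "mean_pcc": s.cv.mean_pcc})
    if not rows:
        return pd.DataFrame(columns=["stratum", "n_subjects", "mean_pcc", "std_pcc"])
    frame = pd.DataFrame(rows)
    out = (
        frame.groupby("stratum", sort=False)
        .agg(n_subjects=("subject_id", "size"), mean_pcc=("mean_pcc", "mean"),
             std_pcc=("mean_pcc", lambda v: v.std(ddof=1)))
        .reset_index()
    )
    order = [lab for lab in _AHI_LABELS if lab in set(out["stratum"])]
    return out.set_index("stratum").loc[order].reset_index()
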