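"""The four linear software-sensor models and their least-squares machinery.

Each model estimates one epoch-level physiological quantity from features of
another, more comfortable, sensor:

``HR``
    pulse = b0 + b1*Xband1 + b2*Xband2 + b3*Xband3 + b4*RMS + b5*Skewness,
    predicting the epoch-average pulse (bpm) from the abdominal belt's mean
    spectral magnitude in three bands (0.07-0.3, 0.3-1.7, 1.7-5 Hz), its RMS
    and its skewness.
``NPF``
    NPF = b0 + b1*XAB + b2*XTH — nasal pneumoflow mean spectral magnitude
    from the full-band mean spectral magnitudes of the two belts.
``PES1``
    Pes = b0 + b1*XNPF + b2*XOPF — esophageal pressure magnitude from the
    nasal and oral pneumoflow magnitudes.
``PES2``
    Pes = b0 + b1*XAB + b2*XTH — esophageal pressure magnitude from the two
    belt magnitudes.

Coefficients are estimated by ordinary least squares on raw (unstandardized)
feature scales, with the classical homoskedastic statistics panel: per
coefficient SE, t and two-sided p-value; per model R^2, adjusted R^2, the
F test against the constant model and the residual RMSE.  Error degrees of
freedom are the number of valid epochs minus the number of estimated
parameters.
"""

from __future__ import annotations

import enum
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    CollinearityError,
    ConfigurationError,
    CorruptModelError,
    UnderdeterminedFitError,
    ValidationError,
)

__all__ = [
    "ModelKind",
    "MODEL_DESIGNS",
    "CoefStats",
    "FitStats",
    "SensorModel",
    "build_design",
    "fit_ols",
    "fit_sensor_model",
    "predict",
    "save_model",
    "load_model",
]


class ModelKind(str, enum.Enum):
    HR = "HR"
    NPF = "NPF"
    PES1 = "PES1"
    PES2 = "PES2"


#: predictor column order (exactly as the model equations are written) and
#: target column, per model kind.  The intercept is implicit and leads.
MODEL_DESIGNS: dict[ModelKind, tuple[tuple[str, ...], str]] = {
    ModelKind.HR: (("Xband1", "Xband2", "Xband3", "RMS", "Skewness"), "target_pulse"),
    ModelKind.NPF: (("XAB", "XTH"), "target_npf_mag"),
    ModelKind.PES1: (("XNPF", "XOPF"), "target_pes_mag"),
    ModelKind.PES2: (("XAB", "XTH"), "target_pes_mag"),
}


@dataclass
class CoefStats:
    se: float
    t_stat: float
    p_value: float


@dataclass
class FitStats:
    n_obs: int
    error_dof: int
    r2: float
    adj_r2: float
    f_vs_constant: float
    f_p_value: float
    residual_rmse: float


@dataclass
class SensorModel:
    """A fitted software sensor: kind, ordered coefficients and statistics.

    ``feature_conventions`` records the extraction settings the model was
    trained under (epoch length, bands, DC handling) so that it is only
    applied to features computed the same way.
    """

    kind: ModelKind
    coefficient_names: tuple[str, ...]
    coefficients: np.ndarray
    coef_stats: list[CoefStats]
    fit_stats: FitStats
    feature_conventions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.kind = ModelKind(self.kind)
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        expected = len(MODEL_DESIGNS[self.kind][0]) + 1
        if self.coefficients.size != expected:
            raise CorruptModelError(
                f"{self.kind.value} model requires {expected} coefficients, "
                f"got {self.coefficients.size}"
            )
        if len(self.coefficient_names) != expected or len(self.coef_stats) != expected:
            raise CorruptModelError("coefficient names/stats do not match coefficient count")


def build_design(
    rows: pd.DataFrame, kind: ModelKind
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Assemble the design matrix and target vector for one model kind.

    Returns ``(X, y, names)`` where ``X`` has a leading constant column and
    the remaining columns follow the model equation's order, and ``names``
    are the coefficient names starting with ``"Intercept"``.
    """
    kind = ModelKind(kind)
    predictors, target = MODEL_DESIGNS[kind]
    missing = [c for c in (*predictors, target) if c not in rows.columns]
    if missing:
        raise ConfigurationError(
            f"feature table lacks columns {missing} required by the {kind.value} model"
        )
    sub = rows.loc[:, list(predictors) + [target]]
    if sub.isna().any().any():
        raise ConfigurationError(
            f"feature table contains missing values in the {kind.value} model columns"
        )
    n = len(sub)
    p_total = len(predictors) + 1
    if n <= p_total:
        raise UnderdeterminedFitError(
            f"{kind.value} model needs more than {p_total} rows, got {n}"
        )
    X = np.column_stack([np.ones(n), sub[list(predictors)].to_numpy(dtype=np.float64)])
    y = sub[target].to_numpy(dtype=np.float64)
    return X, y, ("Intercept", *predictors)


def fit_ols(
    X: np.ndarray,
    y: np.ndarray,
    names: Sequence[str] | None = None,
) -> tuple[np.ndarray, list[CoefStats], FitStats]:
    """Ordinary least squares with the classical statistics panel.

    ``X`` must include its constant column and be of full column rank
    (rank deficiency raises :class:`CollinearityError` naming the dependent
    columns).  Standard errors use the homoskedastic covariance
    ``sigma^2 (X'X)^-1`` with ``sigma^2 = SSE / (n - p)``; the F statistic
    tests against the constant (intercept-only) model.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, p = X.shape
    if y.shape != (n,):
        raise ValidationError("X and y have inconsistent shapes")
    if n <= p:
        raise UnderdeterminedFitError(f"need n > {p} observations, got {n}")
    names = tuple(names) if names is not None else tuple(f"x{j}" for j in range(p))

    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = max(n, p) * np.finfo(np.float64).eps * (diag.max() if diag.size else 0.0)
    dependent = [names[j] for j in range(p) if diag[j] <= tol]
    if dependent:
        raise CollinearityError(
            f"design matrix is rank deficient; dependent columns: {dependent}",
            columns=dependent,
        )

    beta = np.linalg.solve(r, q.T @ y)
    resid = y - X @ beta
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    dof = n - p
    sigma2 = sse / dof
    r_inv = np.linalg.solve(r, np.eye(p))
    xtx_inv_diag = np.sum(r_inv**2, axis=1)
    se = np.sqrt(sigma2 * xtx_inv_diag)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.where(beta == 0, 0.0, np.inf * np.sign(beta)))
    p_coef = np.where(np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(t), dof))
    p_coef = np.where((se == 0) & (beta == 0), 1.0, p_coef)

    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / dof
    if p > 1 and sst > 0:
        if sse > 0:
            f = ((sst - sse) / (p - 1)) / (sse / dof)
            f_p = float(stats.f.sf(f, p - 1, dof))
        else:
            f, f_p = np.inf, 0.0
    else:
        f, f_p = np.nan, np.nan

    coef_stats = [
        CoefStats(se=float(se[j]), t_stat=float(t[j]), p_value=float(p_coef[j]))
        for j in range(p)
    ]
    fit_stats = FitStats(
        n_obs=n,
        error_dof=dof,
        r2=float(r2),
        adj_r2=float(adj_r2),
        f_vs_constant=float(f),
        f_p_value=float(f_p),
        residual_rmse=float(np.sqrt(sse / n)),
    )
    return beta, coef_stats, fit_stats


def fit_sensor_model(
    rows: pd.DataFrame,
    kind: ModelKind,
    feature_conventions: dict | None = None,
) -> SensorModel:
    """Fit one model kind on a feature table and package the result."""
    X, y, names = build_design(rows, kind)
    beta, coef_stats, fit_stats = fit_ols(X, y, names)
    return SensorModel(
        kind=ModelKind(kind),
        coefficient_names=names,
        coefficients=beta,
        coef_stats=coef_stats,
        fit_stats=fit_stats,
        feature_conventions=dict(feature_conventions or {}),
    )


def predict(model: SensorModel, rows: pd.DataFrame) -> np.ndarray:
    """Apply a fitted sensor to a feature table, one prediction per row."""
    predictors = model.coefficient_names[1:]
    missing = [c for c in predictors if c not in rows.columns]
    if missing:
        raise ConfigurationError(
            f"feature table lacks predictors {missing} for the {model.kind.value} model"
        )
    X = np.column_stack(
        [np.ones(len(rows)), rows[list(predictors)].to_numpy(dtype=np.float64)]
    )
    return X @ model.coefficients


def save_model(model: SensorModel, path: str | Path) -> Path:
    """Serialize a model as JSON at full float precision."""
    path = Path(path)
    payload = {
        "kind": model.kind.value,
        "coefficient_names": list(model.coefficient_names),
        "coefficients": [float(b) for b in model.coefficients],
        "coef_stats": [asdict(c) for c in model.coef_stats],
        "fit_stats": asdict(model.fit_stats),
        "feature_conventions": model.feature_conventions,
    }
    path.write_text(json.dumps(payload, indent=2), encoding="utf-8")
    return path


def load_model(path: str | Path) -> SensorModel:
    """Load a model saved by :func:`save_model`; ``load . save`` is the identity."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
        kind = ModelKind(payload["kind"])
        model = SensorModel(
            kind=kind,
            coefficient_names=tuple(payload["coefficient_names"]),
            coefficients=np.asarray(payload["coefficients"], dtype=np.float64),
            coef_stats=[CoefStats(**c) for c in payload["coef_stats"]],
            fit_stats=FitStats(**payload["fit_stats"]),
            feature_conventions=payload.get("feature_conventions", {}),
        )
    except CorruptModelError:
        raise
    except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
        raise CorruptModelError(f"{path}: not a valid sensor model file ({exc})") from exc
    return model
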