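"""Dataset splitting and model-evaluation statistics.

Conventions (N = calibration/prediction sample count, M = prediction count):

* R      — Pearson correlation between measured and predicted values,
           reported per context as R_cal, R_cv, R_pre.
* RMSE   — sqrt(mean squared error), divisor N (not N-1); RMSEC / RMSECV /
           RMSEP by context.
* Bias   — mean(predicted - measured) over the prediction set.
* SEP    — SD of (predicted - measured) about the Bias, divisor M-1.
* RPD    — SD of the *measured* prediction-set values divided by SEP.

RPD is rated on the standard 1-6 chemometrics scale: inapplicable (< 1),
poor [1, 1.4), fair [1.4, 1.8), good [1.8, 2.0), very good [2.0, 2.5),
excellent (>= 2.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import json
import numpy as np

from .chemometrics import RegressionModel, SpectralDataset, predict

__all__ = [
    "DatasetSplit",
    "EvaluationReport",
    "split_dataset",
    "pearson_r",
    "rmse",
    "bias",
    "sep",
    "rpd",
    "rate_rpd",
    "evaluate",
    "RPD_SCALE",
]


@dataclass
class DatasetSplit:
    """Disjoint calibration/prediction index sets covering all samples."""

    calibration: np.ndarray
    prediction: np.ndarray
    ratio: tuple[int, int] = (2, 1)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.calibration = np.asarray(self.calibration, dtype=int)
        self.prediction = np.asarray(self.prediction, dtype=int)
        both = np.concatenate([self.calibration, self.prediction])
        if len(np.unique(both)) != len(both):
            raise ValueError("calibration and prediction sets overlap or repeat indices")


def split_dataset(
    n: int,
    ratio: tuple[int, int] = (2, 1),
    seed: int = 0,
    strata=None,
) -> DatasetSplit:
    """Random calibration/prediction split at the given ratio (default 2:1).

    The calibration share is floored: floor(n * 2/3) at 2:1, so 133 samples
    split 88/45.  With ``strata`` (e.g. variety labels), the permutation and
    flooring happen within each stratum independently.
    """
    if n < 3:
        raise ValueError("need at least 3 samples to split")
    frac = ratio[0] / (ratio[0] + ratio[1])
    rng = np.random.default_rng(seed)
    if strata is None:
        perm = rng.permutation(n)
        n_cal = int(np.floor(n * frac))
        cal, pred = perm[:n_cal], perm[n_cal:]
    else:
        strata = np.asarray(strata)
        if len(strata) != n:
            raise ValueError("strata length must equal n")
        cal_parts, pred_parts = [], []
        for lev in np.unique(strata):
            idx = np.flatnonzero(strata == lev)
            perm = rng.permutation(len(idx))
            k = int(np.floor(len(idx) * frac))
            cal_parts.append(idx[perm[:k]])
            pred_parts.append(idx[perm[k:]])
        cal = np.concatenate(cal_parts)
        pred = np.concatenate(pred_parts)
    return DatasetSplit(np.sort(cal), np.sort(pred), ratio=ratio, seed=seed)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def _pair(y, yhat):
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if len(y) != len(yhat):
        raise ValueError("y and yhat lengths differ")
    return y, yhat


def pearson_r(y, yhat) -> float:
    y, yhat = _pair(y, yhat)
    if len(y) < 2:
        raise ValueError("need at least 2 points")
    if np.std(y) == 0 or np.std(yhat) == 0:
        raise ValueError("zero variance in y or yhat")
    yc, pc = y - y.mean(), yhat - yhat.mean()
    return float((yc @ pc) / np.sqrt((yc @ yc) * (pc @ pc)))


def rmse(y, yhat) -> float:
    y, yhat = _pair(y, yhat)
    if len(y) == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def bias(y, yhat) -> float:
    y, yhat = _pair(y, yhat)
    if len(y) == 0:
        raise ValueError("empty input")
    return float(np.mean(yhat - y))


def sep(y, yhat) -> float:
    """SD of prediction errors about their mean (divisor M-1)."""
    y, yhat = _pair(y, yhat)
    if len(y) < 2:
        raise ValueError("SEP needs M >= 2")
    e = yhat - y
    return float(np.sqrt(np.sum((e - e.mean()) ** 2) / (len(e) - 1)))


def rpd(std_pred: float, sep_value: float) -> float:
    """Residual prediction deviation: measured prediction-set SD / SEP."""
    if sep_value <= 0:
        raise ValueError("SEP must be > 0 for a finite RPD (perfect fit?)")
    return float(std_pred) / float(sep_value)


RPD_SCALE = (
    (1.0, "inapplicable"),
    (1.4, "poor"),
    (1.8, "fair"),
    (2.0, "good"),
    (2.5, "very good"),
    (np.inf, "excellent"),
)


def rate_rpd(rpd_value: float) -> str:
    """Map an RPD onto the 1-6 model-quality scale (left-inclusive bands)."""
    rpd_value = float(rpd_value)
    if not np.isfinite(rpd_value) or rpd_value < 0:
        raise ValueError("RPD must be finite and >= 0")
    for upper, name in RPD_SCALE:
        if rpd_value < upper:
            return name
    return "excellent"


# ---------------------------------------------------------------------------
# Aggregate report
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Calibration / cross-validation / prediction statistics for one model."""

    attribute: str
    model_id: str
    n_cal: int
    n_pred: int
    R_cal: float
    RMSEC: float
    R_cv: float | None
    RMSECV: float | None
    R_pre: float
    RMSEP: float
    SEP: float
    Bias: float
    STD: float
    RPD: float
    rating: str
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=float))


def evaluate(
    model: RegressionModel,
    ds: SpectralDataset,
    split: DatasetSplit,
    model_id: str | None = None,
) -> EvaluationReport:
    """Score a model fitted on the calibration subset of ``ds``.

    Cross-validation statistics are taken from the leave-one-out predictions
    the model recorded at fit time (all families store them); STD is the SD
    (divisor M-1) of the *measured* prediction-set values.
    """
    cal = ds.subset(rows=split.calibration)
    pred = ds.subset(rows=split.prediction)
    yhat_cal = predict(model, cal.X)
    yhat_pred = predict(model, pred.X)

    r_cv = rmsecv = None
    if model.cv_predictions is not None and len(model.cv_predictions) == cal.n_samples:
        r_cv = pearson_r(cal.y, model.cv_predictions)
        rmsecv = rmse(cal.y, model.cv_predictions)

    sep_v = sep(pred.y, yhat_pred)
    std_v = float(np.std(pred.y, ddof=1))
    if sep_v == 0:
        rpd_v, rating = float("inf"), "excellent"
    else:
        rpd_v = rpd(std_v, sep_v)
        rating = rate_rpd(rpd_v)

    params: dict = {}
    if model.n_lvs is not None:
        params["n_lvs"] = model.n_lvs
    if model.gamma is not None:
        params["gamma"] = model.gamma
        params["sigma2"] = model.sigma2

    return EvaluationReport(
        attribute=ds.attribute,
        model_id=model_id or model.family,
        n_cal=cal.n_samples,
        n_pred=pred.n_samples,
        R_cal=pearson_r(cal.y, yhat_cal),
        RMSEC=rmse(cal.y, yhat_cal),
        R_cv=r_cv,
        RMSECV=rmsecv,
        R_pre=pearson_r(pred.y, yhat_pred),
        RMSEP=rmse(pred.y, yhat_pred),
        SEP=sep_v,
        Bias=bias(pred.y, yhat_pred),
        STD=std_v,
        RPD=rpd_v,
        rating=rating,
        params=params,
    )
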