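"""Predictive-accuracy evaluation of calibrated niche models.

Internal evaluation (IE) repeats a random 50/50 split 100 times,
refitting the selected predictor set on each half and scoring the
pooled held-out predictions; external evaluation (EE) calibrates in one
location and predicts the other.  Discrimination of presence-absence
predictions is the area under the ROC curve (AUC, Mann-Whitney midrank
form); agreement of abundance predictions is Spearman's rank
correlation.  Values are mapped onto the conventional qualitative bands
(excellent/good/fair/poor/fail).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .glm import FamilySpec, FittedModel, fit_glm

logger = logging.getLogger(__name__)

AUC_BANDS = [(0.90, "excellent"), (0.80, "good"), (0.70, "fair"),
             (0.60, "poor"), (-np.inf, "fail")]
RHO_BANDS = [(0.80, "excellent"), (0.60, "good"), (0.40, "fair"),
             (0.20, "poor"), (-np.inf, "fail")]


@dataclass
class EvaluationResult:
    metric: str  # "AUC" | "rho"
    value: float
    band: str
    mode: str  # "IE" | "EE" | "transfer" | "resubstitution"
    per_iteration: list[float] = field(default_factory=list)
    calibration_dataset: int | None = None
    evaluation_dataset: int | None = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "metric": self.metric, "value": self.value, "band": self.band,
            "mode": self.mode, "per_iteration": self.per_iteration,
            "calibration_dataset": self.calibration_dataset,
            "evaluation_dataset": self.evaluation_dataset,
            "notes": self.notes,
        }


def auc(scores, labels) -> float:
    """Area under the ROC curve, Mann-Whitney midrank formulation:
    P(score+ > score-) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = stats.rankdata(scores)  # midranks
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def spearman_rho(pred, obs) -> float:
    """Spearman's rank correlation (Pearson correlation of midranks)."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if len(pred) < 3:
        raise ValueError("need at least 3 observations")
    if np.all(pred == pred[0]) or np.all(obs == obs[0]):
        raise ValueError("Spearman rho undefined for constant input")
    return float(stats.spearmanr(pred, obs).statistic)


def classify_band(metric: str, value: float) -> str:
    """Qualitative band, left-closed on each boundary
    (e.g. AUC 0.80 is 'good', rho 0.20 is 'poor')."""
    bands = AUC_BANDS if metric == "AUC" else RHO_BANDS
    for lo, label in bands:
        if value >= lo:
            return label
    return "fail"


def metric_for(response_kind: str) -> str:
    return "AUC" if response_kind == "PA" else "rho"


def _score(metric: str, pred: np.ndarray, obs: np.ndarray) -> float:
    return auc(pred, obs) if metric == "AUC" else spearman_rho(pred, obs)


def internal_evaluate(table: pd.DataFrame, response: str,
                      predictors: list[str], family: FamilySpec,
                      response_kind: str, n_iter: int = 100,
                      seed: int = 0) -> EvaluationResult:
    """Repeated 2-fold cross-validation: per iteration a random 50%
    split, the selected predictor set refitted on each half and scored
    on the pooled held-out predictions; the result is the mean over
    iterations.  Splits whose training half cannot support a fit
    (single-class PA half) are redrawn."""
    rng = np.random.default_rng(seed)
    metric = metric_for(response_kind)
    n = len(table)
    values: list[float] = []
    redraws = 0
    for _ in range(n_iter):
        for attempt in range(100):
            perm = rng.permutation(n)
            halves = (perm[: n // 2], perm[n // 2:])
            ok = True
            for h in halves:
                y = table[response].to_numpy()[h]
                if response_kind == "PA" and len(np.unique(y)) < 2:
                    ok = False
                elif response_kind == "AB" and np.all(y == y[0]):
                    ok = False
            if ok:
                break
            redraws += 1
        else:
            raise RuntimeError(
                f"no valid 50/50 split found in 100 attempts for {response}")
        preds = np.empty(n)
        for train, test in ((halves[0], halves[1]), (halves[1], halves[0])):
            m = fit_glm(table.iloc[train], response, predictors, family)
            preds[test] = m.predict_eta(table.iloc[test])
        values.append(_score(metric, preds, table[response].to_numpy()))
    if redraws:
        logger.info("IE %s: %d invalid splits redrawn", response, redraws)
    mean = float(np.mean(values))
    return EvaluationResult(metric=metric, value=mean,
                            band=classify_band(metric, mean), mode="IE",
                            per_iteration=values,
                            notes=["predictor set refitted per training half"])


def external_evaluate(calib_table: pd.DataFrame, eval_table: pd.DataFrame,
                      response: str, predictors: list[str],
                      family: FamilySpec, response_kind: str
                      ) -> EvaluationResult:
    """Calibrate on one table, predict the rows of the other, score
    against its observed responses."""
    missing = [p for p in predictors if p not in eval_table.columns]
    if missing:
        raise ValueError(
            f"evaluation table lacks predictors: {', '.join(missing)}")
    metric = metric_for(response_kind)
    m = fit_glm(calib_table, response, predictors, family)
    preds = m.predict_eta(eval_table)
    value = _score(metric, preds, eval_table[response].to_numpy())
    return EvaluationResult(metric=metric, value=value,
                            band=classify_band(metric, value), mode="EE")
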