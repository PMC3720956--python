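"""Candidate-predictor screening before model calibration.

Three sequential reductions of the candidate set:

1. univariate screen — keep predictors whose single-term GLM beats the
   intercept-only model at p < 0.1 (likelihood-ratio chi-square, 1 df),
   ranked by explained deviance;
2. correlation filter — greedy pass in rank order dropping any candidate
   with |Spearman rho| >= 0.7 against an already-retained one; among the
   multiscale versions of the same variable only the best-ranked scale
   survives, correlated or not;
3. VIF cascade — repeatedly drop the predictor with the largest variance
   inflation factor until all VIFs are below 10.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from . import catalog
from .glm import FamilySpec, fit_glm

logger = logging.getLogger(__name__)


@dataclass
class VariableScreen:
    name: str
    p_value: float | None = None
    explained_deviance: float | None = None
    included: bool = False
    exclusion_reason: str | None = None  # failed-p | correlated-with:<name> |
    #                                       scale-competition | vif-dropped | fit-failed


@dataclass
class ScreeningReport:
    """Outcome of the full screening chain for one response."""

    response: str
    variables: dict[str, VariableScreen] = field(default_factory=dict)
    retained: list[str] = field(default_factory=list)
    final_vifs: dict[str, float] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "variables": {k: asdict(v) for k, v in self.variables.items()},
            "retained": self.retained,
            "final_vifs": self.final_vifs,
            "notes": self.notes,
        }


def univariate_screen(table: pd.DataFrame, response: str,
                      candidates: list[str], family: FamilySpec,
                      p_threshold: float = 0.1) -> list[VariableScreen]:
    """Single-predictor GLM per candidate; keep p < threshold, rank by
    descending explained deviance (ties broken lexicographically)."""
    if len(table) <= 2:
        raise ValueError("need more than 2 observations to screen")
    results: list[VariableScreen] = []
    null = fit_glm(table, response, [], family)
    for name in candidates:
        vs = VariableScreen(name=name)
        x = table[name]
        if x.nunique() <= 1:
            vs.exclusion_reason = "fit-failed"
            logger.info("screen %s: %s constant, dropped", response, name)
            results.append(vs)
            continue
        try:
            m = fit_glm(table, response, [name], family)
        except Exception as exc:  # non-convergence is not fatal
            vs.exclusion_reason = "fit-failed"
            logger.info("screen %s: %s failed to fit (%s)", response, name, exc)
            results.append(vs)
            continue
        lr = max(null.deviance - m.deviance, 0.0)
        vs.p_value = float(stats.chi2.sf(lr, df=1))
        vs.explained_deviance = (
            (null.deviance - m.deviance) / null.deviance
            if null.deviance > 0 else 0.0)
        if vs.p_value < p_threshold:
            vs.included = True
        else:
            vs.exclusion_reason = "failed-p"
        results.append(vs)
    kept = [v for v in results if v.included]
    kept.sort(key=lambda v: (-v.explained_deviance, v.name))
    dropped = [v for v in results if not v.included]
    return kept + dropped


def correlation_filter(ranked: list[VariableScreen], table: pd.DataFrame,
                       threshold: float = 0.7) -> list[VariableScreen]:
    """Greedy rank-order pass: drop a candidate when |Spearman rho| >=
    threshold against any retained variable, and enforce one scale per
    multiscale family (the best-ranked version wins)."""
    retained: list[str] = []
    taken_families: set[str] = set()
    for vs in ranked:
        if not vs.included:
            continue
        fam = catalog.scale_family(vs.name)
        if fam is not None and fam in taken_families:
            vs.included = False
            vs.exclusion_reason = "scale-competition"
            continue
        x = table[vs.name]
        if x.nunique() <= 1:
            vs.included = False
            vs.exclusion_reason = "fit-failed"
            continue
        clash = None
        for other in retained:
            rho = stats.spearmanr(x, table[other]).statistic
            if not np.isfinite(rho) or abs(rho) >= threshold:
                clash = other
                break
        if clash is not None:
            vs.included = False
            vs.exclusion_reason = f"correlated-with:{clash}"
            continue
        retained.append(vs.name)
        if fam is not None:
            taken_families.add(fam)
    return ranked


def compute_vifs(table: pd.DataFrame, names: list[str]) -> dict[str, float]:
    """VIF_j = 1/(1 - R^2_j) from the OLS regression of predictor j on
    the other predictors (with intercept); exact collinearity -> inf."""
    X = table[names].to_numpy(dtype=float)
    out: dict[str, float] = {}
    for j, name in enumerate(names):
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(len(X)), others])
        y = X[:, j]
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ beta
        ss_tot = np.sum((y - y.mean()) ** 2)
        if ss_tot == 0:
            out[name] = np.inf
            continue
        r2 = 1.0 - np.sum(resid ** 2) / ss_tot
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif_cascade(table: pd.DataFrame, screens: list[VariableScreen],
                vif_threshold: float = 10.0) -> dict[str, float]:
    """Sequentially drop the largest-VIF predictor until all VIFs are
    below threshold.  Mutates the screen entries of dropped variables;
    returns the final VIFs of the survivors."""
    current = [v.name for v in screens if v.included]
    by_name = {v.name: v for v in screens}
    if not current:
        return {}
    while len(current) > 1:
        vifs = compute_vifs(table, current)
        worst = max(current, key=lambda n: (vifs[n], n))
        if vifs[worst] < vif_threshold:
            return vifs
        by_name[worst].included = False
        by_name[worst].exclusion_reason = "vif-dropped"
        current.remove(worst)
    return compute_vifs(table, current) if current else {}


def screen_predictors(table: pd.DataFrame, response: str,
                      candidates: list[str], family: FamilySpec,
                      p_threshold: float = 0.1,
                      correlation_threshold: float = 0.7,
                      vif_threshold: float = 10.0,
                      allowlist: list[str] | None = None,
                      blocklist: list[str] | None = None) -> ScreeningReport:
    """Full screening chain.  ``allowlist``/``blocklist`` stand in for
    the literature-based relevance judgement a modeller would apply:
    blocked variables never enter; allowlisted variables restrict the
    candidate pool."""
    cand = [c for c in candidates if not blocklist or c not in blocklist]
    if allowlist:
        cand = [c for c in cand if c in allowlist]
    report = ScreeningReport(response=response)
    report.notes.append(
        "scale competition applied within the correlation filter "
        "(best-ranked scale per multiscale family retained)")
    screens = univariate_screen(table, response, cand, family, p_threshold)
    screens = correlation_filter(screens, table, correlation_threshold)
    report.final_vifs = vif_cascade(table, screens, vif_threshold)
    for vs in screens:
        report.variables[vs.name] = vs
    ranked_kept = [v.name for v in screens if v.included]
    report.retained = ranked_kept
    return report
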