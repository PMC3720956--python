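"""GLM calibration for presence-absence and abundance responses.

Presence-absence (PA) data are modelled with a logit link under a
binomial family, switching to quasibinomial when grouped data show
overdispersion.  Abundance (AB) counts use a log link under a negative
binomial family whose clumping parameter k (variance = mu + mu^2/k) is
estimated by profile maximum likelihood; when k is large (little
aggregation) the Poisson family is used instead.

Minimal adequate models (MAMs) are found by bidirectional stepwise
selection on AIC, run from both the full-scope and the intercept-only
start, keeping the better endpoint.  Goodness of fit is Nagelkerke's
R^2; the explanatory weight of each abiotic category is the rise in
residual deviance when the category's predictors are removed from the
MAM, as a percentage of the null deviance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize

from . import catalog

logger = logging.getLogger(__name__)

PA_FAMILIES = ("binomial", "quasibinomial")
AB_FAMILIES = ("poisson", "negative_binomial")

_SEPARATION_BOUND = 25.0  # |coef| beyond this on the link scale flags separation
_K_BOUNDS = (np.log(1e-4), np.log(1e6))


@dataclass(frozen=True)
class FamilySpec:
    """Error family and link for one response.

    PA responses use the logit link (binomial/quasibinomial); AB
    responses use the log link (poisson/negative_binomial).  ``k`` is
    the negative-binomial clumping parameter (None = estimate by profile
    likelihood); ``dispersion`` is the quasibinomial scale estimate.
    """

    family: str
    k: float | None = None
    dispersion: float | None = None

    def __post_init__(self) -> None:
        if self.family not in PA_FAMILIES + AB_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.k is not None and self.k <= 0:
            raise ValueError("clumping parameter k must be > 0")

    @property
    def link(self) -> str:
        return "logit" if self.family in PA_FAMILIES else "log"

    @property
    def is_quasi(self) -> bool:
        return self.family == "quasibinomial"


@dataclass
class FittedModel:
    """One calibrated GLM with its fit statistics."""

    family: FamilySpec
    response: str
    predictors: list[str]
    params: "pd.Series[float]"  # index: const + predictor names
    bse: "pd.Series[float]"
    null_deviance: float
    deviance: float
    llf: float
    aic: float
    n: int
    predictor_set: str | None = None  # ABIOT | BIOT | FULL
    dataset_id: int | None = None
    separation: bool = False
    notes: list[str] = field(default_factory=list)

    def predict_eta(self, table: pd.DataFrame) -> np.ndarray:
        missing = [p for p in self.predictors if p not in table.columns]
        if missing:
            raise ValueError(f"missing predictor columns: {', '.join(missing)}")
        eta = np.full(len(table), self.params["const"], dtype=float)
        for p in self.predictors:
            eta += self.params[p] * table[p].to_numpy(dtype=float)
        return eta

    def predict_mean(self, table: pd.DataFrame) -> np.ndarray:
        eta = self.predict_eta(table)
        if self.family.link == "logit":
            return 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        return np.exp(np.clip(eta, -700, 700))

    @property
    def explained_deviance(self) -> float:
        if self.null_deviance <= 0:
            return 0.0
        return (self.null_deviance - self.deviance) / self.null_deviance

    def to_dict(self) -> dict:
        return {
            "family": self.family.family,
            "link": self.family.link,
            "k": self.family.k,
            "dispersion": self.family.dispersion,
            "response": self.response,
            "predictors": self.predictors,
            "coefficients": {k: float(v) for k, v in self.params.items()},
            "standard_errors": {k: float(v) for k, v in self.bse.items()},
            "null_deviance": self.null_deviance,
            "residual_deviance": self.deviance,
            "log_likelihood": self.llf,
            "aic": self.aic,
            "n": self.n,
            "predictor_set": self.predictor_set,
            "dataset_id": self.dataset_id,
            "separation": self.separation,
            "notes": self.notes,
        }


def _design(table: pd.DataFrame, response: str, predictors: list[str]):
    y = table[response].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(table))]
        + [table[p].to_numpy(dtype=float) for p in predictors])
    names = ["const"] + list(predictors)
    return y, X, names


def _sm_family(spec: FamilySpec):
    if spec.family in ("binomial", "quasibinomial"):
        return sm.families.Binomial()
    if spec.family == "poisson":
        return sm.families.Poisson()
    k = spec.k if spec.k is not None else 1.0
    return sm.families.NegativeBinomial(alpha=1.0 / k)


def _profile_k(y: np.ndarray, X: np.ndarray) -> float:
    """Clumping parameter maximizing the NB profile likelihood."""

    def neg_llf(log_k: float) -> float:
        fam = sm.families.NegativeBinomial(alpha=float(np.exp(-log_k)))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(y, X, family=fam).fit(maxiter=100)
            return -res.llf
        except Exception:
            return np.inf

    out = optimize.minimize_scalar(neg_llf, bounds=_K_BOUNDS,
                                   method="bounded",
                                   options={"xatol": 1e-8})
    return float(np.exp(out.x))


def fit_glm(table: pd.DataFrame, response: str, predictors: list[str],
            family: FamilySpec) -> FittedModel:
    """Maximum-likelihood (IRLS) fit of one GLM.

    For a negative-binomial family without a fixed ``k``, k is estimated
    by profile likelihood jointly with the coefficients.  Perfect
    separation of a PA response is caught and replaced with a weakly
    ridge-penalized fit, flagged on the result.
    """
    for p in predictors:
        if table[p].nunique() <= 1:
            raise ValueError(f"predictor {p!r} is constant")
    y, X, names = _design(table, response, predictors)
    n = len(y)
    if n <= len(names):
        raise ValueError(
            f"n={n} too small for {len(names)} parameters ({response})")

    spec = family
    if spec.family == "negative_binomial" and spec.k is None:
        spec = replace(spec, k=_profile_k(y, X))
    fam = _sm_family(spec)

    separation = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=fam).fit(maxiter=200)
        params = np.asarray(res.params, dtype=float)
        if (spec.link == "logit"
                and np.any(np.abs(params[1:]) > _SEPARATION_BOUND)):
            separation = True
    except Exception as exc:
        if spec.link != "logit":
            raise RuntimeError(
                f"GLM fit failed for {response} ~ {predictors}: {exc}") from exc
        separation = True

    if separation:
        logger.warning("separation detected for %s ~ %s; ridge fallback",
                       response, predictors)
        model = sm.GLM(y, X, family=fam)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pen = model.fit_regularized(alpha=1e-4, L1_wt=0.0)
        params = np.asarray(pen.params, dtype=float)
        mu = fam.link.inverse(X @ params)
        deviance = float(fam.deviance(y, mu))
        llf = float(model.loglike(params))
        null = fit_glm(table, response, [], spec) if predictors else None
        null_dev = null.deviance if null is not None else deviance
        bse = pd.Series(np.full(len(names), np.nan), index=names)
        k_params = len(names) + (1 if spec.family == "negative_binomial" else 0)
        return FittedModel(
            family=spec, response=response, predictors=list(predictors),
            params=pd.Series(params, index=names), bse=bse,
            null_deviance=null_dev, deviance=deviance, llf=llf,
            aic=-2.0 * llf + 2.0 * k_params, n=n, separation=True,
            notes=["perfect separation: ridge-penalized fallback fit"])

    n_params = len(names) + (1 if spec.family == "negative_binomial" else 0)
    llf = float(res.llf)
    aic = -2.0 * llf + 2.0 * n_params
    notes = []
    if spec.is_quasi:
        df_resid = max(n - len(names), 1)
        c_hat = spec.dispersion
        if c_hat is None:
            c_hat = float(res.pearson_chi2) / df_resid
            spec = replace(spec, dispersion=c_hat)
        aic = -2.0 * llf / c_hat + 2.0 * len(names)  # QAIC
        notes.append(f"quasibinomial: QAIC with c_hat={c_hat:.4g}")
    bse = pd.Series(np.asarray(res.bse, dtype=float), index=names)
    if spec.is_quasi:
        bse = bse * np.sqrt(spec.dispersion)
    return FittedModel(
        family=spec, response=response, predictors=list(predictors),
        params=pd.Series(np.asarray(res.params, dtype=float), index=names),
        bse=bse,
        null_deviance=float(res.null_deviance), deviance=float(res.deviance),
        llf=llf, aic=aic, n=n, notes=notes)


def choose_family(table: pd.DataFrame, response_kind: str, response: str,
                  dispersion_threshold: float = 1.5,
                  k_threshold: float = 10.0) -> FamilySpec:
    """Pick the error family for a response column.

    PA: binomial; quasibinomial only when the data are grouped (non-binary
    proportions/counts) and the Pearson dispersion of the binomial fit
    exceeds ``dispersion_threshold`` (binary 0/1 data cannot exhibit
    estimable overdispersion).  AB: negative binomial with profile-ML k;
    Poisson when k exceeds ``k_threshold`` (low aggregation) or the
    sample is under-dispersed.
    """
    y = table[response].to_numpy(dtype=float)
    if response_kind == "PA":
        binary = set(np.unique(y)) <= {0.0, 1.0}
        if binary:
            return FamilySpec("binomial")
        m = fit_glm(table, response, [], FamilySpec("binomial"))
        # Pearson dispersion of the intercept-only fit
        mu = m.predict_mean(table)
        disp = float(np.sum((y - mu) ** 2 / (mu * (1 - mu))) / max(len(y) - 1, 1))
        if disp > dispersion_threshold:
            logger.info("%s: Pearson dispersion %.3f > %.2f -> quasibinomial",
                        response, disp, dispersion_threshold)
            return FamilySpec("quasibinomial", dispersion=disp)
        return FamilySpec("binomial")
    if response_kind != "AB":
        raise ValueError("response_kind must be 'PA' or 'AB'")
    if y.var() <= y.mean() or y.mean() == 0:
        logger.info("%s: variance <= mean; Poisson", response)
        return FamilySpec("poisson")
    y_, X, _ = _design(table, response, [])
    k_hat = _profile_k(y_, X)
    if k_hat > k_threshold:
        logger.info("%s: k_hat=%.2f > %.1f (low aggregation) -> Poisson",
                    response, k_hat, k_threshold)
        return FamilySpec("poisson")
    return FamilySpec("negative_binomial", k=k_hat)


def _criterion(m: FittedModel) -> float:
    return m.aic


def stepwise_aic(table: pd.DataFrame, response: str, scope: list[str],
                 family: FamilySpec) -> FittedModel:
    """Bidirectional stepwise AIC from both the full-scope and the
    intercept-only start; the lower-AIC endpoint is the MAM.

    At each step every single-term addition and deletion is evaluated
    and the move with the largest AIC decrease taken; ties go to fewer
    parameters, then to the lexicographically smaller predictor set.
    Stops when no move strictly decreases AIC.
    """
    scope = sorted(scope)
    if family.is_quasi and family.dispersion is None:
        # QAIC needs a common dispersion: estimate it on the largest model
        full = fit_glm(table, response, scope,
                       FamilySpec("binomial"))
        df_resid = max(full.n - len(scope) - 1, 1)
        y, X, _ = _design(table, response, scope)
        mu = full.predict_mean(table)
        c_hat = float(np.sum((y - mu) ** 2 / (mu * (1 - mu))) / df_resid)
        family = replace(family, dispersion=max(c_hat, 1e-8))
        logger.info("quasibinomial stepping with c_hat=%.4g from full model",
                    family.dispersion)

    cache: dict[frozenset, FittedModel] = {}

    def fit_subset(preds: frozenset) -> FittedModel | None:
        if preds in cache:
            return cache[preds]
        try:
            m = fit_glm(table, response, sorted(preds), family)
        except Exception as exc:
            logger.info("stepwise: subset %s failed (%s)", sorted(preds), exc)
            m = None
        cache[preds] = m
        return m

    def walk(start: frozenset) -> FittedModel | None:
        current = fit_subset(start)
        if current is None and start:
            current = fit_subset(frozenset())
        if current is None:
            return None
        while True:
            moves: list[FittedModel] = []
            have = frozenset(current.predictors)
            for p in scope:
                cand = have | {p} if p not in have else have - {p}
                m = fit_subset(cand)
                if m is not None:
                    moves.append(m)
            best = min(
                moves,
                key=lambda m: (m.aic, len(m.predictors), tuple(m.predictors)),
                default=None)
            if best is None or best.aic >= current.aic - 1e-10:
                return current
            current = best

    endpoints = [m for m in (walk(frozenset(scope)), walk(frozenset()))
                 if m is not None]
    if not endpoints:
        raise RuntimeError(f"stepwise selection failed for {response}")
    return min(endpoints,
               key=lambda m: (m.aic, len(m.predictors), tuple(m.predictors)))


def nagelkerke_r2(model: FittedModel) -> float:
    """Nagelkerke's coefficient of determination:
    [1 - exp(-(D0 - D1)/n)] / [1 - exp(-D0/n)]."""
    if model.n == 0:
        raise ValueError("empty model")
    d0, d1, n = model.null_deviance, model.deviance, model.n
    if d0 <= 0:
        raise ValueError("null deviance is zero: R^2 undefined")
    num = 1.0 - np.exp(-(d0 - d1) / n)
    den = 1.0 - np.exp(-d0 / n)
    r2 = float(num / den)
    if -1e-9 < r2 < 0.0:  # null MAM: D1 == D0 up to solver tolerance
        return 0.0
    return min(r2, 1.0)


def category_deviance(mam: FittedModel, table: pd.DataFrame,
                      category_map: dict[str, str] | None = None
                      ) -> dict[str, float | None]:
    """Joint % of null deviance explained by each abiotic category's
    predictors, by refitting the MAM without the category."""
    if not mam.predictors:
        raise ValueError("MAM retains no predictors")
    if category_map is None:
        category_map = {p: catalog.category_of(p) for p in mam.predictors}
    out: dict[str, float | None] = {}
    for cat in ("COVER", "RESISTANCE", "SOIL", "STRUCTURE"):
        members = [p for p in mam.predictors if category_map.get(p) == cat]
        if not members:
            out[cat] = 0.0
            continue
        remaining = [p for p in mam.predictors if p not in members]
        try:
            sub = fit_glm(table, mam.response, remaining, mam.family)
        except Exception as exc:
            logger.warning("category refit without %s failed: %s", cat, exc)
            out[cat] = None
            continue
        out[cat] = float(
            (sub.deviance - mam.deviance) / mam.null_deviance * 100.0)
    return out
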