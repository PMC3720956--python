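"""End-to-end analysis pipeline.

For each of the eight data sets (life stage x sampling scale x
location) and each response (PA, AB) the pipeline:

1. chooses the error family;
2. screens abiotic and biotic candidates separately (univariate p < 0.1,
   |Spearman rho| < 0.7 with scale competition, VIF < 10);
3. selects ABIOT and BIOT minimal adequate models by bidirectional
   stepwise AIC, then a FULL model by stepwise over the union of the
   two selected predictor sets;
4. computes Nagelkerke R^2, AIC tables, per-category explained deviance;
5. evaluates ABIOT models by repeated 2-fold CV (IE) and cross-location
   prediction (EE), and BIOT models by IE;
6. measures cross-stage transferability of the ABIOT models and the
   asymmetric transferability between locations and stages;
7. partitions FULL R^2 into pure-abiotic / pure-biotic / joint parts;
8. tests all ABIOT and BIOT model residuals for spatial autocorrelation
   (Moran's I, permutation test, Holm correction).

Everything is deterministic given the configured seeds; every stage's
decisions (family switches, screening exclusions, tie-breaks) are logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import catalog, synthetic
from .evaluation import (EvaluationResult, external_evaluate,
                         internal_evaluate, metric_for)
from .glm import (FamilySpec, FittedModel, _sm_family, category_deviance,
                  choose_family, fit_glm, nagelkerke_r2, stepwise_aic)
from .partitioning import partition, summarize_partitions
from .screening import ScreeningReport, screen_predictors
from .spatial import MoranReport, residual_autocorrelation
from .transfer import TransferReport, asymmetric_transfer, stage_transfer

logger = logging.getLogger(__name__)

STAGE_TRANSFER_PAIRS = [(1, 5), (2, 6)]  # adult data set, larval 50 cm data set
EE_PAIRS = [(1, 2), (3, 4), (5, 6), (7, 8)]


@dataclass
class RunConfig:
    mode: str = "simulate"  # simulate | csv-dir
    data_dir: str | None = None  # csv-dir mode: dataset_<id>.csv files
    seed: int = 0
    n_points_per_location: int = 120
    cross_scale_rho: float = 0.8
    p_threshold: float = 0.1
    correlation_threshold: float = 0.7
    vif_threshold: float = 10.0
    dispersion_threshold: float = 1.5
    k_threshold: float = 10.0
    cv_iterations: int = 100
    n_permutations: int = 1000
    out_dir: str = "results/run"

    def __post_init__(self) -> None:
        for name in ("p_threshold", "correlation_threshold", "vif_threshold",
                     "dispersion_threshold", "k_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


@dataclass
class ModelTriplet:
    """ABIOT, BIOT and FULL fits of one (data set, response) pair."""

    dataset_id: int
    response_kind: str  # PA | AB
    abiot: FittedModel
    biot: FittedModel
    full: FittedModel
    null_aic: float
    screening: dict[str, ScreeningReport]

    @property
    def r2(self) -> dict[str, float]:
        return {"ABIOT": nagelkerke_r2(self.abiot),
                "BIOT": nagelkerke_r2(self.biot),
                "FULL": nagelkerke_r2(self.full)}


@dataclass
class RunReport:
    config: RunConfig
    triplets: dict[tuple[int, str], ModelTriplet] = field(default_factory=dict)
    r2_table: pd.DataFrame | None = None
    aic_table: pd.DataFrame | None = None
    category_deviance: pd.DataFrame | None = None
    evaluations: list[dict] = field(default_factory=list)
    transfers: list[TransferReport] = field(default_factory=list)
    asymmetric: dict[str, float] = field(default_factory=dict)
    partition_summaries: dict[str, pd.DataFrame] = field(default_factory=dict)
    moran: MoranReport | None = None
    status: dict[str, str] = field(default_factory=dict)


def response_columns(ds_id: int) -> list[tuple[str, str]]:
    """(column, kind) responses modelled for a data set."""
    if ds_id in (1, 2):
        return [("adult_PA", "PA"), ("adult_AB", "AB")]
    return [("larva_PA", "PA"), ("larva_AB", "AB")]


def read_observation_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV observation table, validate column names against the
    catalog, and drop incomplete rows (count logged)."""
    df = pd.read_csv(path)
    catalog.validate_columns(df.columns)
    n0 = len(df)
    df = df.dropna()
    if len(df) < n0:
        logger.warning("%s: dropped %d rows with missing values",
                       path, n0 - len(df))
    return df.reset_index(drop=True)


def _load_datasets(config: RunConfig) -> dict[int, pd.DataFrame]:
    if config.mode == "simulate":
        design = synthetic.SurveyDesignSpec(
            n_points_per_location=config.n_points_per_location)
        truth = synthetic.SyntheticTruth(seed=config.seed,
                                         cross_scale_rho=config.cross_scale_rho)
        survey = synthetic.simulate_survey(design, truth)
        return synthetic.assemble_datasets(survey)
    if config.mode == "csv-dir":
        if config.data_dir is None:
            raise ValueError("csv-dir mode needs data_dir")
        out = {}
        for ds in range(1, 9):
            p = Path(config.data_dir) / f"dataset_{ds}.csv"
            if p.exists():
                out[ds] = read_observation_table(p)
        if not out:
            raise FileNotFoundError(
                f"no dataset_<id>.csv files in {config.data_dir}")
        return out
    raise ValueError(f"unknown mode {config.mode!r}")


def deviance_residuals(model: FittedModel, table: pd.DataFrame) -> np.ndarray:
    """Signed square-root per-observation deviance contributions."""
    fam = _sm_family(model.family)
    y = table[model.response].to_numpy(dtype=float)
    mu = model.predict_mean(table)
    return np.asarray(fam.resid_dev(y, mu), dtype=float)


def fit_triplet(table: pd.DataFrame, ds_id: int, response: str,
                kind: str, config: RunConfig) -> ModelTriplet:
    """Screen, then select the ABIOT, BIOT and FULL MAMs of one response."""
    family = choose_family(table, kind, response,
                           config.dispersion_threshold, config.k_threshold)
    screening = {}
    mams = {}
    for label, candidates in (("ABIOT", synthetic.abiotic_columns(ds_id)),
                              ("BIOT", synthetic.biotic_columns(ds_id))):
        cand = [c for c in candidates if c in table.columns
                and table[c].nunique() > 1]
        rep = screen_predictors(
            table, response, cand, family, config.p_threshold,
            config.correlation_threshold, config.vif_threshold)
        screening[label] = rep
        mam = stepwise_aic(table, response, rep.retained, family)
        mam.predictor_set = label
        mam.dataset_id = ds_id
        mams[label] = mam
    union = sorted(set(mams["ABIOT"].predictors) | set(mams["BIOT"].predictors))
    full = stepwise_aic(table, response, union, family)
    full.predictor_set = "FULL"
    full.dataset_id = ds_id
    null = fit_glm(table, response, [], family)
    return ModelTriplet(ds_id, kind, mams["ABIOT"], mams["BIOT"], full,
                        null_aic=null.aic, screening=screening)


def run_full_analysis(config: RunConfig) -> RunReport:
    report = RunReport(config=config)
    datasets = _load_datasets(config)
    report.status["load"] = "ok"

    r2_rows, aic_rows, cat_rows = [], [], []
    residuals: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    for ds_id in sorted(datasets):
        table = datasets[ds_id]
        for response, kind in response_columns(ds_id):
            if response not in table.columns:
                continue
            label = f"ds{ds_id}-{kind}"
            try:
                trip = fit_triplet(table, ds_id, response, kind, config)
            except Exception as exc:
                logger.error("triplet %s failed: %s", label, exc)
                report.status[label] = f"failed: {exc}"
                continue
            report.triplets[(ds_id, kind)] = trip
            report.status[label] = "ok"
            r2 = trip.r2
            r2_rows.append({"dataset": ds_id, "response": kind, **r2})
            aic_rows.append({"dataset": ds_id, "response": kind,
                             "Null": trip.null_aic, "ABIOT": trip.abiot.aic,
                             "BIOT": trip.biot.aic, "FULL": trip.full.aic})
            if trip.abiot.predictors:
                cats = category_deviance(trip.abiot, table)
                cat_rows.append({"dataset": ds_id, "response": kind, **cats})
            coords = table[["x", "y"]].to_numpy()
            for set_label, m in (("ABIOT", trip.abiot), ("BIOT", trip.biot)):
                residuals[f"{label}-{set_label}"] = (
                    deviance_residuals(m, table), coords)

    report.r2_table = pd.DataFrame(r2_rows)
    report.aic_table = pd.DataFrame(aic_rows)
    report.category_deviance = pd.DataFrame(cat_rows)

    # evaluation: IE for ABIOT and BIOT, EE for ABIOT across locations
    if config.cv_iterations > 0:
        for (ds_id, kind), trip in report.triplets.items():
            table = datasets[ds_id]
            for set_label, m in (("ABIOT", trip.abiot), ("BIOT", trip.biot)):
                if not m.predictors:
                    continue
                try:
                    ev = internal_evaluate(
                        table, m.response, m.predictors, m.family, kind,
                        n_iter=config.cv_iterations,
                        seed=config.seed + 1000 + 10 * ds_id)
                except Exception as exc:
                    logger.warning("IE %s ds%d failed: %s", set_label, ds_id, exc)
                    continue
                ev.calibration_dataset = ds_id
                ev.evaluation_dataset = ds_id
                report.evaluations.append(
                    {"model": set_label, **ev.to_dict(), "response": kind})
    else:
        report.status["evaluation"] = "skipped (cv_iterations = 0)"

    ee_values: dict[str, dict[str, list[float]]] = {
        "A->B": {"AUC": [], "rho": []}, "B->A": {"AUC": [], "rho": []}}
    for a, b in EE_PAIRS:
        for kind in ("PA", "AB"):
            for calib, ev_ds, direction in ((a, b, "A->B"), (b, a, "B->A")):
                trip = report.triplets.get((calib, kind))
                if trip is None or (ev_ds not in datasets):
                    continue
                m = trip.abiot
                if not m.predictors:
                    continue
                try:
                    ev = external_evaluate(
                        datasets[calib], datasets[ev_ds], m.response,
                        m.predictors, m.family, kind)
                except Exception as exc:
                    logger.warning("EE ds%d->ds%d failed: %s", calib, ev_ds, exc)
                    continue
                ev.calibration_dataset = calib
                ev.evaluation_dataset = ev_ds
                report.evaluations.append(
                    {"model": "ABIOT", **ev.to_dict(), "response": kind,
                     "direction": direction})
                ee_values[direction][ev.metric].append(ev.value)

    # cross-stage transferability of the ABIOT MAMs
    t_values: dict[str, dict[str, list[float]]] = {
        "adult->larva": {"AUC": [], "rho": []},
        "larva->adult": {"AUC": [], "rho": []}}
    for adult_ds, larva_ds in STAGE_TRANSFER_PAIRS:
        for kind in ("PA", "AB"):
            target_resp = "larva_" + kind
            adult_resp = "adult_" + kind
            ta = report.triplets.get((adult_ds, kind))
            tl = report.triplets.get((larva_ds, kind))
            if ta is not None and larva_ds in datasets and ta.abiot.predictors:
                try:
                    tr = stage_transfer(ta.abiot, datasets[larva_ds],
                                        target_resp, kind, "adult->larva",
                                        adult_ds, larva_ds)
                    report.transfers.append(tr)
                    t_values["adult->larva"][tr.metric].append(tr.value)
                except Exception as exc:
                    logger.warning("transfer adult->larva ds%d failed: %s",
                                   adult_ds, exc)
            if tl is not None and adult_ds in datasets and tl.abiot.predictors:
                try:
                    tr = stage_transfer(tl.abiot, datasets[adult_ds],
                                        adult_resp, kind, "larva->adult",
                                        larva_ds, adult_ds)
                    report.transfers.append(tr)
                    t_values["larva->adult"][tr.metric].append(tr.value)
                except Exception as exc:
                    logger.warning("transfer larva->adult ds%d failed: %s",
                                   larva_ds, exc)

# positive AT = the forward direction (A->B, larva->adult) transfers worse
    for metric in ("AUC", "rho"):
        fwd, bwd = ee_values["A->B"][metric], ee_values["B->A"][metric]
        if fwd and bwd:
            report.asymmetric[f"AT_location_{metric}"] = asymmetric_transfer(
                float(np.mean(fwd)), float(np.mean(bwd)))
        fwd, bwd = (t_values["larva->adult"][metric],
                    t_values["adult->larva"][metric])
        if fwd and bwd:
            report.asymmetric[f"AT_stage_{metric}"] = asymmetric_transfer(
                float(np.mean(fwd)), float(np.mean(bwd)))

    # hierarchical partitioning of the fitted triplets
    triples = [(ds, kind, partition(*(trip.r2[m] for m in
                                      ("ABIOT", "BIOT", "FULL"))))
               for (ds, kind), trip in sorted(report.triplets.items())]
    if triples:
        for grouping in ("all", "by-location", "by-stage-scale"):
            report.partition_summaries[grouping] = summarize_partitions(
                triples, grouping)

    # residual spatial autocorrelation across the whole model family
    if config.n_permutations > 0 and residuals:
        report.moran = residual_autocorrelation(
            residuals, n_perm=config.n_permutations,
            seed=config.seed + 5000)
    report.status["done"] = "ok"
    return report


def _best_flags(row: pd.Series, cols: list[str], how: str) -> str:
    vals = {c: row[c] for c in cols}
    best = (max if how == "max" else min)(vals, key=lambda c: vals[c])
    return best


def write_report(report: RunReport, out_dir: str | Path) -> None:
    """Serialize every report table: TSVs for the R^2/AIC/coefficient
    tables, JSON for evaluations, transfers, partitions and Moran."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if report.r2_table is not None and len(report.r2_table):
        t3 = report.r2_table.copy()
        t3["best"] = [_best_flags(r, ["ABIOT", "BIOT", "FULL"], "max")
                      for _, r in t3.iterrows()]
        t3.to_csv(out / "table3_style.tsv", sep="\t", index=False,
                  float_format="%.4f",
                  columns=["dataset", "response", "ABIOT", "BIOT", "FULL",
                           "best"])
    if report.aic_table is not None and len(report.aic_table):
        t4 = report.aic_table.copy()
        t4["best"] = [_best_flags(r, ["Null", "ABIOT", "BIOT", "FULL"], "min")
                      for _, r in t4.iterrows()]
        t4.to_csv(out / "table4_style.tsv", sep="\t", index=False,
                  float_format="%.2f")
    if report.category_deviance is not None and len(report.category_deviance):
        report.category_deviance.to_csv(
            out / "category_deviance.tsv", sep="\t", index=False,
            float_format="%.2f")

    coef_rows = []
    for (ds, kind), trip in sorted(report.triplets.items()):
        for m in (trip.abiot, trip.biot, trip.full):
            for term in m.params.index:
                coef_rows.append({
                    "dataset": ds, "response": kind,
                    "model": m.predictor_set, "family": m.family.family,
                    "term": term, "estimate": m.params[term],
                    "se": m.bse[term], "residual_deviance": m.deviance})
    if coef_rows:
        pd.DataFrame(coef_rows).to_csv(out / "coefficients.tsv", sep="\t",
                                       index=False, float_format="%.5f")

    (out / "evaluation.json").write_text(
        json.dumps(report.evaluations, indent=1, default=float))
    (out / "transfer.json").write_text(json.dumps(
        {"transfers": [t.to_dict() for t in report.transfers],
         "asymmetric_transferability_pct": report.asymmetric},
        indent=1, default=float))
    for grouping, df in report.partition_summaries.items():
        df.to_csv(out / f"partition_{grouping}.tsv", sep="\t", index=False,
                  float_format="%.4f")
    if report.moran is not None:
        (out / "moran.json").write_text(
            json.dumps(report.moran.to_dict(), indent=1, default=float))

    screening_payload = {
        f"ds{ds}-{kind}": {lab: rep.to_dict()
                           for lab, rep in trip.screening.items()}
        for (ds, kind), trip in sorted(report.triplets.items())}
    (out / "screening.json").write_text(
        json.dumps(screening_payload, indent=1, default=float))
    (out / "run.json").write_text(json.dumps(
        {"config": asdict(report.config), "status": report.status},
        indent=1, default=float))
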