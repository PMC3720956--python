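"""Seeded synthetic survey generator.

Emulates a two-location, fine-scale survey of a ground beetle with two
co-occurring life stages: 120 stratified sampling points per location
(proportional allocation over five habitat types, minimum 5.5 m spacing),
one pitfall trap per point for adults, and larval burrow maps at three
nested scales — the 1x1 m quadrat, its central 50x50 cm quadrat, and the
sixteen 25x25 cm cells of a 4x4 grid.  Responses are drawn from known
generalized-linear models (logit-link Bernoulli for presence/absence,
log-link negative binomial for counts), so every fitted quantity has a
ground truth to recover.

Counts are conserved across scales by construction: a point's larval
total is allocated multinomially over the 16 cells, the 1x1 m abundance
is the sum of all cells and the 50x50 cm abundance the sum of the
central 2x2 block.  Within-point clumping is induced by gamma-perturbed
allocation weights (``cell_aggregation``), standing in for the burrow
aggregation real surveys show.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import catalog

logger = logging.getLogger(__name__)

# Central 2x2 block of the 4x4 grid = the 50x50 cm quadrat
CENTRAL_CELLS = [(1, 1), (1, 2), (2, 1), (2, 2)]

HABITATS_A = ["BARE_CUSHION", "BARE_SPOT", "DENSE", "GRASSLAND", "SHRUBLAND"]
HABITATS_B = ["BARE_PATH", "BURNED", "DENSE", "GRASSLAND", "SHRUBLAND"]
# location B's mosaic is less favourable (trampled paths / recent burn,
# more closed heath), giving the A-richer-than-B occupancy asymmetry
DEFAULT_ALLOCATION_A = [0.30, 0.20, 0.25, 0.15, 0.10]
DEFAULT_ALLOCATION_B = [0.20, 0.20, 0.30, 0.20, 0.10]

# Habitat mean (logit scale) of the latent percentage-cover variables.
# Bare-ground mosaics carry the open ground; heathland carries Calluna;
# grassland carries herbs/graminoids.  Unlisted bases use a common low mean.
_COVER_MEANS: dict[str, dict[str, float]] = {
    "BARESOIL": {"BARE_CUSHION": 0.2, "BARE_SPOT": -1.0, "BARE_PATH": 0.0,
                 "BURNED": -0.5, "DENSE": -3.0, "GRASSLAND": -2.5,
                 "SHRUBLAND": -2.5},
    "CALLUNA": {"BARE_CUSHION": 0.5, "BARE_SPOT": 1.0, "BARE_PATH": 1.0,
                "DENSE": 2.0, "BURNED": -1.0, "GRASSLAND": -3.0,
                "SHRUBLAND": -2.0},
    "HERB": {"GRASSLAND": 2.0, "BURNED": 0.0},
    "GRAMINOID": {"GRASSLAND": 1.5},
    "SHRUB": {"SHRUBLAND": 2.0, "DENSE": 1.5, "BARE_SPOT": 0.5,
              "BARE_PATH": 0.5, "BARE_CUSHION": 0.0},
    "VACCINIUM": {"DENSE": -0.5, "SHRUBLAND": -1.0},
}
_COVER_DEFAULT_MEAN = -2.5
_COVER_SD = 1.0

# Habitat vegetation-density score driving the RESISTANCE variables.
_DENSITY = {"DENSE": 2.0, "BARE_SPOT": 1.0, "SHRUBLAND": 1.0,
            "BARE_PATH": 0.5, "BARE_CUSHION": 0.0, "BURNED": -1.0,
            "GRASSLAND": -1.5}


@dataclass
class SurveyDesignSpec:
    """Geometry and stratification of the two-location survey."""

    n_locations: int = 2
    n_points_per_location: int = 120
    habitat_types: dict[str, list[str]] = field(
        default_factory=lambda: {"A": list(HABITATS_A), "B": list(HABITATS_B)})
    habitat_allocation: dict[str, list[float]] = field(
        default_factory=lambda: {"A": list(DEFAULT_ALLOCATION_A),
                                 "B": list(DEFAULT_ALLOCATION_B)})
    min_point_spacing: float = 5.5  # metres
    area_extent: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"A": (300.0, 300.0), "B": (300.0, 500.0)})
    quadrat_grid: int = 4  # cells per side of the 1x1 m quadrat
    min_larvae_threshold_per_location: dict[str, int] = field(
        default_factory=lambda: {"A": 5, "B": 3})
    fine_scale_points_cap: dict[str, int | None] = field(
        default_factory=lambda: {"A": 10, "B": 11})

    def __post_init__(self) -> None:
        for loc, props in self.habitat_allocation.items():
            if abs(sum(props) - 1.0) > 1e-9:
                raise ValueError(
                    f"habitat allocation for location {loc} sums to "
                    f"{sum(props)}, not 1")
        if self.quadrat_grid != 4:
            raise ValueError("quadrat_grid must be 4 (16 cells per point)")
        for loc, t in self.min_larvae_threshold_per_location.items():
            if t < 0:
                raise ValueError(f"negative larvae threshold for {loc}")

    @property
    def locations(self) -> list[str]:
        return list(self.habitat_types)[: self.n_locations]


@dataclass
class StageModel:
    """Linear predictor of one response: intercept + coefficients over
    named covariate columns (raw column values)."""

    intercept: float
    coef: dict[str, float] = field(default_factory=dict)

    def eta(self, table: pd.DataFrame) -> np.ndarray:
        out = np.full(len(table), self.intercept, dtype=float)
        for name, c in self.coef.items():
            out += c * table[name].to_numpy(dtype=float)
        # guard the exp/expit against runaway predictors
        clipped = np.clip(out, -30.0, 30.0)
        if np.any(clipped != out):
            logger.warning("linear predictor clipped to +/-30 for %d rows",
                           int(np.sum(clipped != out)))
        return clipped


@dataclass
class SyntheticTruth:
    """Generating model: covariate distributions, per-response linear
    predictors, count dispersion, and the seed."""

    seed: int = 0
    cross_scale_rho: float = 0.8  # target Spearman corr between scales
    cell_aggregation: float = 1.0  # gamma shape of cell-weight noise; small = clumped
    # negative-binomial clumping parameter k per count response
    family_k: dict[str, float] = field(
        default_factory=lambda: {"adult_AB": 1.5, "larva_total": 0.8,
                                 "congener_adult_AB": 1.0,
                                 "congener_larva_total": 0.8})
    instar_probs: tuple[float, float, float] = (0.3, 0.4, 0.3)
    male_fraction: float = 0.5
    stage_models: dict[str, StageModel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.stage_models:
            self.stage_models = default_stage_models()
        for resp, k in self.family_k.items():
            if k <= 0:
                raise ValueError(f"clumping parameter k for {resp} must be > 0")
        known = set(catalog.REGISTRY)
        for resp, m in self.stage_models.items():
            bad = set(m.coef) - known
            if bad:
                raise ValueError(
                    f"stage model {resp} references unknown covariates: {bad}")


def default_stage_models() -> dict[str, StageModel]:
    """Default generating coefficients.

    Calibrated once so that, over the default covariate distributions,
    adults occur in roughly a third of traps with on the order of one
    capture per trap, larvae occupy just under half of the points with a
    few larvae per occupied point, and location A is richer than B —
    the occupancy pattern a heathland survey of this kind reports.
    Larval placement follows bare ground and avoids dense herb cover;
    adults track larval presence on top of the same abiotic gradient.
    """
    return {
        "larva_total": StageModel(
            intercept=-1.2,
            coef={"BARESOIL_1": 0.055, "HERB_1": -0.030, "CALLUNA_1": 0.012}),
        "larva_cell": StageModel(
            intercept=0.0, coef={"BARESOIL_25": 0.030}),
        "adult_PA": StageModel(
            intercept=-2.3,
            coef={"BARESOIL_1": 0.045, "HERB_1": -0.020, "larva_PA_1m": 1.0}),
        "adult_AB": StageModel(
            intercept=-2.2,
            coef={"BARESOIL_1": 0.050, "HERB_1": -0.020, "larva_PA_1m": 0.8}),
        "congener_adult_PA": StageModel(
            intercept=-1.8, coef={"BARESOIL_1": 0.030, "GRAMINOID_1": 0.010}),
        "congener_adult_AB": StageModel(
            intercept=-2.0, coef={"BARESOIL_1": 0.030, "GRAMINOID_1": 0.010}),
        "congener_larva_total": StageModel(
            intercept=-1.6, coef={"BARESOIL_1": 0.040, "HERB_1": -0.010}),
        "congener_larva_cell": StageModel(
            intercept=0.0, coef={"BARESOIL_25": 0.020}),
    }


@dataclass
class LarvalCellMap:
    """4x4 grid of larval counts for one sampling point."""

    location: str
    point_id: int
    counts: np.ndarray  # (4, 4) int
    instars: np.ndarray | None = None  # (4, 4, 3) int, by instar

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (4, 4):
            raise ValueError("cell map must be 4x4")
        if (self.counts < 0).any():
            raise ValueError("cell counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def central_total(self) -> int:
        return int(self.counts[1:3, 1:3].sum())


@dataclass
class Survey:
    """A simulated survey: the point-level table, per-cell covariates,
    and larval cell maps for the target and congeneric species."""

    design: SurveyDesignSpec
    truth: SyntheticTruth
    points: pd.DataFrame
    cell_covariates: pd.DataFrame | None = None
    cell_maps: dict[tuple[str, int], LarvalCellMap] = field(default_factory=dict)
    congener_cell_maps: dict[tuple[str, int], LarvalCellMap] = field(
        default_factory=dict)


# ---------------------------------------------------------------------------
# point placement and covariates

def _place_points(rng: np.random.Generator, n: int, extent: tuple[float, float],
                  min_spacing: float, max_attempts: int = 200_000
                  ) -> np.ndarray:
    """Uniform points in a rectangle, rejection-sampled to min spacing."""
    pts = np.empty((n, 2))
    placed = 0
    attempts = 0
    while placed < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n} points at >= {min_spacing} m spacing "
                f"within a {extent[0]} x {extent[1]} m area "
                f"({placed} placed): min_point_spacing infeasible")
        cand = rng.uniform((0, 0), extent)
        attempts += 1
        d2 = np.sum((pts[:placed] - cand) ** 2, axis=1)
        if placed == 0 or d2.min() >= min_spacing ** 2:
            pts[placed] = cand
            placed += 1
    return pts


def _proportional_counts(props: list[float], n: int) -> list[int]:
    """Largest-remainder allocation of n units over proportions."""
    raw = [p * n for p in props]
    base = [int(np.floor(r)) for r in raw]
    short = n - sum(base)
    order = np.argsort([b - r for b, r in zip(base, raw)])  # largest remainder first
    for i in order[:short]:
        base[i] += 1
    return base


def _correlated_scales(rng: np.random.Generator, mu: np.ndarray, sd: float,
                       rho_s: float, n_versions: int) -> np.ndarray:
    """(n, n_versions) latent draws with pairwise Spearman corr rho_s.

    The marginal latent correlation between scale versions is targeted at
    2*sin(pi*rho_s/6) — the inverse of the Gaussian rank-correlation map —
    so the rank correlation of any monotone transform of the output lands
    on rho_s.  The habitat means mu are shared across versions, so the
    within-habitat noise correlation is solved from
    var(mu) + sd^2 * r = R * (var(mu) + sd^2); when the habitat structure
    alone already exceeds the target (r < 0) the noise is left independent
    and the shortfall logged.
    """
    n = len(mu)
    if rho_s >= 1.0:
        z = rng.standard_normal(n)
        return mu[:, None] + sd * np.repeat(z[:, None], n_versions, axis=1)
    big_r = 2.0 * np.sin(np.pi * rho_s / 6.0)
    v_mu = float(np.var(mu))
    r = (big_r * (v_mu + sd ** 2) - v_mu) / sd ** 2
    if r < 0.0:
        logger.warning("cross-scale rho %.2f unreachable below habitat "
                       "structure floor; using independent noise", rho_s)
        r = 0.0
    r = min(r, 1.0)
    shared = rng.standard_normal(n)
    eps = rng.standard_normal((n, n_versions))
    z = np.sqrt(r) * shared[:, None] + np.sqrt(1.0 - r) * eps
    return mu[:, None] + sd * z


def generate_covariates(design: SurveyDesignSpec, truth: SyntheticTruth,
                        rng: np.random.Generator | None = None) -> Survey:
    """Lay out the sampling points and draw all abiotic covariates.

    Returns a Survey whose ``points`` table has one row per sampling
    point (metadata + abiotic columns; percentage covers in [0, 100])
    and whose ``cell_covariates`` table carries the per-cell 25x25 cm
    COVER values used by the fine-scale data sets.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    frames = []
    cell_frames = []
    for loc in design.locations:
        habs = design.habitat_types[loc]
        counts = _proportional_counts(design.habitat_allocation[loc],
                                      design.n_points_per_location)
        habitat = np.repeat(habs, counts)
        rng.shuffle(habitat)
        xy = _place_points(rng, design.n_points_per_location,
                           design.area_extent[loc], design.min_point_spacing)
        n = design.n_points_per_location
        df = pd.DataFrame({
            "location": loc,
            "point_id": np.arange(1, n + 1),
            "habitat_type": habitat,
            "x": xy[:, 0], "y": xy[:, 1],
        })
        cells = pd.DataFrame({
            "location": loc,
            "point_id": np.repeat(np.arange(1, n + 1), 16),
            "cell_row": np.tile(np.repeat(np.arange(4), 4), n),
            "cell_col": np.tile(np.tile(np.arange(4), 4), n),
        })

        # COVER family: three point-level scale versions + 16 cell values,
        # all sharing one latent per point so scales correlate as configured
        for base in catalog.COVER_BASES:
            means = _COVER_MEANS.get(base, {})
            mu = np.array([means.get(h, _COVER_DEFAULT_MEAN) for h in habitat])
            lat = _correlated_scales(rng, mu, _COVER_SD, truth.cross_scale_rho, 3)
            for j, s in enumerate(catalog.COVER_SCALES):
                df[f"{base}_{s}"] = 100.0 * expit(lat[:, j])
            cell_lat = _correlated_scales(
                rng, np.repeat(mu, 16), _COVER_SD, truth.cross_scale_rho, 1)
            cells[f"{base}_25"] = 100.0 * expit(cell_lat[:, 0])

        dens = np.array([_DENSITY[h] for h in habitat])
        for d in "NESW":
            df[f"COVER_{d}"] = 100.0 * expit(dens + 0.8 * rng.standard_normal(n))
            df[f"SQUARE_{d}"] = np.minimum(
                rng.poisson(np.exp(2.0 + 0.3 * dens)), 36)
        df["HEIGHT"] = np.clip(25 + 5 * dens + 5 * rng.standard_normal(n), 0, None)

        frac = rng.dirichlet([4, 6, 8, 8, 6, 4], size=n) * 100.0
        for j, v in enumerate(["SOIL_0.063", "SOIL_0.125", "SOIL_0.25",
                               "SOIL_0.50", "SOIL_1", "SOIL_2"]):
            df[v] = frac[:, j]
        df["SOIL_HUMID"] = 100.0 * expit(-1.0 + 0.5 * rng.standard_normal(n))
        df["SOIL_OM"] = 100.0 * expit(-2.0 + 0.5 * rng.standard_normal(n))
        df["SOIL_PH"] = 4.5 + 0.3 * rng.standard_normal(n)
        df["LITTER_DEPTH"] = rng.lognormal(0.0, 0.5, n)

        openness = -dens  # open ground mirrors low vegetation density
        open3 = rng.poisson(np.exp(0.8 + 0.4 * openness))
        df["OPEN_3"] = open3
        df["OPEN_6"] = open3 + rng.poisson(np.exp(1.0 + 0.4 * openness))
        sh3 = rng.poisson(np.exp(-0.5 + 0.5 * dens))
        df["SHRUBTALL_3"] = sh3
        df["SHRUBTALL_6"] = sh3 + rng.poisson(np.exp(-0.2 + 0.5 * dens))
        score = np.clip(np.round(3.5 + openness + 0.7 * rng.standard_normal(n)),
                        1, 6).astype(int)
        df["STRUCTURE_3"] = score
        df["STRUCTURE_6"] = np.clip(
            score + rng.integers(-1, 2, n), 1, 6).astype(int)
        df["DIST_OPEN"] = rng.lognormal(3.0 + 0.5 * dens, 0.8, n)
        df["DIST_SHRUB"] = rng.lognormal(4.5 - 0.3 * dens, 0.8, n)

        frames.append(df)
        cell_frames.append(cells)

    points = pd.concat(frames, ignore_index=True)
    points.insert(0, "unit_id",
                  points["location"] + "-" + points["point_id"].map("{:03d}".format))
    return Survey(design=design, truth=truth, points=points,
                  cell_covariates=pd.concat(cell_frames, ignore_index=True))


# ---------------------------------------------------------------------------
# responses

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, k: float) -> np.ndarray:
    """Negative binomial with mean ``mean`` and clumping parameter k
    (variance = mean + mean^2/k), via the gamma-Poisson mixture."""
    lam = rng.gamma(shape=k, scale=np.asarray(mean) / k)
    return rng.poisson(lam)


def _place_cells(rng: np.random.Generator, total: int, weights: np.ndarray,
                 aggregation: float) -> np.ndarray:
    """Allocate a point total over 16 cells: multinomial with
    gamma-perturbed weights (small ``aggregation`` = strong clumping)."""
    w = weights * rng.gamma(aggregation, 1.0 / aggregation, size=16)
    w = w / w.sum()
    return rng.multinomial(total, w).reshape(4, 4)


def _larval_maps(rng, truth, points, cell_covariates, total_model: str,
                 cell_model: str, k: float, with_instars: bool
                 ) -> dict[tuple[str, int], LarvalCellMap]:
    eta_pt = truth.stage_models[total_model].eta(points)
    totals = _nb_draw(rng, np.exp(eta_pt), k)
    cm = truth.stage_models[cell_model]
    maps = {}
    for (loc, pid), tot in zip(points[["location", "point_id"]].itertuples(index=False),
                               totals):
        sub = cell_covariates[(cell_covariates["location"] == loc)
                              & (cell_covariates["point_id"] == pid)]
        w = np.exp(cm.eta(sub))
        counts = _place_cells(rng, int(tot), w, truth.cell_aggregation)
        instars = None
        if with_instars:
            instars = np.zeros((4, 4, 3), dtype=int)
            flat = counts.ravel()
            for idx, c in enumerate(flat):
                if c > 0:
                    instars[idx // 4, idx % 4] = rng.multinomial(
                        c, truth.instar_probs)
        maps[(loc, pid)] = LarvalCellMap(loc, int(pid), counts, instars)
    return maps


def generate_responses(survey: Survey,
                       rng: np.random.Generator | None = None) -> Survey:
    """Draw all responses from the truth models, in dependency order:
    larval cell maps first (target and congener), then adults, whose
    linear predictors may reference larval presence."""
    truth = survey.truth
    if rng is None:
        rng = np.random.default_rng(truth.seed + 1)
    pts = survey.points
    if survey.cell_covariates is None:
        raise ValueError("covariates must be generated first")

    survey.cell_maps = _larval_maps(
        rng, truth, pts, survey.cell_covariates, "larva_total", "larva_cell",
        truth.family_k["larva_total"], with_instars=True)
    survey.congener_cell_maps = _larval_maps(
        rng, truth, pts, survey.cell_covariates, "congener_larva_total",
        "congener_larva_cell", truth.family_k["congener_larva_total"],
        with_instars=False)

    keys = list(zip(pts["location"], pts["point_id"]))
    pts["larva_AB"] = [survey.cell_maps[key].total for key in keys]
    pts["larva_PA"] = (pts["larva_AB"] > 0).astype(int)
    for i in range(3):
        pts[f"larva{i + 1}_AB"] = [
            int(survey.cell_maps[key].instars[:, :, i].sum()) for key in keys]
    pts["congener_larva_AB"] = [survey.congener_cell_maps[key].total
                                for key in keys]
    pts["congener_larva_PA"] = (pts["congener_larva_AB"] > 0).astype(int)

    # biotic columns referenced by the adult truth models
    pts["larva_PA_1m"] = pts["larva_PA"]
    pts["larva_AB_1m"] = pts["larva_AB"]

    pts["adult_PA"] = rng.binomial(
        1, expit(truth.stage_models["adult_PA"].eta(pts)))
    ab = _nb_draw(rng, np.exp(truth.stage_models["adult_AB"].eta(pts)),
                  truth.family_k["adult_AB"])
    # a trap with captures is a presence; reconcile the two draws
    pts["adult_AB"] = np.where(pts["adult_PA"] == 1, np.maximum(ab, 1), 0)
    males = rng.binomial(pts["adult_AB"], truth.male_fraction)
    pts["male_PA"] = (males > 0).astype(int)
    pts["female_PA"] = ((pts["adult_AB"] - males) > 0).astype(int)

    pts["congener_adult_PA"] = rng.binomial(
        1, expit(truth.stage_models["congener_adult_PA"].eta(pts)))
    cab = _nb_draw(rng,
                   np.exp(truth.stage_models["congener_adult_AB"].eta(pts)),
                   truth.family_k["congener_adult_AB"])
    pts["congener_adult_AB"] = np.where(
        pts["congener_adult_PA"] == 1, np.maximum(cab, 1), 0)
    return survey


def simulate_survey(design: SurveyDesignSpec | None = None,
                    truth: SyntheticTruth | None = None,
                    seed: int | None = None) -> Survey:
    """Convenience wrapper: covariates then responses, fully seeded."""
    design = design or SurveyDesignSpec()
    truth = truth or SyntheticTruth()
    if seed is not None:
        truth.seed = seed
    rng = np.random.default_rng(truth.seed)
    survey = generate_covariates(design, truth, rng)
    return generate_responses(survey, rng)


# ---------------------------------------------------------------------------
# neighbour geometry

def neighbour_count(cell_map: LarvalCellMap | np.ndarray,
                    focal: str | tuple[int, int]) -> int:
    """Larvae in the quadrats bordering a focal quadrat of the 4x4 grid.

    ``focal="central"`` is the 50x50 cm quadrat (central 2x2 block); its
    neighbourhood is the 12-cell ring around it.  ``focal=(row, col)`` is
    a single 25x25 cm cell; its neighbourhood is the 8-neighbourhood
    clipped to the grid (3 cells at corners, 5 at edges, 8 interior).
    Neighbourhoods never cross the sampling-point boundary.
    """
    counts = cell_map.counts if isinstance(cell_map, LarvalCellMap) \
        else np.asarray(cell_map, dtype=int)
    if counts.shape != (4, 4):
        raise ValueError("cell map must be 4x4")
    if focal == "central":
        return int(counts.sum() - counts[1:3, 1:3].sum())
    r, c = focal
    if not (0 <= r < 4 and 0 <= c < 4):
        raise ValueError(f"focal cell {focal} outside the 4x4 grid")
    total = 0
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == dc == 0:
                continue
            rr, cc = r + dr, c + dc
            if 0 <= rr < 4 and 0 <= cc < 4:
                total += int(counts[rr, cc])
    return total


def neighbour_set_size(focal: tuple[int, int]) -> int:
    """Number of bordering 25x25 cm quadrats of a cell (3, 5 or 8)."""
    r, c = focal
    if not (0 <= r < 4 and 0 <= c < 4):
        raise ValueError(f"focal cell {focal} outside the 4x4 grid")
    edge = (r in (0, 3)) + (c in (0, 3))
    return {0: 8, 1: 5, 2: 3}[edge]


# ---------------------------------------------------------------------------
# data-set assembly (the eight life-stage x scale tables)

_POINT_ABIOTIC_1M = (catalog.abiotic_names(("RESISTANCE", "SOIL", "STRUCTURE"))
                     )


def _abiotic_cols(cover_scales: tuple[str, ...]) -> list[str]:
    return catalog.abiotic_names(cover_scales=cover_scales)


def _select_fine_points(survey: Survey, loc: str) -> list[int]:
    """Points entering the 25x25 cm data sets: minimum-larvae threshold,
    ranked by total larval count (descending), capped; ties broken by
    ascending point_id; deterministic."""
    design = survey.design
    thr = design.min_larvae_threshold_per_location[loc]
    cap = design.fine_scale_points_cap.get(loc)
    totals = [(pid, survey.cell_maps[(loc, pid)].total)
              for pid in survey.points.loc[
                  survey.points["location"] == loc, "point_id"]]
    passing = [(pid, t) for pid, t in totals if t >= thr]
    passing.sort(key=lambda pt: (-pt[1], pt[0]))
    if cap is not None:
        if len(passing) < cap:
            logger.warning(
                "location %s: only %d points pass the %d-larvae threshold "
                "(cap %d); returning all passing points",
                loc, len(passing), thr, cap)
        passing = passing[:cap]
    return [pid for pid, _ in passing]


def assemble_datasets(survey: Survey) -> dict[int, pd.DataFrame]:
    """Build the eight analysis tables (life stage x sampling scale x
    location).  Odd ids are location A, even ids location B:

    1-2  adult responses at the trap, coarse + structural abiotic
         predictors, larval and congeneric-adult biotic predictors;
    3-4  larval responses in the 1x1 m quadrat, adult and
         congeneric-larva biotic predictors;
    5-6  larval responses in the 50x50 cm quadrat, adult and
         12-ring neighbour-larvae biotic predictors;
    7-8  larval responses per 25x25 cm cell (16 rows per retained
         point, threshold-filtered and capped), adult abundance and
         8-neighbourhood neighbour-larvae biotic predictors.
    """
    pts = survey.points
    locs = survey.design.locations
    out: dict[int, pd.DataFrame] = {}
    meta = ["unit_id", "location", "point_id", "habitat_type", "x", "y"]

    for i, loc in enumerate(locs):
        sub = pts[pts["location"] == loc].reset_index(drop=True)

        # adults (data sets 1-2)
        df = sub[meta + _abiotic_cols(("50", "1"))
                 + ["adult_PA", "adult_AB", "male_PA", "female_PA"]
                 + ["larva_PA_1m", "larva_AB_1m"]].copy()
        for j in range(1, 4):
            df[f"larva{j}_AB_1m"] = sub[f"larva{j}_AB"]
        df["congener_adult_PA"] = sub["congener_adult_PA"]
        df["congener_adult_AB"] = sub["congener_adult_AB"]
        df.insert(5, "sampling_scale", "trap")
        out[1 + i] = df

        # larvae at 1x1 m (data sets 3-4)
        df = sub[meta + _abiotic_cols(("1",))
                 + ["larva_PA", "larva_AB",
                    "larva1_AB", "larva2_AB", "larva3_AB"]].copy()
        df["adult_PA_trap"] = sub["adult_PA"]
        df["adult_AB_trap"] = sub["adult_AB"]
        df["male_PA_trap"] = sub["male_PA"]
        df["female_PA_trap"] = sub["female_PA"]
        df["congener_larva_PA"] = sub["congener_larva_PA"]
        df["congener_larva_AB"] = sub["congener_larva_AB"]
        df.insert(5, "sampling_scale", "1m")
        out[3 + i] = df

        # larvae at 50x50 cm (data sets 5-6): central 2x2 block responses
        df = sub[meta + _abiotic_cols(("50", "1"))].copy()
        keys = list(zip(sub["location"], sub["point_id"]))
        central = [survey.cell_maps[k].central_total for k in keys]
        df["larva_AB"] = central
        df["larva_PA"] = (np.asarray(central) > 0).astype(int)
        df["adult_PA_trap"] = sub["adult_PA"]
        df["adult_AB_trap"] = sub["adult_AB"]
        df["male_PA_trap"] = sub["male_PA"]
        df["female_PA_trap"] = sub["female_PA"]
        df["neighbour_larva_AB"] = [
            neighbour_count(survey.cell_maps[k], "central") for k in keys]
        df.insert(5, "sampling_scale", "50cm")
        out[5 + i] = df

        # larvae per 25x25 cm cell (data sets 7-8)
        chosen = _select_fine_points(survey, loc)
        rows = []
        for pid in chosen:
            cmap = survey.cell_maps[(loc, pid)]
            prow = sub[sub["point_id"] == pid].iloc[0]
            cells = survey.cell_covariates[
                (survey.cell_covariates["location"] == loc)
                & (survey.cell_covariates["point_id"] == pid)]
            for _, crow in cells.iterrows():
                r, c = int(crow["cell_row"]), int(crow["cell_col"])
                rec = {
                    "unit_id": f"{loc}-{pid:03d}-c{r}{c}",
                    "location": loc, "point_id": pid,
                    "cell_id": 4 * r + c,
                    "sampling_scale": "25cm",
                    "habitat_type": prow["habitat_type"],
                    "x": prow["x"] + (c - 1.5) * 0.25,
                    "y": prow["y"] + (r - 1.5) * 0.25,
                }
                for base in catalog.COVER_BASES:
                    rec[f"{base}_25"] = crow[f"{base}_25"]
                    rec[f"{base}_1"] = prow[f"{base}_1"]
                for v in _POINT_ABIOTIC_1M:
                    rec[v] = prow[v]
                rec["larva_AB"] = int(cmap.counts[r, c])
                rec["larva_PA"] = int(cmap.counts[r, c] > 0)
                rec["adult_AB_trap"] = prow["adult_AB"]
                rec["neighbour_larva_AB"] = neighbour_count(cmap, (r, c))
                rows.append(rec)
        out[7 + i] = pd.DataFrame(rows)

    return out


def dataset_metadata(ds_id: int) -> dict[str, str]:
    """Location, life stage and sampling scale of a data-set id."""
    loc = "A" if ds_id % 2 == 1 else "B"
    if ds_id in (1, 2):
        return {"location": loc, "stage": "adult", "scale": "trap"}
    scale = {3: "1m", 4: "1m", 5: "50cm", 6: "50cm", 7: "25cm", 8: "25cm"}[ds_id]
    return {"location": loc, "stage": "larva", "scale": scale}


def biotic_columns(ds_id: int) -> list[str]:
    """Biotic predictor columns attached to a data set."""
    if ds_id in (1, 2):
        return ["larva_PA_1m", "larva_AB_1m", "larva1_AB_1m", "larva2_AB_1m",
                "larva3_AB_1m", "congener_adult_PA", "congener_adult_AB"]
    if ds_id in (3, 4):
        return ["adult_PA_trap", "adult_AB_trap", "male_PA_trap",
                "female_PA_trap", "congener_larva_PA", "congener_larva_AB"]
    if ds_id in (5, 6):
        return ["adult_PA_trap", "adult_AB_trap", "male_PA_trap",
                "female_PA_trap", "neighbour_larva_AB"]
    return ["adult_AB_trap", "neighbour_larva_AB"]


def abiotic_columns(ds_id: int) -> list[str]:
    """Abiotic predictor columns of a data set (COVER scales vary)."""
    if ds_id in (1, 2, 5, 6):
        return _abiotic_cols(("50", "1"))
    if ds_id in (3, 4):
        return _abiotic_cols(("1",))
    return _abiotic_cols(("25", "1"))
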