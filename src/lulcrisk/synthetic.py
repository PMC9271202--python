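"""Synthetic landscapes and ecological site data with known ground truth.

Two generators emulate the inputs of the analysis:

* a per-pixel Markov land-cover process over the base classes
  {forest, pasture, cropland, other} with degradation events (logging,
  fire) layered on primary forest — pixels evolve independently (no
  spatial autocorrelation, which the rate accounting does not use);
* a nested sites-in-catchments-in-regions ecological dataset with known
  class means, covariate slopes and variance components.

Both are deterministic under a fixed seed; :func:`substreams` expands one
global seed into independent per-generator seeds so stages can be
regenerated independently.  :func:`expected_transition_stats` computes,
from the same truth, the exact expectation and standard deviation of
every mean annual transition rate, giving downstream rate accounting a
closed-form recovery oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ANALYSIS_CLASSES, ANALYSIS_CODES, BASE_CLASSES, DegradationSeries, RasterSeries
from .transitions import STANDARD_TRANSITIONS

ECO_CLASSES = ("UF", "LF", "LBF", "SFy", "SFo", "PA", "MA")

#: Site counts per class emulating the 310-site field design.
DEFAULT_CLASS_COUNTS = {
    "UF": 21, "LF": 68, "LBF": 65, "SFy": 33, "SFo": 25, "PA": 72, "MA": 26,
}

DEFAULT_COVARIATE_RANGES = {
    "clay": (5.0, 80.0),        # %
    "elevation": (20.0, 200.0),  # m
    "slope": (0.0, 25.0),        # degrees
}


def substreams(seed: int, names=("landcover", "eco", "occurrence", "analysis")) -> dict[str, int]:
    """Expand one global seed into independent per-generator seeds."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % 2**31) for n, c in zip(names, children)}


# ---------------------------------------------------------------------------
# Land-cover truth and simulator
# ---------------------------------------------------------------------------

@dataclass
class LandCoverTruth:
    """Ground truth of the synthetic land-cover process.

    ``annual_transition_probs`` is the row-stochastic matrix over the
    base classes (forest, pasture, cropland, other) applied independently
    to every pixel each year.  Degradation on primary forest: a logging
    event with probability ``p_logging`` per year given undisturbed, a
    fire event with probability ``p_fire_logged`` given logged (and
    optionally ``p_fire_undisturbed`` given undisturbed).  Initial pixel
    states are drawn from ``initial_probs``; initial forest is primary.
    """

    annual_transition_probs: np.ndarray
    p_logging: float = 0.012
    p_fire_logged: float = 0.02
    p_fire_undisturbed: float = 0.0
    grid_shape: tuple[int, int] = (120, 120)
    pixel_area_km2: float = 1.0
    years: tuple[int, int] = (1985, 2019)
    initial_probs: tuple[float, ...] = (0.60, 0.25, 0.10, 0.05)
    seed: int = 0

    def __post_init__(self) -> None:
        P = np.asarray(self.annual_transition_probs, dtype=float)
        if P.shape != (4, 4):
            raise ValueError("annual_transition_probs must be 4x4 over the base classes")
        if (P < 0).any() or (P > 1).any():
            raise ValueError("transition probabilities must lie in [0, 1]")
        if np.abs(P.sum(axis=1) - 1.0).max() > 1e-12:
            raise ValueError("annual_transition_probs rows must sum to 1")
        self.annual_transition_probs = P
        for name in ("p_logging", "p_fire_logged", "p_fire_undisturbed"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.grid_shape[0] < 1 or self.grid_shape[1] < 1:
            raise ValueError("empty grid")
        if self.years[1] <= self.years[0]:
            raise ValueError("years must be strictly increasing")
        p0 = np.asarray(self.initial_probs, dtype=float)
        if p0.size != 4 or (p0 < 0).any() or abs(p0.sum() - 1) > 1e-12:
            raise ValueError("initial_probs must be 4 probabilities summing to 1")


def default_landcover_truth(seed: int = 0, **overrides) -> LandCoverTruth:
    """Study-condition defaults: a mosaic landscape with slow
    deforestation of a large forest pool, fast pasture/secondary-forest
    turnover and a small cropland conversion share."""
    P = np.array(
        [
            # forest  pasture cropland other
            [0.9790, 0.0180, 0.0010, 0.0020],  # forest
            [0.0600, 0.9050, 0.0200, 0.0150],  # pasture
            [0.0100, 0.0300, 0.9500, 0.0100],  # cropland
            [0.0050, 0.0100, 0.0050, 0.9800],  # other
        ]
    )
    kw = dict(annual_transition_probs=P, seed=seed)
    kw.update(overrides)
    return LandCoverTruth(**kw)


@dataclass
class LandCoverSimulation:
    """Output bundle of :func:`simulate_landcover_series`."""

    base_series: RasterSeries
    degradation: DegradationSeries
    realized: pd.DataFrame  # per-year-pair classified transition areas (ground truth)


def _classified_code(base, primary, deg_state, age, threshold):
    """Vectorized analysis-class code from the simulator's true state."""
    out = np.full(base.shape, ANALYSIS_CODES["other"], dtype=np.int16)
    forest = base == 0
    out[forest & primary & (deg_state == 0)] = ANALYSIS_CODES["UF"]
    out[forest & primary & (deg_state == 1)] = ANALYSIS_CODES["LF"]
    out[forest & primary & (deg_state == 2)] = ANALYSIS_CODES["LBF"]
    sec = forest & ~primary
    out[sec & (age <= threshold)] = ANALYSIS_CODES["SFy"]
    out[sec & (age > threshold)] = ANALYSIS_CODES["SFo"]
    out[base == 1] = ANALYSIS_CODES["PA"]
    out[base == 2] = ANALYSIS_CODES["MA"]
    return out


def simulate_landcover_series(
    truth: LandCoverTruth, age_threshold: int = 20
) -> LandCoverSimulation:
    """Simulate the annual base-class grids and degradation event grids.

    Pixel trajectories are independent Markov chains under the annual
    transition matrix.  Degradation events are sampled on primary-forest
    pixels each year (logging given undisturbed, then fire given logged
    — a newly logged pixel can burn the same year — and optionally fire
    given undisturbed); a cleared pixel re-entering forest becomes
    secondary with age 1 and can never be primary again.

    Returns the base-class raster series, the event series and the
    realized (counted) transition-area table in the seven-class analysis
    schema — the exact ground truth for rate recovery.
    """
    rng = np.random.default_rng(np.random.SeedSequence(truth.seed))
    P = truth.annual_transition_probs
    cum = np.cumsum(P, axis=1)
    rows, cols = truth.grid_shape
    n = rows * cols
    years = np.arange(truth.years[0], truth.years[1] + 1)
    T = years.size

    base = np.empty((T, n), dtype=np.int16)
    logging_ev = np.zeros((T, n), dtype=bool)
    fire_ev = np.zeros((T, n), dtype=bool)

    base[0] = rng.choice(4, size=n, p=np.asarray(truth.initial_probs))
    primary = base[0] == 0
    deg = np.zeros(n, dtype=np.int8)
    age = np.zeros(n, dtype=np.int32)

    classified = np.empty((T, n), dtype=np.int16)
    classified[0] = _classified_code(base[0], primary, deg, age, age_threshold)

    for t in range(1, T):
        u = rng.random(n)
        nxt = np.empty(n, dtype=np.int16)
        for b in range(4):
            m = base[t - 1] == b
            if m.any():
                nxt[m] = np.searchsorted(cum[b], u[m], side="right")
        nxt = np.minimum(nxt, 3)
        was_forest = base[t - 1] == 0
        is_forest = nxt == 0
        # clearing: lose primary status and degradation history, reset age
        cleared = ~is_forest
        primary = primary & is_forest & was_forest
        deg[cleared] = 0
        age[cleared] = 0
        # secondary regrowth and ageing
        regrow = is_forest & ~was_forest
        age[regrow] = 1
        cont_sec = is_forest & was_forest & ~primary
        age[cont_sec] += 1
        # degradation events on primary pixels
        if truth.p_logging > 0 or truth.p_fire_logged > 0 or truth.p_fire_undisturbed > 0:
            undisturbed = primary & (deg == 0)
            new_log = undisturbed & (rng.random(n) < truth.p_logging)
            deg[new_log] = 1
            logging_ev[t] |= new_log
            logged = primary & (deg == 1)
            new_fire = logged & (rng.random(n) < truth.p_fire_logged)
            if truth.p_fire_undisturbed > 0:
                still_uf = primary & (deg == 0)
                new_fire |= still_uf & (rng.random(n) < truth.p_fire_undisturbed)
            deg[new_fire] = 2
            fire_ev[t] |= new_fire
        base[t] = nxt
        classified[t] = _classified_code(nxt, primary, deg, age, age_threshold)

    legend = dict(enumerate(BASE_CLASSES))
    series = RasterSeries(
        base.reshape(T, rows, cols), years, legend, truth.pixel_area_km2
    )
    events = DegradationSeries(
        logging_ev.reshape(T, rows, cols), fire_ev.reshape(T, rows, cols), years
    )

    k = len(ANALYSIS_CLASSES)
    recs = []
    for t in range(T - 1):
        pair = classified[t].astype(np.int64) * k + classified[t + 1]
        counts = np.bincount(pair, minlength=k * k).reshape(k, k)
        nz = np.argwhere(counts)
        for i, j in nz:
            recs.append(
                {
                    "year_from": int(years[t]),
                    "year_to": int(years[t + 1]),
                    "from": ANALYSIS_CLASSES[i],
                    "to": ANALYSIS_CLASSES[j],
                    "area_km2": float(counts[i, j] * truth.pixel_area_km2),
                }
            )
    realized = pd.DataFrame(recs)
    return LandCoverSimulation(series, events, realized)


# ---------------------------------------------------------------------------
# Exact expectations for rate recovery
# ---------------------------------------------------------------------------

def _extended_chain(truth: LandCoverTruth, age_threshold: int):
    """Markov chain over the extended pixel state (degradation states of
    primary forest, secondary ages 1..threshold, old secondary, and the
    non-forest classes), matching the simulator's update order exactly."""
    thr = age_threshold
    names = ["UF", "LF", "LBF"] + [f"S{a}" for a in range(1, thr + 1)] + [
        "SOLD", "PA", "MA", "OT",
    ]
    ix = {nm: i for i, nm in enumerate(names)}
    P = truth.annual_transition_probs
    pf, pp, pc, po = P[0]
    plog, pfl, pfu = truth.p_logging, truth.p_fire_logged, truth.p_fire_undisturbed
    M = np.zeros((len(names), len(names)))

    def deforest(row_state):
        M[ix[row_state], ix["PA"]] = pp
        M[ix[row_state], ix["MA"]] = pc
        M[ix[row_state], ix["OT"]] = po

    M[ix["UF"], ix["UF"]] = pf * (1 - plog) * (1 - pfu)
    M[ix["UF"], ix["LF"]] = pf * plog * (1 - pfl)
    M[ix["UF"], ix["LBF"]] = pf * (plog * pfl + (1 - plog) * pfu)
    deforest("UF")
    M[ix["LF"], ix["LF"]] = pf * (1 - pfl)
    M[ix["LF"], ix["LBF"]] = pf * pfl
    deforest("LF")
    M[ix["LBF"], ix["LBF"]] = pf
    deforest("LBF")
    for a in range(1, thr + 1):
        nxt = f"S{a + 1}" if a < thr else "SOLD"
        M[ix[f"S{a}"], ix[nxt]] = pf
        deforest(f"S{a}")
    M[ix["SOLD"], ix["SOLD"]] = pf
    deforest("SOLD")
    for state, row in (("PA", P[1]), ("MA", P[2]), ("OT", P[3])):
        M[ix[state], ix["S1"]] = row[0]
        M[ix[state], ix["PA"]] = row[1]
        M[ix[state], ix["MA"]] = row[2]
        M[ix[state], ix["OT"]] = row[3]

    labels = []
    for nm in names:
        if nm.startswith("S") and nm != "SOLD":
            labels.append("SFy")
        elif nm == "SOLD":
            labels.append("SFo")
        elif nm == "OT":
            labels.append("other")
        else:
            labels.append(nm)
    pi0 = np.zeros(len(names))
    pi0[ix["UF"]] = truth.initial_probs[0]
    pi0[ix["PA"]] = truth.initial_probs[1]
    pi0[ix["MA"]] = truth.initial_probs[2]
    pi0[ix["OT"]] = truth.initial_probs[3]
    return M, np.array(labels), pi0


def expected_transition_stats(
    truth: LandCoverTruth,
    window: tuple[int, int] | None = None,
    age_threshold: int = 20,
    transitions=STANDARD_TRANSITIONS,
) -> pd.DataFrame:
    """Exact mean and SD of each mean annual transition rate.

    The mean annual rate over a window is an average of counted pixel
    transitions; with independent pixels its expectation and variance
    follow from the extended-state chain in closed form (including the
    across-year covariance of repeated transitions of the same pixel).
    Returns columns ``from``, ``to``, ``expected_rate``, ``sd_rate``.
    """
    M, labels, pi = _extended_chain(truth, age_threshold)
    years = np.arange(truth.years[0], truth.years[1] + 1)
    if window is None:
        window = (int(years[0]), int(years[-1]))
    start, end = window
    if start < years[0] or end > years[-1] or end <= start:
        raise ValueError(f"window {window} invalid for years {years[0]}..{years[-1]}")
    # distribution at each year of the window
    pis = [pi]
    for _ in range(int(end - years[0])):
        pis.append(pis[-1] @ M)
    first = int(start - years[0])
    n_pairs = int(end - start)
    n_pixels = truth.grid_shape[0] * truth.grid_shape[1]
    area = truth.pixel_area_km2

    # powers of M up to the window length
    powers = [np.eye(M.shape[0])]
    for _ in range(n_pairs):
        powers.append(powers[-1] @ M)

    rows = []
    for frm, to in transitions:
        a = (labels == frm).astype(float)
        b = (labels == to).astype(float)
        B = M * np.outer(a, b)
        e = np.array([pis[first + t] @ B @ np.ones_like(a) for t in range(n_pairs)])
        var = float(np.sum(e * (1 - e)))
        for t in range(n_pairs):
            vt = pis[first + t] @ B
            for u in range(t + 1, n_pairs):
                exu = float(vt @ powers[u - t - 1] @ B @ np.ones_like(a))
                var += 2.0 * (exu - e[t] * e[u])
        mean_rate = area * n_pixels * e.mean()
        sd_rate = area * np.sqrt(n_pixels * var) / n_pairs
        rows.append(
            {"from": frm, "to": to, "expected_rate": float(mean_rate), "sd_rate": sd_rate}
        )
    out = pd.DataFrame(rows)
    out.attrs["window"] = (int(start), int(end))
    return out


# ---------------------------------------------------------------------------
# Ecological site data
# ---------------------------------------------------------------------------

@dataclass
class DesignSpec:
    """Nested sampling design: sites in catchments in regions."""

    regions: tuple[str, str] = ("STM", "PGM")
    catchments_per_region: int = 18
    class_counts: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))

    def __post_init__(self) -> None:
        present = [c for c, n in self.class_counts.items() if n > 0]
        if len(present) < 2:
            raise ValueError("design must represent at least 2 classes")
        unknown = [c for c in self.class_counts if c not in ECO_CLASSES]
        if unknown:
            raise ValueError(f"unknown classes in design: {unknown}")


@dataclass
class EcoTruth:
    """Ground truth of the synthetic ecological dataset.

    ``class_means`` is classes x variables (original units);
    ``covariate_slopes`` is variables x (clay, elevation, slope), in
    response units per covariate SD (covariates are uniform on
    ``covariate_ranges``, standardized internally so class means stay the
    marginal means).  ``var_catchment``, ``var_region`` and
    ``var_residual`` are per-variable Gaussian variance components.
    ``region_restrict`` maps a variable to the single region where it is
    observed (elsewhere NaN), emulating taxa sampled in one region only.
    """

    class_means: pd.DataFrame
    covariate_slopes: pd.DataFrame
    var_catchment: pd.Series
    var_region: pd.Series
    var_residual: pd.Series
    design: DesignSpec = field(default_factory=DesignSpec)
    covariate_ranges: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_RANGES))
    region_restrict: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.class_means.index) != list(ECO_CLASSES):
            raise ValueError(f"class_means must have rows {ECO_CLASSES} in order")
        for s in (self.var_catchment, self.var_region, self.var_residual):
            if (np.asarray(s, dtype=float) < 0).any():
                raise ValueError("variance components must be >= 0")

    @property
    def variables(self) -> list[str]:
        return list(self.class_means.columns)


def default_eco_truth(seed: int = 0, **overrides) -> EcoTruth:
    """Study-condition defaults for the 18 response variables.

    Class means qualitatively mirror the field system: forest classes
    rich in species and above-ground carbon, pasture and mechanized
    agriculture poor; soil pH and nutrient cations higher under
    agriculture, exchangeable aluminum lower; soil carbon and sodium flat
    across classes.  Orchid-bee richness is observed in one region only.
    """
    means = {
        #                      UF     LF    LBF   SFy   SFo    PA    MA
        "richness_large_trees":  [55,   48,   41,   15,   30,    1,  0.5],
        "richness_small_trees":  [80,   70,   62,   35,   55,    3,    1],
        "richness_lianas":       [30,   26,   23,   12,   20,    1,  0.5],
        "richness_birds":        [45,   42,   40,   30,   38,   18,    8],
        "richness_dung_beetles": [22,   20,   16,   12,   16,    7,    4],
        "richness_ants":         [35,   33,   31,   24,   28,   20,   14],
        "richness_orchid_bees":  [12,   12,   11,   10,   11,    9,    9],
        "carbon_aboveground":    [150, 100,   80,   35,   85,    2,    1],
        "carbon_dead_wood":      [20,   22,   25,    8,   12,    1,  0.5],
        "carbon_litter":         [6,   5.5,    5,  3.5,  4.5,  0.8,  0.5],
        "carbon_soil":           [60,   60,   60,   60,   60,   60,   60],
        "soil_ph":               [4.2, 4.3,  4.5,  4.6,  4.4,  5.3,  5.6],
        "soil_n":                [0.18, 0.17, 0.16, 0.15, 0.17, 0.14, 0.13],
        "soil_p":                [4,     5,    6,    7,    5,   12,   16],
        "soil_k":                [0.8, 0.9,  1.0,  1.1,  0.9,  1.8,  2.3],
        "soil_ca_mg":            [8,     9,   12,   14,   10,   30,   34],
        "soil_na":               [0.25] * 7,
        "soil_al":               [12,   11,   10,    9,   13,    5,    4],
    }
    class_means = pd.DataFrame(means, index=list(ECO_CLASSES), dtype=float)
    spread = (class_means.max() - class_means.min()).replace(0, np.nan)
    sd_resid = (0.25 * spread).fillna(0.15 * class_means.mean())
    var_residual = sd_resid**2
    var_catchment = (0.4 * sd_resid) ** 2
    var_region = (0.25 * sd_resid) ** 2
    slopes = pd.DataFrame(
        {
            "clay": 0.20 * sd_resid,
            "elevation": 0.10 * sd_resid,
            "slope": 0.05 * sd_resid,
        }
    )
    kw = dict(
        class_means=class_means,
        covariate_slopes=slopes,
        var_catchment=var_catchment,
        var_region=var_region,
        var_residual=var_residual,
        region_restrict={"richness_orchid_bees": "PGM"},
        seed=seed,
    )
    kw.update(overrides)
    return EcoTruth(**kw)


def simulate_ecological_sites(truth: EcoTruth) -> pd.DataFrame:
    """Simulate the nested site table.

    response = class mean + covariate terms + catchment intercept +
    region intercept + residual, all Gaussian.  Site classes are split as
    evenly as possible between regions, shuffled, and dealt round-robin
    into catchments.
    """
    rng = np.random.default_rng(np.random.SeedSequence(truth.seed))
    design = truth.design
    variables = truth.variables

    # allocate classes to sites per region
    site_rows = []
    counts = design.class_counts
    for r, region in enumerate(design.regions):
        cls = []
        for c, total in counts.items():
            n_here = total // len(design.regions) + (
                1 if r < total % len(design.regions) else 0
            )
            cls.extend([c] * n_here)
        cls = np.array(cls)
        rng.shuffle(cls)
        catchments = [f"{region}_c{i:02d}" for i in range(design.catchments_per_region)]
        for i, c in enumerate(cls):
            site_rows.append(
                {
                    "site_id": f"{region}_s{i:03d}",
                    "catchment": catchments[i % len(catchments)],
                    "region": region,
                    "lulc": c,
                }
            )
    df = pd.DataFrame(site_rows)
    n = len(df)

    # covariates: uniform on the stated ranges
    for cov, (lo, hi) in truth.covariate_ranges.items():
        df[cov] = rng.uniform(lo, hi, size=n)

    # random intercepts
    catch_ids = df["catchment"].unique()
    region_ids = list(design.regions)
    b_catch = {
        v: dict(zip(catch_ids, rng.normal(0, np.sqrt(truth.var_catchment[v]), len(catch_ids))))
        for v in variables
    }
    b_region = {
        v: dict(zip(region_ids, rng.normal(0, np.sqrt(truth.var_region[v]), len(region_ids))))
        for v in variables
    }

    cov_std = {}
    for cov, (lo, hi) in truth.covariate_ranges.items():
        sd = (hi - lo) / np.sqrt(12.0)
        mid = (hi + lo) / 2.0
        cov_std[cov] = (df[cov] - mid) / sd if sd > 0 else df[cov] * 0.0

    for v in variables:
        y = df["lulc"].map(truth.class_means[v]).to_numpy(float)
        for cov in truth.covariate_ranges:
            slope = float(truth.covariate_slopes.loc[v, cov])
            y = y + slope * cov_std[cov].to_numpy()
        y = y + df["catchment"].map(b_catch[v]).to_numpy()
        y = y + df["region"].map(b_region[v]).to_numpy()
        y = y + rng.normal(0, np.sqrt(truth.var_residual[v]), size=n)
        if v in truth.region_restrict:
            y = np.where(df["region"] == truth.region_restrict[v], y, np.nan)
        df[v] = y
    return df


# ---------------------------------------------------------------------------
# Occurrence matrices
# ---------------------------------------------------------------------------

def simulate_occurrences(
    n_sites: int,
    site_classes,
    forest_pool_size: int = 40,
    open_pool_size: int = 20,
    occupancy_probs: float | dict | None = None,
    seed: int = 0,
    forest_classes=("UF", "LF", "LBF", "SFy", "SFo"),
) -> pd.DataFrame:
    """Binary site x species incidence matrix.

    Species belong to a forest pool or an open-habitat pool; occupancy
    probabilities may be a single number (applied everywhere) or a dict
    with keys ``forest_at_forest``, ``forest_at_open``, ``open_at_forest``,
    ``open_at_open`` (defaults 0.4 / 0.05 / 0.05 / 0.3), so forest-pool
    species are more frequent at forest-class sites.
    """
    site_classes = pd.Series(list(site_classes))
    if len(site_classes) != n_sites:
        raise ValueError("site_classes length must equal n_sites")
    if occupancy_probs is None:
        occupancy_probs = {
            "forest_at_forest": 0.4,
            "forest_at_open": 0.05,
            "open_at_forest": 0.05,
            "open_at_open": 0.3,
        }
    if np.isscalar(occupancy_probs):
        p = float(occupancy_probs)
        occupancy_probs = {
            "forest_at_forest": p, "forest_at_open": p,
            "open_at_forest": p, "open_at_open": p,
        }
    for k, v in occupancy_probs.items():
        if not (0 <= v <= 1):
            raise ValueError(f"occupancy probability {k}={v} outside [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    at_forest = site_classes.isin(forest_classes).to_numpy()

    probs = np.empty((n_sites, forest_pool_size + open_pool_size))
    probs[at_forest, :forest_pool_size] = occupancy_probs["forest_at_forest"]
    probs[~at_forest, :forest_pool_size] = occupancy_probs["forest_at_open"]
    probs[at_forest, forest_pool_size:] = occupancy_probs["open_at_forest"]
    probs[~at_forest, forest_pool_size:] = occupancy_probs["open_at_open"]
    occ = (rng.random(probs.shape) < probs).astype(np.int8)
    species = [f"f{i:03d}" for i in range(forest_pool_size)] + [
        f"o{i:03d}" for i in range(open_pool_size)
    ]
    sites = [f"site_{i:03d}" for i in range(n_sites)]
    return pd.DataFrame(occ, index=sites, columns=species)
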