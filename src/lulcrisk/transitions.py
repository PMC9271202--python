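"""Transition-rate accounting from annual land-cover map series.

Turns a base-class raster series (forest / pasture / cropland / other)
into the seven-class analysis schema — undisturbed (UF), logged (LF) and
logged-and-burned (LBF) primary forest, young (SFy) and old (SFo)
secondary forest, pasture (PA) and mechanized agriculture (MA) — and
tabulates mean annual transition rates (km²·y⁻¹) between them.

The change-detection rule: a pixel that is forest from the start of the
series is primary forest until its first non-forest year (regrowth that
predates the record is indistinguishable from primary forest and is
counted as such); forest re-appearing after a non-forest year is
secondary, with an age counter starting at 1 and incrementing per
consecutive forest year.  Degradation events (logging, fire) are overlaid
on primary forest as an absorbing state machine UF → LF → LBF that is
reset by clearing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd

from .io import (
    ANALYSIS_CLASSES,
    ANALYSIS_CODES,
    BASE_CODES,
    BURNED_CLASS,
    ClassifiedSeries,
    DegradationSeries,
    RasterSeries,
)

logger = logging.getLogger(__name__)

#: The 18 ordered transitions reported by the rate analysis: degradation
#: within primary forest, deforestation of each forest state to pasture
#: and agriculture, secondary-forest ageing, and the three bidirectional
#: pairs (PA–MA, PA–SFy, MA–SFy) counted in both directions.
STANDARD_TRANSITIONS: tuple[tuple[str, str], ...] = (
    ("UF", "LF"),
    ("UF", "LBF"),
    ("LF", "LBF"),
    ("UF", "PA"),
    ("UF", "MA"),
    ("LF", "PA"),
    ("LF", "MA"),
    ("LBF", "PA"),
    ("LBF", "MA"),
    ("SFo", "PA"),
    ("SFo", "MA"),
    ("SFy", "SFo"),
    ("PA", "MA"),
    ("MA", "PA"),
    ("PA", "SFy"),
    ("SFy", "PA"),
    ("MA", "SFy"),
    ("SFy", "MA"),
)

#: The three transition pairs treated as bidirectional in contrasts.
BIDIRECTIONAL_PAIRS: tuple[tuple[str, str], ...] = (
    ("PA", "MA"),
    ("PA", "SFy"),
    ("MA", "SFy"),
)

#: The 15 unordered transitions entering the effect-size contrasts; for
#: one-way transitions the order is (origin, destination).
CONTRAST_TRANSITIONS: tuple[tuple[str, str], ...] = (
    ("UF", "LF"),
    ("UF", "LBF"),
    ("LF", "LBF"),
    ("UF", "PA"),
    ("UF", "MA"),
    ("LF", "PA"),
    ("LF", "MA"),
    ("LBF", "PA"),
    ("LBF", "MA"),
    ("SFo", "PA"),
    ("SFo", "MA"),
    ("SFy", "SFo"),
    ("PA", "MA"),
    ("PA", "SFy"),
    ("MA", "SFy"),
)


def transition_label(from_class: str, to_class: str, bidirectional: bool = False) -> str:
    sep = "-" if bidirectional else "->"
    return f"{from_class}{sep}{to_class}"


@dataclass
class AgePolicy:
    """Secondary-forest age classes: age <= threshold is young (SFy),
    age > threshold is old (SFo).  The comparison operator is configurable
    (``young_includes_threshold=False`` makes the boundary age old)."""

    age_threshold: int = 20
    young_includes_threshold: bool = True

    def __post_init__(self) -> None:
        if self.age_threshold < 1:
            raise ValueError("age_threshold must be >= 1")

    def is_old(self, age: np.ndarray) -> np.ndarray:
        if self.young_includes_threshold:
            return age > self.age_threshold
        return age >= self.age_threshold


@dataclass
class AllocationRatio:
    """Split of a primary-forest deforestation rate between destination
    classes, when the source maps do not record the destination."""

    f_pasture: float = 0.985
    f_agriculture: float = 0.015

    def __post_init__(self) -> None:
        if not (0 <= self.f_pasture <= 1 and 0 <= self.f_agriculture <= 1):
            raise ValueError("allocation fractions must be in [0, 1]")
        if abs(self.f_pasture + self.f_agriculture - 1.0) > 1e-12:
            raise ValueError("allocation fractions must sum to 1")


# ---------------------------------------------------------------------------
# Primary/secondary discrimination and age classes
# ---------------------------------------------------------------------------

def classify_forest_age(
    series: RasterSeries | ClassifiedSeries, policy: AgePolicy | None = None
) -> ClassifiedSeries:
    """Split the forest class into primary and secondary age classes.

    Primary forest is labelled UF at this stage (degradation is resolved
    by :func:`overlay_degradation`); pasture and cropland map to PA and
    MA.  Classifying an already-classified series is a no-op.
    """
    if isinstance(series, ClassifiedSeries):
        return series
    policy = policy or AgePolicy()
    if series.n_years < 2:
        raise ValueError("need at least 2 years to classify transitions")

    code_of = {v: k for k, v in series.legend.items()}
    for name in BASE_CODES:
        if name not in code_of:
            raise ValueError(f"series legend lacks base class {name!r}")
    forest = series.labels == code_of["forest"]
    pasture = series.labels == code_of["pasture"]
    cropland = series.labels == code_of["cropland"]

    T = series.n_years
    shape = series.labels.shape
    out = np.full(shape, ANALYSIS_CODES["other"], dtype=np.int16)
    ages = np.zeros(shape, dtype=np.int16)

    ever_nonforest = ~forest[0]
    out[0][forest[0]] = ANALYSIS_CODES["UF"]
    out[0][pasture[0]] = ANALYSIS_CODES["PA"]
    out[0][cropland[0]] = ANALYSIS_CODES["MA"]
    for t in range(1, T):
        f = forest[t]
        primary = f & ~ever_nonforest
        secondary = f & ever_nonforest
        # age: +1 per consecutive forest year, re-entry restarts at 1
        ages[t][secondary & forest[t - 1]] = ages[t - 1][secondary & forest[t - 1]] + 1
        ages[t][secondary & ~forest[t - 1]] = 1
        old = policy.is_old(ages[t])
        out[t][primary] = ANALYSIS_CODES["UF"]
        out[t][secondary & ~old] = ANALYSIS_CODES["SFy"]
        out[t][secondary & old] = ANALYSIS_CODES["SFo"]
        out[t][pasture[t]] = ANALYSIS_CODES["PA"]
        out[t][cropland[t]] = ANALYSIS_CODES["MA"]
        ever_nonforest |= ~f
    legend = dict(enumerate(ANALYSIS_CLASSES))
    return ClassifiedSeries(
        out, ages, series.years, legend, series.pixel_area_km2, policy.age_threshold
    )


def overlay_degradation(
    classified: ClassifiedSeries,
    events: DegradationSeries,
    fire_on_unlogged: str = "LBF",
) -> ClassifiedSeries:
    """Resolve primary forest into UF / LF / LBF from degradation events.

    State machine per pixel, applied only while the pixel is primary
    forest: a logging event moves UF to LF; a fire event moves LF to LBF.
    Both states are absorbing while the pixel stays primary; clearing
    resets the history.  Fire on never-logged primary forest routes to
    LBF by default (``fire_on_unlogged="LBF"``) or to a distinct burned
    class (``"distinct"``).  Events on non-primary pixels are ignored
    with a warning.
    """
    if fire_on_unlogged not in ("LBF", "distinct"):
        raise ValueError("fire_on_unlogged must be 'LBF' or 'distinct'")
    labels = classified.labels.copy()
    legend = dict(classified.legend)
    if fire_on_unlogged == "distinct":
        burned_code = max(legend) + 1
        legend[burned_code] = BURNED_CLASS
    else:
        burned_code = ANALYSIS_CODES["LBF"]

    uf, lf, lbf = (ANALYSIS_CODES[c] for c in ("UF", "LF", "LBF"))
    primary_codes = (uf, lf, lbf)
    # align event years with series years
    year_of = {int(y): i for i, y in enumerate(classified.years)}
    n_misplaced = 0
    state = np.zeros(classified.labels.shape[1:], dtype=np.int8)  # 0 UF, 1 LF, 2 BF
    for t in range(classified.n_years):
        is_primary = np.isin(labels[t], primary_codes)
        state[~is_primary] = 0  # clearing resets degradation history
        ev_idx = None
        for i, y in enumerate(events.years):
            if year_of.get(int(y)) == t:
                ev_idx = i
                break
        if ev_idx is not None:
            log_ev = events.logging[ev_idx]
            fire_ev = events.fire[ev_idx]
            misplaced = (log_ev | fire_ev) & ~is_primary
            n_misplaced += int(misplaced.sum())
            state[is_primary & log_ev & (state == 0)] = 1
            fire_logged = is_primary & fire_ev & (state == 1)
            fire_unlogged = is_primary & fire_ev & (state == 0)
            state[fire_logged] = 2
            state[fire_unlogged] = 2 if fire_on_unlogged == "LBF" else 3
        labels[t][is_primary & (state == 1)] = lf
        labels[t][is_primary & (state == 2)] = lbf
        if fire_on_unlogged == "distinct":
            labels[t][is_primary & (state == 3)] = burned_code
    if n_misplaced:
        msg = f"{n_misplaced} degradation events on non-primary pixels ignored"
        warnings.warn(msg)
        logger.warning(msg)
    return ClassifiedSeries(
        labels,
        classified.ages,
        classified.years,
        legend,
        classified.pixel_area_km2,
        classified.age_threshold,
    )


# ---------------------------------------------------------------------------
# Rate tabulation
# ---------------------------------------------------------------------------

def tabulate_rates(
    classified: ClassifiedSeries,
    window: tuple[int, int] | None = None,
    transitions: tuple[tuple[str, str], ...] | None = None,
    include_self: bool = False,
) -> pd.DataFrame:
    """Mean annual transition rates over a year window.

    For each consecutive year pair in ``window`` the transition area
    i -> j is (number of pixels moving) × pixel area; the mean and the
    sample SD (ddof=1) are taken across year pairs.

    Returns a DataFrame with columns ``from``, ``to``, ``mean_annual_rate``,
    ``sd_annual_rate``, ``n_years`` and attrs ``window``.  Self-transitions
    are excluded unless ``include_self``; if ``transitions`` is given, only
    those ordered pairs are reported, in that order (pairs routed through
    classes absent from the legend are reported as zero).
    """
    years = classified.years
    if window is None:
        window = (int(years[0]), int(years[-1]))
    start, end = int(window[0]), int(window[1])
    if end <= start:
        raise ValueError(f"window {window} must span at least 2 years")
    if start < years[0] or end > years[-1]:
        raise ValueError(f"window {window} outside series {years[0]}..{years[-1]}")
    i0, i1 = classified.year_index(start), classified.year_index(end)

    legend = classified.legend
    k = max(legend) + 1
    counts = np.zeros((i1 - i0, k, k), dtype=np.int64)
    flat = classified.labels.reshape(classified.n_years, -1)
    for m, t in enumerate(range(i0, i1)):
        pair = flat[t].astype(np.int64) * k + flat[t + 1]
        c = np.bincount(pair, minlength=k * k)
        counts[m] = c.reshape(k, k)
    areas = counts * classified.pixel_area_km2

    name_of = dict(legend)
    code_of = {v: c for c, v in legend.items()}
    if transitions is None:
        transitions = tuple(
            (name_of[a], name_of[b])
            for a, b in permutations(sorted(legend), 2)
        )
        if include_self:
            transitions = transitions + tuple((name_of[a], name_of[a]) for a in sorted(legend))
    rows = []
    n_pairs = i1 - i0
    for frm, to in transitions:
        if not include_self and frm == to:
            continue
        if frm in code_of and to in code_of:
            series = areas[:, code_of[frm], code_of[to]].astype(float)
        else:
            series = np.zeros(n_pairs)
        rows.append(
            {
                "from": frm,
                "to": to,
                "mean_annual_rate": float(series.mean()),
                "sd_annual_rate": float(series.std(ddof=1)) if n_pairs > 1 else np.nan,
                "n_years": n_pairs,
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["window"] = (start, end)
    table.attrs["pixel_area_km2"] = classified.pixel_area_km2
    return table


def transition_area_conservation(classified: ClassifiedSeries) -> bool:
    """Check that for every year pair the outflows of each class (plus the
    self-transition) sum exactly to the class area in the first year."""
    flat = classified.labels.reshape(classified.n_years, -1)
    k = max(classified.legend) + 1
    for t in range(classified.n_years - 1):
        pair = flat[t].astype(np.int64) * k + flat[t + 1]
        c = np.bincount(pair, minlength=k * k).reshape(k, k)
        if not np.array_equal(c.sum(axis=1), np.bincount(flat[t], minlength=k)):
            return False
    return True


# ---------------------------------------------------------------------------
# Destination allocation and bidirectional aggregation
# ---------------------------------------------------------------------------

def allocate_deforestation(
    rate: float, ratio: AllocationRatio | None = None
) -> tuple[float, float]:
    """Split a primary-forest deforestation rate between pasture and
    agriculture destinations according to the allocation ratio.

    >>> allocate_deforestation(6070.0)
    (5978.95, 91.05)
    """
    if rate < 0:
        raise ValueError("deforestation rate must be >= 0")
    ratio = ratio or AllocationRatio()
    return rate * ratio.f_pasture, rate * ratio.f_agriculture


def aggregate_bidirectional(
    rates: pd.DataFrame,
    pairs: tuple[tuple[str, str], ...] = BIDIRECTIONAL_PAIRS,
) -> pd.DataFrame:
    """Combine the two directions of bidirectional transitions.

    The combined rate is the sum of the two directional mean rates; a
    missing direction is treated as 0 with a warning.  The combined SD is
    the quadrature sum of the directional SDs (directions treated as
    uncorrelated; a documented simplification).
    """
    idx = rates.set_index(["from", "to"])
    rows = []
    for a, b in pairs:
        total, var = 0.0, 0.0
        for frm, to in ((a, b), (b, a)):
            if (frm, to) in idx.index:
                r = idx.loc[(frm, to)]
                total += float(r["mean_annual_rate"])
                sd = float(r.get("sd_annual_rate", np.nan))
                if np.isfinite(sd):
                    var += sd**2
            else:
                warnings.warn(
                    f"direction {frm}->{to} absent from rate table; treated as 0"
                )
        rows.append(
            {
                "pair": transition_label(a, b, bidirectional=True),
                "combined_rate": total,
                "sd_quadrature": float(np.sqrt(var)),
            }
        )
    return pd.DataFrame(rows)


def contrast_rate_table(
    rates: pd.DataFrame,
    contrasts: tuple[tuple[str, str], ...] = CONTRAST_TRANSITIONS,
    bidirectional: tuple[tuple[str, str], ...] = BIDIRECTIONAL_PAIRS,
) -> pd.Series:
    """Per-contrast mean annual rate: the directional rate for one-way
    transitions and the combined rate for bidirectional pairs.  Indexed by
    transition label, for joining with effect-size tables."""
    idx = rates.set_index(["from", "to"])["mean_annual_rate"]
    bid = {frozenset(p) for p in bidirectional}
    out = {}
    for a, b in contrasts:
        if frozenset((a, b)) in bid:
            rate = float(idx.get((a, b), 0.0)) + float(idx.get((b, a), 0.0))
            out[transition_label(a, b, bidirectional=True)] = rate
        else:
            out[transition_label(a, b)] = float(idx.get((a, b), 0.0))
    return pd.Series(out, name="mean_annual_rate")
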