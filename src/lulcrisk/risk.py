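"""Impact x prevalence risk classification of land-cover transitions.

Aggregates standardized effect sizes per ecosystem component (median of
absolute effect sizes across the component's variables), correlates the
per-transition impact with the mean annual transition rate, and classes
each transition into one of four quadrants (high/low impact x high/low
rate) using the medians of both axes as cutoffs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

#: Default assignment of the 18 ecological response variables to the
#: three ecosystem components.
DEFAULT_COMPONENTS: dict[str, str] = {
    "richness_large_trees": "biodiversity",
    "richness_small_trees": "biodiversity",
    "richness_lianas": "biodiversity",
    "richness_birds": "biodiversity",
    "richness_dung_beetles": "biodiversity",
    "richness_ants": "biodiversity",
    "richness_orchid_bees": "biodiversity",
    "carbon_aboveground": "carbon",
    "carbon_dead_wood": "carbon",
    "carbon_litter": "carbon",
    "carbon_soil": "carbon",
    "soil_ph": "soil",
    "soil_n": "soil",
    "soil_p": "soil",
    "soil_k": "soil",
    "soil_ca_mg": "soil",
    "soil_na": "soil",
    "soil_al": "soil",
}

COMPONENTS = ("biodiversity", "carbon", "soil")

QUADRANTS = (
    "high-impact/high-rate",
    "high-impact/low-rate",
    "low-impact/high-rate",
    "low-impact/low-rate",
)


def validate_component_map(component_map: dict[str, str], variables=None) -> None:
    """Every modeled variable must map to exactly one component."""
    if variables is not None:
        missing = [v for v in variables if v not in component_map]
        if missing:
            raise ValueError(f"variables without a component: {missing}")


def median_component_effect(
    effects: pd.DataFrame, component_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Median absolute standardized effect size per (component, transition).

    ``effects`` is tidy with columns ``variable``, ``transition``,
    ``estimate``.  The median of the absolute estimates is taken across
    the component's variables (midpoint convention for even counts, via
    ``numpy.median``).
    """
    component_map = component_map or DEFAULT_COMPONENTS
    validate_component_map(component_map, effects["variable"].unique())
    df = effects.copy()
    df["component"] = df["variable"].map(component_map)
    df["abs_es"] = df["estimate"].abs()
    out = (
        df.groupby(["component", "transition"], sort=False)["abs_es"]
        .agg(median_abs_es="median", n_vars="size")
        .reset_index()
    )
    if (out["n_vars"] == 0).any():
        raise ValueError("component with no estimates for a transition")
    return out


def rank_transitions(medians: pd.DataFrame, component: str) -> list[str]:
    """Transitions ordered by decreasing median |ES| for one component;
    ties keep the input label order (stable sort)."""
    sub = medians[medians["component"] == component]
    if sub.empty:
        raise ValueError(f"no medians for component {component!r}")
    order = sub.sort_values("median_abs_es", ascending=False, kind="stable")
    return list(order["transition"])


def rate_impact_correlation(
    rates: pd.Series,
    impacts: pd.Series,
    method: str = "auto",
    log_rates: bool = True,
    normality_alpha: float = 0.05,
) -> tuple[float, float, str]:
    """Correlation between transition prevalence and impact.

    ``rates`` and ``impacts`` are aligned by index (transition label).
    With ``method="auto"`` the impact vector is tested for normality
    (Shapiro-Wilk at ``normality_alpha``): Pearson if normality is not
    rejected, Spearman otherwise.  Pearson uses log10 rates by default
    (Spearman is invariant to the transform).
    """
    joined = pd.concat([rates.rename("rate"), impacts.rename("impact")], axis=1).dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 transitions with both rate and impact")
    x = joined["rate"].to_numpy(float)
    y = joined["impact"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in rates or impacts")
    if method == "auto":
        _, p_norm = stats.shapiro(y)
        method = "pearson" if p_norm >= normality_alpha else "spearman"
    if method == "pearson":
        if log_rates:
            if np.any(x <= 0):
                keep = x > 0
                if keep.sum() < 3:
                    raise ValueError(
                        "fewer than 3 positive rates for the log-scale correlation"
                    )
                warnings.warn(
                    f"{int((~keep).sum())} transitions with zero rate dropped "
                    "from the log-scale correlation"
                )
                x, y = x[keep], y[keep]
            x = np.log10(x)
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p), method


def classify_quadrants(
    rates: pd.Series,
    impacts: pd.Series,
    tie_rule: str = "gt",
) -> pd.DataFrame:
    """Class each transition into impact x rate quadrants.

    Cutoffs are the medians of the rate vector and of the impact vector.
    With the default tie rule (``"gt"``) a value strictly greater than
    the cutoff is "high" and a value equal to the cutoff is "low"
    (``"ge"`` makes ties "high").  Median cutoffs make the classification
    invariant to strictly monotone transforms of either axis.
    """
    if tie_rule not in ("gt", "ge"):
        raise ValueError("tie_rule must be 'gt' or 'ge'")
    joined = pd.concat([rates.rename("rate"), impacts.rename("median_abs_es")], axis=1).dropna()
    if len(joined) < 2:
        raise ValueError("need at least 2 transitions to classify")
    cut_rate = float(np.median(joined["rate"]))
    cut_imp = float(np.median(joined["median_abs_es"]))
    op = np.greater if tie_rule == "gt" else np.greater_equal
    hi_rate = op(joined["rate"].to_numpy(float), cut_rate)
    hi_imp = op(joined["median_abs_es"].to_numpy(float), cut_imp)
    quad = np.where(
        hi_imp,
        np.where(hi_rate, "high-impact/high-rate", "high-impact/low-rate"),
        np.where(hi_rate, "low-impact/high-rate", "low-impact/low-rate"),
    )
    out = joined.reset_index(names="transition")
    out["quadrant"] = quad
    out.attrs["cutoff_rate"] = cut_rate
    out.attrs["cutoff_impact"] = cut_imp
    out.attrs["tie_rule"] = tie_rule
    return out


def risk_summary(
    effects: pd.DataFrame,
    rates: pd.Series,
    component_map: dict[str, str] | None = None,
    method: str = "auto",
    log_rates: bool = True,
    tie_rule: str = "gt",
) -> pd.DataFrame:
    """Full risk linkage: per-component median |ES|, rate-impact
    correlation and quadrant classification.

    Returns a long DataFrame over (component, transition) with the rate,
    median |ES|, quadrant, cutoffs and the component-level correlation
    (repeated on each of the component's rows).
    """
    medians = median_component_effect(effects, component_map)
    blocks = []
    for component in medians["component"].unique():
        sub = medians[medians["component"] == component].set_index("transition")
        impacts = sub["median_abs_es"]
        quad = classify_quadrants(rates, impacts, tie_rule=tie_rule)
        r, p, used = rate_impact_correlation(
            rates, impacts, method=method, log_rates=log_rates
        )
        quad.insert(0, "component", component)
        quad["n_vars"] = sub["n_vars"].reindex(quad["transition"]).to_numpy()
        quad["correlation"] = r
        quad["correlation_p"] = p
        quad["correlation_method"] = used
        quad["cutoff_rate"] = quad.attrs["cutoff_rate"]
        quad["cutoff_impact"] = quad.attrs["cutoff_impact"]
        blocks.append(quad)
    return pd.concat(blocks, ignore_index=True)


def ranked_report(summary: pd.DataFrame) -> str:
    """Plain-text report of transitions ranked by impact per component."""
    lines = []
    for component in summary["component"].unique():
        sub = summary[summary["component"] == component].sort_values(
            "median_abs_es", ascending=False, kind="stable"
        )
        r = sub["correlation"].iloc[0]
        p = sub["correlation_p"].iloc[0]
        m = sub["correlation_method"].iloc[0]
        lines.append(f"# {component}  (rate-impact {m} r={r:+.3f}, p={p:.3g})")
        for _, row in sub.iterrows():
            lines.append(
                f"  {row['transition']:>10s}  |ES|={row['median_abs_es']:.3f}  "
                f"rate={row['rate']:.1f} km2/y  {row['quadrant']}"
            )
    return "\n".join(lines)


def plot_risk(summary: pd.DataFrame, path=None):
    """Minimal diagnostic scatter of impact vs log10 rate per component."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    components = list(summary["component"].unique())
    fig, axes = plt.subplots(1, len(components), figsize=(4 * len(components), 4))
    axes = np.atleast_1d(axes)
    for ax, component in zip(axes, components):
        sub = summary[summary["component"] == component]
        ax.scatter(np.log10(sub["rate"]), sub["median_abs_es"], s=15)
        ax.axvline(np.log10(sub["cutoff_rate"].iloc[0]), ls=":", c="gray")
        ax.axhline(sub["cutoff_impact"].iloc[0], ls=":", c="gray")
        ax.set_title(component)
        ax.set_xlabel("log10 rate (km2/y)")
        ax.set_ylabel("median |ES|")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig
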