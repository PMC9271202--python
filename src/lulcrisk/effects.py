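"""Mixed-model standardized effect sizes with single-step (max-t) inference.

Per response variable: center and scale, fit a linear mixed model with
the land-use/land-cover class as a 7-level fixed factor, clay, elevation
and slope as covariates, and catchment and region random intercepts
(REML, via statsmodels MixedLM); then estimate the 15 transition
contrasts between class means.  Because responses are standardized the
contrast estimates are standardized effect sizes, comparable across
variables with different units.

Familywise inference is single-step max-t: each contrast's p-value is
adjusted using the joint multivariate normal distribution of all contrast
statistics (exploiting their correlation), and simultaneous confidence
intervals use the equicoordinate quantile of max|Z|.  The joint
probabilities are evaluated by quasi-Monte-Carlo integration (scrambled
Sobol points with a fixed seed), with the integration error estimated
from independent scrambles and the sample size escalated until it meets
the tolerance.  The reference distribution is standard normal by default
(large-sample mixed-model practice); a t reference with a stated df is
available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .transitions import BIDIRECTIONAL_PAIRS, CONTRAST_TRANSITIONS, transition_label

ECO_CLASSES = ("UF", "LF", "LBF", "SFy", "SFo", "PA", "MA")
DEFAULT_COVARIATES = ("clay", "elevation", "slope")


# ---------------------------------------------------------------------------
# Centering and scaling
# ---------------------------------------------------------------------------

@dataclass
class ScaledDataset:
    """Centered/scaled copy of a site table plus the per-variable mean
    and SD needed to back-transform estimates to original units."""

    data: pd.DataFrame
    means: pd.Series
    sds: pd.Series

    def unscale(self, variable: str, values):
        return np.asarray(values) * self.sds[variable] + self.means[variable]


def center_scale(data: pd.DataFrame, variables) -> ScaledDataset:
    """Center (subtract the mean) and scale (divide by the sample SD,
    ddof=1) each listed column, over non-missing values."""
    out = data.copy()
    means, sds = {}, {}
    for v in variables:
        col = out[v].astype(float)
        sd = col.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"column {v!r} has zero or undefined SD; cannot scale")
        means[v] = col.mean()
        sds[v] = sd
        out[v] = (col - means[v]) / sd
    return ScaledDataset(out, pd.Series(means), pd.Series(sds))


# ---------------------------------------------------------------------------
# Mixed model
# ---------------------------------------------------------------------------

@dataclass
class LMMFit:
    """Fixed effects and their covariance from a REML mixed-model fit."""

    beta: pd.Series
    cov_beta: pd.DataFrame
    vcomp: dict
    converged: bool
    loglike: float
    n_obs: int
    classes: tuple
    reference: str
    class_col: str
    response: str

    def class_vector(self, cls: str) -> pd.Series:
        """Indicator of a class mean on the fixed-effect design scale
        (treatment coding: the reference class is the zero vector)."""
        if cls not in self.classes:
            raise ValueError(
                f"class {cls!r} not in fitted model (present: {self.classes})"
            )
        vec = pd.Series(0.0, index=self.beta.index)
        if cls != self.reference:
            name = f"C({self.class_col}, Treatment('{self.reference}'))[T.{cls}]"
            vec[name] = 1.0
        return vec


def fit_lmm(
    data: pd.DataFrame,
    response: str,
    covariates=DEFAULT_COVARIATES,
    class_col: str = "lulc",
    random: tuple = ("catchment", "region"),
    reference: str = "UF",
    require_classes=None,
    region_as_fixed: bool = False,
) -> LMMFit:
    """REML linear mixed model of one (already scaled) response.

    Fixed part: class (treatment-coded against ``reference``) plus the
    covariates.  Random intercepts: catchment nested in region by default
    (``random=("catchment",)`` drops the region term, as for taxa sampled
    in a single region; ``region_as_fixed`` moves region to the fixed
    part — a 2-level random variance is weakly identified).  Rows with
    missing values are dropped (complete-case).  Non-convergence is
    flagged on the result, never silent.
    """
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    cols = [response, class_col, *covariates, *random]
    if region_as_fixed and "region" not in cols:
        cols.append("region")
    df = data.dropna(subset=[c for c in cols if c in data.columns]).copy()
    order = {c: i for i, c in enumerate(ECO_CLASSES)}
    present = tuple(
        sorted(df[class_col].unique(), key=lambda c: (order.get(c, len(order)), c))
    )
    if require_classes is not None:
        missing = [c for c in require_classes if c not in present]
        if missing:
            raise ValueError(f"classes with no sites for {response!r}: {missing}")
    if len(present) < 2:
        raise ValueError(f"fewer than 2 classes represented for {response!r}")
    if reference not in present:
        raise ValueError(f"reference class {reference!r} has no sites for {response!r}")

    terms = [f"C({class_col}, Treatment('{reference}'))", *covariates]
    if region_as_fixed:
        terms.append("C(region)")
    formula = f"{response} ~ " + " + ".join(terms)

    use_region = ("region" in random) and (not region_as_fixed) and df["region"].nunique() > 1

    def build():
        if use_region:
            return smf.mixedlm(
                formula,
                df,
                groups="region",
                re_formula="1",
                vc_formula={"catchment": "0 + C(catchment)"},
            )
        return smf.mixedlm(formula, df, groups="catchment", re_formula="1")

    # A 2-level region variance often sits on the boundary, where
    # gradient-based optimizers can fail; fall back to derivative-free.
    result, converged, last_exc = None, False, None
    for method in ("lbfgs", "powell", "nm"):
        try:
            with warnings.catch_warnings(record=True) as rec:
                warnings.simplefilter("always")
                candidate = build().fit(reml=True, method=method)
            failed = [
                w for w in rec
                if issubclass(w.category, ConvergenceWarning)
                and "failed" in str(w.message)
            ]
            ok = (
                bool(getattr(candidate, "converged", True))
                and not failed
                and np.isfinite(candidate.llf)
            )
            if result is None or (ok and not converged):
                result, converged = candidate, ok
            if ok:
                break
        except (np.linalg.LinAlgError, ValueError) as exc:
            last_exc = exc
    if result is None:
        raise np.linalg.LinAlgError(
            f"mixed-model fit failed for {response!r}: {last_exc}"
        )

    fe_index = result.fe_params.index
    cov_beta = pd.DataFrame(
        np.asarray(result.cov_params())[: len(fe_index), : len(fe_index)],
        index=fe_index,
        columns=fe_index,
    )
    if use_region:
        vcomp = {
            "region": float(np.asarray(result.cov_re).ravel()[0]) if result.cov_re.size else 0.0,
            "catchment": float(result.vcomp[0]) if len(result.vcomp) else 0.0,
            "residual": float(result.scale),
        }
    else:
        vcomp = {
            "catchment": float(np.asarray(result.cov_re).ravel()[0]) if result.cov_re.size else 0.0,
            "residual": float(result.scale),
        }
    return LMMFit(
        beta=result.fe_params.copy(),
        cov_beta=cov_beta,
        vcomp=vcomp,
        converged=converged,
        loglike=float(result.llf),
        n_obs=int(len(df)),
        classes=present,
        reference=reference,
        class_col=class_col,
        response=response,
    )


# ---------------------------------------------------------------------------
# Contrasts
# ---------------------------------------------------------------------------

@dataclass
class ContrastSet:
    """Transition contrasts on the class-mean scale.

    ``matrix`` has one row per transition over the class columns; each
    row is indicator(destination) - indicator(origin) and sums to zero.
    Bidirectional pairs are estimated once, oriented second-minus-first.
    """

    matrix: pd.DataFrame

    def __post_init__(self) -> None:
        sums = self.matrix.sum(axis=1)
        if np.abs(sums).max() > 1e-12:
            raise ValueError("contrast rows must sum to 0")

    @property
    def labels(self) -> list[str]:
        return list(self.matrix.index)


def build_contrast_set(
    transitions=CONTRAST_TRANSITIONS,
    bidirectional=BIDIRECTIONAL_PAIRS,
    classes=ECO_CLASSES,
) -> ContrastSet:
    """The default 15 transition contrasts.

    One-way transitions are destination minus origin (so deforestation
    that lowers richness gives a negative effect size); bidirectional
    pairs appear once, labelled "A-B" and oriented B minus A.
    """
    bid = {frozenset(p) for p in bidirectional}
    rows = {}
    for a, b in transitions:
        is_bid = frozenset((a, b)) in bid
        label = transition_label(a, b, bidirectional=is_bid)
        row = pd.Series(0.0, index=list(classes))
        row[b] += 1.0
        row[a] -= 1.0
        rows[label] = row
    return ContrastSet(pd.DataFrame(rows).T)


@dataclass
class QMCSettings:
    """Quasi-Monte-Carlo settings for the max-|Z| distribution."""

    n: int = 2**13
    reps: int = 8
    tol: float = 2.5e-4
    n_max: int = 2**15
    seed: int = 20220627

    def __post_init__(self) -> None:
        if self.reps < 2:
            raise ValueError("need >= 2 scrambles to estimate the integration error")


def _chol_psd(R: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(R)
        w = np.clip(w, 1e-12, None)
        return v * np.sqrt(w)


def _max_abs_z_samples(R: np.ndarray, settings: QMCSettings) -> list[np.ndarray]:
    """Independent scrambled-Sobol samples of max_k |Z_k|, Z ~ N(0, R)."""
    L = _chol_psd(R)
    k = R.shape[0]
    out = []
    for r in range(settings.reps):
        eng = qmc.Sobol(d=k, scramble=True, rng=np.random.default_rng(settings.seed + r))
        u = eng.random(settings.n)
        u = np.clip(u, 1e-15, 1 - 1e-15)
        z = stats.norm.ppf(u) @ L.T
        out.append(np.abs(z).max(axis=1))
    return out


def single_step_contrasts(
    fit: LMMFit,
    contrast_set: ContrastSet | None = None,
    alpha: float = 0.05,
    df: float | None = None,
    qmc_settings: QMCSettings | None = None,
) -> pd.DataFrame:
    """Single-step (max-t) adjusted contrasts with simultaneous CIs.

    Per transition: estimate = c'beta, SE = sqrt(c'Vc), z = estimate/SE;
    the adjusted p-value is P(max_k |Z_k| >= |z_j|) under the correlated
    multivariate normal of all contrast statistics, and the simultaneous
    (1 - alpha) CI is estimate +/- q * SE with q the equicoordinate
    quantile of max|Z|.  With ``df`` the draws use a t reference
    (multivariate t via a chi-square scale mixture).

    The returned frame carries ``q_crit``, ``alpha``, ``qmc_error`` and
    ``n_qmc`` in ``attrs``.  Adjusted p-values are constrained to the
    theoretical envelope [p_unadjusted, min(1, k * p_unadjusted)], which
    single-step adjustment satisfies exactly; this removes QMC noise at
    the boundaries.
    """
    contrast_set = contrast_set or build_contrast_set()
    settings = qmc_settings or QMCSettings()

    # map class-scale rows to the fixed-effect design scale
    needed = [
        c for c in contrast_set.matrix.columns
        if np.any(contrast_set.matrix[c].to_numpy() != 0)
    ]
    missing = [c for c in needed if c not in fit.classes]
    if missing:
        raise ValueError(f"contrasts reference classes absent from the fit: {missing}")
    C = np.stack(
        [
            sum(
                (w * fit.class_vector(cls).to_numpy()
                 for cls, w in row.items() if w != 0),
                start=np.zeros(len(fit.beta)),
            )
            for _, row in contrast_set.matrix.iterrows()
        ]
    )
    labels = contrast_set.labels
    k = len(labels)

    est = C @ fit.beta.to_numpy()
    Vc = C @ fit.cov_beta.to_numpy() @ C.T
    se = np.sqrt(np.diag(Vc))
    if np.any(se <= 0) or not np.all(np.isfinite(se)):
        raise np.linalg.LinAlgError("rank-deficient contrast covariance")
    R = Vc / np.outer(se, se)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    z = est / se

    ref = stats.norm if df is None else stats.t(df)
    p_unadj = 2.0 * ref.sf(np.abs(z))

    if k == 1:
        p_adj = p_unadj.copy()
        q_crit = float(ref.ppf(1 - alpha / 2))
        qmc_err = 0.0
        n_used = 0
    else:
        while True:
            samples = _max_abs_z_samples(R, settings)
            if df is not None:
                # scale mixture: divide by independent sqrt(chi2_df / df)
                rng = np.random.default_rng(settings.seed - 1)
                samples = [
                    s / np.sqrt(rng.chisquare(df, size=s.size) / df) for s in samples
                ]
            per_rep = np.stack([
                np.array([np.mean(s >= abs(zj)) for zj in z]) for s in samples
            ])
            p_adj = per_rep.mean(axis=0)
            qmc_err = float(
                (per_rep.std(axis=0, ddof=1) / np.sqrt(settings.reps)).max()
            )
            if qmc_err <= settings.tol or settings.n >= settings.n_max:
                break
            settings = QMCSettings(
                n=min(settings.n * 4, settings.n_max),
                reps=settings.reps,
                tol=settings.tol,
                n_max=settings.n_max,
                seed=settings.seed,
            )
        if qmc_err > max(settings.tol, 1e-3):
            raise RuntimeError(
                f"QMC integration error {qmc_err:.2e} above tolerance after "
                f"escalating to n={settings.n}"
            )
        pooled = np.sort(np.concatenate(samples))
        q_crit = float(np.quantile(pooled, 1 - alpha))
        n_used = pooled.size
        p_adj = np.minimum(np.maximum(p_adj, p_unadj), np.minimum(1.0, k * p_unadj))

    lo = est - q_crit * se
    hi = est + q_crit * se
    out = pd.DataFrame(
        {
            "transition": labels,
            "estimate": est,
            "se": se,
            "z": z,
            "p_unadjusted": p_unadj,
            "p_adjusted": p_adj,
            "ci_lower": lo,
            "ci_upper": hi,
        }
    )
    out["direction"] = classify_significance(out, alpha)
    out.attrs.update(
        q_crit=q_crit, alpha=alpha, qmc_error=qmc_err, n_qmc=n_used,
        correlation=R, df=df,
    )
    return out


def classify_significance(contrasts: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Direction per transition: 'increase'/'decrease' when the adjusted
    p-value is below alpha (sign of the estimate), else 'none'."""
    sig = contrasts["p_adjusted"] < alpha
    return pd.Series(
        np.where(sig, np.where(contrasts["estimate"] > 0, "increase", "decrease"), "none"),
        index=contrasts.index,
        name="direction",
    )


# ---------------------------------------------------------------------------
# Per-variable driver
# ---------------------------------------------------------------------------

def run_effects(
    sites: pd.DataFrame,
    variables,
    covariates=DEFAULT_COVARIATES,
    transitions=CONTRAST_TRANSITIONS,
    alpha: float = 0.05,
    class_col: str = "lulc",
    reference: str = "UF",
    qmc_settings: QMCSettings | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Scale, fit and contrast every response variable.

    Responses and covariates are centered and scaled per variable over
    the rows entering that variable's model (complete-case).  Variables
    observed in a single region are fitted with a catchment-only random
    intercept.  Returns the tidy effects table (variable, transition,
    estimate, se, z, p_adjusted, CI bounds, direction) and a meta dict
    (variance components, convergence, REML log-likelihood per variable).
    """
    cset = build_contrast_set(transitions)
    results, meta = [], {}
    for v in variables:
        rows = sites.dropna(subset=[v]).copy()
        scaled = center_scale(rows, [v, *covariates])
        random = ("catchment", "region") if rows["region"].nunique() > 1 else ("catchment",)
        fit = fit_lmm(
            scaled.data, v, covariates=covariates, class_col=class_col,
            random=random, reference=reference,
            require_classes=sorted({c for t in transitions for c in t}),
        )
        table = single_step_contrasts(fit, cset, alpha=alpha, qmc_settings=qmc_settings)
        table.insert(0, "variable", v)
        results.append(table)
        meta[v] = {
            "vcomp": fit.vcomp,
            "converged": fit.converged,
            "loglike": fit.loglike,
            "n_obs": fit.n_obs,
            "random": random,
            "q_crit": table.attrs["q_crit"],
            "qmc_error": table.attrs["qmc_error"],
        }
    return pd.concat(results, ignore_index=True), meta
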