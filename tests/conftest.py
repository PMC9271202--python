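import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

ECO_CLASSES = ("UF", "LF", "LBF", "SFy", "SFo", "PA", "MA")


@pytest.fixture(scope="session")
def small_landcover_truth():
    from lulcrisk import default_landcover_truth

    return default_landcover_truth(seed=3, grid_shape=(50, 50), years=(1990, 2012))


@pytest.fixture(scope="session")
def small_simulation(small_landcover_truth):
    from lulcrisk import simulate_landcover_series

    return simulate_landcover_series(small_landcover_truth)


@pytest.fixture(scope="session")
def eco_sites():
    from lulcrisk import default_eco_truth, simulate_ecological_sites

    return simulate_ecological_sites(default_eco_truth(seed=5))


def balanced_sites(
    n_per_class=10,
    class_shift=None,
    var_catchment=0.0,
    var_region=0.0,
    sd_resid=1.0,
    seed=0,
    per_site_catchments=True,
    covariates=False,
):
    """Hand-rolled balanced nested design for estimator oracles."""
    rng = np.random.default_rng(seed)
    class_shift = class_shift or {}
    rows = []
    i = 0
    catch_effects = {}
    region_effects = {
        "STM": rng.normal(0, np.sqrt(var_region)),
        "PGM": rng.normal(0, np.sqrt(var_region)),
    }
    for c in ECO_CLASSES:
        for j in range(n_per_class):
            region = "STM" if j % 2 == 0 else "PGM"
            cat = f"s{i}" if per_site_catchments else f"{region}_c{j % 5}"
            if cat not in catch_effects:
                catch_effects[cat] = rng.normal(0, np.sqrt(var_catchment))
            row = dict(site_id=f"s{i}", catchment=cat, region=region, lulc=c)
            if covariates:
                row.update(
                    clay=rng.uniform(-1, 1),
                    elevation=rng.uniform(-1, 1),
                    slope=rng.uniform(-1, 1),
                )
            row["y"] = (
                class_shift.get(c, 0.0)
                + catch_effects[cat]
                + region_effects[region]
                + rng.normal(0, sd_resid)
            )
            rows.append(row)
            i += 1
    return pd.DataFrame(rows)


def synthetic_lmm_fit(cov=None, beta_values=None, classes=ECO_CLASSES, reference="UF"):
    """A hand-built LMMFit with a chosen fixed-effect covariance, for
    exercising the contrast machinery against closed forms."""
    from lulcrisk.effects import LMMFit

    names = ["Intercept"] + [
        f"C(lulc, Treatment('{reference}'))[T.{c}]" for c in classes if c != reference
    ]
    k = len(names)
    beta = pd.Series(
        beta_values if beta_values is not None else np.zeros(k), index=names
    )
    V = pd.DataFrame(
        cov if cov is not None else np.eye(k), index=names, columns=names
    )
    return LMMFit(
        beta=beta,
        cov_beta=V,
        vcomp={"residual": 1.0},
        converged=True,
        loglike=0.0,
        n_obs=0,
        classes=tuple(classes),
        reference=reference,
        class_col="lulc",
        response="y",
    )
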