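import numpy as np
import pandas as pd
import pytest

from socsnr.data_model import SocSeries, Visit
from socsnr.features import FeatureMatrix
from socsnr.forest import fit_forest


def make_series(
    site_id="s1",
    years=(2009, 2015, 2018),
    socs=(10.0, 13.0, 19.0),
    lons=None,
    lats=None,
    cns=(10.0, 10.0, 10.0),
    lcs=("C", "C", "C"),
):
    lons = lons or [10.0] * len(years)
    lats = lats or [50.0] * len(years)
    visits = tuple(
        Visit(y, s, lon, lat, cn, lc)
        for y, s, lon, lat, cn, lc in zip(years, socs, lons, lats, cns, lcs)
    )
    return SocSeries(site_id, visits)


@pytest.fixture
def basic_series():
    return make_series()


@pytest.fixture(scope="session")
def gaussian_forest():
    """Forest fit to y = 3x + N(0, 2) — a known conditional distribution.

    Leaves are kept large (min_samples_leaf=40) so each pooled leaf
    distribution approximates the local Gaussian, making the uncertainty
    calibratable.  Returns (model, X_test frame, y_test, sigma).
    """
    rng = np.random.default_rng(7)
    n_train, n_test, sigma = 4000, 2000, 2.0
    x = rng.uniform(0, 10, n_train)
    y = 3.0 * x + rng.normal(0, sigma, n_train)
    X = pd.DataFrame({"x": x})
    matrix = FeatureMatrix(
        X=X, y=pd.Series(y, name="c"), keys=pd.DataFrame({"site_id": range(n_train)}),
        target_kind="c", provenance={"x": "static"},
    )
    model = fit_forest(
        matrix, {"n_estimators": 100, "min_samples_leaf": 40}, seed=7
    )
    x_t = rng.uniform(0.5, 9.5, n_test)
    y_t = 3.0 * x_t + rng.normal(0, sigma, n_test)
    return model, pd.DataFrame({"x": x_t}), y_t, sigma
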