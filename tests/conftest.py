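import numpy as np
import pytest

import priorscope as ps


@pytest.fixture(scope="session")
def cynicism_data():
    """The synthetic cynicism study dataset at the canonical seed."""
    return ps.make_cynicism_like_dataset(ps.FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def cynicism_priors():
    """Original analysis priors: Sex ~ N(0, 10), Lack of Trust ~ N(6, 1)."""
    return ps.PriorSet(
        coefficients=(ps.NormalPrior(0.0, 10.0), ps.NormalPrior(6.0, 1.0)),
        label="original",
    )


@pytest.fixture(scope="session")
def tiny_data():
    """A fixed 10-point single-predictor dataset."""
    rng = np.random.default_rng(7)
    x = rng.standard_normal(10)
    y = 2.0 * x + rng.standard_normal(10)
    return ps.RegressionData(outcome=y, predictors=x[:, None], predictor_names=("x",))


def ols_fit(data: ps.RegressionData, fit_intercept: bool = True) -> np.ndarray:
    """Least-squares oracle, independent of the sampler."""
    x = data.predictors
    if fit_intercept:
        x = np.column_stack([np.ones(data.n), x])
    coef, *_ = np.linalg.lstsq(x, data.outcome, rcond=None)
    return coef
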