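import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fermkin as fk

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1():
    """Bundled 36-h slurry fermentation time course (13 x 5, n=3)."""
    return fk.builtin_fixture("table1")


@pytest.fixture(scope="session")
def table6():
    """Bundled 2^3+center inoculum design table (9 runs, 3 responses)."""
    return fk.builtin_fixture("table6")


# reference fitted coefficients of the starter-culture models, natural
# units, as published for the three responses
PH_COEFFS = dict(fk.synthetic.DEFAULT_DESIGN_TRUTH["pH"])
TTA_COEFFS = dict(fk.synthetic.DEFAULT_DESIGN_TRUTH["tta_pct"])
VISC_COEFFS = dict(fk.synthetic.DEFAULT_DESIGN_TRUTH["viscosity_mPas"])

#: published modified-Gompertz parameter set for the total viable count
TVC_PARAMS = fk.GompertzParams(K=6.911, A=0.790, mu_max=0.202, lag=0.0)


def ols_normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Independent textbook OLS oracle: solve X'X beta = X'y directly."""
    return np.linalg.solve(X.T @ X, X.T @ y)
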