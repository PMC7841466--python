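import numpy as np
import pytest
from scipy.integrate import solve_ivp

import delayrisk as dr

# Published table values: (cancer, delay) -> (tcp_loss mean, lo, hi,
# met risk mean, lo, hi), all in percentage points.
PUBLISHED_TABLE = {
    ("head_and_neck", 2): (4.84, 3.37, 6.40, 0.49, 0.47, 0.51),
    ("head_and_neck", 6): (21.26, 13.40, 30.42, 5.96, 5.23, 6.80),
    ("colorectal", 2): (2.06, 0.70, 3.54, 2.69, 2.58, 2.81),
    ("colorectal", 6): (7.57, 2.24, 14.22, 24.68, 21.89, 27.81),
    ("lung", 2): (1.22, 0.00, 2.78, 0.19, 0.18, 0.20),
    ("lung", 6): (4.26, 0.00, 10.59, 1.86, 1.60, 2.16),
}


def ode_cumulative_hazard(params, g, t, rtol=1e-10):
    """Independent oracle: integrate dM/du = k*P0*e^{g u}, dLambda/du = M.

    Fine-step numeric integration of the hazard ODE system, used to validate
    the closed forms without sharing any code with them.
    """
    if t == 0:
        return params.m0, 0.0

    def rhs(u, y):
        return [params.k * params.p0 * np.exp(g * u), y[0]]

    sol = solve_ivp(rhs, (0.0, t), [params.m0, 0.0], rtol=rtol, atol=1e-18,
                    dense_output=False, t_eval=[t], method="DOP853")
    hazard, lam = sol.y[0][-1], sol.y[1][-1]
    return hazard, lam


@pytest.fixture(scope="session")
def printed_sets():
    return {lab: dr.published_parameters(lab, "printed") for lab in dr.CANCER_LABELS}


@pytest.fixture(scope="session")
def derived_sets():
    return {lab: dr.published_parameters(lab, "derived") for lab in dr.CANCER_LABELS}


@pytest.fixture
def hn_params(printed_sets):
    return printed_sets["head_and_neck"]


def random_parameters(rng):
    """One random but physically plausible parameter draw."""
    return dr.TumorParameters(
        p0=10 ** rng.uniform(6, 10),
        s=10 ** rng.uniform(-12, -7),
        g_mean=rng.uniform(-0.1, 0.3),
        g_sd=rng.uniform(0.0, 0.05),
        k=10 ** rng.uniform(-13, -9),
        m0=rng.choice([0.0, 10 ** rng.uniform(-4, -2)]),
        label="random",
    )
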