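import warnings

import numpy as np
import pytest

import stpdosim as sd

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort (8 patients x 5 sessions)."""
    data, truth = sd.simulate_cohort(seed=0)
    return data, truth


@pytest.fixture(scope="session")
def fast_settings():
    """Cheap but serviceable estimation settings for unit tests."""
    return sd.FitSettings(multistarts=2, seed=0, compute_cov=False,
                          max_restarts=1)


@pytest.fixture(scope="session")
def f4d_fit(cohort, fast_settings):
    """A single shared population fit of the generating model."""
    data, _ = cohort
    return sd.fit_population(data, sd.get_model("f4d"), fast_settings)


def random_valid_params(model, rng):
    """Draw a parameter set satisfying all bounds for the given model."""
    p = {}
    lam = np.sort(np.exp(rng.uniform(np.log(1e-5), np.log(5e-2), 3)))
    while lam[1] / lam[0] < 1.1 or lam[2] / lam[1] < 1.1:
        lam = np.sort(np.exp(rng.uniform(np.log(1e-5), np.log(5e-2), 3)))
    for name in model.param_names:
        if name.startswith("A"):
            p[name] = float(np.exp(rng.uniform(np.log(0.1), np.log(300.0))))
        elif name == "alpha":
            p[name] = float(rng.uniform(0.05, 0.95))
    p["lambda1"] = float(lam[0])
    p["lambda2"] = float(lam[1])
    if "lambda3" in model.param_names:
        p["lambda3"] = float(lam[2])
    return p
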