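import numpy as np
import pytest

from mnrm.inference import NominalResponseModel
from mnrm.simulate import generate_theta, simulate_responses, table2_parameters


@pytest.fixture(scope="session")
def small_fit():
    """A quick 1-D fit on a small simulated dataset, shared across tests."""
    truth = table2_parameters(1)
    latent = generate_theta(150, 1, 1.0, seed=10)
    X = simulate_responses(truth, latent, seed=11)
    model = NominalResponseModel(X, 1)
    results = model.fit(chains=2, iterations=300, warmup=150, seed=12)
    return {"truth": truth, "latent": latent, "X": X, "model": model,
            "results": results}


@pytest.fixture(scope="session")
def recovery_fit():
    """A 1-D fit at N=1000 used for parameter-recovery checks."""
    truth = table2_parameters(1)
    latent = generate_theta(1000, 1, 1.0, seed=20)
    X = simulate_responses(truth, latent, seed=21)
    model = NominalResponseModel(X, 1)
    results = model.fit(chains=2, iterations=500, warmup=250, seed=22)
    return {"truth": truth, "latent": latent, "X": X, "model": model,
            "results": results}
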