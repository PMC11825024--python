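from __future__ import annotations

import numpy as np
import pytest

from mrocc.data_model import Region, Site, StudyDataset
from mrocc.mcmc import SamplerConfig, fit
from mrocc.synthetic import StudyDesign, default_true_params, generate_study


@pytest.fixture
def tiny_dataset() -> StudyDataset:
    """One region, two sites, one detected species."""
    sites = [
        Site("s1", 30, 1200.0, "fast"),
        Site("s2", 30, 5000.0, "moderate"),
    ]
    reg = Region("R01", "Afrotropics", sites, ["sp1"], np.array([[1, 0]]))
    return StudyDataset([reg])


@pytest.fixture(scope="session")
def small_study():
    """A 6-region synthetic study with truth, shared across tests."""
    design = StudyDesign(R=6, J=20, K=30, M_true=40)
    data, truth = generate_study(design, params=default_true_params(6), seed=11)
    return data, truth


@pytest.fixture(scope="session")
def small_fit(small_study):
    """A short 2-chain fit of the shared study (desk-scale smoke posterior)."""
    data, truth = small_study
    cfg = SamplerConfig(n_chains=2, n_iter=1_600, n_burnin=600, seed=7)
    return fit(data, truth.covariates, M=45, config=cfg)
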