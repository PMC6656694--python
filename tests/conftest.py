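import numpy as np
import pandas as pd
import pytest

import cytomon as cm
from cytomon import gate, simulate as sim
from cytomon.io_fcs import EventMatrix


@pytest.fixture(scope="session")
def panel():
    return cm.load_reference_panel()


@pytest.fixture(scope="session")
def pbmc_lineages():
    return cm.load_lineage_table("pbmc_core")


@pytest.fixture(scope="session")
def bmt_lineages():
    return cm.load_lineage_table("bmt_subsets")


@pytest.fixture(scope="session")
def cutoffs(panel):
    return gate.default_cutoffs(panel)


@pytest.fixture(scope="session")
def pbmc_sample():
    """One 20,000-event PBMC sample with default QC contaminants."""
    cfg = sim.profile_config("pbmc_default", 20000, seed=42)
    return sim.simulate_sample(cfg)


@pytest.fixture(scope="session")
def pbmc_transformed(pbmc_sample):
    m, gt = pbmc_sample
    return gate.arcsinh_transform(m), gt


def make_matrix(values, names=None, scale="arcsinh_p995", roles=None):
    """Minimal EventMatrix for synthetic unit-test data."""
    values = np.asarray(values, dtype=float)
    n, c = values.shape
    if names is None:
        names = [f"M{i}" for i in range(c)]
    meta = pd.DataFrame({
        "name": names, "antigen": names, "metal": [""] * c,
        "role": roles if roles is not None else ["antibody"] * c})
    return EventMatrix(values, meta, np.arange(n, dtype=float), scale=scale)
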