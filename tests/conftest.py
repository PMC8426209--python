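import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from immunopanel.normalization import normalize
from immunopanel.scores import load_marker_catalog, score_matrix
from immunopanel.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (the 98-sample study design), seed 7."""
    return simulate_cohort(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def normalized(default_cohort):
    counts, probes, samples, truth = default_cohort
    return normalize(counts, probes)


@pytest.fixture(scope="session")
def marker_catalog():
    return load_marker_catalog()


@pytest.fixture(scope="session")
def cell_scores(normalized, marker_catalog):
    return score_matrix(normalized, marker_catalog)


@pytest.fixture()
def small_counts():
    """Tiny hand-checkable panel: 3 endogenous + 2 HK + 2 neg + 2 pos, 2 samples."""
    genes = ["G1", "G2", "G3", "HK1", "HK2", "NEG1", "NEG2", "POS1", "POS2"]
    counts = pd.DataFrame(
        {
            "A": [100, 200, 400, 500, 600, 2, 4, 1000, 250],
            "B": [200, 400, 800, 1000, 1200, 4, 8, 2000, 500],
        },
        index=pd.Index(genes, name="gene_id"),
    )
    probes = pd.DataFrame(
        {
            "probe_class": ["endogenous"] * 3 + ["housekeeping"] * 2
            + ["negative_control"] * 2 + ["positive_control"] * 2
        },
        index=counts.index,
    )
    return counts, probes
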