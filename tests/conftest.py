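import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from l1burden.catalog import RcL1Catalog, RcL1Locus
from l1burden.synth import SimulationConfig, make_synthetic_study_catalog

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def study_catalog():
    """The study-structured synthetic catalog and its polymorphic ids."""
    return make_synthetic_study_catalog()


@pytest.fixture(scope="session")
def toy_catalog():
    """Five hand-written loci: 3 reference, 2 non-reference point insertions."""
    return RcL1Catalog(
        [
            RcL1Locus("R1", "chr1", 1000, 7019, True, assay_activity_pct=10.0),
            RcL1Locus("R2", "chr2", 5000, 11019, True, germline_td_count=4),
            RcL1Locus("R3", "chrX", 9000, 15019, True, somatic_td_count=30),
            RcL1Locus("N1", "chr1", 15000, 15001, False, assay_activity_pct=120.0, allele_frequency=0.3),
            RcL1Locus("N2", "chr3", 20000, 20001, False),
        ]
    )


@pytest.fixture()
def null_config():
    return SimulationConfig()


def make_phenotypes(n_hc, n_pd, seed=0):
    """Simple balanced covariates for n_hc controls then n_pd cases."""
    rng = np.random.default_rng(seed)
    n = n_hc + n_pd
    return pd.DataFrame(
        {
            "sample_id": [f"S{i:04d}" for i in range(n)],
            "status": ["HC"] * n_hc + ["PD"] * n_pd,
            "sex": rng.choice(["male", "female"], n),
            "age": rng.normal(61, 9, n).clip(30, 85).round(1),
            "family_history": rng.choice(["first_degree", "other", "none"], n, p=[0.1, 0.1, 0.8]),
        }
    )


@pytest.fixture()
def table1_burden_and_phenotypes():
    """Burden table and phenotypes reconstructed from the published 2x2 counts.

    94 controls and 148 cases below the 9-allele threshold (burden 8), 77
    controls and 198 cases at or above it (burden 9).
    """
    counts = [("HC", 8, 94), ("HC", 9, 77), ("PD", 8, 148), ("PD", 9, 198)]
    rows, pheno_rows = [], []
    i = 0
    for status, burden, n in counts:
        for _ in range(n):
            sid = f"T{i:04d}"
            rows.append({"sample_id": sid, "burden": burden, "n_loci_used": 16, "complete": True})
            pheno_rows.append(
                {"sample_id": sid, "status": status, "sex": "male", "age": 61.0, "family_history": "none"}
            )
            i += 1
    return pd.DataFrame(rows), pd.DataFrame(pheno_rows)
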