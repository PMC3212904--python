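import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

import grskit as gk


@pytest.fixture(scope="session")
def seven_snp_cohort():
    """One medium cohort simulated from the 7-SNP multivariate panel."""
    specs = gk.significant_panel()
    config = gk.CohortSimConfig(
        variants=specs,
        per_allele_or={s.snp_id: s.weight for s in specs},
        n_case=369, n_control=503, prevalence=0.005, seed=20240)
    gm, ph = gk.simulate_cohort(config)
    return gm, ph


@pytest.fixture()
def tiny_gm():
    """Hand-built 6-sample, 2-SNP genotype matrix with one missing call."""
    variants = [gk.VariantSpec(snp_id="snpA", gene="G1", control_raf=0.3),
                gk.VariantSpec(snp_id="snpB", gene="G2", control_raf=0.5)]
    dosage = np.array([[0, 1], [1, 2], [2, 0], [0, 0], [1, 1], [2, 2]],
                      dtype=np.int8)
    missing = np.zeros((6, 2), dtype=bool)
    missing[3, 1] = True
    ids = [f"s{i}" for i in range(6)]
    return gk.GenotypeMatrix(ids, variants, dosage, missing)


@pytest.fixture()
def tiny_ph():
    ids = [f"s{i}" for i in range(6)]
    return gk.PhenotypeVector(ids, np.array([1, 1, 1, 0, 0, 0], dtype=bool))
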