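import numpy as np
import pandas as pd
import pytest

from solshift import CohortConfig, QuantMatrix, SampleMeta, generate_cohort
from solshift.io import load_tau_2n4r


@pytest.fixture(scope="session")
def tau_reference() -> str:
    return load_tau_2n4r()


@pytest.fixture(scope="session")
def small_cohort():
    """300-protein cohort with MNAR dropout, no planted effects."""
    config = CohortConfig(n_proteins=300, seed=11)
    return generate_cohort(config)


@pytest.fixture(scope="session")
def planted_cohort():
    """2000-protein cohort, 50 proteins shifted by +1.5 in CBD only.

    Noise is exactly the stated recovery world (residual sd 0.5, no extra
    case-level variance component)."""
    n = 2000
    planted = [f"PROT{i:04d}" for i in range(1, 51)]
    config = CohortConfig(
        n_proteins=n,
        seed=5,
        case_effect_sd=0.0,
        effects={p: {"CBD": 1.5} for p in planted},
    )
    matrix, meta, truth = generate_cohort(config)
    return matrix, meta, truth, planted


def toy_meta(n_cases=2, diseases=("CBD", "PSP")) -> SampleMeta:
    rows = []
    for d in diseases:
        for c in range(n_cases):
            for f in ("soluble", "insoluble"):
                rows.append(
                    {
                        "sample_id": f"{d}_{c + 1}_{f}",
                        "case_id": f"{d}_{c + 1}",
                        "disease": d,
                        "fraction": f,
                    }
                )
    return SampleMeta(pd.DataFrame(rows))


@pytest.fixture
def toy_matrix_meta():
    """Tiny complete modz-scale matrix with matching metadata."""
    meta = toy_meta()
    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        rng.normal(size=(20, len(meta.sample_ids))),
        index=[f"P{i:02d}" for i in range(20)],
        columns=meta.sample_ids,
    )
    return QuantMatrix(values, scale="modz"), meta
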