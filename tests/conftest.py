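import numpy as np
import pandas as pd
import pytest

from gaitdi import (
    CANONICAL_ANGLES,
    GRID_PERCENT,
    AngleCurve,
    CohortMatrix,
    StrideKinematics,
    VECTOR_LENGTH,
    generate_control_cohort,
    make_population_template,
)


def make_stride(values_by_angle=None, stride_id="s1", subject_id="subj1",
                group_label="control", rng=None):
    """Stride with per-angle constant or supplied 51-sample curves."""
    curves = {}
    for name in CANONICAL_ANGLES:
        if values_by_angle and name in values_by_angle:
            vals = np.asarray(values_by_angle[name], dtype=float)
            if vals.ndim == 0:
                vals = np.full(51, float(vals))
        elif rng is not None:
            vals = rng.normal(0.0, 10.0, size=51)
        else:
            vals = np.zeros(51)
        curves[name] = AngleCurve(name, vals)
    return StrideKinematics(
        stride_id=stride_id, subject_id=subject_id,
        group_label=group_label, curves=curves,
    )


def cohort_from_matrix(G, group_label="synthetic"):
    """Wrap a raw 459 x N array as a CohortMatrix with stub metadata."""
    n = G.shape[1]
    meta = pd.DataFrame(
        {
            "stride_id": [f"s{j}" for j in range(n)],
            "subject_id": [f"p{j}" for j in range(n)],
            "group_label": [group_label] * n,
        }
    )
    return CohortMatrix(G, meta)


@pytest.fixture(scope="session")
def template():
    return make_population_template(seed=42)


@pytest.fixture(scope="session")
def control_cohort(template):
    """200 severity-0 strides — the standard control set used across tests."""
    return generate_control_cohort(200, template=template, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
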