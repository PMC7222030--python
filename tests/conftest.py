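import numpy as np
import pandas as pd
import pytest

from eyosvr.datatypes import FeatureMatrix
from eyosvr.harmonize import apply_scaler, fit_reference_scaler
from eyosvr.synthetic_data import (
    CohortSpec,
    generate_adad_cohort,
    generate_sporadic_cohort,
)


@pytest.fixture(scope="session")
def adad_bundle():
    return generate_adad_cohort(CohortSpec.adad_default(seed=42))


@pytest.fixture(scope="session")
def sporadic_bundle():
    return generate_sporadic_cohort(CohortSpec.sporadic_default(seed=43))


@pytest.fixture(scope="session")
def harmonized_adad(adad_bundle):
    ref = adad_bundle.cohort.loc[adad_bundle.cohort.group == "NC", "id"]
    params = fit_reference_scaler(adad_bundle.features, ref, "NC")
    return apply_scaler(adad_bundle.features, params)


@pytest.fixture(scope="session")
def harmonized_sporadic(sporadic_bundle):
    ref = sporadic_bundle.cohort.loc[sporadic_bundle.cohort.group == "CN", "id"]
    params = fit_reference_scaler(sporadic_bundle.features, ref, "CN")
    return apply_scaler(sporadic_bundle.features, params)


@pytest.fixture
def toy_features():
    """Tiny hand-checkable feature matrix: 5 subjects x 3 features."""
    values = pd.DataFrame(
        {
            "A__roi1": [8.0, 10.0, 12.0, 14.0, 6.0],
            "G__roi2": [2.0, 2.5, 3.0, 3.5, 1.5],
            "C__ptau": [20.0, 25.0, 30.0, 35.0, 15.0],
        },
        index=["s1", "s2", "s3", "s4", "s5"],
    )
    return FeatureMatrix(values, cohort="toy")
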