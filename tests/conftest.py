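import numpy as np
import pytest

import twinchol as tc


@pytest.fixture(scope="session")
def published_params() -> tc.CholeskyParams:
    """Generating truth of the packaged best-fitting AE configuration:
    h2_v1 = 0.62, h2_v2 = 0.35 (0.19 visit-2 specific), e21 = 0, unit
    phenotypic variances."""
    return tc.CholeskyParams.from_standardized(0.62, 0.35, 0.19)


@pytest.fixture(scope="session")
def ae_spec() -> tc.ModelSpec:
    return tc.ModelSpec(components=("A", "E"))


@pytest.fixture(scope="session")
def small_cohort(published_params) -> tc.TwinDataset:
    """200 MZ + 200 DZ complete pairs on the log scale, fixed seed."""
    cfg = tc.simple_cohort_config(n_mz=200, n_dz=200, params=published_params)
    return tc.log_transform(tc.simulate_cohort(cfg, seed=42))


@pytest.fixture(scope="session")
def small_fit(small_cohort, ae_spec) -> tc.FitResult:
    return tc.fit(small_cohort, ae_spec, tc.FitOptions(restarts=2, seed=0))


def make_pair(
    family_id="fam1",
    zygosity="MZ",
    ethnicity="EA",
    sex="F",
    phenotype=((1.0, 1.1), (0.9, 1.2)),
    map_bp=None,
    age=None,
    singleton=False,
) -> tc.TwinPair:
    nan = float("nan")
    return tc.TwinPair(
        family_id=family_id,
        zygosity=zygosity,
        ethnicity=ethnicity,
        sex1=sex,
        sex2=None if singleton else sex,
        phenotype=np.asarray(phenotype, dtype=float),
        map_bp=np.asarray(map_bp if map_bp is not None else np.full((2, 2), nan)),
        age=np.asarray(age if age is not None else np.full((2, 2), nan)),
        singleton=singleton,
    )


@pytest.fixture()
def pair_factory():
    return make_pair
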