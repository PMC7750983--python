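import numpy as np
import pytest

from molarcascade.data import average_replicates, build_row_sizes, compute_ratios
from molarcascade.synthetic import GeneratorConfig, add_replicate_noise, simulate_rows


@pytest.fixture(scope="session")
def icm_exact_rows():
    """200 noiseless molar rows lying exactly on the ICM plane."""
    cfg = GeneratorConfig(
        seed=11, n_specimens=200, mode="icm_exact", residual_sd_m3=0.0, groups=()
    )
    return simulate_rows(cfg)


@pytest.fixture(scope="session")
def default_rows():
    """A study-sized sample (n=70, four localities, ICM residual noise)."""
    return simulate_rows(GeneratorConfig(seed=23))


@pytest.fixture(scope="session")
def default_ratios(default_rows):
    return compute_ratios(default_rows)


@pytest.fixture(scope="session")
def measurement_table(default_rows):
    """Replicated length/width measurements around the default rows."""
    return add_replicate_noise(
        default_rows,
        target_repeatability=0.93,
        replicates_per_measurement=3,
        n_observers=2,
        seed=29,
    )


@pytest.fixture(scope="session")
def measurement_csv(tmp_path_factory, measurement_table):
    path = tmp_path_factory.mktemp("data") / "measurements.csv"
    measurement_table.records.to_csv(path, index=False)
    return path
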