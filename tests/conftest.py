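import numpy as np
import pytest

import saffauth as sa
from saffauth.synth import DesignGroup, GeneratorConfig, default_bands


@pytest.fixture(scope="session")
def default_dataset():
    """The full 334-sample study-design dataset at the package default seed."""
    return sa.generate_dataset(sa.default_config())


@pytest.fixture(scope="session")
def model_ii_report(default_dataset):
    """The canonical compliance-screening run (duplex 70/30, 5-fold CV selection)."""
    return sa.run_model_ii(default_dataset, sa.ExperimentSettings(seed=2020))


@pytest.fixture(scope="session")
def model_i_report(default_dataset):
    return sa.run_model_i(default_dataset, sa.ExperimentSettings(seed=2020))


@pytest.fixture
def small_config():
    """A reduced design (fast) with every class/level present."""
    design = (
        DesignGroup("Compliant", 0.0, 2020, (8, 8)),
        DesignGroup("Adulterated2016", 1.0, 2016, (5, 5)),
        DesignGroup("Adulterated2016", 0.40, 2016, (5, 5)),
        DesignGroup("Adulterated2016", 0.25, 2016, (5, 5)),
        DesignGroup("Adulterated2016", 0.10, 2016, (5, 5)),
        DesignGroup("Adulterated2018", 1.0, 2018, (5, 5)),
        DesignGroup("Adulterated2018", 0.40, 2018, (5, 5)),
        DesignGroup("Adulterated2018", 0.25, 2018, (5, 5)),
        DesignGroup("Adulterated2018", 0.10, 2018, (5, 5)),
    )
    return GeneratorConfig(bands=default_bands(), design=design, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
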