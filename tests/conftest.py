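import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from methaneval import (
    GeneratorConfig,
    PairedSeries,
    default_diets,
    generate,
)


@pytest.fixture(scope="session")
def diets():
    return default_diets()


@pytest.fixture
def toy_series():
    """Hand-checkable 3-point series used throughout the worked examples."""
    return PairedSeries(
        o=np.array([2.0, 4.0, 6.0]),
        s=np.array([1.0, 4.0, 7.0]),
        group=np.array([False, False, True]),
        variable="dmi",
        units="kg DM/d",
    )


@pytest.fixture
def identity_series():
    o = np.array([1.3, 2.7, 3.1, 4.9, 5.2])
    return PairedSeries(o=o, s=o.copy(), group=np.zeros(5, dtype=bool),
                        variable="ch4", units="L/d")


@pytest.fixture(scope="session")
def synthetic_records():
    return generate(GeneratorConfig(seed=42))
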