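import numpy as np
import pandas as pd
import pytest

from avflux import GeneratorConfig, simulate_concentrations


def toy_annotations() -> pd.DataFrame:
    """Four valid samples: three vessels at T0 plus one postprandial draw."""
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "animal_id": ["A1", "A1", "A1", "A1"],
            "day": ["D0", "D0", "D0", "D0"],
            "vessel": ["ART", "PV", "HV", "ART"],
            "time_min": [0, 0, 0, 60],
        }
    )


def toy_bucket_long(ann: pd.DataFrame, ppm=(3.0, 2.0, 1.0)) -> pd.DataFrame:
    rows = []
    for i, sid in enumerate(ann["sample_id"]):
        for j, p in enumerate(ppm):
            rows.append((sid, p, 1.0 + i + 0.1 * j))
    return pd.DataFrame(rows, columns=["sample_id", "ppm_center", "intensity"])


@pytest.fixture
def toy_ann():
    return toy_annotations()


@pytest.fixture
def null_cohort():
    """Noise-free cohort with zero extraction everywhere: ART = PV = HV."""
    cfg = GeneratorConfig.uniform_extraction(4, e_int=0.0, e_liv=0.0)
    met, truth = simulate_concentrations(cfg, seed=0)
    return cfg, met, truth


@pytest.fixture
def extraction_cohort():
    """Noise-free cohort with constant e_int = 0.2, e_liv = 0.1."""
    cfg = GeneratorConfig.uniform_extraction(3, e_int=0.2, e_liv=0.1)
    met, truth = simulate_concentrations(cfg, seed=0)
    return cfg, met, truth
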