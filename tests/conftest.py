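import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")

GENOTYPES = ("KRL-210", "Kharchia-65", "HD-2329", "WH-542")

# Published 15-indicator standardized matrix (genotype columns in table order).
STANDARDIZED_TABLE = {
    "KRL-210": [0.603, 1, 0.813, 0.721, 0.653, 0.817, 0.509, 0.504,
                0.838, 0.758, 0.628, 0.726, 0.805, 0.964, 0.859],
    "Kharchia-65": [1, 0.728, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1],
    "HD-2329": [0] * 15,
    "WH-542": [0.344, 0.169, 0.221, 0.303, 0.197, 0.106, 0.184, 0.181,
               0.212, 0.103, 0.396, 0.489, 0.309, 0.316, 0.137],
}

# Published morphology means: (control, salt, printed % change) per genotype.
HEIGHT_TABLE = {
    "KRL-210": (79.59, 60.74, 23.68),
    "Kharchia-65": (91.68, 77.21, 15.78),
    "HD-2329": (71.16, 53.27, 25.14),
    "WH-542": (70.32, 56.43, 19.75),
}
TILLERS_TABLE = {
    "KRL-210": (3.66, 1.99, 45.62),
    "Kharchia-65": (3.33, 2.33, 30.03),
    "HD-2329": (2.66, 1.33, 50.00),
    "WH-542": (2.99, 1.66, 44.48),
}

# Reported shoot fold changes for the HKT2 transporters (direction, fold).
REPORTED_FOLDS = {
    ("TaHKT2;1", "Kharchia-65"): ("down", 4.05),
    ("TaHKT2;1", "KRL-210"): ("down", 3.21),
    ("TaHKT2;1", "WH-542"): ("up", 4.52),
    ("TaHKT2;1", "HD-2329"): ("up", 6.05),
    ("TaHKT2;3", "Kharchia-65"): ("down", 8.05),
    ("TaHKT2;3", "KRL-210"): ("down", 6.52),
    ("TaHKT2;3", "WH-542"): ("up", 8.51),
    ("TaHKT2;3", "HD-2329"): ("up", 10.30),
}


@pytest.fixture
def standardized_matrix() -> pd.DataFrame:
    ids = [f"I{k}" for k in range(1, 16)]
    return pd.DataFrame(STANDARDIZED_TABLE, index=ids, dtype=float)
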