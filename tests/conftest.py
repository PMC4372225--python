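import numpy as np
import pandas as pd
import pytest

from fpqsar.datasets import LABEL_ACTIVE, LABEL_INACTIVE, ActivityDataset
from fpqsar.fingerprints import FingerprintMatrix
from fpqsar.synthetic import generate, planted_preset

FIXTURE_SEED = 0


@pytest.fixture(scope="session")
def planted_data():
    """Balanced planted-signal benchmark: 500/500 compounds, 5 positive bits
    (0.7/0.4), 5 negative bits (0.4/0.7), background 0.3, 881 descriptors."""
    return generate(planted_preset(FIXTURE_SEED))


@pytest.fixture
def toy_dataset():
    """Six hand-labelled compounds (3 inhibitors / 3 non-inhibitors)."""
    frame = pd.DataFrame(
        {
            "compound_id": [f"C{i}" for i in range(6)],
            "smiles": ["CCO", "CCN", "CCC", "CCCl", "CCBr", "CCI"],
            "label": [LABEL_ACTIVE] * 3 + [LABEL_INACTIVE] * 3,
        }
    )
    return ActivityDataset(cutoff_nm=10.0, compounds=frame)


def make_matrix(bits, compound_ids=None, names=None) -> FingerprintMatrix:
    """Small fingerprint matrix from a nested list / array of 0-1 values."""
    arr = np.asarray(bits, dtype=int)
    ids = compound_ids or [f"C{i}" for i in range(arr.shape[0])]
    cols = names or [f"FP{j + 1}" for j in range(arr.shape[1])]
    return FingerprintMatrix(
        pd.DataFrame(arr, index=ids, columns=cols).rename_axis("compound_id")
    )
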