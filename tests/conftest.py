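import numpy as np
import pandas as pd
import pytest

from trialmark.config import validate_config
from trialmark.simulate import mcrc_trial_design, simulate_trial


@pytest.fixture(scope="session")
def mcrc_dataset():
    """One realistic synthetic trial with a planted predictive marker."""
    return simulate_trial(mcrc_trial_design(seed=11))


@pytest.fixture(scope="session")
def mcrc_config():
    return validate_config(
        {
            "subtype_schemes": ["side", "cms"],
            "covariate_names": ["n_met_sites", "prior_resection"],
            "seed": 11,
        }
    )


@pytest.fixture()
def tiny_trial_files(tmp_path):
    """Three-patient clinical + alteration TSV pair with matching ids."""
    clinical = pd.DataFrame(
        {
            "patient_id": ["p1", "p2", "p3"],
            "treatment": [0, 1, 0],
            "os_time": [10.0, 5.5, 7.2],
            "os_event": [1, 0, 1],
            "orr": [1, 0, 1],
        }
    )
    alterations = pd.DataFrame(
        {"patient_id": ["p1", "p2", "p3"], "KRAS": [1, 0, 1], "TP53": [0, 1, 1]}
    )
    cpath, apath = tmp_path / "clinical.tsv", tmp_path / "alterations.tsv"
    clinical.to_csv(cpath, sep="\t", index=False)
    alterations.to_csv(apath, sep="\t", index=False)
    return cpath, apath


def make_binary_trial(counts, seed=0):
    """Build a deterministic ORR-only trial from per-cell response counts.

    ``counts`` maps (x, arm) -> (responders, total).
    """
    rows = []
    i = 0
    for (x, arm), (resp, total) in counts.items():
        for k in range(total):
            rows.append(
                {
                    "patient_id": f"p{i}",
                    "treatment": arm,
                    "orr": 1 if k < resp else 0,
                    "x": x,
                }
            )
            i += 1
    frame = pd.DataFrame(rows)
    clinical = frame[["patient_id", "treatment", "orr"]].copy()
    alterations = frame[["x"]].rename(columns={"x": "G1"}).astype(np.int8)
    from trialmark.data import TrialDataset

    return TrialDataset(
        clinical=clinical.reset_index(drop=True),
        alterations=alterations.reset_index(drop=True),
    )
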