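import numpy as np
import pandas as pd
import pytest


def make_harmonized(gamma, se_gamma, Gamma, se_Gamma, ids=None):
    """Assemble a harmonized-instrument frame from plain arrays."""
    gamma = np.asarray(gamma, dtype=float)
    J = len(gamma)
    return pd.DataFrame({
        "variant_id": ids if ids is not None else [f"rs{i+1}" for i in range(J)],
        "gamma": gamma,
        "se_gamma": np.asarray(se_gamma, dtype=float),
        "Gamma": np.asarray(Gamma, dtype=float),
        "se_Gamma": np.asarray(se_Gamma, dtype=float),
        "eaf": 0.3,
        "harmonization_action": "direct",
    })


def make_sumstats(rows):
    """Canonical summary-statistics frame from a list of row dicts."""
    defaults = dict(chrom="1", pos=1, eaf=0.3, n=100000.0)
    recs = []
    for i, r in enumerate(rows):
        rec = dict(defaults)
        rec.setdefault("pos", 1 + i)
        rec.update(r)
        recs.append(rec)
    df = pd.DataFrame(recs)
    df["pos"] = df["pos"].astype("Int64")
    return df


@pytest.fixture
def harmonized_factory():
    return make_harmonized


@pytest.fixture
def sumstats_factory():
    return make_sumstats
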