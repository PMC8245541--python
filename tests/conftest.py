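import numpy as np
import pandas as pd
import pytest

from bonlac import RatioTable
from bonlac.screen import CandidateCall


def make_table(values, oriented=True, replicate_prefix="rep"):
    """RatioTable from a dict {protein_id: [ratios with None for missing]}."""
    data = pd.DataFrame.from_dict(values, orient="index", dtype=float)
    data.index.name = "protein_id"
    data.columns = [f"{replicate_prefix}{j + 1}" for j in range(data.shape[1])]
    return RatioTable(data=data, oriented=oriented)


def make_calls(n_up=0, n_down=0, n_unchanged=0, n_insufficient=0, prefix="P"):
    """Fabricate a call list with the given class counts."""
    calls, i = [], 0
    for klass, count, mean in (
        ("up", n_up, 1.5),
        ("down", n_down, 0.6),
        ("unchanged", n_unchanged, 1.0),
        ("insufficient", n_insufficient, float("nan")),
    ):
        for _ in range(count):
            i += 1
            n_det = 1 if klass == "insufficient" else 4
            calls.append(
                CandidateCall(
                    protein_id=f"{prefix}{i:05d}",
                    n_detected=n_det,
                    mean_ratio=mean,
                    n_up=3 if klass == "up" else 0,
                    n_down=3 if klass == "down" else 0,
                    klass=klass,
                )
            )
    return calls


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
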