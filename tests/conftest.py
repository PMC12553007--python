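import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mrtriangle.containers import InstrumentSet, LDMatrix

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_instrument_set(bx, by, se_y, r=None, se_x=None,
                        exposure="EXP", outcome="OUT") -> InstrumentSet:
    """Assemble an InstrumentSet from raw arrays (identity LD default)."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    se_y = np.asarray(se_y, dtype=float)
    k = len(bx)
    ids = [f"rs{i + 1:03d}" for i in range(k)]
    if r is None:
        r = np.eye(k)
    table = pd.DataFrame({
        "variant_id": ids,
        "bx": bx,
        "se_x": np.full(k, 0.01) if se_x is None else np.asarray(se_x, float),
        "by": by,
        "se_y": se_y,
    })
    return InstrumentSet(exposure, outcome, table, LDMatrix(ids, r))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def instrument_builder():
    return make_instrument_set
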