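import numpy as np
import pandas as pd
import pytest

from spatedm.containers import SurveyTable


def logistic_series(n: int, r: float = 3.8, x0: float = 0.3, burn: int = 100) -> np.ndarray:
    x = x0
    out = np.empty(n + burn)
    for t in range(n + burn):
        out[t] = x
        x = r * x * (1 - x)
    return out[burn:]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_survey(rows, class_kind="length"):
    """rows: iterable of (year, quarter, subarea, class_id, cpue)."""
    df = pd.DataFrame(rows, columns=["year", "quarter", "subarea", "class_id", "cpue"])
    return SurveyTable.from_records(df, class_kind)


@pytest.fixture
def toy_survey():
    """Two quarters x three subareas x two length classes, no zeros."""
    rows = []
    for year, quarter in [(2000, 1), (2000, 3)]:
        for s in ("A", "B", "C"):
            for c in (0, 1):
                rows.append((year, quarter, s, c, 1.0 + hash((s, c)) % 5))
    return make_survey(rows)
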