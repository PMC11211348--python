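import numpy as np
import pandas as pd
import pytest

from ammodiv.occurrences import OCCURRENCE_COLUMNS


def make_occurrences(rows):
    """Build an occurrence frame from (genus, max_ma, min_ma) or full tuples."""
    full = []
    for i, r in enumerate(rows):
        if len(r) == 3:
            genus, hi, lo = r
            full.append(
                (f"occ{i}", f"loc{i}", "SubA", "SF01", genus, "", hi, lo, 0.0, 0.0, "S")
            )
        else:
            full.append(r)
    return pd.DataFrame(full, columns=OCCURRENCE_COLUMNS)


@pytest.fixture
def toy_table():
    return make_occurrences(
        [
            ("Alpha", 90.0, 85.0),
            ("Alpha", 88.0, 84.0),
            ("Beta", 76.0, 72.0),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240613)
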