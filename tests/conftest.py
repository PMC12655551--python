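import numpy as np
import pytest

from screenval.enrichment import RankedList
from screenval.io import ScreeningRecord


def ranked_from_labels(labels, prefix="C"):
    """Build a RankedList whose best-first order follows the label sequence.

    Scores are the positions themselves (lower is better), so the intended
    order survives the sort and there are no ties.
    """
    records = [ScreeningRecord(f"{prefix}{i:04d}", float(i), lab)
               for i, lab in enumerate(labels)]
    return RankedList.from_records(records, "lower_is_better")


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def ranked_small():
    # actives at ranks 1 and 3 of 4
    return ranked_from_labels(["active", "decoy", "active", "decoy"])
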