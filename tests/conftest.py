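import numpy as np
import pytest

from actimem.activities import ACTIVITY_NAMES
from actimem.types import AGE_GROUPS, ParticipantRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_record(id="p0", age=67, education=12, imm1=5, del1=4, imm2=4, del2=4,
                activities=None, missing_activities=0):
    """Complete record with optional leading missing activity cells."""
    acts = {name: 3 for name in ACTIVITY_NAMES}
    if activities:
        acts.update(activities)
    for name in list(ACTIVITY_NAMES)[:missing_activities]:
        acts[name] = None
    return ParticipantRecord(
        id=id, age_years=age, education_years=education,
        recall_immediate_w1=imm1, recall_delayed_w1=del1,
        recall_immediate_w2=imm2, recall_delayed_w2=del2,
        activities=acts)


@pytest.fixture
def tiny_cohort(rng):
    """Complete 40-record cohort spread over all five age groups."""
    recs = []
    for i in range(40):
        g = AGE_GROUPS[i % 5]
        recs.append(make_record(
            id=f"t{i}", age=int(rng.integers(g.lo, g.hi + 1)),
            education=int(rng.integers(8, 21)),
            imm1=int(rng.integers(0, 11)), del1=int(rng.integers(0, 11)),
            imm2=int(rng.integers(0, 11)), del2=int(rng.integers(0, 11)),
            activities={n: int(rng.integers(0, 6)) for n in ACTIVITY_NAMES}))
    return recs
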