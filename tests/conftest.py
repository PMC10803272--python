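import math

import pytest

from burdenproof.observations import ObservationRecord

Z = 1.959963984540054


def make_record(obs_id="o1", study_id="s1", outcome_id="out", rr=1.2,
                se_log_rr=0.1, **kw):
    """A valid record with sensible defaults; se given directly unless a
    CI pair is passed in kw."""
    if "ci_lower" in kw or "ci_upper" in kw:
        se_log_rr = None
    return ObservationRecord(obs_id=obs_id, study_id=study_id,
                             outcome_id=outcome_id, rr=rr,
                             se_log_rr=se_log_rr, **kw)


def record_from_log(obs_id, study_id, log_rr, se, **kw):
    """Record specified on the log scale via a symmetric CI."""
    return ObservationRecord(
        obs_id=obs_id, study_id=study_id, outcome_id=kw.pop("outcome_id", "out"),
        rr=math.exp(log_rr),
        ci_lower=math.exp(log_rr - Z * se),
        ci_upper=math.exp(log_rr + Z * se),
        **kw,
    )


@pytest.fixture
def record():
    return make_record()
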