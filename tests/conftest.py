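import pytest

from csfsim.cases import CASE_IDS, run_case


@pytest.fixture(scope="session")
def case_runs():
    """25 s monolithic runs of all reference cases, keyed by case id.

    Default settings: dt 0.05 s, outlet states initialized at the
    10 mmHg target mean, metrics over the last 5 s.
    """
    return {cid: run_case(cid) for cid in CASE_IDS}
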