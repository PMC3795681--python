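import pytest

from nsburst import ModelParams, NetworkConfig, run_simulation
from nsburst import events


@pytest.fixture(scope="session")
def baseline_record():
    """One medium-length baseline run at the reduced problem size
    (N=200, dt=0.1 ms), shared across statistics tests."""
    cfg = NetworkConfig(params=ModelParams(), N=200, dt=0.1,
                        duration=220.0, seed=11)
    record, _ = run_simulation(cfg)
    return record


@pytest.fixture(scope="session")
def baseline_events(baseline_record):
    ns = events.detect_ns_record(baseline_record)
    bns = events.partition_bns(ns)
    return ns, bns
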