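import numpy as np
import pytest

from brachyaudit import phantom, tg43
from brachyaudit.audit import AuditConfig, run_audit


@pytest.fixture(scope="session")
def source():
    return tg43.load_default_source()


@pytest.fixture(scope="session")
def geom():
    return phantom.build_default_phantom(seed=0)


@pytest.fixture(scope="session")
def plan(geom, source):
    return phantom.build_plan(geom, source)


@pytest.fixture(scope="session")
def ct(geom):
    return phantom.synthesize_ct(geom)


@pytest.fixture(scope="session")
def single_dwell_plan(source):
    dwell = tg43.DwellPosition(np.zeros(3), np.array([0.0, 0.0, 1.0]), 3600.0)
    return tg43.Plan({1: [dwell]}, source)


@pytest.fixture(scope="session")
def audit_error_free():
    """Full synthetic audit, no injected error (shared across test modules)."""
    return run_audit(AuditConfig(seed=1)).report.data


@pytest.fixture(scope="session")
def audit_shifted():
    """Same audit with the deliberate 2 mm catheter-tip shift."""
    return run_audit(AuditConfig(seed=1, catheter_shift_mm=2.0)).report.data
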