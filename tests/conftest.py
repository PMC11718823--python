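import pytest

from medmax import PatientRecord, default_registry, generate_patient


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def favorable_record() -> PatientRecord:
    """A fully favorable, resectable record (zero flags by construction)."""
    record, _ = generate_patient("clean_pass", 42)
    return record


@pytest.fixture()
def make_record(favorable_record):
    """Factory: the favorable record with field overrides."""
    def _make(**overrides) -> PatientRecord:
        return favorable_record.with_updates(**overrides)
    return _make
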