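from datetime import datetime, timedelta, timezone

import pytest

from seqfab.config import ChemistryConfig, ValidationLimits
from seqfab.model import Role
from seqfab.store import FacilityStore, Principal


def make_clock(start: datetime | None = None, step_seconds: float = 1.0):
    """A deterministic clock: starts at a fixed instant, ticks per call."""
    t0 = start or datetime(2020, 1, 1, tzinfo=timezone.utc)
    state = {"n": -1}

    def clock() -> datetime:
        state["n"] += 1
        return t0 + timedelta(seconds=state["n"] * step_seconds)

    return clock


@pytest.fixture
def limits() -> ValidationLimits:
    return ValidationLimits()


@pytest.fixture
def chemistry() -> ChemistryConfig:
    return ChemistryConfig()


@pytest.fixture
def store() -> FacilityStore:
    s = FacilityStore(clock=make_clock())
    s.add_principal(Principal("alice", "Alice", {"G1"}, Role.USER))
    s.add_principal(Principal("bob", "Bob", {"G2"}, Role.USER))
    s.add_principal(Principal("op", "Operator", {"FACILITY"}, Role.OPERATOR))
    return s


@pytest.fixture
def alice(store) -> Principal:
    return store.get_principal("alice")


@pytest.fixture
def bob(store) -> Principal:
    return store.get_principal("bob")


@pytest.fixture
def operator(store) -> Principal:
    return store.get_principal("op")


def valid_record(**overrides) -> dict:
    """A customer-primer sample record that passes the default limits."""
    record = {
        "template_name": "pET28-insulin",
        "primer_name": "oligo001",
        "primer_source": "customer",
        "template_conc_ng_ul": 100.0,
        "template_vol_ul": 30.0,
        "primer_conc_pmol_ul": 10.0,
        "primer_vol_ul": 20.0,
        "read_length_bp": 700,
        "seq_type": "standard",
    }
    record.update(overrides)
    return record


def facility_record(**overrides) -> dict:
    """A facility-stock-primer record (no primer concentration/volume)."""
    record = valid_record(primer_name="T7", primer_source="facility",
                          primer_conc_pmol_ul="", primer_vol_ul="")
    record.update(overrides)
    return record
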