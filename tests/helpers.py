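"""Shared builders used by tests and by the golden-file generator."""

from seqfab.config import ChemistryConfig, ValidationLimits
from seqfab.model import DoseMode, Role
from seqfab.planner import plan_run
from seqfab.store import FacilityStore, Principal
from seqfab.submission import create_order

from conftest import make_clock, valid_record, facility_record


def build_golden_store(mode: DoseMode = DoseMode.VARIABLE):
    """A small fixed facility: two orders (3 samples) planned onto one run.

    Hand-picked concentrations make the variable-mode recipes exact:
    50 ng/uL -> 2.0 uL template, 100 -> 1.0, 25 -> 4.0; a 10 pmol/uL
    customer primer doses 0.5 uL and facility primers get the fixed
    1.0 uL.  Used for the byte-exact robot/instrument sheet tests.
    """
    store = FacilityStore(clock=make_clock())
    store.add_principal(Principal("alice", "Alice", {"G1"}, Role.USER))
    store.add_principal(Principal("op", "Operator", {"FACILITY"}, Role.OPERATOR))
    limits = ValidationLimits()
    chemistry = ChemistryConfig()
    order1, _ = create_order(
        store, "alice", "G1",
        [
            facility_record(template_name="pUC19", primer_name="M13F",
                            template_conc_ng_ul=50.0),
            valid_record(template_name="pET28a", primer_name="oligo001",
                         template_conc_ng_ul=100.0, primer_conc_pmol_ul=10.0),
        ],
        limits, chemistry,
    )
    order2, _ = create_order(
        store, "alice", "G1",
        [facility_record(template_name="pGEX", primer_name="T7",
                         template_conc_ng_ul=25.0)],
        limits, chemistry,
    )
    run = plan_run(store, [order1, order2], chemistry, mode)
    return store, run, chemistry, limits
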