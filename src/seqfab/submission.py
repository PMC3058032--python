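"""Customer order intake: validation, spreadsheet import, amendment.

Orders arrive either as programmatic records or as a sample sheet (CSV or
XLSX, one row per sample).  Every record is validated against the
facility's configured limits before anything is created — a single bad
field anywhere rejects the whole submission, so the stored order always
corresponds exactly to what the customer sent.  On creation the customer
receives a confirmation listing, per distinct template and per distinct
customer-supplied primer, the minimal volume to hand over to the facility.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd

from .config import ChemistryConfig, ValidationLimits, round_up
from .errors import CapacityError, StateError, ValidationError
from .model import DoseMode, Order, OrderState, PrimerSource, Sample
from .store import FacilityStore

#: Documented sample-sheet schema; one row = one sample, header row required.
SHEET_COLUMNS = [
    "template_name",
    "primer_name",
    "primer_source",
    "template_conc_ng_ul",
    "template_vol_ul",
    "primer_conc_pmol_ul",
    "primer_vol_ul",
    "read_length_bp",
    "seq_type",
]

MAX_SHEET_ROWS = 96  # one plate's worth of samples per sheet


@dataclass
class Violation:
    """One field-level validation failure."""

    field: str
    value: Any
    constraint: str

    def __str__(self) -> str:
        return f"{self.field}={self.value!r}: {self.constraint}"


@dataclass
class OrderConfirmation:
    """Minimal volumes the customer must supply, per template and primer.

    Line items are (name, volume uL) pairs sorted by name; facility-stock
    primers are excluded (the facility supplies those).
    """

    order_id: str
    templates: list[tuple[str, float]]
    primers: list[tuple[str, float]]


def _num(record: Mapping[str, Any], key: str) -> float | None:
    value = record.get(key)
    if value is None or (isinstance(value, str) and not value.strip()):
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        return None


def validate_sample(
    record: Mapping[str, Any], limits: ValidationLimits
) -> list[Violation]:
    """Check one sample record against the facility limits.

    Pure function: returns a (possibly empty) list of violations, each
    naming the field, the offending value and the bound breached.  A
    missing required field is itself a violation.
    """
    v: list[Violation] = []

    template_name = str(record.get("template_name") or "").strip()
    if not template_name:
        v.append(Violation("template_name", record.get("template_name"),
                           "required and non-empty"))
    primer_name = str(record.get("primer_name") or "").strip()
    if not primer_name:
        v.append(Violation("primer_name", record.get("primer_name"),
                           "required and non-empty"))

    source_raw = str(record.get("primer_source") or "").strip().lower()
    source: PrimerSource | None = None
    if source_raw in (PrimerSource.CUSTOMER.value, PrimerSource.FACILITY.value):
        source = PrimerSource(source_raw)
    else:
        v.append(Violation("primer_source", record.get("primer_source"),
                           "must be 'customer' or 'facility'"))

    tconc = _num(record, "template_conc_ng_ul")
    if tconc is None:
        v.append(Violation("template_conc_ng_ul",
                           record.get("template_conc_ng_ul"),
                           "required numeric value"))
    elif not (limits.template_concentration_min <= tconc
              <= limits.template_concentration_max):
        v.append(Violation(
            "template_conc_ng_ul", tconc,
            f"outside [{limits.template_concentration_min}, "
            f"{limits.template_concentration_max}] ng/uL"))

    tvol = _num(record, "template_vol_ul")
    if tvol is None:
        v.append(Violation("template_vol_ul", record.get("template_vol_ul"),
                           "required numeric value"))
    elif tvol < limits.template_volume_min:
        v.append(Violation("template_vol_ul", tvol,
                           f"below minimum {limits.template_volume_min} uL"))

    if source is PrimerSource.CUSTOMER or source is None:
        pconc = _num(record, "primer_conc_pmol_ul")
        if pconc is None:
            if source is PrimerSource.CUSTOMER:
                v.append(Violation("primer_conc_pmol_ul",
                                   record.get("primer_conc_pmol_ul"),
                                   "required for customer primers"))
        elif not (limits.primer_concentration_min <= pconc
                  <= limits.primer_concentration_max):
            v.append(Violation(
                "primer_conc_pmol_ul", pconc,
                f"outside [{limits.primer_concentration_min}, "
                f"{limits.primer_concentration_max}] pmol/uL"))
        pvol = _num(record, "primer_vol_ul")
        if pvol is None:
            if source is PrimerSource.CUSTOMER:
                v.append(Violation("primer_vol_ul",
                                   record.get("primer_vol_ul"),
                                   "required for customer primers"))
        elif pvol < limits.primer_volume_min:
            v.append(Violation("primer_vol_ul", pvol,
                               f"below minimum {limits.primer_volume_min} uL"))

    seq_type = str(record.get("seq_type") or "").strip()
    if seq_type not in limits.sequencing_types:
        v.append(Violation("seq_type", record.get("seq_type"),
                           f"must be one of {sorted(limits.sequencing_types)}"))

    rlen = _num(record, "read_length_bp")
    if rlen is None:
        # default from the sequencing type, when the type itself is valid
        if seq_type not in limits.sequencing_types:
            v.append(Violation("read_length_bp", record.get("read_length_bp"),
                               "required when seq_type is invalid"))
    elif rlen <= 0 or int(rlen) != rlen:
        v.append(Violation("read_length_bp", rlen,
                           "must be a positive integer number of bases"))
    return v


def sample_from_record(
    record: Mapping[str, Any], sample_ref: str, limits: ValidationLimits
) -> Sample:
    """Build a Sample from a validated record (call validate_sample first)."""
    source = PrimerSource(str(record["primer_source"]).strip().lower())
    seq_type = str(record["seq_type"]).strip()
    rlen = _num(record, "read_length_bp")
    if rlen is None:
        rlen = limits.sequencing_types[seq_type]
    pconc = _num(record, "primer_conc_pmol_ul")
    if source is PrimerSource.FACILITY:
        pconc = None
    return Sample(
        sample_ref=sample_ref,
        template_name=str(record["template_name"]).strip(),
        primer_name=str(record["primer_name"]).strip(),
        primer_source=source,
        template_concentration=float(record["template_conc_ng_ul"]),
        template_volume_supplied=float(record["template_vol_ul"]),
        primer_concentration=pconc,
        primer_volume_supplied=_num(record, "primer_vol_ul") or 0.0,
        requested_read_length=int(rlen),
        sequencing_type=seq_type,
    )


def import_spreadsheet(
    source: str | Path | pd.DataFrame, limits: ValidationLimits
) -> list[dict[str, Any]]:
    """Read a sample sheet (CSV or XLSX) into validated sample records.

    The header must match :data:`SHEET_COLUMNS` exactly (order-insensitive);
    1 to 96 data rows are accepted.  Any per-row validation failure rejects
    the whole file, with 1-based data-row numbers in the messages, so the
    file on disk and the order in the system never diverge.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        path = Path(source)
        if path.suffix.lower() in (".xlsx", ".xlsm"):
            df = pd.read_excel(path, dtype=object)
        else:
            df = pd.read_csv(path, dtype=object)
    have = list(df.columns)
    missing = [c for c in SHEET_COLUMNS if c not in have]
    unknown = [c for c in have if c not in SHEET_COLUMNS]
    if missing or unknown:
        problems = []
        if missing:
            problems.append("missing columns: " + ", ".join(missing))
        if unknown:
            problems.append("unknown columns: " + ", ".join(unknown))
        raise ValidationError("sheet schema mismatch", problems)
    if len(df) == 0:
        raise ValidationError("no samples: the sheet contains a header only")
    if len(df) > MAX_SHEET_ROWS:
        raise CapacityError(
            f"plate capacity exceeded: {len(df)} rows > {MAX_SHEET_ROWS}",
            overflow=len(df) - MAX_SHEET_ROWS,
        )
    records: list[dict[str, Any]] = []
    problems: list[str] = []
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        record = {
            c: (None if pd.isna(row[c]) else row[c]) for c in SHEET_COLUMNS
        }
        for violation in validate_sample(record, limits):
            problems.append(f"row {i}: {violation}")
        records.append(record)
    if problems:
        raise ValidationError("sample sheet failed validation", problems)
    return records


def compute_confirmation(
    order: Order, chemistry: ChemistryConfig
) -> OrderConfirmation:
    """Minimal volumes to supply, per distinct template and customer primer.

    Each reaction's demand is the variable-mode dose for that sample
    (what the planner will actually pipette); demands are summed per
    name, multiplied by the configured safety factor, and rounded up to
    the confirmation increment.  Facility-stock primers are excluded.
    """
    from .planner import compute_well_recipe  # local import; no cycle at module load

    template_demand: dict[str, float] = {}
    primer_demand: dict[str, float] = {}
    for sample in order.samples:
        recipe, _ = compute_well_recipe(sample, chemistry, DoseMode.VARIABLE)
        template_demand[sample.template_name] = (
            template_demand.get(sample.template_name, 0.0)
            + recipe.template_volume
        )
        if sample.primer_source is PrimerSource.CUSTOMER:
            primer_demand[sample.primer_name] = (
                primer_demand.get(sample.primer_name, 0.0)
                + recipe.primer_volume
            )

    def finalize(demand: dict[str, float]) -> list[tuple[str, float]]:
        return [
            (name, round_up(total * chemistry.safety_factor,
                            chemistry.confirmation_increment))
            for name, total in sorted(demand.items())
        ]

    return OrderConfirmation(
        order_id=order.order_id,
        templates=finalize(template_demand),
        primers=finalize(primer_demand),
    )


def create_order(
    store: FacilityStore,
    owner: str,
    group: str,
    records: Sequence[Mapping[str, Any]],
    limits: ValidationLimits,
    chemistry: ChemistryConfig,
    account: str = "",
) -> tuple[Order, OrderConfirmation]:
    """Create a NEW order from validated sample records.

    All records are validated first and every violation is reported at
    once; nothing is created on failure.  The confirmation is appended to
    the event log as the ``order_confirmed`` notification (the e-mail
    surrogate).
    """
    if not records:
        raise ValidationError("empty order: at least one sample is required")
    problems: list[str] = []
    for i, record in enumerate(records, start=1):
        for violation in validate_sample(record, limits):
            problems.append(f"sample {i}: {violation}")
    if problems:
        raise ValidationError("order failed validation", problems)
    order_id = store.next_order_id()
    samples = [
        sample_from_record(r, store.next_sample_ref(), limits) for r in records
    ]
    order = Order(
        order_id=order_id,
        owner=owner,
        group=group,
        samples=samples,
        state=OrderState.NEW,
        created_at=store.now(),
        account=account,
    )
    store.add_order(order)
    confirmation = compute_confirmation(order, chemistry)
    store.append_event(
        "order_confirmed",
        owner,
        {
            "order_id": order_id,
            "sample_refs": order.sample_refs(),
            "templates": confirmation.templates,
            "primers": confirmation.primers,
        },
    )
    return order, confirmation


def _require_amendable(order: Order) -> None:
    if order.state is not OrderState.NEW:
        raise StateError(
            f"order {order.order_id} is locked by run planning "
            f"(state {order.state.value})"
        )


def add_sample(
    store: FacilityStore,
    order: Order,
    record: Mapping[str, Any],
    limits: ValidationLimits,
) -> Sample:
    """Append a freshly validated sample to a NEW order."""
    _require_amendable(order)
    violations = validate_sample(record, limits)
    if violations:
        raise ValidationError("sample failed validation",
                              [str(v) for v in violations])
    sample = sample_from_record(record, store.next_sample_ref(), limits)
    order.samples.append(sample)
    store.register_sample(order, sample)
    return sample


def remove_sample(store: FacilityStore, order: Order, sample_ref: str) -> None:
    """Remove one sample from a NEW order; the last sample may not go."""
    _require_amendable(order)
    if len(order.samples) <= 1:
        raise ValidationError(
            "cannot remove the only sample: orders hold at least one"
        )
    for i, s in enumerate(order.samples):
        if s.sample_ref == sample_ref:
            del order.samples[i]
            return
    raise ValidationError(f"sample {sample_ref!r} is not in order {order.order_id}")


def replace_sample(
    store: FacilityStore,
    order: Order,
    sample_ref: str,
    record: Mapping[str, Any],
    limits: ValidationLimits,
) -> Sample:
    """Swap one sample's details for a new validated record (fresh ref)."""
    _require_amendable(order)
    violations = validate_sample(record, limits)
    if violations:
        raise ValidationError("sample failed validation",
                              [str(v) for v in violations])
    for i, s in enumerate(order.samples):
        if s.sample_ref == sample_ref:
            sample = sample_from_record(record, store.next_sample_ref(), limits)
            order.samples[i] = sample
            store.register_sample(order, sample)
            return sample
    raise ValidationError(f"sample {sample_ref!r} is not in order {order.order_id}")


def amend_order(
    store: FacilityStore,
    order: Order,
    action: str,
    limits: ValidationLimits,
    sample_ref: str | None = None,
    record: Mapping[str, Any] | None = None,
) -> None:
    """Dispatch an add/remove/replace edit (CLI convenience)."""
    if action == "add":
        add_sample(store, order, record or {}, limits)
    elif action == "remove":
        remove_sample(store, order, sample_ref or "")
    elif action == "replace":
        replace_sample(store, order, sample_ref or "", record or {}, limits)
    else:
        raise ValidationError(f"unknown amendment action {action!r}")
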