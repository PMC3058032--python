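"""Shared domain types and the order/run state machines.

A sequencing facility processes work in four stages: a customer's *new
order* is pooled with others into a *planned run* (one 96-well plate), the
plate is prepared and handed to the sequencer (*awaiting results*), and
finally the sequencer output is uploaded and scored (*completed run*).
Every other module manipulates the types defined here; persistence lives in
:mod:`seqfab.store`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterator

from .errors import StateError

PLATE_ROWS = 8
PLATE_COLS = 12
PLATE_SIZE = PLATE_ROWS * PLATE_COLS
ROW_LETTERS = "ABCDEFGH"

#: The four lifecycle stages of facility work, in order.
WORKFLOW_STAGES = (
    "New Order",
    "Planned Run",
    "Awaiting Results Run",
    "Completed Run",
)


class OrderState(str, enum.Enum):
    NEW = "NEW"
    LOCKED = "LOCKED"
    COMPLETED = "COMPLETED"


class RunState(str, enum.Enum):
    PLANNED = "PLANNED"
    AWAITING_RESULTS = "AWAITING_RESULTS"
    COMPLETED = "COMPLETED"


class RunEvent(str, enum.Enum):
    SETUP_SHEET_EXPORTED = "setup_sheet_exported"
    RESULTS_COMPLETED = "results_completed"
    ABANDONED = "abandoned"


class WellKind(str, enum.Enum):
    SAMPLE = "SAMPLE"
    REACTION_CONTROL = "REACTION_CONTROL"
    INSTRUMENT_CONTROL = "INSTRUMENT_CONTROL"


#: Labels printed on sheets for control wells (as shown to operators).
CONTROL_LABELS = {
    WellKind.REACTION_CONTROL: "R.Control",
    WellKind.INSTRUMENT_CONTROL: "I.Control",
}


class ResultStatus(str, enum.Enum):
    OK = "OK"
    FAILED = "FAILED"
    IN_PROCESS = "IN_PROCESS"


class Tag(str, enum.Enum):
    RP = "Rp"  # re-process: re-prepare the reaction from the sample
    RJ = "Rj"  # re-inject: re-run the prepared reaction on the sequencer


class Visibility(str, enum.Enum):
    PRIVATE = "PRIVATE"
    PUBLIC = "PUBLIC"


class Role(str, enum.Enum):
    USER = "USER"
    OPERATOR = "OPERATOR"


class DoseMode(str, enum.Enum):
    FIXED = "FIXED"
    VARIABLE = "VARIABLE"


class PrimerSource(str, enum.Enum):
    CUSTOMER = "customer"
    FACILITY = "facility"


# ---------------------------------------------------------------------------
# entities
# ---------------------------------------------------------------------------


@dataclass
class Sample:
    """One template+primer sequencing request.

    ``sample_ref`` is a globally unique opaque token minted at submission;
    it is what the instrument set-up sheet prints and what sequencer result
    files are matched back by.  ``primer_concentration`` is ``None`` for
    facility-stock primers (e.g. T7, M13F) whose concentration the facility
    controls.
    """

    sample_ref: str
    template_name: str
    primer_name: str
    primer_source: PrimerSource
    template_concentration: float  # ng/uL
    template_volume_supplied: float  # uL
    primer_concentration: float | None  # pmol/uL; None for facility primers
    primer_volume_supplied: float  # uL; 0 for facility primers
    requested_read_length: int  # bases
    sequencing_type: str


@dataclass
class Order:
    order_id: str
    owner: str
    group: str
    samples: list[Sample]
    state: OrderState
    created_at: datetime
    account: str = ""
    #: sample_ref of the failed sample this order was cloned from, if any
    resubmitted_from: str | None = None

    def sample_refs(self) -> list[str]:
        return [s.sample_ref for s in self.samples]


@dataclass
class WellRecipe:
    """Per-well liquid volumes (uL); they sum to the reaction volume."""

    template_volume: float
    primer_volume: float
    mix_volume: float
    water_volume: float

    def total(self) -> float:
        return (
            self.template_volume
            + self.primer_volume
            + self.mix_volume
            + self.water_volume
        )

    def scaled(self, factor: float) -> "WellRecipe":
        return WellRecipe(
            self.template_volume * factor,
            self.primer_volume * factor,
            self.mix_volume * factor,
            self.water_volume * factor,
        )


@dataclass
class WellContent:
    kind: WellKind
    recipe: WellRecipe
    sample_ref: str | None = None  # present iff kind == SAMPLE

    def __post_init__(self) -> None:
        if (self.kind is WellKind.SAMPLE) != (self.sample_ref is not None):
            raise ValueError("sample_ref present iff kind is SAMPLE")

    @property
    def label(self) -> str | None:
        """Display label for control wells, None for sample wells."""
        return CONTROL_LABELS.get(self.kind)


@dataclass
class PlannedRun:
    """One plate (or partial plate) mapping samples and controls to wells."""

    run_name: str
    state: RunState
    wells: dict[str, WellContent]
    order_ids: list[str]
    mode: DoseMode
    plate_rows: int = PLATE_ROWS
    plate_cols: int = PLATE_COLS
    traversal: str = "column"
    warnings: list[str] = field(default_factory=list)

    def sample_refs(self) -> list[str]:
        """Sample refs in well-traversal order."""
        refs = []
        for pos in well_positions(self.traversal):
            content = self.wells.get(pos)
            if content is not None and content.kind is WellKind.SAMPLE:
                refs.append(content.sample_ref)
        return refs

    def occupied_positions(self) -> list[str]:
        """Non-empty well positions in traversal order."""
        return [p for p in well_positions(self.traversal) if p in self.wells]


@dataclass
class Note:
    author: str
    created_at: datetime
    text: str
    visibility: Visibility


@dataclass
class SequencingResult:
    """Per-sample outcome: files, sequence text, scores, status, annotations."""

    sample_ref: str
    sequence_text: str = ""
    attachments: dict[str, bytes] = field(default_factory=dict)
    pct_read: float | None = None
    pct_amb: float | None = None
    status: ResultStatus = ResultStatus.IN_PROCESS
    tags: set[Tag] = field(default_factory=set)
    notes: list[Note] = field(default_factory=list)
    #: True once an operator has overridden the status by hand; a manual
    #: status outranks any subsequent automatic re-scoring.
    manual_status: bool = False


# ---------------------------------------------------------------------------
# well geometry
# ---------------------------------------------------------------------------


def well_positions(traversal: str = "column") -> Iterator[str]:
    """Yield the 96 well positions of a plate in traversal order.

    ``column`` (default): A1, B1, ..., H1, A2, ..., H12 — capillary
    sequencers inject by column groups.  ``row``: A1, A2, ..., A12, B1, ...
    No zero padding ("A1", never "A01").
    """
    if traversal == "column":
        for col in range(1, PLATE_COLS + 1):
            for row in ROW_LETTERS:
                yield f"{row}{col}"
    elif traversal == "row":
        for row in ROW_LETTERS:
            for col in range(1, PLATE_COLS + 1):
                yield f"{row}{col}"
    else:  # pragma: no cover - config validation catches this earlier
        raise ValueError(f"unknown traversal {traversal!r}")


# ---------------------------------------------------------------------------
# naming and state machines
# ---------------------------------------------------------------------------


def next_run_name(series: str, counter: int) -> str:
    """Format a run name from a letter series and a counter, e.g. A726.

    The series letter disambiguates parallel naming sequences (instruments,
    years); the counter is monotone within a series so names sort by age.
    """
    if len(series) != 1 or not series.isalpha() or not series.isupper():
        raise ValueError(f"series must be one uppercase letter, got {series!r}")
    if not isinstance(counter, int) or counter < 0:
        raise ValueError(f"counter must be a non-negative integer, got {counter!r}")
    return f"{series}{counter}"


#: Exhaustive (state, event) -> next-state table for runs.  A value of
#: ``None`` means the run is removed (abandonment).  Any pair absent from
#: this table is an illegal transition and is rejected, never ignored.
RUN_TRANSITIONS: dict[tuple[RunState, RunEvent], RunState | None] = {
    (RunState.PLANNED, RunEvent.SETUP_SHEET_EXPORTED): RunState.AWAITING_RESULTS,
    (RunState.PLANNED, RunEvent.ABANDONED): None,
    (RunState.AWAITING_RESULTS, RunEvent.RESULTS_COMPLETED): RunState.COMPLETED,
}

ORDER_TRANSITIONS: dict[tuple[OrderState, OrderState], bool] = {
    (OrderState.NEW, OrderState.LOCKED): True,  # placed in a planned run
    (OrderState.LOCKED, OrderState.NEW): True,  # plan abandoned
    (OrderState.LOCKED, OrderState.COMPLETED): True,  # run completed
}


def transition(run: PlannedRun, event: RunEvent) -> RunState | None:
    """Advance ``run`` through the state machine for ``event``.

    Returns the new state, or ``None`` when the event removes the run
    (abandonment of a PLANNED run; the caller deletes it from the store).
    Raises :class:`StateError` for any (state, event) pair not in
    :data:`RUN_TRANSITIONS` — there are no silent no-ops.
    """
    key = (run.state, event)
    if key not in RUN_TRANSITIONS:
        raise StateError(
            f"run {run.run_name}: event {event.value!r} is illegal in state "
            f"{run.state.value}"
        )
    new = RUN_TRANSITIONS[key]
    if new is not None:
        run.state = new
    return new


def set_order_state(order: Order, new: OrderState) -> None:
    """Move an order along its lifecycle, rejecting illegal jumps."""
    if not ORDER_TRANSITIONS.get((order.state, new), False):
        raise StateError(
            f"order {order.order_id}: transition {order.state.value} -> "
            f"{new.value} is illegal"
        )
    order.state = new
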