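"""Machine-readable set-up sheets for liquid handlers and the sequencer.

Three robot worklist dialects are supported, reflecting the different deck
layouts of the facility's liquid handlers:

``FIXED_DECK_A``
    Constant template/primer volumes on every row (one time-optimised
    robot program for the whole plate); source tubes addressed by deck
    slot.  Columns: ``well,template_slot,primer_slot,template_vol_ul,
    primer_vol_ul``.  Only valid for runs planned in FIXED mode.
``VARIABLE``
    Per-well volumes with source names.  Columns: ``well,template_name,
    primer_name,template_vol_ul,primer_vol_ul,mix_vol_ul,water_vol_ul``.
``DECK_B``
    The VARIABLE columns reordered for an alternate deck: ``template_name,
    well,template_vol_ul,primer_name,primer_vol_ul,mix_vol_ul,
    water_vol_ul``.

All CSV output is RFC 4180 (CRLF line endings, header row, quoting only
when needed) with volumes printed to 1 decimal place, and is byte-for-byte
deterministic for a given run.  Control wells appear on every sheet under
their control label.  The manual-processing variant is an XLSX spreadsheet
covering all 96 wells (empty wells marked) with volumes scaled by the
configured manual multiplier; operators may edit its volumes, or a
VARIABLE CSV's, and upload the file back to record the alterations.

Exporting the instrument set-up sheet is the moment the facility commits
the plate: the first export moves the run from PLANNED to
AWAITING_RESULTS (a re-export re-emits the sheet without a second
transition).
"""

from __future__ import annotations

import csv
import enum
import io
from pathlib import Path

import openpyxl

from .config import ChemistryConfig
from .errors import SheetError, StateError, ValidationError
from .model import (
    DoseMode,
    PlannedRun,
    RunEvent,
    RunState,
    WellKind,
    WellRecipe,
    well_positions,
    transition,
)
from .store import Amendment, FacilityStore


class Dialect(str, enum.Enum):
    FIXED_DECK_A = "FIXED_DECK_A"
    VARIABLE = "VARIABLE"
    DECK_B = "DECK_B"


#: The supported robot worklist dialects (exactly these three).
SUPPORTED_DIALECTS = frozenset(Dialect)

VARIABLE_COLUMNS = [
    "well", "template_name", "primer_name", "template_vol_ul",
    "primer_vol_ul", "mix_vol_ul", "water_vol_ul",
]
DECK_B_COLUMNS = [
    "template_name", "well", "template_vol_ul", "primer_name",
    "primer_vol_ul", "mix_vol_ul", "water_vol_ul",
]
FIXED_DECK_A_COLUMNS = [
    "well", "template_slot", "primer_slot", "template_vol_ul", "primer_vol_ul",
]
INSTRUMENT_COLUMNS = ["well", "display_name", "run_name", "sample_ref"]
MANUAL_COLUMNS = VARIABLE_COLUMNS + ["notes"]


def _vol(v: float) -> str:
    return f"{v:.1f}"


def _names_for(store: FacilityStore, content) -> tuple[str, str]:
    """(template_name, primer_name) for a well; controls use their label."""
    if content.kind is WellKind.SAMPLE:
        _, sample = store.get_sample(content.sample_ref)
        return sample.template_name, sample.primer_name
    return content.label, content.label


def _csv_text(header: list[str], rows: list[list[str]]) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\r\n")
    writer.writerow(header)
    writer.writerows(rows)
    return buf.getvalue()


def write_robot_sheet(
    store: FacilityStore, run: PlannedRun, dialect: Dialect | str
) -> str:
    """Render a run's worklist CSV in one of the three robot dialects.

    Rows cover the non-empty wells in traversal order.  FIXED_DECK_A
    additionally assigns deck slots (T1, T2, ... / P1, P2, ...) to each
    distinct template and primer in order of first appearance.
    """
    dialect = Dialect(dialect)
    if run.state is not RunState.PLANNED:
        raise StateError(
            f"run {run.run_name} is {run.state.value}; worklists are "
            "exported while PLANNED"
        )
    if dialect is Dialect.FIXED_DECK_A and run.mode is not DoseMode.FIXED:
        raise ValidationError(
            "dialect FIXED_DECK_A requires a run planned in FIXED mode"
        )
    occupied = run.occupied_positions()
    if not any(run.wells[p].kind is WellKind.SAMPLE for p in occupied):
        raise ValidationError(f"run {run.run_name} has no sample wells")

    if dialect is Dialect.FIXED_DECK_A:
        template_slots: dict[str, str] = {}
        primer_slots: dict[str, str] = {}
        rows = []
        for pos in occupied:
            content = run.wells[pos]
            tname, pname = _names_for(store, content)
            tslot = template_slots.setdefault(tname, f"T{len(template_slots) + 1}")
            pslot = primer_slots.setdefault(pname, f"P{len(primer_slots) + 1}")
            r = content.recipe
            rows.append(
                [pos, tslot, pslot, _vol(r.template_volume), _vol(r.primer_volume)]
            )
        return _csv_text(FIXED_DECK_A_COLUMNS, rows)

    rows = []
    for pos in occupied:
        content = run.wells[pos]
        tname, pname = _names_for(store, content)
        r = content.recipe
        fields = {
            "well": pos,
            "template_name": tname,
            "primer_name": pname,
            "template_vol_ul": _vol(r.template_volume),
            "primer_vol_ul": _vol(r.primer_volume),
            "mix_vol_ul": _vol(r.mix_volume),
            "water_vol_ul": _vol(r.water_volume),
        }
        columns = (
            VARIABLE_COLUMNS if dialect is Dialect.VARIABLE else DECK_B_COLUMNS
        )
        rows.append([fields[c] for c in columns])
    header = VARIABLE_COLUMNS if dialect is Dialect.VARIABLE else DECK_B_COLUMNS
    return _csv_text(header, rows)


def write_manual_sheet(
    store: FacilityStore, run: PlannedRun, config: ChemistryConfig
) -> openpyxl.Workbook:
    """Plate map spreadsheet for manual pipetting (all 96 wells).

    One worksheet named after the run; empty wells are marked so the
    bench sheet shows the whole plate.  Volumes are multiplied by the
    manual-mode multiplier (manual pipetting typically uses larger
    volumes than the robots).
    """
    if run.state is not RunState.PLANNED:
        raise StateError(
            f"run {run.run_name} is {run.state.value}; manual sheets are "
            "exported while PLANNED"
        )
    wb = openpyxl.Workbook()
    ws = wb.active
    ws.title = run.run_name
    ws.append(MANUAL_COLUMNS)
    m = config.manual_volume_multiplier
    for pos in well_positions(run.traversal):
        content = run.wells.get(pos)
        if content is None:
            ws.append([pos, "EMPTY", "", None, None, None, None, ""])
            continue
        tname, pname = _names_for(store, content)
        r = content.recipe.scaled(m)
        ws.append([
            pos, tname, pname,
            round(r.template_volume, 3), round(r.primer_volume, 3),
            round(r.mix_volume, 3), round(r.water_volume, 3), "",
        ])
    return wb


def write_instrument_sheet(store: FacilityStore, run: PlannedRun) -> str:
    """Sequencer set-up sheet; first export commits the run.

    One row per non-empty well: the display name (``template_primer`` for
    samples, the control label for controls), the run name, and the
    sample reference (blank for controls).  Display names need not be
    unique — the sample reference is the stable key results link back by.
    """
    if run.state is RunState.COMPLETED:
        raise StateError(
            f"run {run.run_name} is COMPLETED; its set-up sheet is final"
        )
    rows = []
    for pos in run.occupied_positions():
        content = run.wells[pos]
        if content.kind is WellKind.SAMPLE:
            _, sample = store.get_sample(content.sample_ref)
            display = f"{sample.template_name}_{sample.primer_name}"
            ref = content.sample_ref
        else:
            display = content.label
            ref = ""
        rows.append([pos, display, run.run_name, ref])
    text = _csv_text(INSTRUMENT_COLUMNS, rows)
    if run.state is RunState.PLANNED:
        transition(run, RunEvent.SETUP_SHEET_EXPORTED)
        store.append_event(
            "setup_sheet_exported", "operator", {"run_name": run.run_name}
        )
    return text


# ---------------------------------------------------------------------------
# amended-volume upload
# ---------------------------------------------------------------------------

_VOLUME_FIELDS = [
    ("template_vol_ul", "template_volume"),
    ("primer_vol_ul", "primer_volume"),
    ("mix_vol_ul", "mix_volume"),
    ("water_vol_ul", "water_volume"),
]


def _parse_variable_csv(text: str) -> dict[str, dict[str, object]]:
    reader = csv.reader(io.StringIO(text))
    try:
        header = next(reader)
    except StopIteration:
        raise SheetError("empty sheet") from None
    if header != VARIABLE_COLUMNS:
        raise SheetError(
            "sheet does not match run: expected the VARIABLE worklist columns"
        )
    wells: dict[str, dict[str, object]] = {}
    for i, row in enumerate(reader, start=2):
        if not row:
            continue
        entry = dict(zip(header, row))
        parsed: dict[str, object] = {
            "template_name": entry["template_name"],
            "primer_name": entry["primer_name"],
        }
        for col, attr in _VOLUME_FIELDS:
            try:
                parsed[attr] = float(entry[col])
            except (KeyError, ValueError):
                raise SheetError(
                    f"row {i}: unparseable volume in column {col}"
                ) from None
        wells[entry["well"]] = parsed
    return wells


def _parse_manual_xlsx(
    path: str | Path, multiplier: float
) -> tuple[str, dict[str, dict[str, object]]]:
    wb = openpyxl.load_workbook(path, data_only=True)
    ws = wb.active
    run_name = ws.title
    rows = ws.iter_rows(values_only=True)
    header = [str(c) for c in next(rows)]
    if header[: len(MANUAL_COLUMNS)] != MANUAL_COLUMNS:
        raise SheetError("sheet does not match run: manual columns expected")
    wells: dict[str, dict[str, object]] = {}
    for i, row in enumerate(rows, start=2):
        if row is None or row[0] is None:
            continue
        well = str(row[0])
        entry = dict(zip(header, row))
        if entry.get("template_name") == "EMPTY":
            continue
        parsed: dict[str, object] = {
            "template_name": entry.get("template_name"),
            "primer_name": entry.get("primer_name"),
        }
        for col, attr in _VOLUME_FIELDS:
            value = entry.get(col)
            try:
                parsed[attr] = float(value) / multiplier
            except (TypeError, ValueError, ZeroDivisionError):
                raise SheetError(
                    f"row {i}: unparseable volume in column {col}"
                ) from None
        wells[well] = parsed
    return run_name, wells


def load_amended_volumes(
    store: FacilityStore,
    run: PlannedRun,
    document: str | Path,
    config: ChemistryConfig,
    operator: str = "operator",
) -> tuple[list[Amendment], list[str]]:
    """Re-absorb an operator-edited volume sheet into a PLANNED run.

    Accepts the VARIABLE worklist CSV or the manual XLSX (whose volumes
    are de-scaled by the manual multiplier).  The document must describe
    exactly this run: the manual sheet's worksheet name must equal the
    run name, and every sheet's well set and per-well template/primer
    names must match the plan.  Each changed volume is applied and logged
    as an :class:`Amendment` (well, field, old, new, operator, time).
    Closure violations — a well no longer summing to the reaction volume
    — are returned as warnings, not rejected: the operator's judgement
    overrides the standard chemistry.
    """
    if run.state is not RunState.PLANNED:
        raise StateError(
            f"run {run.run_name} is {run.state.value}; volumes can only be "
            "amended while PLANNED"
        )
    document = Path(document)
    if document.suffix.lower() in (".xlsx", ".xlsm"):
        sheet_run, wells = _parse_manual_xlsx(
            document, config.manual_volume_multiplier
        )
        if sheet_run != run.run_name:
            raise SheetError(
                f"sheet does not match run: worksheet {sheet_run!r} vs run "
                f"{run.run_name!r}"
            )
    else:
        wells = _parse_variable_csv(document.read_text(encoding="utf-8"))

    expected = set(run.occupied_positions())
    if set(wells) != expected:
        raise SheetError(
            "sheet does not match run: well sets differ "
            f"(sheet has {len(wells)}, run has {len(expected)})"
        )
    for pos, parsed in wells.items():
        content = run.wells[pos]
        tname, pname = _names_for(store, content)
        if parsed["template_name"] != tname or parsed["primer_name"] != pname:
            raise SheetError(
                f"sheet does not match run: well {pos} names differ"
            )

    amendments: list[Amendment] = []
    warnings: list[str] = []
    for pos in run.occupied_positions():
        content = run.wells[pos]
        r = content.recipe
        for _, attr in _VOLUME_FIELDS:
            old = getattr(r, attr)
            new = float(wells[pos][attr])
            if abs(new - old) > 1e-6:
                amendments.append(
                    Amendment(
                        run_name=run.run_name,
                        well=pos,
                        field=attr,
                        old=old,
                        new=new,
                        operator=operator,
                        timestamp=store.now(),
                    )
                )
                setattr(r, attr, new)
        if abs(r.total() - config.total_reaction_volume) > 0.01:
            warnings.append(
                f"well {pos}: volumes sum to {r.total():.2f} uL, not "
                f"{config.total_reaction_volume:.2f} uL (operator override)"
            )
    if amendments:
        store.amendments.extend(amendments)
        store.append_event(
            "volumes_amended",
            operator,
            {
                "run_name": run.run_name,
                "n_changes": len(amendments),
                "wells": sorted({a.well for a in amendments}),
            },
        )
    return amendments, warnings
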