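"""Sequencer results: ingestion, scoring, trimming, annotation, delivery.

The sequencer produces a set of files per sample (a plain-text ``.seq``
with the base calls plus opaque ``.ab1``/``.scf`` chromatogram files);
operators upload them as one ZIP archive.  Each member file is linked back
to its sample by the unique sample reference embedded in the file name,
the sequence text is scored, and the sample is rated OK (readable length
meets the requested read length) or FAILED.  Customers retrieve their
sequences as FASTA (plain or end-trimmed) or as a ZIP of everything,
with failed samples' files hidden from them.

Scoring uses only the sequence text.  The *readable* length of a read is
its length after chopping the unresolved (ambiguous) runs off both ends;
``% Read`` is readable length over requested length (uncapped — more
sequence than asked for is informative), and ``% Amb`` is the fraction of
ambiguous letters over the raw upload.  An ambiguous letter is any IUPAC
code other than A, C, G, T (U is treated as unambiguous so RNA text is
not mangled); case is irrelevant to scoring and preserved by trimming.
"""

from __future__ import annotations

import dataclasses
import enum
import io
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AuthorizationError,
    SeqFabError,
    SheetError,
    StateError,
    ValidationError,
)
from .model import (
    Note,
    Order,
    OrderState,
    PlannedRun,
    ResultStatus,
    RunEvent,
    RunState,
    Tag,
    Visibility,
    transition,
)
from .store import FacilityStore, Principal

UNAMBIGUOUS = frozenset("ACGTUacgtu")

#: Fixed member date for deterministic ZIP output (ZIP epoch).
_ZIP_DATE = (1980, 1, 1, 0, 0, 0)


def is_ambiguous(letter: str) -> bool:
    return letter not in UNAMBIGUOUS


def trim_sequence(seq: str) -> str:
    """Chop unresolved runs off both ends of a sequence.

    Removes the longest prefix and suffix consisting solely of ambiguity
    codes; interior ambiguity is untouched and case is preserved.
    """
    start = 0
    end = len(seq)
    while start < end and is_ambiguous(seq[start]):
        start += 1
    while end > start and is_ambiguous(seq[end - 1]):
        end -= 1
    return seq[start:end]


class Score(NamedTuple):
    pct_read: float
    pct_amb: float
    status: ResultStatus


def score_result(seq: str, requested_read_length: int) -> Score:
    """Rate one read against the customer's requested read length.

    ``pct_read`` = 100 x readable/requested (readable = post-trim length),
    deliberately uncapped; ``pct_amb`` = 100 x ambiguous letters / raw
    length (0 for an empty read).  Status is OK exactly when the readable
    sequence is at least as long as requested.
    """
    if requested_read_length <= 0:
        raise ValidationError("requested read length must be positive")
    readable = len(trim_sequence(seq))
    pct_read = 100.0 * readable / requested_read_length
    pct_amb = (
        100.0 * sum(1 for c in seq if is_ambiguous(c)) / len(seq) if seq else 0.0
    )
    status = (
        ResultStatus.OK if readable >= requested_read_length else ResultStatus.FAILED
    )
    return Score(pct_read, pct_amb, status)


@dataclass
class LinkageReport:
    """Outcome of one archive ingest: who got files, who is still waiting."""

    matched: dict[str, list[str]] = field(default_factory=dict)
    unmatched_files: list[str] = field(default_factory=list)
    samples_without_results: list[str] = field(default_factory=list)


def _parse_seq_member(data: bytes) -> str:
    """Extract sequence text from a .seq member (plain text or 1-record FASTA)."""
    text = data.decode("utf-8", errors="replace").strip()
    if text.startswith(">"):
        lines = [ln.strip() for ln in text.splitlines()[1:]]
        return "".join(lines)
    return "".join(text.split())


def _name_tokens(stem: str) -> set[str]:
    out, token = set(), []
    for ch in stem:
        if ch.isalnum():
            token.append(ch)
        else:
            if token:
                out.add("".join(token))
            token = []
    if token:
        out.add("".join(token))
    return out


def ingest_results_zip(
    store: FacilityStore,
    run: PlannedRun,
    archive: str | Path | bytes,
    use_name_fallback: bool = False,
) -> LinkageReport:
    """Attach an archive of sequencer output files to a run's samples.

    A member matches a sample when its base name contains the sample's
    reference as an exact token (the sequencer output convention is
    ``<sample_ref>.<ext>``).  ``.seq`` members supply the sequence text
    and trigger automatic scoring — unless an operator has already set
    the status by hand, which always wins.  Repeated ingestion merges:
    later files overwrite earlier files of the same name.  Unmatched
    members are reported, never fatal.

    The optional fallback matcher on ``templateName_primerName`` is off by
    default: display names need not be unique, so it only fires when the
    name maps to exactly one sample in the run.
    """
    if run.state is not RunState.AWAITING_RESULTS:
        raise StateError(
            f"run {run.run_name} is {run.state.value}; results can only be "
            "ingested while AWAITING_RESULTS"
        )
    if isinstance(archive, (str, Path)):
        data = Path(archive).read_bytes()
    else:
        data = archive
    try:
        zf = zipfile.ZipFile(io.BytesIO(data))
    except zipfile.BadZipFile as exc:
        raise SheetError(f"corrupt archive: {exc}") from exc

    refs = run.sample_refs()
    by_name: dict[str, list[str]] = {}
    if use_name_fallback:
        for ref in refs:
            _, sample = store.get_sample(ref)
            by_name.setdefault(
                f"{sample.template_name}_{sample.primer_name}", []
            ).append(ref)

    report = LinkageReport()
    with zf:
        for info in zf.infolist():
            if info.is_dir():
                continue
            base = Path(info.filename).name
            stem = Path(base).stem
            tokens = _name_tokens(stem)
            target = next((r for r in refs if r in tokens), None)
            if target is None and use_name_fallback:
                candidates = by_name.get(stem, [])
                if len(candidates) == 1:
                    target = candidates[0]
            if target is None:
                report.unmatched_files.append(base)
                continue
            result = store.result_for(target, create=True)
            result.attachments[base] = zf.read(info)
            if base.lower().endswith(".seq"):
                _, sample = store.get_sample(target)
                result.sequence_text = _parse_seq_member(result.attachments[base])
                score = score_result(
                    result.sequence_text, sample.requested_read_length
                )
                result.pct_read = score.pct_read
                result.pct_amb = score.pct_amb
                if not result.manual_status:
                    result.status = score.status
            report.matched.setdefault(target, []).append(base)

    for ref in refs:
        result = store.results.get(ref)
        if ref not in report.matched and (result is None or not result.attachments):
            report.samples_without_results.append(ref)
        elif ref not in report.matched:
            # matched in an earlier ingest; count it as matched overall
            report.matched[ref] = sorted(result.attachments)
    store.append_event(
        "results_ingested",
        "operator",
        {
            "run_name": run.run_name,
            "matched": sorted(report.matched),
            "unmatched_files": sorted(report.unmatched_files),
            "samples_without_results": sorted(report.samples_without_results),
        },
    )
    return report


def set_status(
    store: FacilityStore,
    sample_ref: str,
    status: ResultStatus,
    operator: Principal,
) -> None:
    """Operator override of the automatic rating; manual status wins."""
    if not operator.is_operator:
        raise AuthorizationError("only operators may override a result status")
    result = store.result_for(sample_ref)
    old = result.status
    result.status = status
    result.manual_status = True
    if status is not ResultStatus.FAILED:
        result.tags.clear()  # tags only mark failed samples
    store.append_event(
        "status_overridden",
        operator.user_id,
        {"sample_ref": sample_ref, "old": old.value, "new": status.value},
    )


def tag_sample(
    store: FacilityStore, sample_ref: str, tag: Tag, operator: Principal
) -> None:
    """Mark a FAILED sample for re-processing (Rp) or re-injection (Rj)."""
    if not operator.is_operator:
        raise AuthorizationError("only operators may tag samples")
    result = store.result_for(sample_ref)
    if result.status is not ResultStatus.FAILED:
        raise ValidationError(
            f"sample {sample_ref} is {result.status.value}; only FAILED "
            "samples can be tagged"
        )
    result.tags.add(tag)  # idempotent
    store.append_event(
        "sample_tagged", operator.user_id,
        {"sample_ref": sample_ref, "tag": tag.value},
    )


def add_note(
    store: FacilityStore,
    sample_ref: str,
    text: str,
    author: Principal,
    visibility: Visibility = Visibility.PUBLIC,
) -> Note:
    """Attach a timestamped note; PRIVATE notes are operator-only."""
    if not text.strip():
        raise ValidationError("note text must be non-empty")
    result = store.result_for(sample_ref, create=True)
    note = Note(
        author=author.user_id,
        created_at=store.now(),
        text=text,
        visibility=visibility,
    )
    result.notes.append(note)
    store.append_event(
        "note_added", author.user_id,
        {"sample_ref": sample_ref, "visibility": visibility.value},
    )
    return note


def complete_run(
    store: FacilityStore,
    run: PlannedRun,
    force: bool = False,
    actor: str = "operator",
) -> None:
    """Close out an AWAITING_RESULTS run and notify affected customers.

    Requires every sample to be scored unless ``force`` is passed (the
    forced samples stay IN_PROCESS).  Each member order whose samples are
    now all resolved becomes COMPLETED and gets one ``order_completed``
    event carrying a retrieval locator — the e-mail surrogate.
    """
    if run.state is not RunState.AWAITING_RESULTS:
        raise StateError(
            f"run {run.run_name} is {run.state.value}; only an "
            "AWAITING_RESULTS run can be completed"
        )
    in_process = [
        ref
        for ref in run.sample_refs()
        if store.result_for(ref, create=True).status is ResultStatus.IN_PROCESS
    ]
    if in_process and not force:
        raise StateError(
            "run has unscored samples (pass force to complete anyway): "
            + ", ".join(in_process)
        )
    transition(run, RunEvent.RESULTS_COMPLETED)
    for order_id in run.order_ids:
        order = store.get_order(order_id)
        if order.state is not OrderState.LOCKED:
            continue
        resolved = all(
            store.result_for(ref, create=True).status
            is not ResultStatus.IN_PROCESS
            for ref in order.sample_refs()
        )
        runs_done = all(
            r.state is RunState.COMPLETED
            for r in store.runs_containing(order_id)
        )
        if resolved and runs_done:
            store.set_order_state(order, OrderState.COMPLETED)
            store.append_event(
                "order_completed",
                actor,
                {
                    "order_id": order_id,
                    "owner": order.owner,
                    "locator": f"seqfab://orders/{order_id}",
                },
            )
    store.append_event(
        "run_completed", actor,
        {"run_name": run.run_name, "forced_in_process": in_process},
    )


class TrafficLight(str, enum.Enum):
    GREEN = "GREEN"
    YELLOW = "YELLOW"
    RED = "RED"


def order_traffic_light(store: FacilityStore, order: Order) -> TrafficLight:
    """Upload summary for an order in a run: all/some/no results uploaded.

    Green means every sample has a result uploaded (regardless of whether
    it passed), red none, yellow anything in between.
    """
    if order.state is OrderState.NEW:
        raise StateError(
            f"order {order.order_id} is not in a run yet; no upload status"
        )
    uploaded = [
        ref
        for ref in order.sample_refs()
        if ref in store.results
        and store.results[ref].status is not ResultStatus.IN_PROCESS
    ]
    if len(uploaded) == len(order.samples):
        return TrafficLight.GREEN
    if not uploaded:
        return TrafficLight.RED
    return TrafficLight.YELLOW


def _check_export_access(
    store: FacilityStore, order: Order, viewer: Principal
) -> None:
    if viewer.is_operator:
        return
    if not store.visible(viewer, order):
        raise AuthorizationError(
            f"{viewer.user_id} has no access to order {order.order_id}"
        )
    if order.state is not OrderState.COMPLETED:
        raise AuthorizationError(
            f"order {order.order_id} is not completed yet"
        )


def _exportable_samples(
    store: FacilityStore, order: Order, viewer: Principal
) -> list[str]:
    """Sample refs the viewer may download; users never see FAILED samples."""
    out = []
    for ref in order.sample_refs():
        result = store.results.get(ref)
        if result is None:
            continue
        if not viewer.is_operator and result.status is ResultStatus.FAILED:
            continue
        out.append(ref)
    return out


def export_fasta(
    store: FacilityStore,
    order: Order,
    viewer: Principal,
    variant: str = "plain",
) -> str:
    """All of an order's sequences as FASTA (wrapped at 60 columns).

    The ``trimmed`` variant chops the unresolved runs off both ends of
    every record.  Record headers are ``sample_ref template_primer``.
    Samples with no sequence yet are skipped; FAILED samples are omitted
    for non-operator viewers.
    """
    if variant not in ("plain", "trimmed"):
        raise ValidationError(f"unknown FASTA variant {variant!r}")
    _check_export_access(store, order, viewer)
    records = []
    for ref in _exportable_samples(store, order, viewer):
        result = store.results[ref]
        seq = result.sequence_text
        if variant == "trimmed":
            seq = trim_sequence(seq)
        if not seq:
            continue
        _, sample = store.get_sample(ref)
        records.append(
            SeqRecord(
                Seq(seq),
                id=ref,
                description=f"{sample.template_name}_{sample.primer_name}",
            )
        )
    buf = io.StringIO()
    SeqIO.write(records, buf, "fasta")
    return buf.getvalue()


def export_archive(
    store: FacilityStore, order: Order, viewer: Principal
) -> bytes:
    """ZIP of every visible result file plus the plain FASTA for the order."""
    _check_export_access(store, order, viewer)
    members: dict[str, bytes] = {}
    for ref in _exportable_samples(store, order, viewer):
        for name, data in store.results[ref].attachments.items():
            members[name] = data
    if not members:
        raise ValidationError(
            f"nothing to export for order {order.order_id}"
        )
    members[f"{order.order_id}.fasta"] = export_fasta(
        store, order, viewer, "plain"
    ).encode()
    buf = io.BytesIO()
    with zipfile.ZipFile(buf, "w", zipfile.ZIP_DEFLATED) as zf:
        for name in sorted(members):
            info = zipfile.ZipInfo(name, date_time=_ZIP_DATE)
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, members[name])
    return buf.getvalue()


def resubmit_failed(
    store: FacilityStore, sample_ref: str, actor: Principal
) -> Order:
    """Clone a FAILED sample into a fresh one-sample order, no re-typing.

    The clone carries every user-entered field of the original, a fresh
    sample reference, and a provenance link back to the failed sample.
    """
    result = store.result_for(sample_ref)
    if result.status is not ResultStatus.FAILED:
        raise ValidationError(
            f"sample {sample_ref} is {result.status.value}; only FAILED "
            "samples can be resubmitted"
        )
    original_order, original = store.get_sample(sample_ref)
    if not actor.is_operator and actor.user_id != original_order.owner:
        raise AuthorizationError(
            f"{actor.user_id} may not resubmit samples from order "
            f"{original_order.order_id}"
        )
    clone = dataclasses.replace(original, sample_ref=store.next_sample_ref())
    order = Order(
        order_id=store.next_order_id(),
        owner=original_order.owner,
        group=original_order.group,
        samples=[clone],
        state=OrderState.NEW,
        created_at=store.now(),
        account=original_order.account,
        resubmitted_from=sample_ref,
    )
    store.add_order(order)
    store.append_event(
        "sample_resubmitted",
        actor.user_id,
        {
            "original_sample_ref": sample_ref,
            "new_order_id": order.order_id,
            "new_sample_ref": clone.sample_ref,
        },
    )
    return order
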