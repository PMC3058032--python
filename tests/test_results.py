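"""Ingestion, scoring/trimming, annotation, completion and exports."""

import io
import zipfile

import pytest
from hypothesis import given, settings, strategies as st

from conftest import facility_record, valid_record
from helpers import build_golden_store
from seqfab.errors import AuthorizationError, SheetError, StateError, \
    ValidationError
from seqfab.model import (
    DoseMode,
    OrderState,
    ResultStatus,
    RunState,
    Tag,
    Visibility,
)
from seqfab.results import (
    TrafficLight,
    add_note,
    complete_run,
    export_archive,
    export_fasta,
    ingest_results_zip,
    order_traffic_light,
    resubmit_failed,
    score_result,
    set_status,
    tag_sample,
    trim_sequence,
)
from seqfab.robot_io import write_instrument_sheet

IUPAC = "ACGTUacgtuNRYSWKMBDHVnryswkmbdhv"


def brute_trim(seq: str) -> str:
    """Independent character-by-character oracle for end-trimming."""
    ok = set("ACGTU")
    i = 0
    while i < len(seq) and seq[i].upper() not in ok:
        i += 1
    j = len(seq)
    while j > i and seq[j - 1].upper() not in ok:
        j -= 1
    return seq[i:j]


class TestTrim:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("NNNACGTNN", "ACGT"),
            ("ACGT", "ACGT"),
            ("ACNNGT", "ACNNGT"),  # interior ambiguity preserved
            ("NNNN", ""),
            ("", ""),
            ("nnnacgtNNN", "acgt"),  # case preserved
            ("RYacguWS", "acgu"),  # U is unambiguous (RNA-safe)
        ],
    )
    def test_examples(self, seq, expected):
        assert trim_sequence(seq) == expected

    @settings(derandomize=True, max_examples=200)
    @given(st.text(alphabet=IUPAC, max_size=80))
    def test_matches_brute_force_and_is_idempotent(self, seq):
        trimmed = trim_sequence(seq)
        assert trimmed == brute_trim(seq)
        assert trim_sequence(trimmed) == trimmed
        assert trimmed in seq  # substring of the input
        # removed letters are exactly the terminal ambiguity runs
        removed = len(seq) - len(trimmed)
        assert removed >= 0


class TestScore:
    def test_long_clean_read_overshoots_100_percent(self):
        score = score_result("A" * 800, 700)
        assert score.pct_read == pytest.approx(114.2857, abs=0.001)
        assert score.pct_amb == 0.0
        assert score.status is ResultStatus.OK

    def test_empty_read_fails_with_zero_percent(self):
        score = score_result("", 500)
        assert (score.pct_read, score.pct_amb) == (0.0, 0.0)
        assert score.status is ResultStatus.FAILED

    def test_ambiguity_is_counted_on_the_raw_sequence(self):
        # 14 letters, 6 ambiguous; readable middle is 8 -> exactly on target
        score = score_result("NNNACGTACGTNNN", 8)
        assert score.pct_read == pytest.approx(100.0)
        assert score.pct_amb == pytest.approx(100 * 6 / 14, abs=0.01)
        assert score.status is ResultStatus.OK

    def test_requested_length_must_be_positive(self):
        with pytest.raises(ValidationError):
            score_result("ACGT", 0)

    @settings(derandomize=True, max_examples=200)
    @given(st.text(alphabet=IUPAC, max_size=60),
           st.integers(1, 100))
    def test_ok_exactly_when_pct_read_reaches_100(self, seq, requested):
        score = score_result(seq, requested)
        assert (score.status is ResultStatus.OK) == (score.pct_read >= 100.0)


def make_archive(members: dict[str, bytes]) -> bytes:
    buf = io.BytesIO()
    with zipfile.ZipFile(buf, "w") as zf:
        for name, data in members.items():
            zf.writestr(name, data)
    return buf.getvalue()


@pytest.fixture
def awaiting_run():
    store, run, chemistry, limits = build_golden_store(DoseMode.VARIABLE)
    write_instrument_sheet(store, run)  # -> AWAITING_RESULTS
    operator = store.get_principal("op")
    alice = store.get_principal("alice")
    return store, run, operator, alice


def full_archive(store, run, length=800):
    members = {}
    for ref in run.sample_refs():
        members[f"{ref}.seq"] = ("A" * length).encode()
        members[f"{ref}.ab1"] = b"FIXTURE-AB1 blob"
    return make_archive(members)


class TestIngest:
    def test_complete_upload_scores_every_sample(self, awaiting_run):
        store, run, *_ = awaiting_run
        report = ingest_results_zip(store, run, full_archive(store, run))
        assert len(report.matched) == 3
        assert report.unmatched_files == []
        assert report.samples_without_results == []
        for ref in run.sample_refs():
            assert store.results[ref].status in (ResultStatus.OK,
                                                 ResultStatus.FAILED)

    def test_partial_upload_leaves_the_rest_in_process(self, awaiting_run):
        store, run, *_ = awaiting_run
        refs = run.sample_refs()
        members = {f"{refs[0]}.seq": b"ACGT" * 200}
        report = ingest_results_zip(store, run, make_archive(members))
        assert list(report.matched) == [refs[0]]
        assert set(report.samples_without_results) == set(refs[1:])
        for ref in refs[1:]:
            assert store.results[ref].status is ResultStatus.IN_PROCESS

    def test_unmatched_member_is_reported_not_fatal(self, awaiting_run):
        store, run, *_ = awaiting_run
        archive = make_archive({"misc_readme.txt": b"hello"})
        report = ingest_results_zip(store, run, archive)
        assert report.unmatched_files == ["misc_readme.txt"]

    def test_fasta_formatted_seq_member_is_accepted(self, awaiting_run):
        store, run, *_ = awaiting_run
        ref = run.sample_refs()[0]
        fasta = f">{ref} some description\nACGTACGT\nACGTACGT\n".encode()
        ingest_results_zip(store, run, make_archive({f"{ref}.seq": fasta}))
        assert store.results[ref].sequence_text == "ACGTACGT" * 2

    def test_reingestion_merges_and_overwrites_same_names(self, awaiting_run):
        store, run, *_ = awaiting_run
        ref = run.sample_refs()[0]
        ingest_results_zip(store, run,
                           make_archive({f"{ref}.seq": b"ACGT"}))
        ingest_results_zip(store, run,
                           make_archive({f"{ref}.seq": b"GGGG" * 300}))
        assert store.results[ref].sequence_text == "GGGG" * 300
        assert store.results[ref].status is ResultStatus.OK

    def test_planned_run_rejects_ingestion(self):
        store, run, chemistry, _ = build_golden_store(DoseMode.VARIABLE)
        assert run.state is RunState.PLANNED
        with pytest.raises(StateError):
            ingest_results_zip(store, run, make_archive({}))

    def test_corrupt_archive_is_rejected(self, awaiting_run):
        store, run, *_ = awaiting_run
        with pytest.raises(SheetError, match="corrupt"):
            ingest_results_zip(store, run, b"this is not a zip")

    def test_matched_and_missing_partition_the_run(self, awaiting_run):
        store, run, *_ = awaiting_run
        refs = run.sample_refs()
        members = {f"{refs[1]}.ab1": b"FIXTURE-AB1"}
        report = ingest_results_zip(store, run, make_archive(members))
        assert sorted(
            list(report.matched) + report.samples_without_results
        ) == sorted(refs)
        assert not set(report.matched) & set(report.samples_without_results)


class TestStatusTagsNotes:
    def test_operator_override_hides_files_from_the_owner(self, awaiting_run):
        store, run, operator, alice = awaiting_run
        ingest_results_zip(store, run, full_archive(store, run))
        ref = run.sample_refs()[0]
        assert store.visible_files(alice, ref)  # OK -> visible
        set_status(store, ref, ResultStatus.FAILED, operator)
        assert store.visible_files(alice, ref) == {}
        assert store.visible_files(operator, ref)  # preserved for operators

    def test_user_cannot_override_status(self, awaiting_run):
        store, run, _, alice = awaiting_run
        ingest_results_zip(store, run, full_archive(store, run))
        with pytest.raises(AuthorizationError):
            set_status(store, run.sample_refs()[0], ResultStatus.FAILED, alice)

    def test_manual_status_survives_reingestion(self, awaiting_run):
        store, run, operator, _ = awaiting_run
        ingest_results_zip(store, run, full_archive(store, run))
        ref = run.sample_refs()[0]
        set_status(store, ref, ResultStatus.FAILED, operator)
        ingest_results_zip(store, run, full_archive(store, run))
        assert store.results[ref].status is ResultStatus.FAILED  # manual wins

    def test_tags_require_a_failed_sample_and_are_idempotent(
        self, awaiting_run
    ):
        store, run, operator, _ = awaiting_run
        ingest_results_zip(store, run, full_archive(store, run))
        ref = run.sample_refs()[0]
        with pytest.raises(ValidationError):
            tag_sample(store, ref, Tag.RP, operator)  # OK sample
        set_status(store, ref, ResultStatus.FAILED, operator)
        tag_sample(store, ref, Tag.RJ, operator)
        tag_sample(store, ref, Tag.RJ, operator)
        assert store.results[ref].tags == {Tag.RJ}

    def test_private_notes_are_hidden_from_users(self, awaiting_run):
        store, run, operator, alice = awaiting_run
        ref = run.sample_refs()[0]
        add_note(store, ref, "re-ran column 3", operator, Visibility.PRIVATE)
        add_note(store, ref, "looks good", operator, Visibility.PUBLIC)
        assert [n.text for n in store.visible_notes(alice, ref)] == [
            "looks good"
        ]
        assert len(store.visible_notes(operator, ref)) == 2

    def test_notes_keep_creation_order_and_authorship(self, awaiting_run):
        store, run, operator, _ = awaiting_run
        ref = run.sample_refs()[0]
        n1 = add_note(store, ref, "first", operator)
        n2 = add_note(store, ref, "second", operator)
        assert store.results[ref].notes == [n1, n2]
        assert n1.created_at <= n2.created_at

    def test_empty_note_is_rejected(self, awaiting_run):
        store, run, operator, _ = awaiting_run
        with pytest.raises(ValidationError):
            add_note(store, run.sample_refs()[0], "   ", operator)


class TestCompleteRun:
    def test_scored_run_completes_and_notifies_each_order(self, awaiting_run):
        store, run, *_ = awaiting_run
        ingest_results_zip(store, run, full_archive(store, run))
        complete_run(store, run)
        assert run.state is RunState.COMPLETED
        completed = [e for e in store.events if e.kind == "order_completed"]
        assert {e.payload["order_id"] for e in completed} == set(run.order_ids)
        assert all("locator" in e.payload for e in completed)
        for oid in run.order_ids:
            assert store.get_order(oid).state is OrderState.COMPLETED

    def test_unscored_samples_block_completion_and_are_listed(
        self, awaiting_run
    ):
        store, run, *_ = awaiting_run
        refs = run.sample_refs()
        ingest_results_zip(
            store, run, make_archive({f"{refs[0]}.seq": b"ACGT" * 200})
        )
        with pytest.raises(StateError) as err:
            complete_run(store, run)
        assert refs[1] in str(err.value)

    def test_force_completes_but_leaves_samples_in_process(self, awaiting_run):
        store, run, *_ = awaiting_run
        refs = run.sample_refs()
        ingest_results_zip(
            store, run, make_archive({f"{refs[0]}.seq": b"ACGT" * 200})
        )
        complete_run(store, run, force=True)
        assert run.state is RunState.COMPLETED
        for ref in refs[1:]:
            assert store.results[ref].status is ResultStatus.IN_PROCESS


class TestTrafficLight:
    @pytest.mark.parametrize("n_uploaded,expected", [
        (3, TrafficLight.GREEN), (0, TrafficLight.RED),
        (1, TrafficLight.YELLOW), (2, TrafficLight.YELLOW),
    ])
    def test_all_some_none_rule(self, n_uploaded, expected):
        store, run, chemistry, _ = build_golden_store(DoseMode.VARIABLE)
        write_instrument_sheet(store, run)
        refs = run.sample_refs()
        members = {f"{r}.seq": b"ACGT" for r in refs[:n_uploaded]}
        if members:
            ingest_results_zip(store, run, make_archive(members))
        order = store.get_order(run.order_ids[0])  # holds refs[0] and refs[1]
        own = order.sample_refs()
        uploaded_here = len(set(own) & set(refs[:n_uploaded]))
        want = (TrafficLight.GREEN if uploaded_here == len(own)
                else TrafficLight.RED if uploaded_here == 0
                else TrafficLight.YELLOW)
        assert order_traffic_light(store, order) is want

    def test_failed_uploads_still_count_as_uploaded(self):
        # green measures upload completeness, not sequencing success
        store, run, chemistry, _ = build_golden_store(DoseMode.VARIABLE)
        write_instrument_sheet(store, run)
        members = {f"{r}.seq": b"NN" for r in run.sample_refs()}
        ingest_results_zip(store, run, make_archive(members))
        for oid in run.order_ids:
            order = store.get_order(oid)
            assert order_traffic_light(store, order) is TrafficLight.GREEN
            assert all(
                store.results[r].status is ResultStatus.FAILED
                for r in order.sample_refs()
            )


class TestExports:
    def _completed(self, length_by_index=None):
        store, run, chemistry, _ = build_golden_store(DoseMode.VARIABLE)
        write_instrument_sheet(store, run)
        refs = run.sample_refs()
        members = {}
        for i, ref in enumerate(refs):
            seq = "NN" + "ACGT" * 250 + "N"  # OK at 700 requested
            if length_by_index and i in length_by_index:
                seq = length_by_index[i]
            members[f"{ref}.seq"] = seq.encode()
            members[f"{ref}.ab1"] = b"FIXTURE-AB1x"
            members[f"{ref}.scf"] = b"FIXTURE-SCFx"
        ingest_results_zip(store, run, make_archive(members))
        complete_run(store, run)
        return store, run, refs

    def test_plain_fasta_has_one_wrapped_record_per_sample(self):
        store, run, refs = self._completed()
        operator = store.get_principal("op")
        order = store.get_order(run.order_ids[0])
        text = export_fasta(store, order, operator)
        assert text.count(">") == len(order.samples)
        ref = order.sample_refs()[0]
        _, sample = store.get_sample(ref)
        assert f">{ref} {sample.template_name}_{sample.primer_name}" in text
        body_lines = [l for l in text.splitlines() if not l.startswith(">")]
        assert max(len(l) for l in body_lines) <= 60

    def test_trimmed_variant_chops_terminal_ambiguity(self):
        store, run, refs = self._completed({0: "NNACGTN" + "A" * 700})
        operator = store.get_principal("op")
        order = store.get_order(run.order_ids[0])
        plain = export_fasta(store, order, operator, "plain")
        trimmed = export_fasta(store, order, operator, "trimmed")
        assert "NNACGT" in plain.replace("\n", "")
        first_trimmed = trimmed.split(">")[1]
        assert "".join(first_trimmed.splitlines()[1:]).startswith("ACGT")
        assert not "".join(first_trimmed.splitlines()[1:]).startswith("NN")

    def test_users_never_receive_failed_samples(self):
        store, run, refs = self._completed({0: "short"})  # ref[0] FAILED
        alice = store.get_principal("alice")
        operator = store.get_principal("op")
        order = store.get_order(run.order_ids[0])  # contains refs[0], refs[1]
        user_fasta = export_fasta(store, order, alice)
        op_fasta = export_fasta(store, order, operator)
        assert refs[0] not in user_fasta and refs[0] in op_fasta
        user_zip = zipfile.ZipFile(io.BytesIO(
            export_archive(store, order, alice)))
        assert not any(refs[0] in n for n in user_zip.namelist())

    def test_archive_contains_all_attachments_and_the_fasta(self):
        store, run, refs = self._completed()
        operator = store.get_principal("op")
        order = store.get_order(run.order_ids[0])
        zf = zipfile.ZipFile(io.BytesIO(export_archive(store, order,
                                                       operator)))
        names = set(zf.namelist())
        for ref in order.sample_refs():
            assert {f"{ref}.seq", f"{ref}.ab1", f"{ref}.scf"} <= names
        assert f"{order.order_id}.fasta" in names

    def test_cross_group_viewer_is_rejected(self):
        store, run, refs = self._completed()
        from seqfab.model import Role
        from seqfab.store import Principal

        store.add_principal(Principal("eve", "Eve", {"G9"}, Role.USER))
        eve = store.get_principal("eve")
        order = store.get_order(run.order_ids[0])
        with pytest.raises(AuthorizationError):
            export_fasta(store, order, eve)

    def test_empty_visible_set_rejects_archive_export(self):
        store, run, refs = self._completed(
            {i: "short" for i in range(3)}
        )  # everything FAILED
        alice = store.get_principal("alice")
        order = store.get_order(run.order_ids[0])
        with pytest.raises(ValidationError, match="nothing to export"):
            export_archive(store, order, alice)


class TestResubmit:
    def _failed_sample(self):
        store, run, chemistry, _ = build_golden_store(DoseMode.VARIABLE)
        write_instrument_sheet(store, run)
        refs = run.sample_refs()
        members = {f"{r}.seq": (b"A" * 800 if r != refs[0] else b"AC")
                   for r in refs}
        ingest_results_zip(store, run, make_archive(members))
        return store, run, refs

    def test_clone_keeps_fields_but_gets_a_fresh_ref(self):
        store, run, refs = self._failed_sample()
        alice = store.get_principal("alice")
        new_order = resubmit_failed(store, refs[0], alice)
        assert new_order.state is OrderState.NEW
        assert len(new_order.samples) == 1
        original_order, original = store.get_sample(refs[0])
        clone = new_order.samples[0]
        assert clone.sample_ref != refs[0]
        assert clone.template_name == original.template_name
        assert clone.primer_name == original.primer_name
        assert clone.template_concentration == original.template_concentration
        assert new_order.resubmitted_from == refs[0]
        assert new_order.owner == original_order.owner

    def test_ok_sample_cannot_be_resubmitted(self):
        store, run, refs = self._failed_sample()
        alice = store.get_principal("alice")
        with pytest.raises(ValidationError):
            resubmit_failed(store, refs[1], alice)

    def test_strangers_cannot_resubmit(self):
        store, run, refs = self._failed_sample()
        from seqfab.model import Role
        from seqfab.store import Principal

        store.add_principal(Principal("eve", "Eve", {"G9"}, Role.USER))
        with pytest.raises(AuthorizationError):
            resubmit_failed(store, refs[0], store.get_principal("eve"))
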