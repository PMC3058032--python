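"""Deterministic synthetic data: orders, rosters and sequencer output.

The whole pipeline is testable end-to-end with no instrument and no
external downloads: this module fabricates customer sample sheets drawn
from configurable concentration distributions, a principal/group roster,
and ZIP archives that look like capillary-sequencer output — a plain-text
``.seq`` per sample plus dummy ``.ab1``/``.scf`` blobs (prefixed
``FIXTURE-AB1``/``FIXTURE-SCF`` so tests can assert nothing ever parses
them).  All randomness flows from one seeded :class:`numpy.random
.Generator` passed explicitly; the same seed yields byte-identical files.

Synthetic reads emulate the failure modes the scoring pipeline must
handle: a configurable fraction of outright failures (short reads), runs
of terminal ambiguity (the unresolved start/end of a capillary trace) and
a low rate of internal ambiguous calls.  They do not emulate chromatogram
content, quality scores or vector contamination.
"""

from __future__ import annotations

import io
import zipfile
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .config import ValidationLimits
from .errors import StateError
from .model import PlannedRun, Role, RunState
from .store import FacilityStore, Principal
from .submission import SHEET_COLUMNS

#: IUPAC ambiguity codes used for synthetic unresolved calls (N dominant).
AMBIGUITY_CODES = "NRYSWKM"

AB1_MAGIC = b"FIXTURE-AB1"
SCF_MAGIC = b"FIXTURE-SCF"

_ZIP_DATE = (1980, 1, 1, 0, 0, 0)


class FixtureSpec(BaseModel):
    """Knobs for synthetic order and read generation.

    Concentration ranges default to the shipped submission limits so
    generated sheets validate cleanly; ``error_fraction`` deliberately
    pushes that share of rows outside the limits to exercise validation.
    Read quality: ``fail_p`` is the chance a sample fails outright;
    successful reads run ``mean_read_fraction`` of the requested length
    (drawn within +-10%, floored so a success always meets the request),
    with terminal ambiguity run lengths ~ Poisson(``terminal_amb_mean``)
    on each end and internal ambiguity at ``internal_amb_rate`` per base.
    """

    seed: int = 0
    n_orders: int = 3
    samples_per_order: tuple[int, int] = (8, 16)
    template_conc_range: tuple[float, float] = (20.0, 200.0)
    primer_conc_range: tuple[float, float] = (2.0, 20.0)
    template_vol_range: tuple[float, float] = (15.0, 50.0)
    primer_vol_range: tuple[float, float] = (15.0, 40.0)
    facility_primer_prob: float = 0.3
    error_fraction: float = 0.0
    fail_p: float = 0.1
    mean_read_fraction: float = 1.15
    failed_read_fraction_max: float = 0.5
    terminal_amb_mean: float = 12.0
    internal_amb_rate: float = 0.01

    @model_validator(mode="after")
    def _probabilities(self) -> "FixtureSpec":
        for name in ("facility_primer_prob", "error_fraction", "fail_p",
                     "internal_amb_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        lo, hi = self.samples_per_order
        if not 1 <= lo <= hi <= 96:
            raise ValueError("samples_per_order must satisfy 1 <= lo <= hi <= 96")
        return self

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def make_roster(
    spec: FixtureSpec, store: FacilityStore
) -> tuple[list[Principal], Principal]:
    """Register one group+user per order plus one operator; returns them."""
    users = []
    for i in range(1, spec.n_orders + 1):
        p = Principal(
            user_id=f"user{i}",
            display_name=f"Customer {i}",
            groups={f"G{i}"},
            role=Role.USER,
        )
        store.add_principal(p)
        users.append(p)
    operator = Principal(
        user_id="op", display_name="Facility Operator",
        groups={"FACILITY"}, role=Role.OPERATOR,
    )
    store.add_principal(operator)
    return users, operator


def generate_order_records(
    spec: FixtureSpec,
    rng: np.random.Generator,
    limits: ValidationLimits,
    n_samples: int | None = None,
) -> list[dict]:
    """Fabricate one order's worth of sample records.

    With ``error_fraction`` > 0 that share of rows (in expectation) gets
    an out-of-range template concentration so it fails validation.
    """
    if n_samples is None:
        lo, hi = spec.samples_per_order
        n_samples = int(rng.integers(lo, hi + 1))
    seq_types = sorted(limits.sequencing_types)
    records = []
    for j in range(n_samples):
        seq_type = seq_types[int(rng.integers(len(seq_types)))]
        facility = rng.random() < spec.facility_primer_prob
        tconc = float(rng.uniform(*spec.template_conc_range))
        if rng.random() < spec.error_fraction:
            # push the concentration above the acceptance window
            tconc = limits.template_concentration_max * float(
                rng.uniform(1.5, 3.0)
            )
        record = {
            "template_name": f"pCLONE{int(rng.integers(1, 500)):03d}",
            "primer_name": (
                ["T7", "M13F", "M13R"][int(rng.integers(3))]
                if facility
                else f"oligo{int(rng.integers(1, 200)):03d}"
            ),
            "primer_source": "facility" if facility else "customer",
            "template_conc_ng_ul": round(tconc, 1),
            "template_vol_ul": round(
                float(rng.uniform(*spec.template_vol_range)), 1
            ),
            "primer_conc_pmol_ul": (
                ""
                if facility
                else round(float(rng.uniform(*spec.primer_conc_range)), 1)
            ),
            "primer_vol_ul": (
                "" if facility
                else round(float(rng.uniform(*spec.primer_vol_range)), 1)
            ),
            "read_length_bp": limits.sequencing_types[seq_type],
            "seq_type": seq_type,
        }
        records.append(record)
    return records


def generate_orders(
    spec: FixtureSpec,
    out_dir: str | Path,
    limits: ValidationLimits | None = None,
) -> list[Path]:
    """Write one submission CSV per order plus a roster file; return paths."""
    limits = limits or ValidationLimits()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = spec.rng()
    paths = []
    for i in range(1, spec.n_orders + 1):
        records = generate_order_records(spec, rng, limits)
        df = pd.DataFrame(records, columns=SHEET_COLUMNS)
        path = out_dir / f"order_{i:02d}.csv"
        df.to_csv(path, index=False)
        paths.append(path)
    roster = out_dir / "roster.csv"
    rows = [
        {"user_id": f"user{i}", "display_name": f"Customer {i}",
         "groups": f"G{i}", "role": "USER"}
        for i in range(1, spec.n_orders + 1)
    ]
    rows.append({"user_id": "op", "display_name": "Facility Operator",
                 "groups": "FACILITY", "role": "OPERATOR"})
    pd.DataFrame(rows).to_csv(roster, index=False)
    paths.append(roster)
    return paths


def _synthesize_read(
    rng: np.random.Generator, requested: int, spec: FixtureSpec
) -> str:
    """One synthetic read honouring the spec's quality profile."""
    bases = "ACGT"
    if rng.random() < spec.fail_p:
        # outright failure: clearly short (or empty) read
        core_len = int(requested * rng.uniform(0.0, spec.failed_read_fraction_max))
    else:
        frac = rng.uniform(
            spec.mean_read_fraction - 0.1, spec.mean_read_fraction + 0.1
        )
        core_len = max(requested, int(np.ceil(requested * frac)))
    core = rng.choice(list(bases), size=core_len)
    if core_len and spec.internal_amb_rate > 0:
        # interior ambiguity never touches the first/last base, so the
        # readable (post-trim) length stays exactly core_len
        mask = rng.random(core_len) < spec.internal_amb_rate
        mask[0] = mask[-1] = False
        amb = rng.choice(list(AMBIGUITY_CODES), size=int(mask.sum()))
        core[mask] = amb
    head = "N" * int(rng.poisson(spec.terminal_amb_mean))
    tail = "N" * int(rng.poisson(spec.terminal_amb_mean))
    return head + "".join(core) + tail


def generate_sequencer_output(
    store: FacilityStore,
    run: PlannedRun,
    spec: FixtureSpec,
    rng: np.random.Generator | None = None,
    omit_refs: set[str] | frozenset[str] = frozenset(),
) -> bytes:
    """Fabricate the sequencer's ZIP archive for an AWAITING_RESULTS run.

    Each sample well yields ``<sample_ref>.seq`` (text), ``.ab1`` and
    ``.scf`` (opaque blobs), except refs listed in ``omit_refs`` (to
    emulate a partial upload).  Deterministic under the generator state.
    """
    if run.state is not RunState.AWAITING_RESULTS:
        raise StateError(
            f"run {run.run_name} is {run.state.value}; sequencer output "
            "exists only once the run is AWAITING_RESULTS"
        )
    rng = rng if rng is not None else spec.rng()
    buf = io.BytesIO()
    with zipfile.ZipFile(buf, "w", zipfile.ZIP_DEFLATED) as zf:

        def member(name: str, data: bytes) -> None:
            info = zipfile.ZipInfo(name, date_time=_ZIP_DATE)
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, data)

        for ref in run.sample_refs():
            if ref in omit_refs:
                continue
            _, sample = store.get_sample(ref)
            read = _synthesize_read(rng, sample.requested_read_length, spec)
            member(f"{ref}.seq", (read + "\n").encode())
            member(
                f"{ref}.ab1",
                AB1_MAGIC + rng.integers(0, 256, size=64, dtype=np.uint8).tobytes(),
            )
            member(
                f"{ref}.scf",
                SCF_MAGIC + rng.integers(0, 256, size=64, dtype=np.uint8).tobytes(),
            )
    return buf.getvalue()


def run_demo(seed: int = 0, spec: FixtureSpec | None = None) -> dict:
    """Full pipeline on synthetic data; returns the final exports.

    generate orders -> submit -> plan -> export instrument sheet ->
    generate sequencer output -> ingest -> complete -> export FASTA and
    archives.  Returns a dict with the store and, per order, the plain
    FASTA text, trimmed FASTA text and archive bytes — the artefacts whose
    byte-identity across repeated runs demonstrates end-to-end
    determinism.
    """
    from datetime import datetime, timedelta, timezone

    from .config import ChemistryConfig
    from .planner import plan_runs
    from .results import complete_run, export_archive, export_fasta, ingest_results_zip
    from .robot_io import write_instrument_sheet
    from .submission import create_order

    spec = spec or FixtureSpec(seed=seed)
    if spec.seed != seed:
        spec = spec.model_copy(update={"seed": seed})
    limits = ValidationLimits()
    chemistry = ChemistryConfig()

    # fixed, stepping clock so timestamps are reproducible too
    t0 = datetime(2020, 1, 1, tzinfo=timezone.utc)
    ticks = iter(range(10**9))

    def clock() -> datetime:
        return t0 + timedelta(seconds=next(ticks))

    store = FacilityStore(clock=clock)
    users, operator = make_roster(spec, store)
    rng = spec.rng()
    orders = []
    for user in users:
        records = generate_order_records(spec, rng, limits)
        order, _ = create_order(
            store, user.user_id, sorted(user.groups)[0], records,
            limits, chemistry,
        )
        orders.append(order)
    runs = plan_runs(store, orders, chemistry)
    sheets = {run.run_name: write_instrument_sheet(store, run) for run in runs}
    reports = []
    for run in runs:
        archive = generate_sequencer_output(store, run, spec, rng)
        reports.append(ingest_results_zip(store, run, archive))
    for run in runs:
        complete_run(store, run, force=True)
    exports = {}
    for user, order in zip(users, orders):
        exports[order.order_id] = {
            "fasta": export_fasta(store, order, operator, "plain"),
            "trimmed": export_fasta(store, order, operator, "trimmed"),
            "archive": export_archive(store, order, operator),
        }
    return {
        "store": store,
        "orders": orders,
        "runs": runs,
        "instrument_sheets": sheets,
        "linkage_reports": reports,
        "exports": exports,
    }
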