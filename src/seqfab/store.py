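"""Facility store: persistence, identity, access control, search, events.

The store is the single stateful object in seqfab.  It holds orders, runs,
per-sample results, the principal/group roster and an append-only event
log, and persists the lot to a single-file SQLite database so a facility
can run desk-scale with no server.  All identifier minting (order ids,
sample references, run names) goes through the store so uniqueness holds
across the whole lifetime of the database — names are never reused, even
after a plan is abandoned.

Two roles exist: ordinary facility *users*, who see only data belonging to
groups that grant theirs view access (their own group implicitly), and
*operators*, who see everything including run planning, failed-sample
files and private notes.
"""

from __future__ import annotations

import json
import sqlite3
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Any, Callable

from .errors import AuthorizationError, SeqFabError
from .model import (
    DoseMode,
    Note,
    Order,
    OrderState,
    PlannedRun,
    PrimerSource,
    ResultStatus,
    Role,
    RunState,
    Sample,
    SequencingResult,
    Tag,
    Visibility,
    WellContent,
    WellKind,
    WellRecipe,
    next_run_name,
    set_order_state,
)


@dataclass
class Principal:
    user_id: str
    display_name: str
    groups: set[str]
    role: Role = Role.USER

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("a principal belongs to at least one group")

    @property
    def is_operator(self) -> bool:
        return self.role is Role.OPERATOR


@dataclass
class GroupPolicy:
    """Cross-group grants; absence of a grant means no access."""

    group_id: str
    grants: dict[str, set[str]] = field(default_factory=dict)

    def grants_view(self, other_groups: set[str]) -> bool:
        return any("VIEW" in self.grants.get(g, set()) for g in other_groups)


@dataclass
class Event:
    seq: int
    kind: str
    timestamp: datetime
    actor: str
    payload: dict[str, Any]


@dataclass
class Amendment:
    """One operator edit to a planned well volume, kept for the audit trail."""

    run_name: str
    well: str
    field: str
    old: float
    new: float
    operator: str
    timestamp: datetime


@dataclass
class SearchPage:
    items: list[tuple[str, Any]]  # ("order"|"sample", entity)
    page: int
    page_size: int
    total: int


class FacilityStore:
    """In-memory facility state with SQLite save/open round-trip."""

    def __init__(
        self,
        clock: Callable[[], datetime] | None = None,
        page_size: int = 20,
    ):
        self.clock = clock or (lambda: datetime.now(timezone.utc))
        self.page_size = page_size
        self.orders: dict[str, Order] = {}
        self.runs: dict[str, PlannedRun] = {}
        self.results: dict[str, SequencingResult] = {}
        self.principals: dict[str, Principal] = {}
        self.policies: dict[str, GroupPolicy] = {}
        self.events: list[Event] = []
        self.amendments: list[Amendment] = []
        self._sample_order: dict[str, str] = {}  # sample_ref -> order_id
        self._order_counter = 0
        self._sample_counter = 0
        self._run_counters: dict[str, int] = {}
        self._retired_run_names: set[str] = set()

    # -- time and identifiers -------------------------------------------------

    def now(self) -> datetime:
        return self.clock()

    def next_order_id(self) -> str:
        self._order_counter += 1
        return f"ORD-{self._order_counter:06d}"

    def next_sample_ref(self) -> str:
        self._sample_counter += 1
        return f"S{self._sample_counter:06d}"

    def mint_run_name(self, series: str = "A") -> str:
        counter = self._run_counters.get(series, 0) + 1
        name = next_run_name(series, counter)
        while name in self.runs or name in self._retired_run_names:
            counter += 1
            name = next_run_name(series, counter)
        self._run_counters[series] = counter
        return name

    def retire_run_name(self, name: str) -> None:
        self._retired_run_names.add(name)

    # -- roster ---------------------------------------------------------------

    def add_principal(self, principal: Principal) -> None:
        self.principals[principal.user_id] = principal

    def get_principal(self, user_id: str) -> Principal:
        try:
            return self.principals[user_id]
        except KeyError:
            raise AuthorizationError(f"unknown principal {user_id!r}") from None

    def grant(self, group_id: str, other_group: str, perms: set[str]) -> None:
        policy = self.policies.setdefault(group_id, GroupPolicy(group_id))
        policy.grants.setdefault(other_group, set()).update(perms)

    # -- entities -------------------------------------------------------------

    def add_order(self, order: Order) -> None:
        if order.order_id in self.orders:
            raise SeqFabError(f"duplicate order id {order.order_id}")
        self.orders[order.order_id] = order
        for s in order.samples:
            self._sample_order[s.sample_ref] = order.order_id

    def register_sample(self, order: Order, sample: Sample) -> None:
        self._sample_order[sample.sample_ref] = order.order_id

    def get_order(self, order_id: str) -> Order:
        try:
            return self.orders[order_id]
        except KeyError:
            raise SeqFabError(f"unknown order {order_id!r}") from None

    def get_sample(self, sample_ref: str) -> tuple[Order, Sample]:
        order_id = self._sample_order.get(sample_ref)
        if order_id is None:
            raise SeqFabError(f"unknown sample reference {sample_ref!r}")
        order = self.orders[order_id]
        for s in order.samples:
            if s.sample_ref == sample_ref:
                return order, s
        raise SeqFabError(f"unknown sample reference {sample_ref!r}")

    def add_run(self, run: PlannedRun) -> None:
        if run.run_name in self.runs or run.run_name in self._retired_run_names:
            raise SeqFabError(f"run name {run.run_name} already used")
        self.runs[run.run_name] = run

    def get_run(self, run_name: str) -> PlannedRun:
        try:
            return self.runs[run_name]
        except KeyError:
            raise SeqFabError(f"unknown run {run_name!r}") from None

    def remove_run(self, run_name: str) -> None:
        del self.runs[run_name]
        self.retire_run_name(run_name)

    def runs_containing(self, order_id: str) -> list[PlannedRun]:
        return [r for r in self.runs.values() if order_id in r.order_ids]

    def result_for(self, sample_ref: str, create: bool = False) -> SequencingResult:
        if sample_ref not in self.results:
            if not create:
                raise SeqFabError(f"no result record for sample {sample_ref!r}")
            self.results[sample_ref] = SequencingResult(sample_ref=sample_ref)
        return self.results[sample_ref]

    def set_order_state(self, order: Order, new: OrderState) -> None:
        set_order_state(order, new)

    # -- event log ------------------------------------------------------------

    def append_event(self, kind: str, actor: str, payload: dict[str, Any]) -> Event:
        ts = self.now()
        if self.events and ts < self.events[-1].timestamp:
            ts = self.events[-1].timestamp  # clock skew guard: never go back
        event = Event(len(self.events) + 1, kind, ts, actor, payload)
        self.events.append(event)
        return event

    # -- visibility -----------------------------------------------------------

    def _group_visible(self, principal: Principal, group: str) -> bool:
        if group in principal.groups:
            return True
        policy = self.policies.get(group)
        return policy is not None and policy.grants_view(principal.groups)

    def visible(self, principal: Principal, entity: Any) -> bool:
        """Whether ``principal`` may see ``entity`` at all.

        Operators see everything.  Runs are operator-only (planning is a
        facility-internal concern).  Orders and samples follow group
        policy; private notes are operator-only.  File-level hiding of
        FAILED samples is enforced where files are served (exports).
        """
        if principal.is_operator:
            return True
        if isinstance(entity, PlannedRun):
            return False
        if isinstance(entity, Order):
            return self._group_visible(principal, entity.group)
        if isinstance(entity, Sample):
            order, _ = self.get_sample(entity.sample_ref)
            return self._group_visible(principal, order.group)
        if isinstance(entity, SequencingResult):
            order, _ = self.get_sample(entity.sample_ref)
            return self._group_visible(principal, order.group)
        if isinstance(entity, Note):
            return entity.visibility is Visibility.PUBLIC
        raise SeqFabError(f"visibility undefined for {type(entity).__name__}")

    def visible_notes(self, principal: Principal, sample_ref: str) -> list[Note]:
        if sample_ref not in self.results:
            return []
        notes = self.results[sample_ref].notes
        if principal.is_operator:
            return list(notes)
        return [n for n in notes if n.visibility is Visibility.PUBLIC]

    def visible_files(self, principal: Principal, sample_ref: str) -> dict[str, bytes]:
        """Attachments the principal may download for one sample.

        FAILED samples' files are hidden from ordinary users but preserved
        for operators.
        """
        if sample_ref not in self.results:
            return {}
        result = self.results[sample_ref]
        if not principal.is_operator:
            order, _ = self.get_sample(sample_ref)
            if not self._group_visible(principal, order.group):
                return {}
            if result.status is ResultStatus.FAILED:
                return {}
        return dict(result.attachments)

    # -- search and dashboards ------------------------------------------------

    def search(
        self,
        principal: Principal,
        query: str | dict[str, str],
        page: int = 1,
        page_size: int | None = None,
    ) -> SearchPage:
        """Find orders and samples by field=value pairs or a bare token.

        A bare token is matched (case-insensitively, substring) against
        order id, sample reference, template name, primer name and the
        owner's user/display name.  Results are filtered by visibility and
        ordered newest first, then by id, and paginated.
        """
        page_size = page_size or self.page_size
        if isinstance(query, str):
            fields = None
            token = query.lower()
        else:
            fields = {k: str(v).lower() for k, v in query.items()}
            token = None

        def owner_names(order: Order) -> list[str]:
            names = [order.owner]
            p = self.principals.get(order.owner)
            if p is not None:
                names.append(p.display_name)
            return [n.lower() for n in names]

        def order_matches(order: Order) -> bool:
            if token is not None:
                hay = [order.order_id.lower(), *owner_names(order)]
                return any(token in h for h in hay)
            checks = {
                "order_id": lambda v: v == order.order_id.lower(),
                "owner": lambda v: v in owner_names(order),
                "user": lambda v: v in owner_names(order),
            }
            return all(
                checks[k](v) for k, v in fields.items() if k in checks
            ) and any(k in checks for k in fields)

        def sample_matches(sample: Sample) -> bool:
            if token is not None:
                hay = [
                    sample.sample_ref.lower(),
                    sample.template_name.lower(),
                    sample.primer_name.lower(),
                ]
                return any(token in h for h in hay)
            checks = {
                "sample_ref": lambda v: v == sample.sample_ref.lower(),
                "template_name": lambda v: v in sample.template_name.lower(),
                "primer_name": lambda v: v in sample.primer_name.lower(),
            }
            return all(
                checks[k](v) for k, v in fields.items() if k in checks
            ) and any(k in checks for k in fields)

        hits: list[tuple[datetime, str, str, Any]] = []
        for order in self.orders.values():
            if not self.visible(principal, order):
                continue
            if order_matches(order):
                hits.append((order.created_at, order.order_id, "order", order))
            for sample in order.samples:
                if sample_matches(sample):
                    hits.append(
                        (order.created_at, sample.sample_ref, "sample", sample)
                    )
        hits.sort(key=lambda h: (h[0], h[1]))
        hits.reverse()  # newest first, then id descending
        total = len(hits)
        start = (page - 1) * page_size
        items = [(kind, ent) for _, _, kind, ent in hits[start : start + page_size]]
        return SearchPage(items=items, page=page, page_size=page_size, total=total)

    def dashboard(self, principal: Principal, now: datetime | None = None) -> dict:
        """Operator: stage counts and queue ages.  User: recent own orders."""
        now = now or self.now()
        if principal.is_operator:
            counts = {
                "new_orders": sum(
                    1 for o in self.orders.values() if o.state is OrderState.NEW
                ),
                "planned_runs": sum(
                    1 for r in self.runs.values() if r.state is RunState.PLANNED
                ),
                "awaiting_results_runs": sum(
                    1
                    for r in self.runs.values()
                    if r.state is RunState.AWAITING_RESULTS
                ),
                "completed_runs": sum(
                    1 for r in self.runs.values() if r.state is RunState.COMPLETED
                ),
            }
            queue_age = {
                o.order_id: now - o.created_at
                for o in self.orders.values()
                if o.state is OrderState.NEW
            }
            return {"counts": counts, "queue_age": queue_age}
        own = [o for o in self.orders.values() if o.owner == principal.user_id]
        week = [o for o in own if now - o.created_at <= timedelta(days=7)]
        month = [o for o in own if now - o.created_at <= timedelta(days=30)]
        key = lambda o: (o.created_at, o.order_id)
        return {
            "last_week_orders": sorted(week, key=key, reverse=True),
            "last_month_orders": sorted(month, key=key, reverse=True),
        }

    # -- persistence ----------------------------------------------------------

    _SCHEMA = """
    CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT);
    CREATE TABLE principals (
        user_id TEXT PRIMARY KEY, display_name TEXT, role TEXT, groups TEXT);
    CREATE TABLE policies (group_id TEXT PRIMARY KEY, grants TEXT);
    CREATE TABLE orders (
        order_id TEXT PRIMARY KEY, owner TEXT, grp TEXT, account TEXT,
        state TEXT, created_at TEXT, resubmitted_from TEXT);
    CREATE TABLE samples (
        sample_ref TEXT PRIMARY KEY, order_id TEXT, idx INTEGER,
        template_name TEXT, primer_name TEXT, primer_source TEXT,
        template_conc REAL, template_vol REAL, primer_conc REAL,
        primer_vol REAL, read_length INTEGER, seq_type TEXT);
    CREATE TABLE runs (
        run_name TEXT PRIMARY KEY, state TEXT, mode TEXT, traversal TEXT,
        order_ids TEXT, warnings TEXT);
    CREATE TABLE wells (
        run_name TEXT, well TEXT, kind TEXT, sample_ref TEXT,
        template_vol REAL, primer_vol REAL, mix_vol REAL, water_vol REAL,
        PRIMARY KEY (run_name, well));
    CREATE TABLE results (
        sample_ref TEXT PRIMARY KEY, sequence_text TEXT, pct_read REAL,
        pct_amb REAL, status TEXT, manual_status INTEGER, tags TEXT);
    CREATE TABLE attachments (
        sample_ref TEXT, name TEXT, data BLOB, PRIMARY KEY (sample_ref, name));
    CREATE TABLE notes (
        sample_ref TEXT, idx INTEGER, author TEXT, created_at TEXT,
        text TEXT, visibility TEXT, PRIMARY KEY (sample_ref, idx));
    CREATE TABLE events (
        seq INTEGER PRIMARY KEY, kind TEXT, timestamp TEXT, actor TEXT,
        payload TEXT);
    CREATE TABLE amendments (
        id INTEGER PRIMARY KEY, run_name TEXT, well TEXT, field TEXT,
        old REAL, new REAL, operator TEXT, timestamp TEXT);
    CREATE TABLE retired_runs (run_name TEXT PRIMARY KEY);
    """

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.exists():
            path.unlink()
        con = sqlite3.connect(path)
        try:
            con.executescript(self._SCHEMA)
            meta = {
                "order_counter": self._order_counter,
                "sample_counter": self._sample_counter,
                "run_counters": self._run_counters,
                "page_size": self.page_size,
            }
            con.executemany(
                "INSERT INTO meta VALUES (?, ?)",
                [(k, json.dumps(v)) for k, v in meta.items()],
            )
            con.executemany(
                "INSERT INTO principals VALUES (?, ?, ?, ?)",
                [
                    (p.user_id, p.display_name, p.role.value,
                     json.dumps(sorted(p.groups)))
                    for p in self.principals.values()
                ],
            )
            con.executemany(
                "INSERT INTO policies VALUES (?, ?)",
                [
                    (pol.group_id,
                     json.dumps({g: sorted(v) for g, v in pol.grants.items()}))
                    for pol in self.policies.values()
                ],
            )
            for o in self.orders.values():
                con.execute(
                    "INSERT INTO orders VALUES (?, ?, ?, ?, ?, ?, ?)",
                    (o.order_id, o.owner, o.group, o.account, o.state.value,
                     o.created_at.isoformat(), o.resubmitted_from),
                )
                for i, s in enumerate(o.samples):
                    con.execute(
                        "INSERT INTO samples VALUES (?,?,?,?,?,?,?,?,?,?,?,?)",
                        (s.sample_ref, o.order_id, i, s.template_name,
                         s.primer_name, s.primer_source.value,
                         s.template_concentration, s.template_volume_supplied,
                         s.primer_concentration, s.primer_volume_supplied,
                         s.requested_read_length, s.sequencing_type),
                    )
            for r in self.runs.values():
                con.execute(
                    "INSERT INTO runs VALUES (?, ?, ?, ?, ?, ?)",
                    (r.run_name, r.state.value, r.mode.value, r.traversal,
                     json.dumps(r.order_ids), json.dumps(r.warnings)),
                )
                for well, c in r.wells.items():
                    con.execute(
                        "INSERT INTO wells VALUES (?,?,?,?,?,?,?,?)",
                        (r.run_name, well, c.kind.value, c.sample_ref,
                         c.recipe.template_volume, c.recipe.primer_volume,
                         c.recipe.mix_volume, c.recipe.water_volume),
                    )
            for res in self.results.values():
                con.execute(
                    "INSERT INTO results VALUES (?,?,?,?,?,?,?)",
                    (res.sample_ref, res.sequence_text, res.pct_read,
                     res.pct_amb, res.status.value, int(res.manual_status),
                     json.dumps(sorted(t.value for t in res.tags))),
                )
                for name, data in res.attachments.items():
                    con.execute(
                        "INSERT INTO attachments VALUES (?,?,?)",
                        (res.sample_ref, name, data),
                    )
                for i, n in enumerate(res.notes):
                    con.execute(
                        "INSERT INTO notes VALUES (?,?,?,?,?,?)",
                        (res.sample_ref, i, n.author, n.created_at.isoformat(),
                         n.text, n.visibility.value),
                    )
            con.executemany(
                "INSERT INTO events VALUES (?,?,?,?,?)",
                [
                    (e.seq, e.kind, e.timestamp.isoformat(), e.actor,
                     json.dumps(e.payload, sort_keys=True))
                    for e in self.events
                ],
            )
            con.executemany(
                "INSERT INTO amendments VALUES (?,?,?,?,?,?,?,?)",
                [
                    (i + 1, a.run_name, a.well, a.field, a.old, a.new,
                     a.operator, a.timestamp.isoformat())
                    for i, a in enumerate(self.amendments)
                ],
            )
            con.executemany(
                "INSERT INTO retired_runs VALUES (?)",
                [(n,) for n in sorted(self._retired_run_names)],
            )
            con.commit()
        finally:
            con.close()

    @classmethod
    def open(
        cls, path: str | Path, clock: Callable[[], datetime] | None = None
    ) -> "FacilityStore":
        con = sqlite3.connect(path)
        try:
            store = cls(clock=clock)
            meta = {k: json.loads(v) for k, v in con.execute("SELECT * FROM meta")}
            store._order_counter = meta.get("order_counter", 0)
            store._sample_counter = meta.get("sample_counter", 0)
            store._run_counters = meta.get("run_counters", {})
            store.page_size = meta.get("page_size", 20)
            for uid, name, role, groups in con.execute("SELECT * FROM principals"):
                store.principals[uid] = Principal(
                    uid, name, set(json.loads(groups)), Role(role)
                )
            for gid, grants in con.execute("SELECT * FROM policies"):
                store.policies[gid] = GroupPolicy(
                    gid, {g: set(v) for g, v in json.loads(grants).items()}
                )
            samples_by_order: dict[str, list[tuple[int, Sample]]] = {}
            for row in con.execute("SELECT * FROM samples"):
                (ref, oid, idx, tname, pname, psrc, tconc, tvol, pconc, pvol,
                 rlen, stype) = row
                samples_by_order.setdefault(oid, []).append(
                    (idx, Sample(ref, tname, pname, PrimerSource(psrc),
                                 tconc, tvol, pconc, pvol, rlen, stype))
                )
            for row in con.execute("SELECT * FROM orders"):
                oid, owner, grp, account, state, created, resub = row
                samples = [s for _, s in sorted(samples_by_order.get(oid, []))]
                order = Order(
                    oid, owner, grp, samples, OrderState(state),
                    datetime.fromisoformat(created), account, resub,
                )
                store.orders[oid] = order
                for s in samples:
                    store._sample_order[s.sample_ref] = oid
            wells_by_run: dict[str, dict[str, WellContent]] = {}
            for row in con.execute("SELECT * FROM wells"):
                rname, well, kind, ref, tv, pv, mv, wv = row
                wells_by_run.setdefault(rname, {})[well] = WellContent(
                    kind=WellKind(kind),
                    recipe=WellRecipe(tv, pv, mv, wv),
                    sample_ref=ref,
                )
            for row in con.execute("SELECT * FROM runs"):
                rname, state, mode, traversal, oids, warnings = row
                store.runs[rname] = PlannedRun(
                    run_name=rname,
                    state=RunState(state),
                    wells=wells_by_run.get(rname, {}),
                    order_ids=json.loads(oids),
                    mode=DoseMode(mode),
                    traversal=traversal,
                    warnings=json.loads(warnings),
                )
            notes_by_ref: dict[str, list[tuple[int, Note]]] = {}
            for ref, idx, author, created, text, vis in con.execute(
                "SELECT * FROM notes"
            ):
                notes_by_ref.setdefault(ref, []).append(
                    (idx, Note(author, datetime.fromisoformat(created), text,
                               Visibility(vis)))
                )
            attachments_by_ref: dict[str, dict[str, bytes]] = {}
            for ref, name, data in con.execute("SELECT * FROM attachments"):
                attachments_by_ref.setdefault(ref, {})[name] = data
            for row in con.execute("SELECT * FROM results"):
                ref, seqtext, pr, pa, status, manual, tags = row
                store.results[ref] = SequencingResult(
                    sample_ref=ref,
                    sequence_text=seqtext,
                    attachments=attachments_by_ref.get(ref, {}),
                    pct_read=pr,
                    pct_amb=pa,
                    status=ResultStatus(status),
                    tags={Tag(t) for t in json.loads(tags)},
                    notes=[n for _, n in sorted(notes_by_ref.get(ref, []))],
                    manual_status=bool(manual),
                )
            for seq, kind, ts, actor, payload in con.execute(
                "SELECT * FROM events ORDER BY seq"
            ):
                store.events.append(
                    Event(seq, kind, datetime.fromisoformat(ts), actor,
                          json.loads(payload))
                )
            for row in con.execute("SELECT * FROM amendments ORDER BY id"):
                _, rname, well, fieldname, old, new, op, ts = row
                store.amendments.append(
                    Amendment(rname, well, fieldname, old, new, op,
                              datetime.fromisoformat(ts))
                )
            for (name,) in con.execute("SELECT * FROM retired_runs"):
                store._retired_run_names.add(name)
            return store
        finally:
            con.close()
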