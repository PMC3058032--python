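# Methods

## The workflow model

seqfab models a Sanger sequencing facility as a four-stage pipeline with
two explicit state machines.

**Orders** (`NEW → LOCKED → COMPLETED`, with `LOCKED → NEW` when a plan is
abandoned) hold one or more samples; a sample is one template+primer
reaction with the customer's stated concentrations, supplied volumes and a
requested read length. Orders are editable exactly while `NEW`: once an
operator places an order in a planned run it locks, so the plate plan and
the order can never disagree. Every sample gets a globally unique, opaque
reference (`S000001`, …) at submission time; references are minted from a
persistent counter and never reused, because they are the join key between
the plate, the instrument sheet and the result files.

**Runs** (`PLANNED → AWAITING_RESULTS → COMPLETED`, with `PLANNED`
abandonable) are one 96-well plate each. The transition table is
exhaustive: every (state, event) pair either transitions or raises — there
are no silent no-ops, which is what makes the lifecycle testable by
enumeration. The trigger from `PLANNED` to `AWAITING_RESULTS` is the first
export of the instrument set-up sheet: that is the moment the plate's
chemistry is committed. Run names are a letter series plus a monotone
counter (`A1`, `A2`, …, `A726`); abandoned names are retired, never
reissued, so a name is forever a stable pointer into the audit trail.

## Plate planning and packing

Orders are consumed first-in-first-out and packed greedily; samples keep
their in-order listing and orders stay contiguous. The default traversal
is column-major (A1, B1, …, H1, A2, …) because capillary instruments
inject by column group; row-major is a config switch. By default an order
may straddle a plate boundary (`--no-split` keeps orders whole at the cost
of empty wells). With splitting, greedy FIFO fill provably reaches the
minimum plate count ⌈total / (96 − controls)⌉ — capacity is the only
constraint — and the acceptance suite checks this against that closed form
on random queues.

Controls default to one reaction control and one instrument control in the
last wells of the traversal (G12, H12 column-major); both counts and the
placement are configuration. A control is a real reaction with a known
template, so control wells are dosed with the fixed-mode recipe and appear
on every robot sheet under their `R.Control` / `I.Control` label (used in
both name columns of the worklists).

## Well chemistry

Every well closes to the configured total reaction volume (default 10 µL,
of which 4 µL is pre-made mix), water being the balancing component:

* **FIXED** mode: constant template and primer volumes (default 1.0 µL
  each) for all wells — one time-optimised robot program.
* **VARIABLE** mode: `template = target mass / stated concentration`
  (default 100 ng for standard chemistry, 150 ng for long reads) and
  `primer = target amount / stated concentration` (default 5 pmol), each
  rounded half-up to the pipetting increment (0.1 µL) and clamped to
  [increment, total − mix]. Facility-stock primers have no customer-stated
  concentration and get the fixed primer volume. Any clamp, and any
  cut-back needed to keep the well from overflowing (template first, then
  primer), is surfaced as a warning naming the well; the closure invariant
  (sum = total within 0.01 µL) always holds because water is computed as
  the exact remainder.

Sample *quality* is not modelled — only concentration enters the dose.

Order confirmations ("provide at least this much") sum each template's
(and customer primer's) per-reaction variable-mode dose, multiply by a
safety factor (default 1.5) and round **up** to a hand-over grid (default
0.5 µL). Summing before rounding keeps the demand linear in the number of
reactions.

All numeric policy — limits, chemistry, increments, multipliers — lives in
a YAML config (`seqfab --config`), never in code constants, because every
facility runs its own chemistry.

## Sheets and the amendment audit trail

The three worklist dialects (`FIXED_DECK_A`, `VARIABLE`, `DECK_B`) are
defined by this package and versioned with it: column sets and order are
documented in `seqfab.robot_io`, output is RFC 4180 CSV with CRLF endings,
volumes at one decimal, and is byte-deterministic for a given run (hence
the golden-file tests). Which physical robot maps to which dialect is a
deployment decision; the names here are neutral.

Operators may edit volumes in the manual XLSX (whose worksheet name is the
run name, and whose volumes are scaled by the manual multiplier) or in the
VARIABLE CSV, and upload the file back. Identity is checked before
anything is applied: worksheet name (XLSX), exact well set, and per-well
template/primer names must all match the run — the CSV dialect carries no
run name column, so its identity rests on the well/name match. Each
changed cell becomes one immutable amendment record (well, field, old,
new, operator, timestamp). A well that no longer sums to the reaction
volume is a *warning*, not a rejection: the operator's judgement
deliberately outranks the standard chemistry.

## Scoring and trimming

Scoring uses sequence text only (no Phred/chromatogram parsing — traces
are stored as opaque attachments). An *ambiguous* letter is any IUPAC code
outside {A, C, G, T}, case-insensitive, with U counted as unambiguous so
RNA-alphabet text is not mangled. The *readable* length is the sequence
after removing the maximal ambiguous prefix and suffix (interior ambiguity
untouched, case preserved).

* `%Read = 100 × readable / requested`, uncapped — over-delivery is
  information, not an error.
* `%Amb` is computed on the **raw** upload, not the trimmed read: it
  measures the quality of what the instrument delivered, and on the
  trimmed read it would be blind to exactly the terminal junk it is meant
  to flag.
* Status is `OK` iff readable ≥ requested, `FAILED` otherwise,
  `IN_PROCESS` until a result is uploaded. A manual operator override sets
  a sticky flag; later re-ingestion re-scores the percentages but never
  flips a manually set status.

Result files are matched to samples by exact token match of the sample
reference in the file's base name (`<sample_ref>.<ext>` is the enforced
convention for generated fixtures). A fallback matcher on
`templateName_primerName` exists but is off by default: display names need
not be unique, so it only ever fires on an unambiguous hit.

## Access control

Two roles: users and operators. Operators see everything; run planning is
operator-only. A user sees an order iff it belongs to one of their groups
or to a group that grants theirs `VIEW`. On top of group visibility, two
file-level rules hold for non-operators everywhere files or notes are
served (views, FASTA, archives): failed samples' files are hidden (but
preserved for operators), and private notes are hidden. Search and
dashboards filter through the same predicate, which is what the randomized
leak test exercises. Authentication is out of scope — the CLI trusts
`--as` — the tested artefact is the ACL logic itself.

## Synthetic data

The fixture generator emulates the *shape* of facility traffic, not its
biology: sample sheets drawn from uniform concentration windows matching
the default limits (20–200 ng/µL templates, 2–20 pmol/µL primers, ~30% of
primers facility stock), and reads built as a clean A/C/G/T core with
Poisson-length terminal `N` runs (mean 12 per end) and 1% interior
ambiguity. Failures (default rate 0.1) are short reads below half the
requested length; successes draw their length within ±10% of 1.15× the
requested length, floored at the request so a "success" always scores OK.
These defaults make the generated mix realistic for a plasmid-sequencing
facility, and the failure knob is what the statistical-fidelity test pins
(observed failure fraction within 3 standard errors of the knob at
n = 1000).

What passing tests on this data shows: the pipeline's bookkeeping,
scoring arithmetic, state machines and access control are correct. What it
does not show: robustness to real chromatograms, base-caller quirks,
vendor file-naming schemes other than the `<sample_ref>.<ext>` contract,
or chemistry outside the configured windows.

All generation flows from one `numpy` `Generator` seeded explicitly; the
end-to-end demo additionally uses a fixed stepping clock, so two runs at
the same seed are byte-identical down to the exported ZIPs (members are
written with a fixed timestamp for exactly this reason).

## Numerical and design choices

* Rounding of doses is half-up on the pipetting increment with a 1e-9
  epsilon against float ties; confirmation volumes round up (never
  under-supply). Comparisons against re-uploaded volumes use a 1e-6 µL
  tolerance so 1-decimal formatting never fabricates amendments.
* Degenerate inputs are first-class: empty orders, header-only sheets,
  zero-concentration templates, corrupt ZIPs, empty reads and empty
  visible export sets are all explicit rejections with named causes.
* Persistence is a single-file SQLite schema (one table per entity kind,
  JSON for small nested values, BLOBs for attachments) behind a plain
  save/open interface; a server-backed store could replace it without
  touching the domain modules.
* The `seqfab` CLI is a thin layer: every command body is a couple of
  library calls plus printing, so the library surface remains the tested
  artefact.

## Known limitations

No base-calling or quality scores; no vector/adapter masking; no
multi-plate optimisation beyond greedy FIFO fill (e.g. no grouping by
primer to save robot tips); no instrument scheduling; no real e-mail
transport (the event log plus a pluggable notifier is the integration
point); payment is a free-text account field only.
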