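# seqfab

A headless, scriptable workflow engine for Sanger DNA-sequencing core
facilities. It covers the whole service loop a facility runs every day:

1. **Order intake** — customers submit up to 96 samples per sheet (CSV or
   XLSX, one row per template+primer reaction); every record is validated
   against the facility's concentration/volume limits, and the customer
   gets back an order id plus the minimal volumes of each template and
   customer-supplied primer to hand over.
2. **Run planning** — pending orders are pooled FIFO onto 96-well plates
   (rows A–H × columns 1–12), with reaction/instrument control wells and a
   per-well liquid recipe: template, primer, reaction mix and water summing
   to the configured reaction volume. Variable-volume dosing divides the
   target template mass (ng) and primer amount (pmol) by the customer's
   stated concentrations; fixed-volume dosing uses one constant recipe so
   the robot can run a time-optimised program.
3. **Robot and sequencer sheets** — worklist CSVs in three dialects for
   different liquid-handler decks, an XLSX plate map for manual pipetting
   (editable and re-uploadable, with every volume change audited), and the
   instrument set-up sheet whose first export moves the run to *awaiting
   results*.
4. **Results** — sequencer output (a `.seq` text file plus opaque
   `.ab1`/`.scf` chromatograms per sample) is uploaded as one ZIP and
   linked back to samples by their unique references. Each read is scored:
   `%Read = 100 × readable/requested` where *readable* is the length after
   chopping ambiguous runs (any IUPAC code outside A/C/G/T) off both ends,
   `%Amb` is the ambiguous fraction of the raw read, and the sample is
   **OK** iff readable ≥ requested. Operators can override statuses, tag
   failed samples `Rp`/`Rj`, and attach public or private notes.
5. **Delivery** — per-order traffic light (green/yellow/red for
   all/some/no results uploaded), FASTA export (plain or end-trimmed),
   full ZIP archives, and one-click resubmission of failed samples.
   Ordinary users never see other groups' data (unless granted), failed
   samples' files, private notes, or run planning; operators see
   everything. Notifications are an append-only event log.

State lives in a single-file SQLite store; everything is driven either
from Python or from the `seqfab` CLI.

## Worked example

Deterministic synthetic data stands in for real customers and the
sequencer (`seqfab fixtures ...`):

```console
$ seqfab --store fac.db user add alice --group G1
$ seqfab --store fac.db user add op --group FACILITY --role OPERATOR
$ seqfab --store fac.db fixtures orders --seed 7 --out fx --n-orders 1
$ seqfab --store fac.db --as alice order create --sheet fx/order_01.csv
created ORD-000001 with 16 samples
provide (template, uL): pCLONE022=3.5; pCLONE028=1.0; pCLONE040=2.0; ...
provide (primer, uL): oligo003=0.5; oligo011=3.0; oligo060=4.0; ...
```

The volumes are each template's summed per-reaction dose × the 1.5 safety
factor, rounded up to the 0.5 µL hand-over grid. Plan the plate and export
the sheets:

```console
$ seqfab --store fac.db --as op run plan --orders ORD-000001
planned A1: 16 samples, orders ORD-000001
$ seqfab --store fac.db --as op run export-robot A1 --dialect VARIABLE --out robot.csv
$ head -3 robot.csv
well,template_name,primer_name,template_vol_ul,primer_vol_ul,mix_vol_ul,water_vol_ul
A1,pCLONE028,oligo060,0.6,2.4,4.0,3.0
B1,pCLONE398,oligo144,2.0,0.5,4.0,3.5
$ seqfab --store fac.db --as op run export-instrument A1 --out instr.csv
wrote instr.csv; run A1 is now AWAITING_RESULTS
```

Well A1 holds 0.6 µL of a concentrated template and 2.4 µL of a dilute
primer; water tops every well up to the 10 µL reaction. Ingest the
(synthetic) sequencer archive, complete the run, and collect results:

```console
$ seqfab --store fac.db --as op fixtures sequencer-output --run A1 --seed 7 --out res.zip
$ seqfab --store fac.db --as op run ingest A1 res.zip
matched 16 sample(s); 0 unmatched file(s); 0 sample(s) without results
$ seqfab --store fac.db --as op run complete A1
completed A1
$ seqfab --store fac.db --as alice order show ORD-000001 | head -3
ORD-000001 [COMPLETED] owner=alice group=G1 samples=16
  S000001  pCLONE028_oligo060  OK  %Read=123.0 %Amb=3.5
  S000002  pCLONE398_oligo144  OK  %Read=114.3 %Amb=2.4
$ seqfab --store fac.db --as alice order export ORD-000001 --format trimmed --out out.fasta
```

Sample S000001 read 123% of its requested 700 bases (more than asked for —
%Read is deliberately uncapped) with 3.5% ambiguous calls on the raw read;
the trimmed FASTA starts at the first unambiguous base.

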