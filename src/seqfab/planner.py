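"""Plate planning: pool pending orders into 96-well runs and dose wells.

Orders are consumed first-in-first-out and packed greedily onto plates so
that plates carry no (or very few) empty wells; an order may straddle a
plate boundary unless splitting is disabled.  Each sample well gets a
liquid recipe — template, primer, pre-made reaction mix and water summing
to the configured reaction volume — either with fixed volumes (one
time-optimised robot program for the whole plate) or with per-well
variable volumes derived from the customer's stated concentrations.

Control wells (a reaction control and an instrument control by default)
are placed in the last wells of the plate traversal and dosed with the
fixed-mode volumes: a control is a real reaction with known template.
"""

from __future__ import annotations

import math
from typing import Sequence

from .config import ChemistryConfig, round_half_up
from .errors import CapacityError, StateError, ValidationError
from .model import (
    DoseMode,
    Order,
    OrderState,
    PlannedRun,
    PrimerSource,
    RunState,
    Sample,
    WellContent,
    WellKind,
    WellRecipe,
    well_positions,
)
from .store import FacilityStore


def count_plates(
    orders: Sequence[Order], config: ChemistryConfig
) -> tuple[int, int]:
    """Total sample count and the number of plates needed to run them.

    Each plate offers ``96 - controls_per_plate`` sample wells, so the
    plate count is the ceiling of total/usable.  An empty queue needs no
    plates.
    """
    for order in orders:
        if order.state is not OrderState.NEW:
            raise StateError(
                f"order {order.order_id} is {order.state.value}, not NEW"
            )
    total = sum(len(o.samples) for o in orders)
    if total == 0:
        return (0, 0)
    plates = math.ceil(total / config.usable_wells)
    return (total, plates)


def compute_well_recipe(
    sample: Sample, config: ChemistryConfig, mode: DoseMode
) -> tuple[WellRecipe, list[str]]:
    """Volumes of template, primer, mix and water for one well.

    FIXED mode uses the configured constant volumes for every well.
    VARIABLE mode doses by amount: ``template = target mass / stated
    concentration`` and ``primer = target pmol / stated concentration``,
    each rounded half-up to the pipetting increment and clamped to
    [increment, total - mix]; a facility-stock primer (no stated
    concentration) gets the fixed primer volume.  Water fills the well to
    the total reaction volume; if the dosed volumes would overflow it the
    template, then the primer, is cut back to fit.  Every adjustment is
    reported as a warning naming the sample and the reason.
    """
    inc = config.pipetting_increment
    total = config.total_reaction_volume
    mix = config.mix_volume
    warnings: list[str] = []

    if mode is DoseMode.FIXED:
        template = config.fixed_template_volume
        primer = config.fixed_primer_volume
    else:
        if sample.template_concentration == 0:
            raise ValidationError(
                f"sample {sample.sample_ref}: cannot dose zero-concentration "
                "template"
            )
        mass = config.template_mass_for(sample.sequencing_type)
        template = round_half_up(mass / sample.template_concentration, inc)
        cap = total - mix
        if template > cap:
            template = math.floor(cap / inc + 1e-9) * inc
            warnings.append(
                f"sample {sample.sample_ref}: template volume clamped to "
                f"{template:.1f} uL (dilute template exceeds well capacity)"
            )
        if template < inc:
            template = inc
            warnings.append(
                f"sample {sample.sample_ref}: template volume raised to the "
                f"pipetting increment {inc:.1f} uL (very concentrated template)"
            )
        if sample.primer_concentration is None:
            primer = config.fixed_primer_volume
        else:
            if sample.primer_concentration == 0:
                raise ValidationError(
                    f"sample {sample.sample_ref}: cannot dose "
                    "zero-concentration primer"
                )
            primer = round_half_up(
                config.target_primer_amount / sample.primer_concentration, inc
            )
            if primer > cap:
                primer = math.floor(cap / inc + 1e-9) * inc
                warnings.append(
                    f"sample {sample.sample_ref}: primer volume clamped to "
                    f"{primer:.1f} uL (dilute primer exceeds well capacity)"
                )
            if primer < inc:
                primer = inc
                warnings.append(
                    f"sample {sample.sample_ref}: primer volume raised to the "
                    f"pipetting increment {inc:.1f} uL"
                )

    water = total - template - primer - mix
    if water < -1e-9:
        # overflow: cut template back, then primer, to make the well close
        fit = max(0.0, total - mix - primer)
        new_template = math.floor(fit / inc + 1e-9) * inc
        if new_template < template:
            warnings.append(
                f"sample {sample.sample_ref}: template volume reduced "
                f"{template:.1f} -> {new_template:.1f} uL to fit the well"
            )
            template = new_template
        water = total - template - primer - mix
        if water < -1e-9:
            fit = max(0.0, total - mix - template)
            new_primer = math.floor(fit / inc + 1e-9) * inc
            warnings.append(
                f"sample {sample.sample_ref}: primer volume reduced "
                f"{primer:.1f} -> {new_primer:.1f} uL to fit the well"
            )
            primer = new_primer
            water = total - template - primer - mix
    water = max(0.0, round(water, 6))
    recipe = WellRecipe(
        template_volume=round(template, 6),
        primer_volume=round(primer, 6),
        mix_volume=mix,
        water_volume=water,
    )
    return recipe, warnings


def control_recipe(config: ChemistryConfig) -> WellRecipe:
    """Controls run the fixed-mode chemistry (known template and primer)."""
    template = config.fixed_template_volume
    primer = config.fixed_primer_volume
    water = round(
        config.total_reaction_volume - template - primer - config.mix_volume, 6
    )
    return WellRecipe(template, primer, config.mix_volume, water)


def _assemble_run(
    store: FacilityStore,
    parts: Sequence[tuple[Order, Sequence[Sample]]],
    config: ChemistryConfig,
    mode: DoseMode,
    run_name: str | None,
) -> PlannedRun:
    """Lay out one plate from (order, samples) parts already sized to fit."""
    n_samples = sum(len(samples) for _, samples in parts)
    if n_samples == 0:
        raise ValidationError("cannot plan a run with no samples")
    overflow = n_samples + config.controls_per_plate - 96
    if overflow > 0:
        raise CapacityError(
            f"plate capacity exceeded by {overflow} well(s): {n_samples} "
            f"samples + {config.controls_per_plate} controls > 96",
            overflow=overflow,
        )
    positions = list(well_positions(config.traversal))
    wells: dict[str, WellContent] = {}
    warnings: list[str] = []
    i = 0
    for order, samples in parts:
        for sample in samples:
            pos = positions[i]
            recipe, recipe_warnings = compute_well_recipe(sample, config, mode)
            wells[pos] = WellContent(
                kind=WellKind.SAMPLE, recipe=recipe, sample_ref=sample.sample_ref
            )
            warnings.extend(f"well {pos}: {w}" for w in recipe_warnings)
            i += 1
    # controls occupy the last wells of the traversal
    control_kinds = [WellKind.REACTION_CONTROL] * config.n_reaction_controls + [
        WellKind.INSTRUMENT_CONTROL
    ] * config.n_instrument_controls
    for kind, pos in zip(control_kinds, positions[96 - len(control_kinds) :]):
        wells[pos] = WellContent(kind=kind, recipe=control_recipe(config))
    run = PlannedRun(
        run_name=run_name or store.mint_run_name(config.run_series),
        state=RunState.PLANNED,
        wells=wells,
        order_ids=[o.order_id for o, _ in parts],
        mode=mode,
        traversal=config.traversal,
        warnings=warnings,
    )
    store.add_run(run)
    for order, _ in parts:
        if order.state is OrderState.NEW:
            store.set_order_state(order, OrderState.LOCKED)
    for _, samples in parts:
        for sample in samples:
            store.result_for(sample.sample_ref, create=True)
    store.append_event(
        "run_planned",
        "operator",
        {
            "run_name": run.run_name,
            "orders": run.order_ids,
            "n_samples": n_samples,
            "mode": mode.value,
        },
    )
    return run


def plan_run(
    store: FacilityStore,
    orders: Sequence[Order],
    config: ChemistryConfig,
    mode: DoseMode = DoseMode.VARIABLE,
    run_name: str | None = None,
) -> PlannedRun:
    """Plan a single plate from whole orders (which must all fit).

    Samples are placed in well-traversal order; orders stay contiguous in
    submission (FIFO) order and samples keep their in-order listing.  All
    placed orders become LOCKED and can no longer be amended.
    """
    if not orders:
        raise ValidationError("cannot plan a run from an empty order list")
    for order in orders:
        if order.state is not OrderState.NEW:
            raise StateError(
                f"order {order.order_id} is {order.state.value}, not NEW"
            )
    return _assemble_run(
        store, [(o, o.samples) for o in orders], config, mode, run_name
    )


def plan_runs(
    store: FacilityStore,
    orders: Sequence[Order],
    config: ChemistryConfig,
    mode: DoseMode = DoseMode.VARIABLE,
    allow_split: bool = True,
) -> list[PlannedRun]:
    """Plan as many plates as the queue needs, FIFO, greedy fill.

    With ``allow_split`` (default) an order straddling a plate boundary is
    split across two consecutive runs, so the number of plates equals the
    :func:`count_plates` minimum.  With ``--no-split`` semantics an order
    is kept whole and a new plate is started when it does not fit (an
    order larger than one plate's sample capacity is then rejected).
    """
    if not orders:
        return []
    for order in orders:
        if order.state is not OrderState.NEW:
            raise StateError(
                f"order {order.order_id} is {order.state.value}, not NEW"
            )
    usable = config.usable_wells
    batches: list[list[tuple[Order, list[Sample]]]] = []
    if allow_split:
        current: list[tuple[Order, list[Sample]]] = []
        room = usable
        for order in orders:
            samples = list(order.samples)
            while samples:
                take = samples[:room]
                samples = samples[room:]
                current.append((order, take))
                room -= len(take)
                if room == 0:
                    batches.append(current)
                    current = []
                    room = usable
        if current:
            batches.append(current)
    else:
        current = []
        room = usable
        for order in orders:
            n = len(order.samples)
            if n > usable:
                raise CapacityError(
                    f"order {order.order_id} has {n} samples but a plate "
                    f"holds {usable}; re-run with splitting enabled",
                    overflow=n - usable,
                )
            if n > room:
                batches.append(current)
                current = []
                room = usable
            current.append((order, list(order.samples)))
            room -= n
        if current:
            batches.append(current)
    return [_assemble_run(store, parts, config, mode, None) for parts in batches]


def abandon_plan(store: FacilityStore, run: PlannedRun) -> None:
    """Delete a PLANNED run and make its orders amendable again.

    The run name is retired, never reused.  An order reverts to NEW only
    when no other live run still contains part of it (orders split across
    plates stay locked until every containing plan is abandoned).
    """
    if run.state is not RunState.PLANNED:
        raise StateError(
            f"run {run.run_name} is {run.state.value}; only a PLANNED run "
            "can be abandoned"
        )
    member_ids = list(run.order_ids)
    sample_refs = run.sample_refs()
    store.remove_run(run.run_name)
    for ref in sample_refs:
        # drop the untouched placeholder result unless the sample is still
        # in another live run
        if ref in store.results and not any(
            ref in r.sample_refs() for r in store.runs.values()
        ):
            result = store.results[ref]
            if (
                result.status.value == "IN_PROCESS"
                and not result.attachments
                and not result.notes
            ):
                del store.results[ref]
    for order_id in member_ids:
        order = store.get_order(order_id)
        if not store.runs_containing(order_id):
            store.set_order_state(order, OrderState.NEW)
    store.append_event(
        "run_abandoned", "operator", {"run_name": run.run_name, "orders": member_ids}
    )
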