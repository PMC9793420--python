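"""Cellular dynamics: growth, division, differentiation, culling, shedding.

Cells carry a continuous length (per-micrometre exponential growth) next to
their discrete, grid-based length; whenever the continuous length exceeds
the integer length by one row, a grid row is inserted at the cell's
mid-height (duplicating the local auxin concentration - no dilution).
Meristematic cells divide upon doubling their birth length, with a
deterministic +5/-5/0 % staggering of growth rate by the parity (mod 3) of
the cell-centre row at birth, avoiding artificial whole-meristem synchrony
without any random number generator.  The simulation domain is
constant-sized: cells reaching the domain top are culled, and LR-cap cells
are shed once displaced past the LR-cap meristem boundary.
"""
from __future__ import annotations

import math
from typing import List, Optional, Tuple

import numpy as np

from .geometry import (DZ, EZ, LRCAP, MZ, OUTSIDE, TZ, WALL, Cell, Tissue,
                       apply_prepattern, zone_of)
from .params import GeometryConfig, GrowthParameters

Event = Tuple[float, str, int, int]  # time, kind, cell id, row


def division_rate_of(cell: Cell, gp: GrowthParameters) -> float:
    """Effective per-micrometre growth rate of a dividing (MZ) cell.

    mean_j % 3 == 0 -> average rate, == 1 -> +noise_amplitude,
    == 2 -> -noise_amplitude; fixed at cell creation (mean_j is immutable).
    """
    r = gp.mz_rate
    k = cell.mean_j % 3
    if k == 1:
        return r * (1.0 + gp.noise_amplitude)
    if k == 2:
        return r * (1.0 - gp.noise_amplitude)
    return r


def growth_rate_of(cell: Cell, gp: GrowthParameters) -> float:
    """Zone-dependent per-micrometre growth rate (0 in the DZ)."""
    if not cell.growing or cell.strip < 0:
        return 0.0
    if cell.zone == MZ:
        return division_rate_of(cell, gp)
    if cell.zone == TZ:
        return gp.tz_growth_rate if gp.tz_growth_rate is not None else gp.mz_rate
    if cell.zone == EZ:
        return gp.ez_rate
    return 0.0


# ---------------------------------------------------------------------------
# grid-row surgery (per cell file; neighbouring files are unaffected)
# ---------------------------------------------------------------------------

def _shift_strip_up(tissue: Tissue, c0: int, c1: int, from_row: int) -> None:
    """Move rows [from_row, top-1] of a column strip up by one; the topmost
    row's content is discarded (it is outside the living tissue by the time
    this is called)."""
    for arr in (tissue.auxin, tissue.point_kind, tissue.cell_slot):
        block = arr[from_row:-1, c0:c1 + 1].copy()
        arr[from_row + 1:, c0:c1 + 1] = block
    block = tissue.weights[from_row:-1, c0:c1 + 1, :].copy()
    tissue.weights[from_row + 1:, c0:c1 + 1, :] = block


def _cull_guard(tissue: Tissue, strip_idx: int, state, events: List[Event],
                t: float) -> None:
    """Remove the file's topmost cell(s) if a row insertion would push their
    apical wall out of the domain."""
    while True:
        top = tissue.topmost_cell(strip_idx)
        if top is None or top.r1 + 1 <= tissue.cfg.n_rows - 2:
            return
        events.append((t, "cull", top.id, top.r1))
        state.clear_slot(top.slot)
        tissue.remove_cell(top, clear_kind=OUTSIDE)


def insert_row(tissue: Tissue, cell: Cell, state, events: List[Event],
               t: float) -> bool:
    """Insert one grid row at the cell's mid-height (duplicating the local
    auxin concentration and membrane weights).  Returns False if the cell
    itself was culled by the domain-top guard instead of growing."""
    _cull_guard(tissue, cell.strip, state, events, t)
    if cell.id not in tissue.cells:
        return False
    r_mid = (cell.r0 + cell.r1) // 2
    _shift_strip_up(tissue, cell.c0, cell.c1, r_mid + 1)
    for arr in (tissue.auxin, tissue.point_kind, tissue.cell_slot):
        arr[r_mid + 1, cell.c0:cell.c1 + 1] = arr[r_mid, cell.c0:cell.c1 + 1]
    tissue.weights[r_mid + 1, cell.c0:cell.c1 + 1, :] = \
        tissue.weights[r_mid, cell.c0:cell.c1 + 1, :]
    strip = tissue.strips[cell.strip]
    for cid in strip.cell_ids:
        other = tissue.cells[cid]
        if other.r0 > r_mid:
            other.r0 += 1
            other.r1 += 1
    cell.r1 += 1
    events.append((t, "insert", cell.id, r_mid + 1))
    tissue.geometry_dirty = True
    return True


def grow_cell(tissue: Tissue, cell: Cell, gp: GrowthParameters, dt: float,
              state, events: List[Event], t: float) -> None:
    """Advance the continuous length; insert grid rows on threshold crossing."""
    r = growth_rate_of(cell, gp)
    if r <= 0.0:
        return
    cell.length_cont += r * cell.length_cont * dt
    while cell.id in tissue.cells and cell.length_cont - cell.length_int >= 1.0:
        if not insert_row(tissue, cell, state, events, t):
            return


def divide_cell(tissue: Tissue, cell: Cell, state, events: List[Event],
                t: float) -> Tuple[Cell, Cell]:
    """Split a meristematic cell that has doubled its birth length.

    A new wall row is inserted at the division plane; the rootward daughter
    receives the extra row for odd lengths.  Daughters inherit the mother's
    expression state and membrane prepattern assignment verbatim; their
    division clocks (birth length, mean_j) are reset at creation.
    """
    if cell.zone != MZ:
        raise ValueError("division attempted outside the meristem proper")
    _cull_guard(tissue, cell.strip, state, events, t)
    if cell.id not in tissue.cells:
        raise ValueError("cell was culled before division")
    h = cell.length_int
    h_a = (h + 1) // 2  # rootward daughter; gets the extra row if h is odd
    r0, r1 = cell.r0, cell.r1
    split = r0 + h_a
    _shift_strip_up(tissue, cell.c0, cell.c1, split)
    tissue.point_kind[split, cell.c0:cell.c1 + 1] = WALL
    tissue.cell_slot[split, cell.c0:cell.c1 + 1] = -1
    tissue.weights[split, cell.c0:cell.c1 + 1, :] = 0.0
    # the new cell plate takes the local (former cytoplasm) auxin level
    tissue.auxin[split, cell.c0:cell.c1 + 1] = tissue.auxin[split - 1, cell.c0:cell.c1 + 1]

    strip = tissue.strips[cell.strip]
    for cid in strip.cell_ids:
        other = tissue.cells[cid]
        if other is not cell and other.r0 > r1:
            other.r0 += 1
            other.r1 += 1

    frac = cell.length_cont - cell.length_int
    d_a = tissue.new_cell(cell.ctype, cell.side, cell.strip, cell.c0, cell.c1,
                          r0, split - 1, ctf=cell.ctf,
                          length_cont=h_a + frac)
    d_b = tissue.new_cell(cell.ctype, cell.side, cell.strip, cell.c0, cell.c1,
                          split + 1, r1 + 1, ctf=cell.ctf)
    for d in (d_a, d_b):
        d.zone = cell.zone
        d.assigned_weights = (None if cell.assigned_weights is None
                              else cell.assigned_weights.copy())
        state.clone_slot(cell.slot, d.slot)
    # replace mother in the file's ordered cell list
    k = strip.cell_ids.index(cell.id)
    strip.cell_ids[k:k + 1] = [d_a.id, d_b.id]
    state.clear_slot(cell.slot)
    tissue._free_slots.append(cell.slot)
    tissue._slot_to_id[cell.slot] = -1
    del tissue.cells[cell.id]
    tissue.paint_cell(d_a)
    tissue.paint_cell(d_b)
    events.append((t, "divide", cell.id, split))
    tissue.geometry_dirty = True
    return d_a, d_b


def cull_and_shed(tissue: Tissue, state, events: List[Event], t: float) -> None:
    """Domain-top culling and LR-cap shedding; no other removals."""
    lr_end = tissue.cfg.scaled("lrcap_mz_end")
    for si, strip in enumerate(tissue.strips):
        while True:
            top = tissue.topmost_cell(si)
            if top is None:
                break
            if top.r1 + 1 >= tissue.cfg.n_rows - 1:
                events.append((t, "cull", top.id, top.r1))
                state.clear_slot(top.slot)
                tissue.remove_cell(top, clear_kind=OUTSIDE)
                continue
            if strip.ctype == LRCAP and top.distance(tissue.cfg.dx) > lr_end:
                events.append((t, "shed", top.id, top.r0))
                state.clear_slot(top.slot)
                tissue.remove_cell(top, clear_kind=OUTSIDE)
                continue
            break


def update_zones(tissue: Tissue, state, events: List[Event], t: float,
                 th_diff: float = 85.0) -> None:
    """Re-evaluate developmental zones from position and differentiation;
    reassign membrane prepatterns on every transition."""
    cfg = tissue.cfg
    for cell in list(tissue.cells.values()):
        if cell.strip < 0:
            continue
        nz = zone_of(cell.distance(cfg.dx), cell.ctype, state.Diff[cell.slot],
                     cfg, th_diff)
        if nz != cell.zone:
            cell.zone = nz
            apply_prepattern(cell, tissue.table, tissue)
            events.append((t, "zone-change", cell.id, cell.r0))


def growth_pass(tissue: Tissue, gp: GrowthParameters, dt: float, state,
                events: List[Event], t: float) -> None:
    """One growth/division/culling sweep: grow -> insert rows -> divide ->
    cull & shed (zone transitions are applied separately after the
    differentiation update)."""
    for cell in list(tissue.cells.values()):
        if cell.id not in tissue.cells or not cell.growing or cell.strip < 0:
            continue
        grow_cell(tissue, cell, gp, dt, state, events, t)
        if (cell.id in tissue.cells and cell.zone == MZ
                and cell.length_cont >= 2.0 * cell.birth_length):
            divide_cell(tissue, cell, state, events, t)
    cull_and_shed(tissue, state, events, t)
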