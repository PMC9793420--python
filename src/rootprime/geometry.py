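"""Discrete root-tip tissue: grid layout, cells, zones and transporter prepatterns.

The tissue is a 2-D longitudinal cross-section laid out on a regular grid
(row 0 = root tip).  Each grid point is exactly one of outside / cell
interior / membrane / wall.  Cells above the curved tip are rectangles of
grid points organised in vertical files ("strips"); neighbouring files are
separated by one-point-thick vertical walls, and vertically stacked cells by
one-point-thick horizontal walls.  The curved quiescent-centre / columella /
lateral-root-cap tip is a static stepped template whose cells never grow or
divide.

Polar transport arises from membrane "prepatterns": per-face relative
placement weights for PIN, AUX1 and LAX3 that depend on cell type and
developmental zone.  Membrane carrier level = prepattern weight x cellular
expression level.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .params import GeometryConfig

# point kinds
OUTSIDE, INTERIOR, MEMBRANE, WALL = 0, 1, 2, 3
# cell types
QC, COLUMELLA, LRCAP, EPIDERMIS, CORTEX, ENDODERMIS, PERICYCLE, VASCULATURE = range(8)
CELL_TYPE_NAMES = {
    QC: "QC", COLUMELLA: "columella", LRCAP: "LR-cap", EPIDERMIS: "epidermis",
    CORTEX: "cortex", ENDODERMIS: "endodermis", PERICYCLE: "pericycle",
    VASCULATURE: "vasculature",
}
# zones
MZ, TZ, EZ, DZ = 0, 1, 2, 3
ZONE_NAMES = {MZ: "MZ", TZ: "TZ", EZ: "EZ", DZ: "DZ"}
# membrane faces
BASAL, APICAL, INNER, OUTER = 0, 1, 2, 3
# weight channels
W_PIN, W_AUX1, W_LAX3 = 0, 1, 2

GROWING_TYPES = (LRCAP, EPIDERMIS, CORTEX, ENDODERMIS, PERICYCLE, VASCULATURE)


def zone_of(distance: float, cell_type: int, diff_level: float,
            geo: GeometryConfig, th_diff: float = 85.0) -> int:
    """Developmental zone of a cell from its lower-boundary distance (um).

    Meristem (MZ) up to ``mz_end`` (LR cap: ``lrcap_mz_end``), with the
    shootward 364-514 um band flagged TZ (growing, non-dividing); elongation
    zone beyond; differentiation zone once the differentiation factor
    exceeds ``th_diff``.  Total function, monotone MZ -> TZ -> EZ in distance
    below the differentiation threshold.
    """
    mz_end = geo.scaled("lrcap_mz_end" if cell_type == LRCAP else "mz_end")
    if distance <= mz_end:
        if cell_type != LRCAP and distance > geo.scaled("tz_start"):
            return TZ
        return MZ
    if diff_level > th_diff:
        return DZ
    return EZ


# ---------------------------------------------------------------------------
# prepattern tables
# ---------------------------------------------------------------------------

@dataclass
class PrepatternTable:
    """Per (cell type, zone, face) relative weights for PIN / AUX1 / LAX3,
    plus per-type auxin production factors."""

    weights: Dict[Tuple[int, int], np.ndarray]  # (ctype, zone) -> (4 faces, 3)
    celltypefactor: Dict[int, float]

    def entry(self, ctype: int, zone: int) -> np.ndarray:
        key = (ctype, zone)
        if key not in self.weights:
            raise KeyError(
                f"no prepattern entry for ({CELL_TYPE_NAMES[ctype]}, {ZONE_NAMES[zone]})")
        return self.weights[key]


def _w(pin=(), aux1=0.0, lax3=0.0) -> np.ndarray:
    """Build a 4x3 face-weight block.  ``pin`` is a dict face->weight;
    aux1/lax3 scalars apply to all faces (apolar placement)."""
    out = np.zeros((4, 3))
    for face, val in dict(pin).items():
        out[face, W_PIN] = val
    out[:, W_AUX1] = aux1
    out[:, W_LAX3] = lax3
    return out


def default_prepattern(dz_pin_variant: str = "default") -> PrepatternTable:
    """The default transporter placement table.

    PIN polarity follows the root-tip reflux loop: rootward in stele files,
    shootward in epidermis and LR cap, inward-rotating in the elongation
    zone, and (by default) more apolar endodermal/cortical placement in the
    DZ.  The ``apolar-equal`` variant keeps endodermis and cortex DZ PIN
    identical to their EZ placement.
    """
    T: Dict[Tuple[int, int], np.ndarray] = {}
    # vasculature: rootward at all stages; in the DZ partially redirected
    # outward, passing remaining auxin on to the pericycle
    for z in (MZ, TZ):
        T[(VASCULATURE, z)] = _w({BASAL: 1.0, OUTER: 0.1}, aux1=0.3)
    T[(VASCULATURE, EZ)] = _w({BASAL: 1.0, OUTER: 0.1}, aux1=1.0, lax3=1.0)
    T[(VASCULATURE, DZ)] = _w({BASAL: 0.5, OUTER: 0.7}, aux1=1.0, lax3=1.0)
    # pericycle
    for z in (MZ, TZ):
        T[(PERICYCLE, z)] = _w({BASAL: 1.0}, aux1=0.2)
    T[(PERICYCLE, EZ)] = _w({BASAL: 0.8, INNER: 0.2}, aux1=0.6, lax3=1.0)
    T[(PERICYCLE, DZ)] = _w({BASAL: 0.3, OUTER: 0.5, INNER: 0.2}, aux1=0.6, lax3=1.0)
    # endodermis: rootward -> inward -> apolar (default) in the DZ
    for z in (MZ, TZ):
        T[(ENDODERMIS, z)] = _w({BASAL: 1.0}, aux1=0.3)
    T[(ENDODERMIS, EZ)] = _w({INNER: 0.8, BASAL: 0.2}, aux1=0.3)
    # cortex: shootward -> shootward+inward -> apolar (default) in the DZ
    for z in (MZ, TZ):
        T[(CORTEX, z)] = _w({APICAL: 1.0}, aux1=0.3)
    T[(CORTEX, EZ)] = _w({APICAL: 0.7, INNER: 0.3}, aux1=0.3)
    if dz_pin_variant == "apolar-equal":
        T[(ENDODERMIS, DZ)] = T[(ENDODERMIS, EZ)].copy()
        T[(CORTEX, DZ)] = T[(CORTEX, EZ)].copy()
    else:
        apolar = {BASAL: 0.4, APICAL: 0.4, INNER: 0.4, OUTER: 0.4}
        T[(ENDODERMIS, DZ)] = _w(apolar, aux1=0.3)
        T[(CORTEX, DZ)] = _w(apolar, aux1=0.3)
    # epidermis: shootward, turning partly inward in the EZ; the DZ
    # conveyor is largely depolarised so shootward auxin dissipates with
    # distance instead of being ferried to the domain top
    for z in (MZ, TZ):
        T[(EPIDERMIS, z)] = _w({APICAL: 1.0}, aux1=1.0)
    T[(EPIDERMIS, EZ)] = _w({APICAL: 0.8, INNER: 0.2}, aux1=1.0)
    T[(EPIDERMIS, DZ)] = _w({APICAL: 0.3, INNER: 0.3}, aux1=1.0)
    # LR cap (meristem only; shed at its zone boundary)
    T[(LRCAP, MZ)] = _w({APICAL: 1.0, OUTER: 0.2}, aux1=1.0)
    # curved-tip template types
    T[(COLUMELLA, MZ)] = _w({BASAL: 0.3, APICAL: 0.1, OUTER: 1.0}, aux1=1.0)
    T[(QC, MZ)] = _w({BASAL: 0.5}, aux1=0.5)
    ctf = {QC: 100.0, COLUMELLA: 50.0, LRCAP: 30.0, EPIDERMIS: 1.0,
           CORTEX: 1.0, ENDODERMIS: 1.0, PERICYCLE: 1.0, VASCULATURE: 1.0}
    return PrepatternTable(weights=T, celltypefactor=ctf)


# ---------------------------------------------------------------------------
# cells and tissue
# ---------------------------------------------------------------------------

@dataclass
class Cell:
    id: int
    slot: int
    ctype: int
    side: int                    # -1 left, +1 right
    strip: int                   # index into Tissue.strips (-1: cap template)
    c0: int
    c1: int
    r0: int
    r1: int
    length_cont: float           # continuous length, rows
    birth_length: int            # rows
    mean_j: int                  # centre row at creation (immutable)
    zone: int = MZ
    ctf: float = 1.0             # celltypefactor for auxin production
    growing: bool = True
    assigned_weights: Optional[np.ndarray] = None  # (4 faces, 3), current assignment

    @property
    def length_int(self) -> int:
        return self.r1 - self.r0 + 1

    def distance(self, dx: float) -> float:
        """Distance of the lower (rootward) cell boundary from the tip (um)."""
        return self.r0 * dx


@dataclass
class Strip:
    ctype: int
    side: int
    c0: int
    c1: int
    cell_ids: List[int] = field(default_factory=list)  # bottom -> top


class Tissue:
    """Grid arrays plus the cell inventory; the mutable geometric state."""

    def __init__(self, cfg: GeometryConfig, table: PrepatternTable):
        self.cfg = cfg
        self.table = table
        n, m = cfg.n_rows, cfg.n_cols
        self.point_kind = np.zeros((n, m), dtype=np.uint8)
        self.cell_slot = np.full((n, m), -1, dtype=np.int32)
        self.auxin = np.zeros((n, m), dtype=np.float64)
        self.weights = np.zeros((n, m, 3), dtype=np.float64)  # PIN/AUX1/LAX3
        self.strips: List[Strip] = []
        self.cells: Dict[int, Cell] = {}
        self._slot_to_id: List[int] = []
        self._free_slots: List[int] = []
        self._next_id = 0
        self.geometry_dirty = True

    # -- slots ------------------------------------------------------------
    @property
    def n_slots(self) -> int:
        return len(self._slot_to_id)

    def _alloc(self) -> Tuple[int, int]:
        cid = self._next_id
        self._next_id += 1
        if self._free_slots:
            slot = self._free_slots.pop()
            self._slot_to_id[slot] = cid
        else:
            slot = len(self._slot_to_id)
            self._slot_to_id.append(cid)
        return cid, slot

    def slot_of(self, cid: int) -> int:
        return self.cells[cid].slot

    def alive_slots(self) -> np.ndarray:
        return np.array([c.slot for c in self.cells.values()], dtype=np.int64)

    # -- construction helpers --------------------------------------------
    def new_cell(self, ctype, side, strip, c0, c1, r0, r1, *, ctf=1.0,
                 growing=True, birth_length=None, length_cont=None) -> Cell:
        cid, slot = self._alloc()
        h = r1 - r0 + 1
        cell = Cell(id=cid, slot=slot, ctype=ctype, side=side, strip=strip,
                    c0=c0, c1=c1, r0=r0, r1=r1,
                    length_cont=float(h if length_cont is None else length_cont),
                    birth_length=int(h if birth_length is None else birth_length),
                    mean_j=(r0 + r1) // 2, ctf=ctf, growing=growing)
        self.cells[cid] = cell
        return cell

    def remove_cell(self, cell: Cell, clear_kind: int = OUTSIDE) -> None:
        r0, r1, c0, c1 = cell.r0, cell.r1, cell.c0, cell.c1
        self.point_kind[r0:r1 + 1, c0:c1 + 1] = clear_kind
        self.cell_slot[r0:r1 + 1, c0:c1 + 1] = -1
        self.auxin[r0:r1 + 1, c0:c1 + 1] = 0.0
        self.weights[r0:r1 + 1, c0:c1 + 1, :] = 0.0
        if cell.strip >= 0:
            self.strips[cell.strip].cell_ids.remove(cell.id)
        self._free_slots.append(cell.slot)
        self._slot_to_id[cell.slot] = -1
        del self.cells[cell.id]
        self.geometry_dirty = True

    def paint_cell(self, cell: Cell) -> None:
        """Write the cell's rectangle (kinds, slot, membrane weights)."""
        r0, r1, c0, c1 = cell.r0, cell.r1, cell.c0, cell.c1
        self.point_kind[r0:r1 + 1, c0:c1 + 1] = INTERIOR
        self.point_kind[r0, c0:c1 + 1] = MEMBRANE
        self.point_kind[r1, c0:c1 + 1] = MEMBRANE
        self.point_kind[r0:r1 + 1, c0] = MEMBRANE
        self.point_kind[r0:r1 + 1, c1] = MEMBRANE
        self.cell_slot[r0:r1 + 1, c0:c1 + 1] = cell.slot
        self._paint_weights(cell)
        self.geometry_dirty = True

    def _paint_weights(self, cell: Cell) -> None:
        w = cell.assigned_weights
        r0, r1, c0, c1 = cell.r0, cell.r1, cell.c0, cell.c1
        self.weights[r0:r1 + 1, c0:c1 + 1, :] = 0.0
        if w is None:
            return
        # lateral faces first, then basal/apical rows override the corners
        outer_col, inner_col = (c0, c1) if cell.side < 0 else (c1, c0)
        self.weights[r0:r1 + 1, outer_col, :] = w[OUTER]
        self.weights[r0:r1 + 1, inner_col, :] = w[INNER]
        self.weights[r0, c0:c1 + 1, :] = w[BASAL]
        self.weights[r1, c0:c1 + 1, :] = w[APICAL]

    # -- queries ----------------------------------------------------------
    def topmost_cell(self, strip_idx: int) -> Optional[Cell]:
        ids = self.strips[strip_idx].cell_ids
        return self.cells[ids[-1]] if ids else None

    def bottom_cell(self, strip_idx: int) -> Optional[Cell]:
        ids = self.strips[strip_idx].cell_ids
        return self.cells[ids[0]] if ids else None

    def refresh_vascular_initials(self) -> None:
        """The rootward-most vasculature cell of each file carries the
        elevated (initials) auxin-production factor."""
        for s in self.strips:
            if not s.cell_ids:
                continue
            base_ctf = self.table.celltypefactor[s.ctype]
            for cid in s.cell_ids:
                self.cells[cid].ctf = base_ctf
            if s.ctype == VASCULATURE:
                self.cells[s.cell_ids[0]].ctf = 100.0


def apply_prepattern(cell: Cell, table: PrepatternTable, tissue: Tissue) -> None:
    """Assign the (cell type, zone) face weights to a cell and paint them.

    Re-invoked on every zone transition; daughters inherit the mother's
    assignment verbatim until their own next transition.
    """
    zone = MZ if cell.ctype in (QC, COLUMELLA) else cell.zone
    cell.assigned_weights = table.entry(cell.ctype, zone).copy()
    tissue._paint_weights(cell)
    tissue.geometry_dirty = True


# ---------------------------------------------------------------------------
# tissue construction
# ---------------------------------------------------------------------------

def _strip_layout(cfg: GeometryConfig) -> List[Tuple[int, int, int, int]]:
    """(ctype, side, c0, c1) for every file, left to right."""
    seq = [(LRCAP, cfg.width_lrcap), (EPIDERMIS, cfg.width_epidermis),
           (CORTEX, cfg.width_cortex), (ENDODERMIS, cfg.width_endodermis),
           (PERICYCLE, cfg.width_pericycle)]
    seq += [(VASCULATURE, cfg.width_vasculature)] * cfg.n_vasc_files
    left = []
    c = 0
    for i, (ct, w) in enumerate(seq):
        if i > 0:
            c += 1  # wall column between files
        left.append((ct, -1, c, c + w - 1))
        c += w
    centre_wall = c  # one wall column at the root axis
    if centre_wall != cfg.n_cols // 2:
        raise ValueError("geometry layout does not centre on the root axis")
    right = [(ct, 1, cfg.n_cols - 1 - c1, cfg.n_cols - 1 - c0)
             for (ct, _s, c0, c1) in left]
    return left + right[::-1]


def build_root_tissue(cfg: GeometryConfig,
                      table: Optional[PrepatternTable] = None,
                      dz_pin_variant: str = "default") -> Tissue:
    """Build the bilaterally symmetric root-tip tissue.

    Raises ``ValueError`` for geometry that cannot host all nine cell files
    (every file needs >= 2 columns; the domain must leave room for the
    curved tip template plus at least one cell per file).
    """
    for name in ("width_lrcap", "width_epidermis", "width_cortex",
                 "width_endodermis", "width_pericycle", "width_vasculature"):
        if getattr(cfg, name) < 2:
            raise ValueError(f"{name} must be >= 2 grid columns")
    if cfg.n_rows < cfg.cap_rows + 3 * (cfg.initial_cell_height + 1):
        raise ValueError("domain too short for tip template plus cell files")
    if table is None:
        table = default_prepattern(dz_pin_variant)
    t = Tissue(cfg, table)
    layout = _strip_layout(cfg)
    # vertical walls between files and at the centre
    t.point_kind[:, :] = WALL
    dx = cfg.dx
    lh = cfg.cap_layer_height
    cap_rows = cfg.cap_rows

    # how many cap layers (from the top of the template downward) each file
    # type occupies; the step pattern approximates the curved tip
    cap_occupancy = {VASCULATURE: 4, PERICYCLE: 4, ENDODERMIS: 4,
                     CORTEX: 3, EPIDERMIS: 2, LRCAP: 1}

    for ct, side, c0, c1 in layout:
        si = len(t.strips)
        t.strips.append(Strip(ctype=ct, side=side, c0=c0, c1=c1))
        # ---- curved tip template (static cells) ----
        occ = min(cap_occupancy[ct], cfg.cap_layers)
        for layer in range(cfg.cap_layers):
            r0 = layer * (lh + 1)
            r1 = r0 + lh - 1
            if layer < cfg.cap_layers - occ:
                t.point_kind[r0:r1 + 2, c0:c1 + 1] = OUTSIDE
                continue
            if ct in (VASCULATURE, PERICYCLE, ENDODERMIS):
                if layer < 2:
                    cap_ct, ctf = COLUMELLA, 50.0       # lower columella
                elif layer == 2:
                    cap_ct, ctf = COLUMELLA, 100.0      # top columella layer
                else:
                    cap_ct, ctf = (QC, 100.0) if ct == VASCULATURE else (COLUMELLA, 100.0)
            else:
                cap_ct, ctf = LRCAP, 30.0
            cell = t.new_cell(cap_ct, side, -1, c0, c1, r0, r1,
                              ctf=ctf, growing=False)
            cell.zone = MZ
            t.paint_cell(cell)
            apply_prepattern(cell, table, t)
        # ---- rectangular file ----
        h0 = cfg.initial_cell_height
        r0 = cap_rows + 1  # wall row at cap_rows
        lr_end = cfg.scaled("lrcap_mz_end")
        while r0 + h0 - 1 <= cfg.n_rows - 2:
            if ct == LRCAP and r0 * dx > lr_end:
                break
            cell = t.new_cell(ct, side, si, c0, c1, r0, r0 + h0 - 1,
                              ctf=table.celltypefactor[ct])
            t.strips[si].cell_ids.append(cell.id)
            t.paint_cell(cell)
            r0 += h0 + 1
        # everything above the file is outside the root
        top = t.topmost_cell(si)
        top_r = (top.r1 + 2) if top is not None else cap_rows + 1
        t.point_kind[top_r:, c0:c1 + 1] = OUTSIDE
        if not t.strips[si].cell_ids:
            raise ValueError("domain cannot host at least one cell per file")

    # initial zones and differentiation prepattern: cells already beyond the
    # elongation zone start as (partly) differentiated so that the initial
    # tissue is not uniformly meristematic
    for cell in t.cells.values():
        if cell.strip < 0:
            continue
        d = cell.distance(dx)
        cell.zone = zone_of(d, cell.ctype, 0.0, cfg)
        apply_prepattern(cell, table, t)
    t.refresh_vascular_initials()
    t.geometry_dirty = True
    return t


def initial_diff_profile(tissue: Tissue, th_diff: float = 85.0) -> np.ndarray:
    """Starting differentiation levels: ramp from 0 at the EZ onset to 100
    one elongation-zone-length shootward, so the upper domain begins as DZ."""
    cfg = tissue.cfg
    ez0 = cfg.scaled("mz_end")
    ramp = max(ez0, cfg.dx)  # EZ length comparable to the meristem length
    diff = np.zeros(tissue.n_slots)
    for cell in tissue.cells.values():
        d = cell.distance(cfg.dx)
        if d > ez0:
            diff[cell.slot] = min(100.0, 100.0 * (d - ez0) / ramp)
        cell.zone = zone_of(d, cell.ctype, diff[cell.slot], cfg, th_diff)
        if cell.strip >= 0:
            apply_prepattern(cell, tissue.table, tissue)
    return diff


# ---------------------------------------------------------------------------
# validation (used by the test-suite and after geometry edits)
# ---------------------------------------------------------------------------

def validate_tissue(t: Tissue) -> None:
    """Check the structural invariants; raise AssertionError on violation."""
    pk = t.point_kind
    n, m = pk.shape
    assert set(np.unique(pk)) <= {OUTSIDE, INTERIOR, MEMBRANE, WALL}
    # membrane points belong to exactly one cell and touch a wall or the
    # domain edge
    mem = np.argwhere(pk == MEMBRANE)
    for i, j in mem:
        assert t.cell_slot[i, j] >= 0
        neigh = []
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ii, jj = i + di, j + dj
            if 0 <= ii < n and 0 <= jj < m:
                neigh.append(pk[ii, jj])
            else:
                neigh.append(WALL)  # domain edge acts as a closed wall
        assert WALL in neigh or OUTSIDE in neigh
    # cell rectangles: slot map matches extents; membranes = perimeter
    for cell in t.cells.values():
        sub = t.cell_slot[cell.r0:cell.r1 + 1, cell.c0:cell.c1 + 1]
        assert (sub == cell.slot).all()
        perim = 2 * (cell.r1 - cell.r0 + 1) + 2 * (cell.c1 - cell.c0 + 1) - 4
        count = (t.point_kind[cell.r0:cell.r1 + 1, cell.c0:cell.c1 + 1]
                 == MEMBRANE).sum()
        assert count == min(perim, sub.size)
        assert 0.0 <= cell.length_cont - cell.length_int < 1.0
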