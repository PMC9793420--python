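"""Grid-level auxin dynamics.

Solves the auxin reaction-transport equation on the tissue grid with a
Peaceman-Rachford alternating-direction scheme: intracellular and apoplast
diffusion plus carrier-mediated membrane transport are treated implicitly
(tridiagonal solves along alternating axes), while production, first-order
degradation, the shootward boundary exchange and the radial (3-D-emulating)
left-right coupling are treated explicitly within the half-steps.

Membrane transport across each membrane|wall interface:

    efflux = (eff_basal + p_PIN * PIN_mem)   * auxin_cell
    influx = (inf_pas  + p_auxlax * (AUX1_mem + LAX3_mem)) * auxin_wall

with membrane carrier level = prepattern weight x cellular expression
(PIN expression is constant at 100).  Rates are permeabilities (um/s),
converted to per-second exchange rates by dividing by dx.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _adi
from .geometry import (APICAL, CORTEX, ENDODERMIS, EPIDERMIS, LRCAP, MEMBRANE,
                       PERICYCLE, Tissue, VASCULATURE, WALL, W_AUX1, W_LAX3,
                       W_PIN)
from .params import TransportParameters

INFLOW_TYPES = (VASCULATURE, PERICYCLE, ENDODERMIS)
OUTFLOW_TYPES = (EPIDERMIS, CORTEX)


def production_rate(ctf, yucca4, cell_height, params: TransportParameters,
                    reference_height: float, prod_scale: float = 1.0):
    """Per-grid-point auxin production rate (a.u. s^-1).

    Baseline rate times the cell-type factor plus the YUCCA4-dependent
    increment, normalised by cell height so that a cell's total production
    is independent of how many rows it spans.
    """
    return (params.p_auxin_baseline * prod_scale
            * (np.asarray(ctf, dtype=float) + params.yucca4factor * np.asarray(yucca4))
            * (reference_height / np.asarray(cell_height, dtype=float)))


def membrane_flux(auxin_cell, auxin_wall, pin_w, aux1_w, lax3_w,
                  pin_expr, aux1_expr, lax3_expr, params: TransportParameters):
    """(efflux, influx) across one membrane|wall interface, in a.u. um s^-1
    (divide by dx for the per-point exchange rate)."""
    efflux = (params.eff_basal + params.p_PIN * pin_w * pin_expr) * auxin_cell
    influx = (params.inf_pas + params.p_auxlax
              * (aux1_w * aux1_expr + lax3_w * lax3_expr)) * auxin_wall
    return efflux, influx


@dataclass
class _Interfaces:
    """Index arrays describing one axis' membrane|wall interfaces."""
    i: np.ndarray
    j: np.ndarray
    slot: np.ndarray
    cell_first: np.ndarray  # True: cell point on the low-index side
    wpin: np.ndarray
    waux: np.ndarray
    wlax: np.ndarray


class AuxinSolver:
    """Assembles and advances the auxin field for one tissue."""

    def __init__(self, tissue: Tissue, params: TransportParameters, dx: float,
                 radial_mode: str = "walls-only", prod_scale: float = 1.0,
                 ext_scale: float = 1.0, homeostasis_k: float = 0.0,
                 arf_max: float = 300.0):
        self.tissue = tissue
        self.p = params
        self.dx = dx
        self.radial_mode = radial_mode
        self.prod_scale = prod_scale
        self.ext_scale = ext_scale
        self.homeostasis_k = homeostasis_k
        self.arf_max = arf_max
        self.reference_height = float(tissue.cfg.initial_cell_height)
        self.negative_clips = 0
        self.rebuild()

    # ------------------------------------------------------------------
    def rebuild(self) -> None:
        """Recompute all geometry-derived structure (after growth events)."""
        t = self.tissue
        pk = t.point_kind
        cs = t.cell_slot
        dx2 = self.dx * self.dx
        Dc, Dw = self.p.D_cell / dx2, self.p.D_wall / dx2

        def diff_conductance(k_lo, k_hi, s_lo, s_hi):
            same_cell = (s_lo >= 0) & (s_lo == s_hi)
            both_wall = (k_lo == WALL) & (k_hi == WALL)
            return np.where(same_cell, Dc, 0.0) + np.where(both_wall, Dw, 0.0)

        self._gx = diff_conductance(pk[:, :-1], pk[:, 1:], cs[:, :-1], cs[:, 1:])
        self._gy = diff_conductance(pk[:-1, :], pk[1:, :], cs[:-1, :], cs[1:, :])

        def interfaces(axis):
            if axis == 0:
                k_lo, k_hi = pk[:, :-1], pk[:, 1:]
                s_lo, s_hi = cs[:, :-1], cs[:, 1:]
            else:
                k_lo, k_hi = pk[:-1, :], pk[1:, :]
                s_lo, s_hi = cs[:-1, :], cs[1:, :]
            mw = (k_lo == MEMBRANE) & (k_hi == WALL)
            wm = (k_lo == WALL) & (k_hi == MEMBRANE)
            i1, j1 = np.nonzero(mw)
            i2, j2 = np.nonzero(wm)
            i = np.concatenate([i1, i2])
            j = np.concatenate([j1, j2])
            cell_first = np.concatenate([np.ones(i1.size, bool), np.zeros(i2.size, bool)])
            if axis == 0:
                mi, mj = i, np.where(cell_first, j, j + 1)
            else:
                mi, mj = np.where(cell_first, i, i + 1), j
            slot = cs[mi, mj]
            w = t.weights[mi, mj]
            return _Interfaces(i=i, j=j, slot=slot, cell_first=cell_first,
                               wpin=w[:, W_PIN].copy(), waux=w[:, W_AUX1].copy(),
                               wlax=w[:, W_LAX3].copy())

        self._ifx = interfaces(0)
        self._ify = interfaces(1)

        # production points
        pi, pj = np.nonzero(cs >= 0)
        self._pp_i, self._pp_j = pi, pj
        self._pp_slot = cs[pi, pj]
        nslots = t.n_slots
        self._ctf = np.zeros(max(nslots, 1))
        self._height = np.ones(max(nslots, 1))
        for cell in t.cells.values():
            self._ctf[cell.slot] = cell.ctf
            self._height[cell.slot] = cell.length_int
        counts = np.bincount(self._pp_slot, minlength=max(nslots, 1))
        self._slot_counts = np.maximum(counts, 1)
        self._cell_mask = np.zeros(max(nslots, 1), bool)
        self._cell_mask[:counts.size] = counts > 0

        # shootward boundary exchange
        bi_in, bj_in, bcoef_in = [], [], []
        bi_out, bj_out, bslot_out, bwa_out, bwl_out = [], [], [], [], []
        for si, s in enumerate(t.strips):
            if not s.cell_ids:
                continue
            top = t.cells[s.cell_ids[-1]]
            r = top.r1 + 1
            if r >= t.cfg.n_rows:
                continue
            w = top.assigned_weights
            if w is None:
                continue
            cols = range(s.c0, s.c1 + 1)
            if s.ctype in INFLOW_TYPES:
                coef = (self.p.auxin_ext * self.ext_scale * self.prod_scale
                        * (self.p.eff_basal + self.p.p_PIN * self.p.pin_expression
                           * w[APICAL, W_PIN]) / self.dx)
                for c in cols:
                    if pk[r, c] == WALL:
                        bi_in.append(r); bj_in.append(c); bcoef_in.append(coef)
            elif s.ctype in OUTFLOW_TYPES:
                for c in cols:
                    if pk[r, c] == WALL:
                        bi_out.append(r); bj_out.append(c)
                        bslot_out.append(top.slot)
                        bwa_out.append(w[APICAL, W_AUX1])
                        bwl_out.append(w[APICAL, W_LAX3])
        self._b_in = (np.array(bi_in, int), np.array(bj_in, int),
                      np.array(bcoef_in, float))
        self._b_out = (np.array(bi_out, int), np.array(bj_out, int),
                       np.array(bslot_out, int), np.array(bwa_out, float),
                       np.array(bwl_out, float))

        # radial (left-right) coupling pairs
        n, m = pk.shape
        centre = m // 2
        jL = np.arange(centre)
        base_rate = self.p.D_rad * (5.0 if self.radial_mode == "enhanced" else 1.0)
        # near-axis pairs are capped: the explicit radial term must stay
        # well inside the stability limit of the splitting scheme
        rate_cap = 0.2
        ri, rj, rrate = [], [], []
        ci, cj, crate, cslotL, cslotR = [], [], [], [], []
        if self.radial_mode != "off":
            for j in jL:
                jj = m - 1 - j
                dist = (jj - j) * self.dx
                wall_rows = np.nonzero((pk[:, j] == WALL) & (pk[:, jj] == WALL))[0]
                if wall_rows.size:
                    ri.append(wall_rows)
                    rj.append(np.full(wall_rows.size, j))
                    rrate.append(np.full(wall_rows.size,
                                         min(base_rate / dist, rate_cap)))
                if self.radial_mode == "walls+cells":
                    cell_rows = np.nonzero((cs[:, j] >= 0) & (cs[:, jj] >= 0))[0]
                    if cell_rows.size:
                        ci.append(cell_rows)
                        cj.append(np.full(cell_rows.size, j))
                        crate.append(np.full(cell_rows.size,
                                             min(base_rate / dist, rate_cap)))
                        cslotL.append(cs[cell_rows, j])
                        cslotR.append(cs[cell_rows, jj])
        cat = lambda lst, dt=float: (np.concatenate(lst) if lst else np.array([], dt))
        self._rad_wall = (cat(ri, int), cat(rj, int), cat(rrate))
        self._rad_cell = (cat(ci, int), cat(cj, int), cat(crate),
                          cat(cslotL, int), cat(cslotR, int))

        shape = pk.shape
        self._fpx = np.zeros((shape[0], shape[1] - 1))
        self._fmx = np.zeros_like(self._fpx)
        self._fpy = np.zeros((shape[0] - 1, shape[1]))
        self._fmy = np.zeros_like(self._fpy)
        self._scratch = [np.empty(shape) for _ in range(3)]
        t.geometry_dirty = False

    # ------------------------------------------------------------------
    def update_transport(self, aux1_expr: np.ndarray, lax3_expr: np.ndarray,
                         aux1_factor: Optional[np.ndarray] = None) -> None:
        """Refresh the directional interface rates from current expression."""
        p = self.p
        for ifc, fp, fm, g in ((self._ifx, self._fpx, self._fmx, self._gx),
                               (self._ify, self._fpy, self._fmy, self._gy)):
            fp[:] = g
            fm[:] = g
            if ifc.i.size == 0:
                continue
            a1 = aux1_expr[ifc.slot]
            if aux1_factor is not None:
                a1 = a1 * aux1_factor[ifc.slot]
            eff = (p.eff_basal + p.p_PIN * p.pin_expression * ifc.wpin) / self.dx
            inf = (p.inf_pas + p.p_auxlax
                   * (a1 * ifc.waux + lax3_expr[ifc.slot] * ifc.wlax)) / self.dx
            cf = ifc.cell_first
            # cell on low side: efflux flows low->high, influx high->low
            fp[ifc.i[cf], ifc.j[cf]] += eff[cf]
            fm[ifc.i[cf], ifc.j[cf]] += inf[cf]
            fp[ifc.i[~cf], ifc.j[~cf]] += inf[~cf]
            fm[ifc.i[~cf], ifc.j[~cf]] += eff[~cf]

    # ------------------------------------------------------------------
    def production_field(self, yucca4: np.ndarray) -> np.ndarray:
        prod = np.zeros_like(self.tissue.auxin)
        if self._pp_i.size:
            rate = production_rate(self._ctf[self._pp_slot],
                                   yucca4[self._pp_slot],
                                   self._height[self._pp_slot],
                                   self.p, self.reference_height,
                                   self.prod_scale)
            prod[self._pp_i, self._pp_j] = rate
        return prod

    def boundary_terms(self, a: np.ndarray, aux1_expr, lax3_expr,
                       out: np.ndarray) -> None:
        """Shootward boundary: inflow above stele files, partial outflow
        (``outflow_frac`` of the influx capacity) above epidermis/cortex.
        (Diagnostic form; inside :meth:`step` the outflow is folded into
        the implicit sweep for stability.)"""
        bi, bj, coef = self._b_in
        if bi.size:
            out[bi, bj] += coef
        out -= self.outflow_sink(aux1_expr, lax3_expr) * a

    def outflow_sink(self, aux1_expr, lax3_expr) -> np.ndarray:
        """Per-point first-order boundary outflow rate (s^-1)."""
        sink = np.zeros_like(self.tissue.auxin)
        bi, bj, slot, wa, wl = self._b_out
        if bi.size:
            cap = (self.p.inf_pas + self.p.p_auxlax
                   * (aux1_expr[slot] * wa + lax3_expr[slot] * wl)) / self.dx
            sink[bi, bj] = self.p.outflow_frac * cap
        return sink

    def radial_terms(self, a: np.ndarray, out: np.ndarray,
                     effinf: Optional[np.ndarray] = None) -> None:
        """Distance-scaled passive exchange between laterally symmetric wall
        points; the walls+cells mode adds efflux/influx-ratio weighted
        exchange between symmetric cell points."""
        ri, rj, rate = self._rad_wall
        m = a.shape[1]
        if ri.size:
            jj = m - 1 - rj
            flux = rate * (a[ri, jj] - a[ri, rj])
            out[ri, rj] += flux
            out[ri, jj] -= flux
        ci, cj, rate, sL, sR = self._rad_cell
        if ci.size and effinf is not None:
            jj = m - 1 - cj
            flux = rate * (effinf[sR] * a[ci, jj] - effinf[sL] * a[ci, cj])
            out[ci, cj] += flux
            out[ci, jj] -= flux

    def decay_field(self, arf_total: Optional[np.ndarray]) -> np.ndarray:
        """Per-point degradation rate; with homeostasis enabled, cells add
        an ARF-dependent extra degradation (1 + k * ARFtotal/ARFmax)."""
        t = self.tissue
        d = np.where(t.point_kind == 0, 0.0, self.p.d_auxin)
        if self.homeostasis_k > 0.0 and arf_total is not None:
            factor = 1.0 + self.homeostasis_k * arf_total / self.arf_max
            extra = np.ones_like(d)
            extra[self._pp_i, self._pp_j] = factor[self._pp_slot]
            d = d * extra
        return d

    # ------------------------------------------------------------------
    def step(self, dt: float, yucca4: np.ndarray, aux1_expr: np.ndarray,
             lax3_expr: np.ndarray, aux1_factor: Optional[np.ndarray] = None,
             arf_total: Optional[np.ndarray] = None,
             effinf: Optional[np.ndarray] = None,
             production: bool = True) -> None:
        """Advance the field by one Peaceman-Rachford step (in place)."""
        if self.tissue.geometry_dirty:
            self.rebuild()
        self.update_transport(aux1_expr, lax3_expr, aux1_factor)
        a = self.tissue.auxin
        prod = self.production_field(yucca4) if production else np.zeros_like(a)
        decay = self.decay_field(arf_total)
        tmp, rhs, out = self._scratch
        sink = self.outflow_sink(aux1_expr, lax3_expr)

        def source(field, into):
            into[:] = prod
            into -= decay * field
            bi, bj, coef = self._b_in
            if bi.size:
                into[bi, bj] += coef
            self.radial_terms(field, into, effinf)

        # Strang composition: half reaction, implicit x half-sweep, implicit
        # y sweep, implicit x half-sweep, half reaction.  The implicit
        # sweeps are unconditionally stable, positivity-preserving and
        # mass-conserving for the stiff carrier-transport rates.
        source(a, tmp)
        np.multiply(tmp, 0.5 * dt, out=tmp)
        np.add(a, tmp, out=rhs)
        _adi.solve_x(rhs, self._fpx, self._fmx, 0.5 * dt, out)
        _adi.solve_y(out, self._fpy, self._fmy, dt, rhs, sink)
        _adi.solve_x(rhs, self._fpx, self._fmx, 0.5 * dt, out)
        source(out, tmp)
        np.multiply(tmp, 0.5 * dt, out=tmp)
        np.add(out, tmp, out=a)

        if not np.isfinite(a).all():
            raise FloatingPointError("auxin solver diverged (non-finite values)")
        neg = a < 0.0
        if neg.any():
            self.negative_clips += int(neg.sum())
            np.maximum(a, 0.0, out=a)

    # ------------------------------------------------------------------
    def cell_means(self) -> np.ndarray:
        """Mean auxin per cell slot."""
        t = self.tissue
        sums = np.bincount(self._pp_slot, weights=t.auxin[self._pp_i, self._pp_j],
                           minlength=self._slot_counts.size)
        return sums / self._slot_counts

    def total_auxin(self) -> float:
        return float(self.tissue.auxin.sum())

    # ------------------------------------------------------------------
    def compute_flux_vectors(self, aux1_expr, lax3_expr,
                             aux1_factor: Optional[np.ndarray] = None) -> dict:
        """Net membrane-flux vector per cell: vector sum of all membrane
        fluxes (outward positive), as (angle_rad, magnitude, fx, fy).
        fy > 0 points shootward, fx > 0 points to increasing column."""
        t = self.tissue
        a = t.auxin
        p = self.p
        acc = {}
        for axis, ifc in ((0, self._ifx), (1, self._ify)):
            if ifc.i.size == 0:
                continue
            a1 = aux1_expr[ifc.slot]
            if aux1_factor is not None:
                a1 = a1 * aux1_factor[ifc.slot]
            if axis == 0:
                cell_ij = (ifc.i, np.where(ifc.cell_first, ifc.j, ifc.j + 1))
                wall_ij = (ifc.i, np.where(ifc.cell_first, ifc.j + 1, ifc.j))
            else:
                cell_ij = (np.where(ifc.cell_first, ifc.i, ifc.i + 1), ifc.j)
                wall_ij = (np.where(ifc.cell_first, ifc.i + 1, ifc.i), ifc.j)
            eff, inf = membrane_flux(a[cell_ij], a[wall_ij], ifc.wpin, ifc.waux,
                                     ifc.wlax, p.pin_expression, a1,
                                     lax3_expr[ifc.slot], p)
            net = eff - inf  # outward positive
            sign = np.where(ifc.cell_first, 1.0, -1.0)  # outward direction
            for k in range(ifc.i.size):
                slot = int(ifc.slot[k])
                fx, fy = acc.get(slot, (0.0, 0.0))
                if axis == 0:
                    fx += sign[k] * net[k]
                else:
                    fy += sign[k] * net[k]
                acc[slot] = (fx, fy)
        return {slot: (float(np.arctan2(fy, fx)), float(np.hypot(fx, fy)), fx, fy)
                for slot, (fx, fy) in acc.items()}
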