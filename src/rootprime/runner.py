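"""Scenario orchestration: couple auxin transport, gene regulation and
growth into a deterministic time-stepped simulation.

Each step: one alternating-direction PDE step for auxin (using the previous
step's expression levels), then the cell-level updates (AUX/IAA
quasi-steady-state signalling, gene/EpiO/TOLS2 forward-Euler step), then a
growth/division/culling pass.  There is no random number generator anywhere:
two runs from the same configuration are bit-identical.
"""
from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import growth as gr
from . import regulation as reg
from .auxin import AuxinSolver
from .geometry import (DZ, EZ, LRCAP, MZ, PERICYCLE, TZ, VASCULATURE, Tissue,
                       build_root_tissue, initial_diff_profile)
from .params import (GeometryConfig, HOUR, ParameterSet, PulseConfig,
                     ScenarioConfig)

TRACE_COLUMNS = ["time", "cell_id", "ctype", "side", "dist", "auxin",
                 "signalling", "EpiO", "ARFtot", "ARFfree", "LAX3", "YUCCA4",
                 "TOLS2", "Diff", "zone"]


@dataclass
class SimulationOutputs:
    """Sampled fields, per-cell traces and the event log of one run."""

    config: ScenarioConfig
    times: np.ndarray                      # sampling times (s)
    kymo_signalling: np.ndarray            # time x row, left pericycle file
    kymo_auxin: np.ndarray
    inserts_below: np.ndarray              # cumulative row insertions in that file
    traces: pd.DataFrame                   # long format, TRACE_COLUMNS
    events: pd.DataFrame                   # time, kind, cell_id, row
    final_auxin: np.ndarray
    dx: float

    def trace_of(self, cell_id: int) -> pd.DataFrame:
        return self.traces[self.traces.cell_id == cell_id]


class Simulation:
    """A live simulation; ``run()`` drives it and collects outputs."""

    def __init__(self, config: ScenarioConfig):
        config.validate()
        self.config = config
        ps = config.params
        self.geo = ps.geometry
        self.tissue: Tissue = build_root_tissue(self.geo,
                                                dz_pin_variant=config.dz_pin_variant)
        self.state = reg.CellState(capacity=2 * len(self.tissue.cells),
                                   lax3_constant=ps.regulation.lax3_constant)
        diff0 = initial_diff_profile(self.tissue, ps.regulation.Th_Diff)
        self.state.ensure_capacity(diff0.size)
        self.state.Diff[:diff0.size] = diff0
        if config.feedback_mode != "none":
            # baseline induced-ARF expression level
            alive = self.tissue.alive_slots()
            self.state.ARFtot[alive] = (ps.regulation.p_ARFbasal
                                        / ps.regulation.d_ARF)
        self.solver = AuxinSolver(
            self.tissue, ps.transport, self.geo.dx,
            radial_mode=config.radial_mode,
            prod_scale=config.auxin_content_scale,
            ext_scale=config.boundary_influx_scale,
            homeostasis_k=(ps.transport.homeostasis_k
                           if config.homeostasis_enabled else 0.0),
            arf_max=(ps.regulation.p_ARFbasal + ps.regulation.p_ARFauxin)
                    / ps.regulation.d_ARF * config.arf_max_scale)
        self.t = 0.0
        self.events: List[gr.Event] = []
        self._zone_interval = max(1, int(round(10.0 / config.dt)))
        self._step_count = 0
        # left pericycle file for kymographs
        self._kymo_strip = next(i for i, s in enumerate(self.tissue.strips)
                                if s.ctype == PERICYCLE and s.side == -1)
        ks = self.tissue.strips[self._kymo_strip]
        self._kymo_col = (ks.c0 + ks.c1) // 2
        self._inserts_below = 0
        self._refresh_slot_tables()
        # sampling buffers
        self._times: List[float] = []
        self._kymo_s: List[np.ndarray] = []
        self._kymo_a: List[np.ndarray] = []
        self._ins: List[int] = []
        self._trace_rows: List[tuple] = []

    # ------------------------------------------------------------------
    def _refresh_slot_tables(self) -> None:
        """Slot-indexed masks and factors; rebuilt whenever geometry (and
        hence zones/positions) changed."""
        t = self.tissue
        t.refresh_vascular_initials()
        n = max(t.n_slots, 1)
        self._in_ez_dz = np.zeros(n)
        self._is_vp = np.zeros(n)
        self._epio_open = np.ones(n)
        self._aux1_factor = np.ones(n)
        cfg = self.config
        block_lo = self.geo.scaled("mz_end")
        block_hi = block_lo + cfg.epio_block_window * self.geo.zone_scale
        for cell in t.cells.values():
            s = cell.slot
            if cell.zone in (EZ, DZ):
                self._in_ez_dz[s] = 1.0
            if cell.ctype in (PERICYCLE, VASCULATURE):
                self._is_vp[s] = 1.0
                if (cfg.aux1_asymmetry > 0.0
                        and cell.side == cfg.aux1_asymmetry_side):
                    self._aux1_factor[s] = 1.0 - cfg.aux1_asymmetry
            if cfg.epio_block_ez_start and cell.strip >= 0:
                d = cell.distance(self.geo.dx)
                if block_lo < d <= block_hi:
                    self._epio_open[s] = 0.0
        # TOLS2 cell-adjacency graph (file neighbours + lateral contacts)
        pairs_a, pairs_b = [], []
        for si, strip in enumerate(t.strips):
            ids = strip.cell_ids
            for k in range(len(ids) - 1):
                pairs_a.append(t.cells[ids[k]].slot)
                pairs_b.append(t.cells[ids[k + 1]].slot)
            if si + 1 < len(t.strips):
                nxt = t.strips[si + 1]
                if nxt.c0 == strip.c1 + 2:  # separated by one wall column
                    for ca in ids:
                        a = t.cells[ca]
                        for cb in nxt.cell_ids:
                            b = t.cells[cb]
                            if a.r0 <= b.r1 and b.r0 <= a.r1:
                                pairs_a.append(a.slot)
                                pairs_b.append(b.slot)
        self._adjacency = (np.array(pairs_a, dtype=int),
                           np.array(pairs_b, dtype=int))
        # pulse target points
        self._pulse_mask = None
        pu = cfg.pulse
        if pu.amplitude > 0.0:
            mask = np.zeros_like(t.point_kind, dtype=bool)
            for cell in t.cells.values():
                d = cell.distance(self.geo.dx)
                if pu.region_lo <= d <= pu.region_hi:
                    mask[cell.r0:cell.r1 + 1, cell.c0:cell.c1 + 1] = True
            self._pulse_mask = mask
        # mean membrane-weight capacities for the walls+cells radial mode
        if cfg.radial_mode == "walls+cells":
            tp = self.config.params.transport
            self._effinf = np.zeros(n)
            for cell in t.cells.values():
                w = cell.assigned_weights
                if w is None:
                    continue
                effcap = tp.eff_basal + tp.p_PIN * tp.pin_expression * w[:, 0].mean()
                infcap = (tp.inf_pas + tp.p_auxlax
                          * (self.state.AUX1[cell.slot] * w[:, 1].mean()
                             + self.state.LAX3[cell.slot] * w[:, 2].mean()))
                self._effinf[cell.slot] = effcap / (effcap + infcap)
        else:
            self._effinf = None

    # ------------------------------------------------------------------
    def step(self) -> None:
        cfg = self.config
        ps = cfg.params
        dt = cfg.dt
        st = self.state
        if self.tissue.geometry_dirty:
            self._refresh_slot_tables()
            self.solver.rebuild()
            st.ensure_capacity(self.tissue.n_slots)
        n = self.solver._slot_counts.size
        st.ensure_capacity(n)

        # 1. PDE step with current expression levels
        self.solver.step(dt, st.YUCCA4[:n], st.AUX1[:n], st.LAX3[:n],
                         aux1_factor=self._aux1_factor[:n],
                         arf_total=(st.ARFtot[:n]
                                    if cfg.homeostasis_enabled else None),
                         effinf=(self._effinf[:n]
                                 if self._effinf is not None else None))
        pu = cfg.pulse
        if (self._pulse_mask is not None
                and pu.start <= self.t < pu.start + pu.duration):
            # the superimposed signal holds the target cells at the stated
            # auxin level (a clamp, not a floor: carrier recycling would
            # otherwise concentrate cells far above a floor value)
            self.tissue.auxin[self._pulse_mask] = pu.amplitude

        # 2. signalling (AUX/IAA quasi-steady state)
        means = self.solver.cell_means()
        st.auxin[:n] = means[:n]
        rp = ps.regulation
        if cfg.feedback_mode == "none":
            st.ARFfree[:n] = 0.0
            signalling = st.auxin[:n].copy()
        else:
            st.ARFfree[:n] = reg.free_arf_qss(st.auxin[:n], st.ARFtot[:n], rp,
                                              st.IAAreg[:n])
            signalling = reg.auxin_signalling(st.auxin[:n], st.ARFtot[:n],
                                              st.ARFfree[:n])
        self._signalling = signalling

        # 3. gene expression (forward Euler)
        st.AUX1[:n], st.Diff[:n] = reg.step_baseline_expression(
            st.AUX1[:n], st.Diff[:n], st.auxin[:n], self._in_ez_dz[:n], dt, rp)
        st.LAX3[:n], st.YUCCA4[:n], st.ARFtot[:n] = reg.step_feedback_expression(
            st.LAX3[:n], st.YUCCA4[:n], st.ARFtot[:n], signalling, st.Diff[:n],
            st.EpiO[:n], self._in_ez_dz[:n], self._is_vp[:n], dt, rp,
            cfg.feedback_mode, cfg.arf_max_scale)
        if cfg.feedback_mode == "epio" and self.t >= cfg.burn_in:
            # the chromatin integrator is held closed during burn-in so the
            # studied feedback engages on the established baseline root, not
            # on the start-up transient
            st.EpiO[:n] = reg.step_epio(st.EpiO[:n], signalling, dt, rp,
                                        self._epio_open[:n])
        if cfg.tols2_enabled:
            st.TOLS2[:n] = reg.step_tols2(st.TOLS2[:n], st.ARFfree[:n],
                                          self._adjacency, dt, rp)
            st.IAAreg[:n] = reg.iaareg(st.TOLS2[:n], st.ARFfree[:n], rp)

        # 4. growth / division / culling at event granularity
        if cfg.growth_enabled:
            before = len(self.events)
            gr.growth_pass(self.tissue, ps.growth, dt, st, self.events, self.t)
            for ev in self.events[before:]:
                if ev[1] == "insert":
                    cell = self.tissue.cells.get(ev[2])
                    if cell is not None and cell.strip == self._kymo_strip:
                        self._inserts_below += 1
        if self._step_count % self._zone_interval == 0:
            gr.update_zones(self.tissue, st, self.events, self.t, rp.Th_Diff)

        self.t += dt
        self._step_count += 1

    # ------------------------------------------------------------------
    def sample(self) -> None:
        t = self.tissue
        col = self._kymo_col
        slots = t.cell_slot[:, col]
        line_s = np.zeros(t.cfg.n_rows)
        ok = slots >= 0
        sig = np.zeros(self.state.capacity)
        nsig = self._signalling.size if hasattr(self, "_signalling") else 0
        if nsig:
            sig[:nsig] = self._signalling
        line_s[ok] = sig[slots[ok]]
        self._times.append(self.t)
        self._kymo_s.append(line_s)
        self._kymo_a.append(t.auxin[:, col].copy())
        self._ins.append(self._inserts_below)
        st = self.state
        for cell in t.cells.values():
            if cell.ctype not in (PERICYCLE, VASCULATURE):
                continue
            s = cell.slot
            self._trace_rows.append((
                self.t, cell.id, cell.ctype, cell.side,
                cell.distance(t.cfg.dx), st.auxin[s], sig[s], st.EpiO[s],
                st.ARFtot[s], st.ARFfree[s], st.LAX3[s], st.YUCCA4[s],
                st.TOLS2[s], st.Diff[s], cell.zone))

    # ------------------------------------------------------------------
    def run(self, duration: Optional[float] = None) -> SimulationOutputs:
        cfg = self.config
        duration = cfg.duration if duration is None else duration
        n_steps = int(round(duration / cfg.dt))
        sample_every = max(1, int(round(cfg.sampling_interval / cfg.dt)))
        burn_steps = int(round(cfg.burn_in / cfg.dt))
        for k in range(n_steps):
            self.step()
            if self._step_count > burn_steps and self._step_count % sample_every == 0:
                self.sample()
        return self.outputs()

    def outputs(self) -> SimulationOutputs:
        traces = pd.DataFrame(self._trace_rows, columns=TRACE_COLUMNS)
        events = pd.DataFrame(self.events,
                              columns=["time", "kind", "cell_id", "row"])
        return SimulationOutputs(
            config=self.config,
            times=np.asarray(self._times),
            kymo_signalling=(np.vstack(self._kymo_s) if self._kymo_s
                             else np.zeros((0, self.geo.n_rows))),
            kymo_auxin=(np.vstack(self._kymo_a) if self._kymo_a
                        else np.zeros((0, self.geo.n_rows))),
            inserts_below=np.asarray(self._ins, dtype=int),
            traces=traces, events=events,
            final_auxin=self.tissue.auxin.copy(), dx=self.geo.dx)

    def fork(self) -> "Simulation":
        """Deterministic deep copy; resuming a fork reproduces the
        uninterrupted run bit-identically."""
        return copy.deepcopy(self)


def run_scenario(config: ScenarioConfig) -> SimulationOutputs:
    """Build the tissue and run the configured scenario to completion."""
    return Simulation(config).run()


# ---------------------------------------------------------------------------
# named figure presets
# ---------------------------------------------------------------------------

PRESET_NAMES = ("baseline", "direct_feedback", "epio", "tols2",
                "symmetry_breaking", "low_auxin", "potent_arf7",
                "homeostasis", "apolar_dz_pin", "nogrowth_pulse")


def preset(name: str, fixture_scale: bool = False) -> ScenarioConfig:
    """The named in-silico experiment configurations.

    Perturbation presets build on the full model of the symmetry-breaking
    experiment where the corresponding figure does; the robustness presets
    (apolar DZ PIN, no-growth pulse) use the time-integrated model without
    AUX1 asymmetry or TOLS2 signalling.
    """
    cfg = ScenarioConfig()
    cfg.duration = 48 * HOUR
    if name == "baseline":
        cfg.feedback_mode = "none"
    elif name == "direct_feedback":
        cfg.feedback_mode = "direct"
    elif name == "epio":
        cfg.feedback_mode = "epio"
    elif name == "tols2":
        cfg.feedback_mode = "epio"
        cfg.tols2_enabled = True
    elif name == "symmetry_breaking":
        cfg.feedback_mode = "epio"
        cfg.tols2_enabled = True
        cfg.aux1_asymmetry = 0.10
        cfg.params.regulation.Km_AUX1 = 85.0
    elif name == "low_auxin":
        cfg = preset("symmetry_breaking")
        cfg.auxin_content_scale = 0.9
    elif name == "potent_arf7":
        cfg = preset("symmetry_breaking")
        cfg.arf_max_scale = 0.5
        cfg.boundary_influx_scale = 1.4
    elif name == "homeostasis":
        cfg = preset("symmetry_breaking")
        cfg.boundary_influx_scale = 1.4
        cfg.homeostasis_enabled = True
    elif name == "apolar_dz_pin":
        cfg.feedback_mode = "epio"
        cfg.dz_pin_variant = "apolar-equal"
    elif name == "nogrowth_pulse":
        cfg.feedback_mode = "epio"
        cfg.growth_enabled = False
        cfg.epio_block_ez_start = True
        # without growth the elongation-zone auxin-loading domain persists
        # indefinitely; chromatin opening is blocked across it so that only
        # the superimposed pulse can trigger the secondary response
        cfg.epio_block_window = 200.0
        geo = cfg.params.geometry
        cfg.pulse = PulseConfig(amplitude=250.0, duration=3 * HOUR,
                                start=55 * HOUR,
                                region_lo=800.0 * geo.zone_scale,
                                region_hi=1000.0 * geo.zone_scale)
        cfg.duration = 80 * HOUR
    else:
        raise KeyError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    if fixture_scale:
        make_fixture(cfg)
    return cfg


def make_fixture(cfg: ScenarioConfig, n_rows: int = 200,
                 zone_scale: float = 0.25, dt: float = 2.0) -> ScenarioConfig:
    """Shrink a configuration to the miniature test tissue (45 x 200 points,
    zone boundaries scaled to a quarter)."""
    geo = cfg.params.geometry
    geo.n_rows = n_rows
    geo.zone_scale = zone_scale
    geo.width_lrcap = geo.width_epidermis = geo.width_cortex = 2
    geo.width_endodermis = geo.width_pericycle = 2
    geo.width_vasculature = 3
    geo.n_vasc_files = 2
    cfg.dt = dt
    if cfg.pulse.amplitude > 0:
        cfg.pulse.region_lo = 800.0 * zone_scale
        cfg.pulse.region_hi = 1000.0 * zone_scale
    return cfg
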