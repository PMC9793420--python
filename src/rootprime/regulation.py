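"""Per-cell regulatory network: gene expression ODEs, ARF/AUX-IAA signalling,
the EpiO chromatin integrator and TOLS2 lateral inhibition.

All state variables are cell-level protein/state amounts (a.u.), advanced by
forward Euler at the simulation time step.  The signalling backbone:

* AUX/IAA is taken at quasi-steady state given cellular auxin (TIR1-mediated
  degradation), which yields the free fraction of the induced ARF pool;
* total auxin signalling = cellular auxin (baseline signalling through
  ubiquitous, unmodelled ARFs) + the free part of the induced ARF pool
  (the used fraction of the added signalling capacity);
* EpiO integrates signalling over time: opening saturates in signalling,
  closing is inhibited by both signalling and the open state itself, with a
  floor ``frac_min`` on the closing rate;
* a sigmoidal gate F3(EpiO) licenses the auxin-induced expression of LAX3,
  YUCCA4 and ARF in the time-integrated model.
"""
from __future__ import annotations

from typing import Tuple

import numpy as np

from .params import RegulationParameters


def hill(x, km, n=1.0):
    """Saturating (Hill) function x^n / (x^n + km^n), zero at x <= 0."""
    x = np.maximum(x, 0.0)
    if n == 1.0:
        return x / (x + km)
    xn = x ** n
    return xn / (xn + km ** n)


# ---------------------------------------------------------------------------
# signalling
# ---------------------------------------------------------------------------

def iaa_qss(auxin, params: RegulationParameters, iaareg=1.0):
    """Quasi-steady-state AUX/IAA level at the given cellular auxin."""
    return (params.pIAA * iaareg) / (params.d_IAAbasal + params.dIAATIR1 * np.maximum(auxin, 0.0))


def free_arf_qss(auxin, arf_total, params: RegulationParameters, iaareg=1.0):
    """Free ARF under AUX/IAA quasi-steady state.

    Binding equilibrium with the QSS AUX/IAA pool gives
    ARFfree = ARFtotal / (1 + (bind/unbind) * IAA_qss(auxin)); monotone
    increasing in auxin (more TIR1-mediated AUX/IAA degradation releases
    more ARF) and equal to ARFtotal when ``bind`` is zero.
    """
    seq = (params.bind / params.unbind) * iaa_qss(auxin, params, iaareg)
    return np.asarray(arf_total) / (1.0 + seq)


def auxin_signalling(auxin, arf_total, arf_free):
    """Total auxin signalling: baseline (= auxin) plus the additional
    signalling from the induced ARF pool, i.e. the total added capacity
    ``ARFtotal`` times its free (usable) fraction ``ARFfree/ARFtotal``."""
    arf_total = np.asarray(arf_total, dtype=float)
    arf_free = np.asarray(arf_free, dtype=float)
    frac = np.divide(arf_free, arf_total,
                     out=np.zeros_like(arf_free), where=arf_total > 0)
    return np.asarray(auxin, dtype=float) + arf_total * frac


# ---------------------------------------------------------------------------
# EpiO chromatin integrator
# ---------------------------------------------------------------------------

def epio_f1(signalling, p: RegulationParameters):
    return hill(signalling, p.Km_EpiO_1, p.n_EpiO_1)


def epio_f2(epio, p: RegulationParameters):
    return hill(epio, p.Km_EpiO_2, p.n_EpiO_2)


def epio_gate(epio, p: RegulationParameters):
    """F3: sigmoidal transcription gate; 0.5 at Km_trans, monotone."""
    return hill(epio, p.Km_trans, p.n_trans)


def step_epio(epio, signalling, dt, p: RegulationParameters, open_scale=1.0):
    """One Euler step of the chromatin open state.

    dEpiO/dt = open * F1(S) * (1 - EpiO/EpiO_cap)
               - close * max(frac_min, (1-F1)(1-F2(EpiO))) * EpiO.

    Opening is capacity-limited (a finite pool of chromatin sites);
    ``EpiO_cap`` is calibrated so the steady state under saturating
    signalling is exactly 100.  ``open_scale`` locally disables opening
    (blocked-activation scenarios).
    """
    f1 = epio_f1(signalling, p)
    closing = np.maximum(p.frac_min, (1.0 - f1) * (1.0 - epio_f2(epio, p)))
    de = (p.open_EpiO * open_scale * f1 * (1.0 - epio / p.EpiO_cap)
          - p.close_EpiO * closing * epio)
    return np.maximum(epio + dt * de, 0.0)


# ---------------------------------------------------------------------------
# gene expression steps
# ---------------------------------------------------------------------------

def step_baseline_expression(aux1, diff, auxin, in_ez_dz, dt,
                             p: RegulationParameters, aux1_factor=1.0):
    """AUX1 (auxin-saturating production) and the differentiation factor
    (production only outside the meristem)."""
    aux1 = aux1 + dt * (p.p_AUX1 * aux1_factor * hill(auxin, p.Km_AUX1)
                        - p.d_AUX1 * aux1)
    diff = diff + dt * (p.p_Diff * in_ez_dz - p.d_Diff * diff)
    return np.maximum(aux1, 0.0), np.maximum(diff, 0.0)


def step_feedback_expression(lax3, yucca4, arf_total, signalling, diff, epio,
                             in_ez_dz, is_vasc_peri, dt,
                             p: RegulationParameters, mode: str,
                             arf_max_scale: float = 1.0):
    """LAX3, YUCCA4 and induced-ARF dynamics for the three feedback modes.

    ``none``: LAX3 pinned at its constant level, no YUCCA4/ARF induction.
    ``direct``: auxin-induced terms gated only by differentiation (> 80).
    ``epio``: auxin-induced terms additionally gated by F3(EpiO); LAX3 is
    split into an ungated vascular part and a gated priming part.
    """
    if mode == "none":
        return (np.full_like(np.asarray(lax3, dtype=float), p.lax3_constant),
                np.maximum(yucca4 - dt * p.d_YUCCA4 * yucca4, 0.0),
                np.asarray(arf_total, dtype=float))
    gate = (np.asarray(diff) > p.diff_gate_threshold).astype(float)
    if mode == "direct":
        lax3_prod = (p.p_LAX3_basal
                     + p.p_LAX3_auxin * gate * hill(signalling, p.Km_LAX3))
        y_prod = p.p_YUCCA4 * gate * hill(signalling, p.Km_YUCCA4)
        arf_prod = (p.p_ARFbasal + arf_max_scale * p.p_ARFauxin * gate
                    * in_ez_dz * hill(signalling, p.Km_ARF))
    elif mode == "epio":
        f3 = epio_gate(epio, p)
        lax3_prod = (p.p_vasc * hill(signalling, p.Km_LAX3_vasc)
                     + p.p_priming * gate * f3 * hill(signalling, p.Km_LAX3_priming))
        y_prod = p.p_YUCCA4 * gate * f3 * hill(signalling, p.Km_YUCCA4_epio)
        arf_prod = (p.p_ARFbasal + arf_max_scale * p.p_ARFauxin * gate * f3
                    * in_ez_dz * hill(signalling, p.Km_ARF))
    else:
        raise ValueError(f"unknown feedback mode {mode!r}")
    lax3 = lax3 + dt * (lax3_prod - p.d_LAX3 * lax3)
    yucca4 = yucca4 + dt * (y_prod * is_vasc_peri * in_ez_dz - p.d_YUCCA4 * yucca4)
    arf_total = arf_total + dt * (arf_prod - p.d_ARF * arf_total)
    return (np.maximum(lax3, 0.0), np.maximum(yucca4, 0.0),
            np.maximum(arf_total, 0.0))


# ---------------------------------------------------------------------------
# TOLS2 lateral inhibition
# ---------------------------------------------------------------------------

def step_tols2(tols2, arf_free, adjacency: Tuple[np.ndarray, np.ndarray],
               dt, p: RegulationParameters):
    """TOLS2 peptide: free-ARF-dependent production, first-order decay and
    cell-to-cell diffusion over the adjacency graph (conservative)."""
    prod = p.p_TOLS2 * hill(arf_free, p.Km_TOLS2, p.n_TOLS2)
    dT = prod - p.d_TOLS2 * tols2
    a, b = adjacency
    if a.size:
        flux = p.D_TOLS2 * (tols2[b] - tols2[a])
        dT = np.asarray(dT, dtype=float).copy()
        np.add.at(dT, a, flux)
        np.add.at(dT, b, -flux)
    return np.maximum(tols2 + dt * dT, 0.0)


def iaareg(tols2, arf_free, p: RegulationParameters):
    """AUX/IAA production multiplier from TOLS2 signalling, of the form
    1 + p * saturation(TOLS2) * repression(ARFfree): equals 1 without
    TOLS2, exceeds 1 in low-free-ARF neighbours of TOLS2 sources."""
    up = hill(tols2, p.Km_IAA_1, 2.0)
    repress = 1.0 - hill(arf_free, p.Km_IAA_2, 2.0)
    return 1.0 + p.p_IAA_TOLS2 * up * repress


# ---------------------------------------------------------------------------
# state container
# ---------------------------------------------------------------------------

_FIELDS = ("AUX1", "LAX3", "YUCCA4", "Diff", "ARFtot", "EpiO", "TOLS2",
           "IAAreg", "ARFfree", "auxin")


class CellState:
    """Compact slot-indexed arrays of all per-cell regulatory variables."""

    def __init__(self, capacity: int = 64, lax3_constant: float = 40.0):
        self._lax3_constant = lax3_constant
        for f in _FIELDS:
            setattr(self, f, np.zeros(capacity))
        self.IAAreg[:] = 1.0
        self.LAX3[:] = lax3_constant

    @property
    def capacity(self) -> int:
        return self.AUX1.size

    def ensure_capacity(self, n: int) -> None:
        cap = self.capacity
        if n <= cap:
            return
        new = max(n, 2 * cap)
        for f in _FIELDS:
            arr = np.zeros(new)
            arr[:cap] = getattr(self, f)
            if f == "IAAreg":
                arr[cap:] = 1.0
            elif f == "LAX3":
                arr[cap:] = self._lax3_constant
            setattr(self, f, arr)

    def clone_slot(self, src: int, dst: int) -> None:
        self.ensure_capacity(dst + 1)
        for f in _FIELDS:
            getattr(self, f)[dst] = getattr(self, f)[src]

    def clear_slot(self, slot: int) -> None:
        for f in _FIELDS:
            getattr(self, f)[slot] = 0.0
        self.IAAreg[slot] = 1.0
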