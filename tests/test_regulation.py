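"""Signalling, gene-expression, chromatin-integrator and TOLS2 dynamics."""
import numpy as np
import pytest
from scipy.integrate import solve_ivp

from rootprime.params import RegulationParameters
from rootprime.regulation import (CellState, auxin_signalling, epio_f1,
                                  epio_gate, free_arf_qss, iaareg,
                                  step_baseline_expression, step_epio,
                                  step_feedback_expression, step_tols2)

P = RegulationParameters()
DT = 0.4


# ---------------------------------------------------------------------------
# auxin signalling / free-ARF quasi-steady state
# ---------------------------------------------------------------------------

def test_signalling_reduces_to_auxin_without_added_capacity():
    assert auxin_signalling(12.5, 0.0, 0.0) == 12.5


def test_signalling_near_zero_without_auxin():
    """Baseline ARF only and no auxin: AUX/IAA sequesters nearly all ARF."""
    free = free_arf_qss(0.0, 10.0, P)
    assert auxin_signalling(0.0, 10.0, free) < 0.1


def test_signalling_monotone_in_arf_total_at_fixed_bound_fraction():
    frac_free = 0.3
    totals = np.linspace(0, 300, 50)
    s = auxin_signalling(5.0, totals, frac_free * totals)
    assert (np.diff(s) >= 0).all()


def test_free_arf_without_binding_equals_total():
    p = RegulationParameters(bind=0.0)
    assert free_arf_qss(3.0, 123.0, p) == pytest.approx(123.0)


def test_free_arf_matches_full_ode_equilibrium():
    """QSS reduction vs long-time integration of the unreduced AUX/IAA and
    ARF-AUX/IAA complex equations, within 1 % across a log auxin grid."""
    arf_total = 200.0

    def rhs(_t, y, auxin):
        iaa, complx = y
        free = arf_total - complx
        bindflux = P.bind * free * iaa - P.unbind * complx
        d_iaa = (P.pIAA - P.d_IAAbasal * iaa - P.dIAATIR1 * auxin * iaa
                 - bindflux)
        return [d_iaa, bindflux]

    for auxin in np.logspace(-2, np.log10(500.0), 8):
        sol = solve_ivp(rhs, (0.0, 5e5), [0.0, 0.0], args=(auxin,),
                        method="Radau", rtol=1e-9, atol=1e-11)
        free_ode = arf_total - sol.y[1, -1]
        free_qss = free_arf_qss(auxin, arf_total, P)
        assert free_qss == pytest.approx(free_ode, rel=0.01)


def test_free_arf_monotone_in_auxin():
    grid = np.linspace(0.0, 500.0, 200)
    free = free_arf_qss(grid, 300.0, P)
    assert (np.diff(free) > 0).all()


# ---------------------------------------------------------------------------
# baseline expression
# ---------------------------------------------------------------------------

def _integrate_aux1(auxin, hours=40.0, p=P):
    aux1 = np.array(0.0)
    diff = np.array(0.0)
    for _ in range(int(hours * 3600 / DT)):
        aux1, diff = step_baseline_expression(aux1, diff, auxin, 0.0, DT, p)
    return float(aux1)


def test_aux1_saturating_steady_state_is_100():
    assert _integrate_aux1(1e9) == pytest.approx(100.0, abs=0.5)


def test_aux1_half_saturation():
    assert _integrate_aux1(P.Km_AUX1) == pytest.approx(50.0, abs=0.5)


def test_diff_decays_in_meristem():
    aux1, diff = np.array(0.0), np.array(20.0)
    for _ in range(1000):
        aux1, diff = step_baseline_expression(aux1, diff, 0.0, 0.0, DT, P)
    assert diff < 20.0 * np.exp(-P.d_Diff * 1000 * DT) * 1.01


# ---------------------------------------------------------------------------
# feedback expression
# ---------------------------------------------------------------------------

def _feedback_step(mode, diff, epio, signalling, lax3=0.0, y4=0.0, arf=10.0,
                   vp=1.0, ezdz=1.0):
    return step_feedback_expression(
        np.array(lax3), np.array(y4), np.array(arf), np.array(signalling),
        np.array(diff), np.array(epio), np.array(ezdz), np.array(vp), DT, P,
        mode)


@pytest.mark.parametrize("mode", ["direct", "epio"])
def test_no_induction_below_differentiation_gate(mode):
    """Diff = 50: only basal/vascular production remains in any mode."""
    lax3, y4, arf = _feedback_step(mode, diff=50.0, epio=100.0,
                                   signalling=1e6)
    _, y4_0, arf_0 = _feedback_step(mode, diff=50.0, epio=100.0, signalling=1e6,
                                    y4=0.0, arf=10.0)
    assert y4 == pytest.approx(y4_0)
    # ARF production reduced to the baseline term
    assert arf == pytest.approx(10.0 + DT * (P.p_ARFbasal - P.d_ARF * 10.0))


def test_mode_none_pins_lax3_at_constant_level():
    lax3, y4, arf = _feedback_step("none", diff=100.0, epio=100.0,
                                   signalling=1e6, lax3=0.0, arf=0.0)
    assert float(lax3) == P.lax3_constant
    assert float(arf) == 0.0


def test_epio_mode_without_open_chromatin_keeps_only_vascular_lax3():
    lax3_gated, _, _ = _feedback_step("epio", diff=100.0, epio=0.0,
                                      signalling=1e6)
    expected = DT * P.p_vasc  # saturating signalling, vascular part only
    assert float(lax3_gated) == pytest.approx(expected, rel=1e-4)


def test_arf_reaches_maximum_300_under_saturating_input():
    arf = np.array(10.0)
    lax3 = np.array(0.0)
    y4 = np.array(0.0)
    for _ in range(int(40 * 3600 / 2.0)):
        lax3, y4, arf = step_feedback_expression(
            lax3, y4, arf, np.array(1e9), np.array(100.0), np.array(100.0),
            np.array(1.0), np.array(1.0), 2.0, P, "epio")
    assert float(arf) == pytest.approx(300.0, rel=0.01)


# ---------------------------------------------------------------------------
# EpiO
# ---------------------------------------------------------------------------

def test_epio_opening_half_saturation():
    assert epio_f1(P.Km_EpiO_1, P) == pytest.approx(0.5)


def test_epio_steady_state_is_100_under_saturating_signalling():
    e = np.array(0.0)
    for _ in range(int(80 * 3600 / 2.0)):
        e = step_epio(e, 1e9, 2.0, P)
    assert float(e) == pytest.approx(100.0, rel=0.01)


def test_epio_fixed_point_at_zero():
    assert float(step_epio(np.array(0.0), 0.0, DT, P)) == 0.0


def _epio_after_pulse(duration_s, amplitude=1e6, total_s=8 * 3600.0, dt=2.0):
    e = np.array(0.0)
    t = 0.0
    while t < total_s:
        s = amplitude if t < duration_s else 0.0
        e = step_epio(e, s, dt, P)
        t += dt
    return float(e)


def test_epio_integrates_pulse_duration():
    """Equal-amplitude pulses: the longer pulse leaves more open chromatin."""
    short = _epio_after_pulse(1.0 * 3600)
    long = _epio_after_pulse(2.0 * 3600)
    assert long > short


def test_epio_amplifies_normalized_input_differences():
    """Two input traces, one scaled to 75 %: the peak-normalized EpiO gap
    exceeds the 25-a.u. normalized input gap (temporal integration)."""
    t = np.arange(0, 20 * 3600, 2.0)
    bump = 300.0 * np.exp(-0.5 * ((t - 4 * 3600) / 5400.0) ** 2)
    e_hi, e_lo = np.array(0.0), np.array(0.0)
    hi_peak = lo_peak = 0.0
    for k in range(t.size):
        e_hi = step_epio(e_hi, bump[k], 2.0, P)
        e_lo = step_epio(e_lo, 0.75 * bump[k], 2.0, P)
        hi_peak = max(hi_peak, float(e_hi))
        lo_peak = max(lo_peak, float(e_lo))
    norm_gap = 100.0 * (1.0 - lo_peak / hi_peak)
    assert norm_gap > 25.0


def test_transcription_gate_shape():
    assert epio_gate(0.0, P) == 0.0
    assert epio_gate(P.Km_trans, P) == pytest.approx(0.5)
    grid = np.linspace(0, 100, 300)
    assert (np.diff(epio_gate(grid, P)) >= 0).all()


# ---------------------------------------------------------------------------
# TOLS2 lateral inhibition
# ---------------------------------------------------------------------------

def _chain_adjacency(n):
    return (np.arange(n - 1), np.arange(1, n))


def test_tols2_stays_zero_without_free_arf():
    t = np.zeros(5)
    for _ in range(200):
        t = step_tols2(t, np.zeros(5), _chain_adjacency(5), DT, P)
    assert (t == 0).all()


def test_iaareg_is_one_without_tols2():
    assert iaareg(0.0, 50.0, P) == 1.0


def test_iaareg_represses_low_arf_neighbours():
    """High TOLS2 with little free ARF raises IAAreg above 1, which lowers
    the free-ARF level on re-evaluation (the lateral-inhibition loop)."""
    reg = iaareg(200.0, 5.0, P)
    assert reg > 1.0
    free_before = free_arf_qss(20.0, 100.0, P, 1.0)
    free_after = free_arf_qss(20.0, 100.0, P, reg)
    assert free_after < free_before
    # protection: the same TOLS2 in a high-free-ARF cell represses far less
    assert iaareg(200.0, 500.0, P) < reg


def test_tols2_pure_diffusion_conserves_total():
    p = RegulationParameters(p_TOLS2=0.0, d_TOLS2=0.0)
    t = np.array([100.0, 0.0, 0.0, 0.0])
    for _ in range(5000):
        t = step_tols2(t, np.zeros(4), _chain_adjacency(4), DT, p)
    assert t.sum() == pytest.approx(100.0, rel=1e-9)
    assert t.std() < 25.0  # spreading


# ---------------------------------------------------------------------------
# stability / state container
# ---------------------------------------------------------------------------

def test_forward_euler_stable_at_default_step(rng):
    """All state variables stay finite and non-negative under dt = 0.4 s
    from randomised initial conditions (stiffness check)."""
    n = 40
    state = CellState(capacity=n)
    state.AUX1[:] = rng.uniform(0, 100, n)
    state.LAX3[:] = rng.uniform(0, 100, n)
    state.YUCCA4[:] = rng.uniform(0, 100, n)
    state.Diff[:] = rng.uniform(0, 100, n)
    state.ARFtot[:] = rng.uniform(0, 300, n)
    state.EpiO[:] = rng.uniform(0, 100, n)
    state.TOLS2[:] = rng.uniform(0, 500, n)
    auxin = rng.uniform(0, 300, n)
    adj = _chain_adjacency(n)
    for _ in range(2000):
        state.ARFfree[:] = free_arf_qss(auxin, state.ARFtot, P, state.IAAreg)
        s = auxin_signalling(auxin, state.ARFtot, state.ARFfree)
        state.AUX1, state.Diff = step_baseline_expression(
            state.AUX1, state.Diff, auxin, 1.0, DT, P)
        state.LAX3, state.YUCCA4, state.ARFtot = step_feedback_expression(
            state.LAX3, state.YUCCA4, state.ARFtot, s, state.Diff, state.EpiO,
            1.0, 1.0, DT, P, "epio")
        state.EpiO = step_epio(state.EpiO, s, DT, P)
        state.TOLS2 = step_tols2(state.TOLS2, state.ARFfree, adj, DT, P)
        state.IAAreg = iaareg(state.TOLS2, state.ARFfree, P)
    for f in ("AUX1", "LAX3", "YUCCA4", "Diff", "ARFtot", "EpiO", "TOLS2"):
        arr = getattr(state, f)
        assert np.isfinite(arr).all() and (arr >= 0).all()
    assert (state.ARFfree <= state.ARFtot + 1e-9).all()


def test_state_clone_and_clear():
    s = CellState(capacity=2)
    s.AUX1[0] = 42.0
    s.EpiO[0] = 7.0
    s.clone_slot(0, 5)
    assert s.AUX1[5] == 42.0 and s.EpiO[5] == 7.0
    s.clear_slot(5)
    assert s.AUX1[5] == 0.0 and s.IAAreg[5] == 1.0
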