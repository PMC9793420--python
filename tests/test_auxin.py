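"""Auxin transport solver: conservation, accuracy, production and fluxes."""
import numpy as np
import pytest

from rootprime import _adi
from rootprime.auxin import AuxinSolver, membrane_flux, production_rate
from rootprime.geometry import build_root_tissue
from rootprime.params import GeometryConfig, TransportParameters
from rootprime.regulation import CellState


def closed_params(**kw) -> TransportParameters:
    """Transport parameters for a closed system (no sources or sinks)."""
    base = dict(p_auxin_baseline=0.0, d_auxin=0.0, auxin_ext=0.0,
                outflow_frac=0.0)
    base.update(kw)
    return TransportParameters(**base)


def small_tissue(params=None, radial="off"):
    geo = GeometryConfig(n_rows=80, zone_scale=0.2, width_lrcap=2,
                         width_epidermis=2, width_cortex=2,
                         width_endodermis=2, width_pericycle=2,
                         width_vasculature=3, n_vasc_files=1)
    t = build_root_tissue(geo)
    p = params if params is not None else closed_params()
    solver = AuxinSolver(t, p, geo.dx, radial_mode=radial)
    n = t.n_slots
    expr = np.full(n, 50.0)
    return t, solver, expr


# ---------------------------------------------------------------------------
# conservation / relaxation / accuracy
# ---------------------------------------------------------------------------

def test_closed_system_conserves_mass(rng):
    t, solver, expr = small_tissue()
    inside = t.point_kind > 0
    t.auxin[inside] = rng.uniform(0.0, 10.0, inside.sum())
    total0 = t.auxin.sum()
    for _ in range(25):
        before = t.auxin.sum()
        solver.step(2.0, np.zeros(t.n_slots), expr, expr, production=False)
        after = t.auxin.sum()
        assert after == pytest.approx(before, rel=1e-8)
    assert t.auxin.sum() == pytest.approx(total0, rel=1e-7)
    assert (t.auxin >= 0).all()


def test_uniform_field_relaxes_to_production_over_decay():
    """With no transport at all, every cell point relaxes to p/d."""
    p = TransportParameters(d_auxin=1e-3, auxin_ext=0.0, outflow_frac=0.0,
                            eff_basal=0.0, inf_pas=0.0, p_PIN=0.0,
                            p_auxlax=0.0, D_cell=0.0, D_wall=0.0)
    t, solver, expr = small_tissue(params=p)
    expr0 = np.zeros(t.n_slots)
    for _ in range(8000):
        solver.step(2.0, expr0, expr0, expr0)
    # pick a celltypefactor-1 cell of reference height
    cell = next(c for c in t.cells.values()
                if c.ctf == 1.0 and c.length_int == t.cfg.initial_cell_height)
    expected = p.p_auxin_baseline / p.d_auxin
    got = solver.cell_means()[cell.slot]
    assert got == pytest.approx(expected, rel=1e-3)


def _random_rates(rng, shape):
    return rng.uniform(0.0, 5.0, shape)


def test_adi_matches_explicit_euler_oracle(rng):
    """One alternating-direction step against a brute-force explicit
    finite-difference reference at dt/100 on a 20 x 20 system."""
    n = m = 20
    a0 = rng.uniform(0.0, 10.0, (n, m))
    fpx, fmx = _random_rates(rng, (n, m - 1)), _random_rates(rng, (n, m - 1))
    fpy, fmy = _random_rates(rng, (n - 1, m)), _random_rates(rng, (n - 1, m))
    dt = 0.004

    # ADI (Strang: x half, y full, x half)
    out = np.empty_like(a0)
    rhs = np.empty_like(a0)
    _adi.solve_x(a0, fpx, fmx, dt / 2, out)
    _adi.solve_y(out, fpy, fmy, dt, rhs, np.zeros_like(a0))
    _adi.solve_x(rhs, fpx, fmx, dt / 2, out)

    # independent dense oracle
    def L(a):
        d = np.zeros_like(a)
        d[:, :-1] += -fpx * a[:, :-1] + fmx * a[:, 1:]
        d[:, 1:] += fpx * a[:, :-1] - fmx * a[:, 1:]
        d[:-1, :] += -fpy * a[:-1, :] + fmy * a[1:, :]
        d[1:, :] += fpy * a[:-1, :] - fmy * a[1:, :]
        return d

    ref = a0.copy()
    sub = dt / 100.0
    for _ in range(100):
        ref = ref + sub * L(ref)

    err = np.abs(out - ref).max() / ref.max()
    assert err <= 1e-3


def test_halving_dt_changes_little():
    """Temporal convergence at the production step (0.4 s): halving dt
    changes per-cell auxin after one simulated hour by about 10 % of the
    field maximum (the directional splitting of the stiff carrier terms is
    formally first order in dt); 15 % is the stated accuracy bound."""
    results = []
    for dt in (0.4, 0.2):
        t, solver, expr = small_tissue(params=TransportParameters())
        y = np.zeros(t.n_slots)
        for _ in range(int(3600.0 / dt)):
            solver.step(dt, y, expr, expr)
        results.append(solver.cell_means()[:t.n_slots].copy())
    diff = np.abs(results[0] - results[1]).max()
    assert diff <= 0.15 * results[1].max()


# ---------------------------------------------------------------------------
# production
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("ctf,yucca,expected_factor", [
    (100.0, 0.0, 100.0),     # QC
    (30.0, 0.0, 30.0),       # LR cap
    (1.0, 100.0, 16.25),     # YUCCA4 at maximum in an ordinary cell
])
def test_production_celltype_and_yucca_factors(ctf, yucca, expected_factor):
    p = TransportParameters()
    rate = production_rate(ctf, yucca, 4.0, p, reference_height=4.0)
    assert rate == pytest.approx(expected_factor * p.p_auxin_baseline)


def test_production_height_normalisation():
    """Doubling cell height halves the per-point rate; the cell total is
    unchanged."""
    p = TransportParameters()
    r1 = production_rate(1.0, 0.0, 4.0, p, reference_height=4.0)
    r2 = production_rate(1.0, 0.0, 8.0, p, reference_height=4.0)
    assert r2 == pytest.approx(r1 / 2.0)
    assert 8.0 * r2 == pytest.approx(4.0 * r1)


# ---------------------------------------------------------------------------
# membrane flux / boundary / radial
# ---------------------------------------------------------------------------

def test_membrane_flux_components():
    p = TransportParameters(eff_basal=0.0, inf_pas=0.0)
    # zero PIN weight: no efflux regardless of expression
    eff, _ = membrane_flux(5.0, 1.0, 0.0, 1.0, 1.0, 100.0, 50.0, 40.0, p)
    assert eff == 0.0
    # zero wall auxin: no influx
    _, inf = membrane_flux(5.0, 0.0, 1.0, 1.0, 1.0, 100.0, 50.0, 40.0, p)
    assert inf == 0.0
    # PIN expression fixed at 100 with weight g: efflux = p_PIN*100*g*a_cell
    g = 0.7
    eff, _ = membrane_flux(5.0, 1.0, g, 0.0, 0.0, 100.0, 0.0, 0.0, p)
    assert eff == pytest.approx(p.p_PIN * 100.0 * g * 5.0)


def test_boundary_exchange_zero_without_external_auxin():
    t, solver, expr = small_tissue()
    out = np.zeros_like(t.auxin)
    solver.boundary_terms(np.zeros_like(t.auxin), expr, expr, out)
    assert (out == 0).all()


def test_boundary_inflow_linear_in_top_cell_pin_efflux():
    """Inflow above stele files = external auxin x the topmost cell's
    (basal + PIN) efflux capacity; doubling that capacity doubles the
    inflow coefficient."""
    p = TransportParameters(auxin_ext=0.5, eff_basal=0.0)
    t, solver, expr = small_tissue(params=p)
    coef1 = solver._b_in[2].copy()
    assert coef1.size > 0
    for cell in t.cells.values():
        if cell.assigned_weights is not None:
            cell.assigned_weights[:, 0] *= 2.0
    solver.rebuild()
    coef2 = solver._b_in[2]
    assert np.allclose(coef2, 2.0 * coef1)


def test_boundary_outflow_is_ten_percent_of_influx_capacity():
    p = TransportParameters(auxin_ext=0.0)
    t, solver, expr = small_tissue(params=p)
    a = np.zeros_like(t.auxin)
    bi, bj, slot, wa, wl = solver._b_out
    assert bi.size > 0
    a[bi, bj] = 2.0
    out = np.zeros_like(a)
    solver.boundary_terms(a, expr, expr, out)
    cap = (p.inf_pas + p.p_auxlax * (expr[slot] * wa + expr[slot] * wl)) / t.cfg.dx
    assert out[bi, bj] == pytest.approx(-2.0 * 0.10 * cap)


def test_radial_terms_vanish_for_symmetric_field(rng):
    t, solver, expr = small_tissue(radial="walls-only")
    half = rng.uniform(0, 5, (t.cfg.n_rows, t.cfg.n_cols // 2))
    a = np.concatenate([half, rng.uniform(0, 5, (t.cfg.n_rows, 1)),
                        half[:, ::-1]], axis=1)
    out = np.zeros_like(a)
    solver.radial_terms(a, out)
    assert np.abs(out).max() < 1e-12


def test_radial_rate_scales_inversely_with_distance():
    t, solver, expr = small_tissue(radial="walls-only")
    ri, rj, rate = solver._rad_wall
    m = t.cfg.n_cols
    dist = (m - 1 - 2 * rj) * t.cfg.dx
    # inverse-distance scaling wherever the near-axis stability cap is not
    # active; capped pairs sit exactly at the cap
    free = rate < 0.2
    assert free.any()
    assert np.allclose(rate[free] * dist[free], solver.p.D_rad)
    assert np.allclose(rate[~free], 0.2)


def test_radial_mode_off_adds_nothing(rng):
    t, solver, expr = small_tissue(radial="off")
    a = rng.uniform(0, 5, t.auxin.shape)
    out = np.zeros_like(a)
    solver.radial_terms(a, out)
    assert (out == 0).all()


# ---------------------------------------------------------------------------
# flux vectors
# ---------------------------------------------------------------------------

def test_flux_vector_zero_for_isolated_symmetric_cell():
    from rootprime.geometry import PERICYCLE
    t, solver, expr = small_tissue()
    # uniform auxin and apolar weights: net flux cancels on opposite faces
    # (an interior cell: domain-edge cells lack one lateral wall)
    cell = next(c for c in t.cells.values()
                if c.strip >= 0 and c.ctype == PERICYCLE)
    cell.assigned_weights = np.full((4, 3), 0.5)
    t._paint_weights(cell)
    t.auxin[:, :] = 1.0
    solver.rebuild()
    vecs = solver.compute_flux_vectors(expr, expr)
    ang, mag, fx, fy = vecs[cell.slot]
    assert abs(fx) < 1e-9 and abs(fy) < 1e-9


def test_flux_vector_points_rootward_for_basal_pin():
    from rootprime.geometry import PERICYCLE
    t, solver, expr = small_tissue()
    cell = next(c for c in t.cells.values()
                if c.strip >= 0 and c.ctype == PERICYCLE)
    w = np.zeros((4, 3))
    w[0, 0] = 1.0  # basal PIN only
    for other in t.cells.values():
        other.assigned_weights = np.zeros((4, 3))
        t._paint_weights(other)
    cell.assigned_weights = w
    t._paint_weights(cell)
    t.auxin[:, :] = 0.0
    t.auxin[cell.r0:cell.r1 + 1, cell.c0:cell.c1 + 1] = 1.0
    p = TransportParameters(eff_basal=0.0, inf_pas=0.0, auxin_ext=0.0)
    solver.p = p
    solver.rebuild()
    vecs = solver.compute_flux_vectors(np.zeros(t.n_slots), np.zeros(t.n_slots))
    ang, mag, fx, fy = vecs[cell.slot]
    assert fy < 0 and abs(fx) < 1e-9  # rootward = decreasing row


# ---------------------------------------------------------------------------
# invariants on the full fixture
# ---------------------------------------------------------------------------

def test_mass_balance_with_sources(fixture_config):
    """Per-step change in total auxin equals production - degradation +
    boundary net flux within solver tolerance."""
    t = build_root_tissue(fixture_config.params.geometry)
    p = fixture_config.params.transport
    solver = AuxinSolver(t, p, t.cfg.dx, radial_mode="walls-only")
    n = t.n_slots
    y, expr = np.zeros(n), np.full(n, 40.0)
    for _ in range(50):
        solver.step(2.0, y, expr, expr)
    before = t.auxin.sum()
    prod = solver.production_field(y)
    decay = solver.decay_field(None) * t.auxin
    bnd = np.zeros_like(t.auxin)
    solver.boundary_terms(t.auxin, expr, expr, bnd)
    expected_rate = prod.sum() - decay.sum() + bnd.sum()
    solver.step(2.0, y, expr, expr)
    change = t.auxin.sum() - before
    assert change == pytest.approx(2.0 * expected_rate, rel=0.02)


def test_left_right_symmetry_preserved(fixture_config):
    t = build_root_tissue(fixture_config.params.geometry)
    solver = AuxinSolver(t, fixture_config.params.transport, t.cfg.dx,
                         radial_mode="walls-only")
    n = t.n_slots
    y, expr = np.zeros(n), np.full(n, 40.0)
    for _ in range(400):
        solver.step(2.0, y, expr, expr)
    assert np.allclose(t.auxin, t.auxin[:, ::-1], atol=1e-9)
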