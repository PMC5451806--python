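import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from cordsim.dynamics import (
    WellMixedSystem,
    clamped_cord_rhs,
    cord_pack,
    cord_rhs,
    irreversible_steady_state,
    sphere_rhs,
    wellmixed_rhs,
)
from cordsim.geometry import build_cord_grid, build_sphere_grid
from cordsim.params import default_params
from cordsim.pk_profiles import ConstantInfusion, make_profile


@pytest.fixture(scope="module")
def p():
    return default_params()


@pytest.fixture(scope="module")
def sysm(p):
    return WellMixedSystem(V1=p.delta1, V2=p.delta2, a=p.alpha)


class TestWellMixed:
    def test_binding_equilibrium_is_fixed_point(self, p, sysm):
        c = 3.7
        state = np.array([c, c, p.C0 * c / (p.beta + c)])
        dc = wellmixed_rhs(0.0, state, p, sysm)
        assert np.all(np.abs(dc) < 1e-10)

    def test_mass_conservation_any_state(self, p, sysm, rng):
        for _ in range(20):
            c = rng.uniform(0, 100, size=3)
            dc = wellmixed_rhs(0.0, c, p, sysm)
            total = sysm.V1 * dc[0] + sysm.V2 * (dc[1] + dc[2])
            assert abs(total) < 1e-9 * np.max(np.abs(dc) + 1)

    def test_term_by_term_oracle(self, p, sysm):
        # independent transcription of the three balance equations
        C1, C2, C3 = 1.0, 0.0, 0.0
        dC1 = sysm.a * p.k1 * (C2 - C1) / sysm.V1
        dC2 = (
            sysm.a * p.k1 * (C1 - C2) / sysm.V2
            - p.k2 * C2 * (p.C0 - C3)
            + p.k_m2 * C3
        )
        dC3 = p.k2 * C2 * (p.C0 - C3) - p.k_m2 * C3
        got = wellmixed_rhs(0.0, np.array([C1, C2, C3]), p, sysm)
        np.testing.assert_allclose(got, [dC1, dC2, dC3], rtol=1e-14)


class TestIrreversibleSteadyState:
    def test_dilute_branch_all_drug_binds(self, p):
        C1_0 = 100.0  # delta*C1_0 = 6.25 < C0
        assert irreversible_steady_state(C1_0, p) == (0.0, 0.0, p.delta * C1_0)

    def test_saturated_branch(self, p):
        C1_0 = 1.0e5  # delta*C1_0 = 6250 >= C0
        free = (p.delta * C1_0 - p.C0) / (p.delta + 1.0)
        c1, c2, c3 = irreversible_steady_state(C1_0, p)
        assert (c1, c2) == (free, free) and c3 == p.C0

    def test_branches_coincide_at_knee(self, p):
        C1_0 = p.C0 / p.delta
        c1, c2, c3 = irreversible_steady_state(C1_0, p)
        assert c1 == pytest.approx(0.0, abs=1e-12)
        assert c3 == pytest.approx(p.C0, rel=1e-12)

    def test_negative_input_rejected(self, p):
        with pytest.raises(ValueError):
            irreversible_steady_state(-1.0, p)


class TestCordRhs:
    def test_zero_state_zero_profile(self, p):
        g = build_cord_grid(p)
        y = np.zeros(3 * g.n * g.m + g.m)
        dy = cord_rhs(0.0, y, g, p, lambda t: 0.0)
        assert np.all(dy == 0.0)

    def test_uniform_equilibrium_state_is_stationary(self, p):
        g = build_cord_grid(p)
        c = 2.0
        C = np.full((g.n, g.m), c)
        C3 = np.full((g.n, g.m), p.C0 * c / (p.beta + c))
        y = cord_pack(C, C, C3, np.full(g.m, c))
        dy = cord_rhs(1.0, y, g, p, ConstantInfusion(level=c, duration=1e9))
        assert np.max(np.abs(dy)) < 1e-8

    def test_interior_fluxes_cancel_in_mass_budget(self, p, rng):
        # brute-force bookkeeping: volume-weighted sum of all derivatives
        # must equal the net advective boundary flux of the vessel
        g = build_cord_grid(p)
        C1, C2 = rng.uniform(0, 5, (2, g.n, g.m))
        C3 = rng.uniform(0, p.C0, (g.n, g.m))
        Cv = rng.uniform(0, 5, g.m)
        cv_in = 3.3
        y = cord_pack(C1, C2, C3, Cv)
        dy = cord_rhs(0.0, y, g, p, lambda t: cv_in)
        N = g.n * g.m
        dC1 = dy[:N].reshape(g.n, g.m)
        dC2 = dy[N : 2 * N].reshape(g.n, g.m)
        dC3 = dy[2 * N : 3 * N].reshape(g.n, g.m)
        dCv = dy[3 * N :]
        tissue = np.sum(
            g.V[:, None] * (p.delta1 * dC1 + p.delta2 * (dC2 + dC3))
        )
        vessel = g.Vv * np.sum(dCv)
        boundary = g.Av * p.lam * (cv_in - Cv[-1])
        assert tissue + vessel == pytest.approx(boundary, rel=1e-9)


class TestClampedRhs:
    def test_axially_uniform_state_stays_uniform(self, p, rng):
        g = build_cord_grid(p)
        prof = rng.uniform(0, 4, (3, g.n))
        C1 = np.repeat(prof[0][:, None], g.m, axis=1)
        C2 = np.repeat(prof[1][:, None], g.m, axis=1)
        C3 = np.repeat(prof[2][:, None], g.m, axis=1)
        dy = clamped_cord_rhs(0.0, cord_pack(C1, C2, C3), g, p, lambda t: 1.5)
        N = g.n * g.m
        for comp in range(3):
            d = dy[comp * N : (comp + 1) * N].reshape(g.n, g.m)
            assert np.max(np.abs(d - d[:, :1])) < 1e-16 * max(1, np.max(np.abs(d)))

    def test_matches_cord_tissue_part_with_vessel_overwritten(self, p, rng):
        g = build_cord_grid(p)
        C1, C2 = rng.uniform(0, 5, (2, g.n, g.m))
        C3 = rng.uniform(0, p.C0, (g.n, g.m))
        cv = 2.2
        tissue = clamped_cord_rhs(0.0, cord_pack(C1, C2, C3), g, p, lambda t: cv)
        full = cord_rhs(0.0, cord_pack(C1, C2, C3, np.full(g.m, cv)), g, p, lambda t: cv)
        np.testing.assert_allclose(tissue, full[: 3 * g.n * g.m], rtol=1e-14)

    def test_matches_independent_radial_chain_integrator(self, p):
        """Clamped single-disc dynamics equal a separately coded 1D oracle."""
        q = p.replace(m_discs=1)
        g = build_cord_grid(q)
        pk = make_profile("pk3", level=1.0, duration=1e6)

        def radial_oracle(t, y):
            # independently written radial chain (scalar loops, 1-based maths)
            n = q.n
            C1, C2, C3 = y[:n], y[n : 2 * n], y[2 * n :]
            dC1 = np.zeros(n)
            for i in range(n):
                acc = 0.0
                if i == 0:
                    acc += g.Ar[0] * q.kv * (1.0 - C1[0])
                else:
                    acc += g.Ar[i] * q.k0 * (C1[i - 1] - C1[i])
                if i < n - 1:
                    acc += g.Ar[i + 1] * q.k0 * (C1[i + 1] - C1[i])
                acc += g.a_mem[i] * q.k1 * (C2[i] - C1[i])
                dC1[i] = acc / (q.delta1 * g.V[i])
            dC2 = np.array(
                [
                    g.a_mem[i] * q.k1 * (C1[i] - C2[i]) / (q.delta2 * g.V[i])
                    - q.k2 * C2[i] * (q.C0 - C3[i])
                    + q.k_m2 * C3[i]
                    for i in range(n)
                ]
            )
            dC3 = np.array(
                [q.k2 * C2[i] * (q.C0 - C3[i]) - q.k_m2 * C3[i] for i in range(n)]
            )
            return np.concatenate([dC1, dC2, dC3])

        y0 = np.zeros(3 * q.n)
        t_end = 2 * 3600.0
        ours = solve_ivp(
            lambda t, y: clamped_cord_rhs(t, y, g, q, pk),
            (0, t_end),
            y0,
            method="BDF",
            rtol=1e-9,
            atol=1e-13,
        )
        oracle = solve_ivp(
            radial_oracle, (0, t_end), y0, method="BDF", rtol=1e-9, atol=1e-13
        )
        np.testing.assert_allclose(
            ours.y[:, -1], oracle.y[:, -1], rtol=1e-5, atol=1e-10
        )


class TestSphereRhs:
    def test_zero_everywhere(self, p):
        g = build_sphere_grid(5 * p.d, p.d)
        dy = sphere_rhs(0.0, np.zeros(3 * g.n), g, p, lambda t: 0.0)
        assert np.all(dy == 0.0)

    def test_mass_budget_equals_surface_flux(self, p, rng):
        g = build_sphere_grid(8 * p.d, p.d)
        y = rng.uniform(0, 5, 3 * g.n)
        ext = 2.5
        dy = sphere_rhs(0.0, y, g, p, lambda t: ext)
        n = g.n
        dC1, dC2, dC3 = dy[:n], dy[n : 2 * n], dy[2 * n :]
        total = np.sum(g.V * (p.delta1 * dC1 + p.delta2 * (dC2 + dC3)))
        boundary = g.A[-1] * p.k0 * (ext - y[n - 1])
        assert total == pytest.approx(boundary, rel=1e-9)

    def test_fast_diffusion_equilibrates_to_bath(self, p):
        # with a large intercellular permeability every shell approaches the
        # external concentration under a constant bath
        q = p.replace(k0=2.5e-4)
        g = build_sphere_grid(5 * q.d, q.d)
        bath = 1.3
        pk = ConstantInfusion(level=bath, duration=1e12)
        sol = solve_ivp(
            lambda t, y: sphere_rhs(t, y, g, q, pk),
            (0, 5e5),
            np.zeros(3 * g.n),
            method="BDF",
            rtol=1e-8,
            atol=1e-12,
        )
        C1 = sol.y[: g.n, -1]
        np.testing.assert_allclose(C1, bath, rtol=1e-3)
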