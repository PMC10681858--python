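"""Semi-Lagrangian distribution solver: conservation, convergence and the
closed-form gamma stationary law of the constitutive gene.

The 1-gene oracle: with constant promoter activity the stationary density
of the drift+burst-jump equation is Gamma(shape a = km/gx, scale b = kx/gm).
Before using it as an oracle we substitute it through the discrete operator
and check the residual is at discretization level (see
test_gamma_is_discrete_fixed_point).
"""

import numpy as np
import pytest
from scipy import stats

import stocirc as sc
from stocirc import pide
from stocirc.circuit import CircuitConfigError


def gamma_on(grid, a=10.0, b=1.0):
    g = stats.gamma.pdf(grid.nodes[0], a, scale=b)
    return g / np.trapezoid(g, grid.nodes[0])


class TestGrid:
    def test_truncation_rule(self, constitutive):
        grid = pide.make_grid(constitutive, 64, safety_factor=4.0)
        assert grid.x_max == (40.0,)   # 4 x km*kx/(gm*gx)
        assert grid.nodes[0][0] == 0.0 and grid.shape == (64,)

    def test_bad_safety_factor(self, constitutive):
        with pytest.raises(CircuitConfigError):
            pide.make_grid(constitutive, 64, safety_factor=0.0)

    def test_min_points(self, constitutive):
        with pytest.raises(CircuitConfigError):
            pide.make_grid(constitutive, 8)

    def test_identical_genes_identical_axes(self, toggle):
        grid = pide.make_grid(toggle, 32)
        assert np.array_equal(grid.nodes[0], grid.nodes[1])

    def test_dimensionality_cap(self):
        topo = sc.Topology(np.zeros((4, 4), dtype=int))
        c = sc.GeneCircuit(topo, sc.KineticParameters(
            km=[5.0] * 4, kx=[5.0] * 4, gm=[5.0] * 4, gx=[1.0] * 4,
            eps=[0.0] * 4))
        with pytest.raises(CircuitConfigError, match="at most 3"):
            pide.make_grid(c, 32)


class TestBurstKernel:
    def test_density_normalized(self):
        from scipy.integrate import quad

        k = pide.BurstKernel(2.5)
        total, _ = quad(lambda y: k.density(np.array([y]))[0], 0.0, 200.0)
        assert total == pytest.approx(1.0, abs=1e-8)
        assert (k.density(np.array([-1.0])) == 0).all()

    def test_quadrature_rows_integrate_kernel_exactly(self):
        x = np.linspace(0, 40, 97)
        L = pide._burst_matrix(x, 1.7)
        # acting on f == 1 must give int_0^x beta = 1 - exp(-x/b) exactly
        assert np.allclose(L.sum(axis=1), 1 - np.exp(-x / 1.7), atol=1e-13)

    def test_tiny_burst_size_approaches_identity(self, constitutive):
        # b -> 0 makes the jump a no-op (gain cancels loss), up to quadrature
        c = constitutive.copy_with(**{"kx[0]": 5e-4})  # b = 1e-4
        grid = pide.make_grid(constitutive, 64)
        ws = pide._Workspace(c, grid)
        f = gamma_on(grid)
        gain = ws.jump_mats[0] @ f
        # interior nodes: gain ~= f (kernel is a near-delta)
        assert np.allclose(gain[5:], f[5:], rtol=0.02)


class TestStep:
    def test_mass_exactly_one_after_normalized_step(self, constitutive):
        P = pide.default_initial_field(constitutive, n_points=64)
        out = pide.step(P, constitutive, 0.002)
        assert out.mass() == pytest.approx(1.0, abs=1e-12)
        assert (out.values >= 0).all()

    def test_pure_degradation_contracts_mean(self):
        # negligible transcription: the drift alone scales the density,
        # mean(t+dt) = mean(t) * exp(-gx*dt)
        c = sc.GeneCircuit(sc.Topology(np.array([[0]])), sc.KineticParameters(
            km=[1e-9], kx=[5.0], gm=[5.0], gx=[1.0], eps=[0.0]))
        grid = pide.Grid((np.linspace(0, 40, 201),))
        g = stats.gamma.pdf(grid.nodes[0], 10.0, scale=1.0)
        P = pide.DistributionField(grid, g / np.trapezoid(g, grid.nodes[0]))
        dt = 0.02
        out = pide.step(P, c, dt, workspace=pide._Workspace(c, grid))
        assert out.mean()[0] == pytest.approx(P.mean()[0] * np.exp(-dt),
                                              rel=1e-3)

    def test_substepping_warns_on_large_dt(self, constitutive):
        P = pide.default_initial_field(constitutive, n_points=64)
        with pytest.warns(UserWarning, match="substepping"):
            out = pide.step(P, constitutive, 1.0)
        assert out.diagnostics["n_sub"] > 1
        assert out.mass() == pytest.approx(1.0, abs=1e-12)

    def test_bad_dt(self, constitutive):
        P = pide.default_initial_field(constitutive, n_points=64)
        with pytest.raises(ValueError):
            pide.step(P, constitutive, 0.0)


class TestSolve:
    def test_time_zero_returns_initial(self, constitutive):
        P0 = pide.default_initial_field(constitutive, n_points=64)
        out = pide.solve(constitutive, P0, [0.0])
        assert np.array_equal(out[0].values, P0.values)

    def test_snapshot_times_exact(self, constitutive):
        P0 = pide.default_initial_field(constitutive, n_points=64)
        out = pide.solve(constitutive, P0, [0.5, 1.25, 2.0])
        assert [f.t for f in out] == [0.5, 1.25, 2.0]

    def test_first_order_self_convergence(self, constitutive):
        grid = pide.make_grid(constitutive, 96)
        # start away from stationarity so the transient is informative
        P0 = pide.DistributionField(
            grid, stats.gamma.pdf(grid.nodes[0], 4.0, scale=2.0)).normalize()
        coarse = pide.solve(constitutive, P0, [1.0], dt=0.008)[0]
        fine = pide.solve(constitutive, P0, [1.0], dt=0.004)[0]
        l1 = np.trapezoid(np.abs(coarse.values - fine.values), grid.nodes[0])
        assert l1 < 0.01

    def test_l1_distance_to_stationary_decreases(self, constitutive):
        grid = pide.make_grid(constitutive, 128)
        target = gamma_on(grid)
        P0 = pide.DistributionField(
            grid, stats.gamma.pdf(grid.nodes[0], 3.0, scale=1.5)).normalize()
        snaps = pide.solve(constitutive, P0, [0.5, 1.0, 2.0, 4.0, 8.0])
        dists = [np.trapezoid(np.abs(s.values - target), grid.nodes[0])
                 for s in snaps]
        assert all(d1 > d2 for d1, d2 in zip(dists, dists[1:]))


class TestStationary:
    def test_gamma_is_discrete_fixed_point(self, constitutive):
        # oracle sanity: one step applied to the closed-form density moves it
        # by no more than the discretization error of a full relaxation
        grid = pide.make_grid(constitutive, 200)
        ws = pide._Workspace(constitutive, grid)
        g = gamma_on(grid)
        out = ws.substep(g.copy(), ws.dt_stable)
        drift_rate = np.trapezoid(np.abs(out - g), grid.nodes[0]) / ws.dt_stable
        assert drift_rate < 0.05   # |dP/dt| in L1, should be ~0 at the f.p.

    def test_matches_gamma_within_tolerance(self, constitutive):
        grid = pide.make_grid(constitutive, 200)
        st = pide.stationary(constitutive, grid=grid, tol=1e-5)
        l1 = np.trapezoid(np.abs(st.values - gamma_on(grid)), grid.nodes[0])
        assert l1 < 0.02
        assert st.mean()[0] == pytest.approx(10.0, rel=0.02)  # Gamma mean a*b

    def test_grid_refinement_reduces_error(self, constitutive):
        errors = []
        for n in (50, 100, 200):
            grid = pide.make_grid(constitutive, n)
            st = pide.stationary(constitutive, grid=grid, tol=1e-5)
            errors.append(np.trapezoid(np.abs(st.values - gamma_on(grid)),
                                       grid.nodes[0]))
        assert errors[0] > errors[1] > errors[2]

    def test_toggle_switch_is_bimodal(self, toggle):
        st = pide.stationary(toggle, grid=pide.make_grid(toggle, 64), tol=3e-5)
        maxima = st.local_maxima()
        vals = sorted((float(st.values[ix]) for ix in maxima), reverse=True)
        assert len(maxima) >= 2
        # the two dominant modes are comparable (symmetric switch)
        assert vals[1] > 0.25 * vals[0]

    def test_nonconvergence_raises(self, constitutive):
        with pytest.raises(pide.PIDENonConvergence) as err:
            pide.stationary(constitutive, tol=1e-12, max_iter=100,
                            grid=pide.make_grid(constitutive, 64))
        assert err.value.last_change > 0


class TestFieldContainer:
    def test_default_initial_field_is_product_of_gammas(self, toggle):
        fld = pide.default_initial_field(toggle, n_points=48)
        assert fld.mass() == pytest.approx(1.0, abs=1e-9)
        nodes, marg = fld.marginal(0)
        a = toggle.params.km[0] / toggle.params.gx[0]
        b = toggle.params.burst_size[0]
        expect = stats.gamma.pdf(nodes, a, scale=b)
        expect /= np.trapezoid(expect, nodes)
        assert np.trapezoid(np.abs(marg - expect), nodes) < 1e-6

    def test_mean_and_marginal_consistency(self, constitutive):
        fld = pide.default_initial_field(constitutive, n_points=200)
        assert fld.mean()[0] == pytest.approx(10.0, rel=1e-3)

    def test_bin_masses_sum_to_total(self, constitutive):
        fld = pide.default_initial_field(constitutive, n_points=200)
        edges = np.linspace(0, 40, 21)
        m = fld.bin_masses(0, edges)
        assert m.sum() == pytest.approx(1.0, abs=1e-6)
        assert (m >= 0).all()

    def test_text_io_roundtrip_1d_2d(self, tmp_path, constitutive, toggle):
        for circ, n in ((constitutive, 64), (toggle, 24)):
            fld = pide.default_initial_field(circ, n_points=max(n, 16))
            fld.t = 1.5
            path = tmp_path / f"f{circ.n_genes}.tsv"
            pide.write_field(fld, path)
            back = pide.read_field(path)
            assert back.t == 1.5
            assert np.allclose(back.values, fld.values, atol=1e-10)
            assert np.allclose(back.grid.nodes[0], fld.grid.nodes[0])
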