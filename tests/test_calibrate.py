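"""KL cost, histogram datasets and parameter-recovery behavior."""

import numpy as np
import pytest

import stocirc as sc
from stocirc import pide
from stocirc.calibrate import (CalibrationModel, CalibrationProblem,
                               FreeParameter, HistogramDataset,
                               calibration_cost, kl_divergence)


class TestKLDivergence:
    def test_identical_histograms_zero(self):
        p = np.array([0.2, 0.3, 0.5])
        assert kl_divergence(p, p) == pytest.approx(0.0, abs=1e-10)

    def test_hand_computed_two_bin_value(self):
        # 0.5*ln 2 + 0.5*ln(2/3), summed by hand
        expect = 0.5 * np.log(2.0) + 0.5 * np.log(2.0 / 3.0)
        assert kl_divergence([0.5, 0.5], [0.25, 0.75]) == pytest.approx(
            expect, abs=1e-12)
        assert expect == pytest.approx(0.1438, abs=5e-5)

    def test_point_mass_against_uniform(self):
        assert kl_divergence([1.0, 0.0], [0.5, 0.5]) == pytest.approx(
            np.log(2.0), abs=1e-12)

    def test_asymmetric(self):
        p, q = [0.9, 0.1], [0.4, 0.6]
        assert kl_divergence(p, q) != pytest.approx(kl_divergence(q, p))

    def test_empty_model_bins_floored_not_infinite(self):
        val = kl_divergence([0.5, 0.5], [1.0, 0.0])
        assert np.isfinite(val) and val > 5

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            kl_divergence([1.0], [0.5, 0.5])

    def test_nonnegative_on_random_pairs(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            p = rng.dirichlet(np.ones(8))
            q = rng.dirichlet(np.ones(8))
            assert kl_divergence(p, q) >= 0


class TestHistogramDataset:
    def make(self):
        edges = np.linspace(0, 10, 6)
        h = np.array([0.1, 0.2, 0.4, 0.2, 0.1])
        return HistogramDataset([1.0, 2.0], {0: edges},
                                [{0: h}, {0: h[::-1].copy()}])

    def test_roundtrip(self, tmp_path):
        ds = self.make()
        path = tmp_path / "ds.tsv"
        ds.write(path)
        back = HistogramDataset.read(path)
        assert np.allclose(back.times, ds.times)
        assert np.allclose(back.bin_edges[0], ds.bin_edges[0])
        for a, b in zip(back.marginals, ds.marginals):
            assert np.allclose(a[0], b[0])

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            HistogramDataset([1.0], {0: np.linspace(0, 1, 3)},
                             [{0: np.array([0.5, 0.6])}])

    def test_from_samples_bins_raw_data(self):
        samples = np.zeros((200, 1, 1))
        samples[:100, 0, 0] = 1.5
        samples[100:, 0, 0] = 4.5
        ds = HistogramDataset.from_samples(
            [1.0], samples, [0], {0: np.array([0.0, 3.0, 6.0])})
        assert np.allclose(ds.marginals[0][0], [0.5, 0.5])
        assert ds.n_samples == 200


def pide_dataset(truth, times, edges, n_points, genes=(0,)):
    """Synthetic histogram time series solved from the model itself."""
    grid = pide.make_grid(truth, n_points)
    fields = pide.solve(truth, pide.default_initial_field(truth, grid),
                        np.asarray(times, float))
    marg = []
    for f in fields:
        entry = {}
        for g in genes:
            m = f.bin_masses(g, edges)
            entry[g] = m / m.sum()
        marg.append(entry)
    return HistogramDataset(np.asarray(times, float),
                            {g: edges for g in genes}, marg)


class TestCalibrationCost:
    def setup_method(self):
        self.template = sc.load_fixture("constitutive_1gene")
        self.truth_km = 13.0
        truth = self.template.copy_with(**{"km[0]": self.truth_km})
        self.edges = np.linspace(0, 60, 31)
        self.ds = pide_dataset(truth, [1.0, 3.0], self.edges, 64)
        self.problem = CalibrationProblem(
            self.template, [FreeParameter("km[0]", 2.0, 50.0)], self.ds,
            simulator="pide", budget=40, seed=3, n_points=64)

    def test_cost_vanishes_at_generating_parameters(self):
        c = calibration_cost(np.array([np.log10(self.truth_km)]), self.problem)
        assert c < 1e-6

    def test_truth_beats_random_perturbations(self):
        rng = np.random.default_rng(8)
        c0 = calibration_cost(np.array([np.log10(self.truth_km)]), self.problem)
        for _ in range(20):
            z = np.log10(self.truth_km) + rng.uniform(-0.4, 0.4)
            z = np.clip(z, np.log10(2.0), np.log10(50.0))
            assert calibration_cost(np.array([z]), self.problem) >= c0

    def test_simulation_failure_gives_finite_penalty(self, monkeypatch):
        monkeypatch.setattr(pide, "solve",
                            lambda *a, **k: 1 / 0)  # raises ZeroDivisionError
        val = calibration_cost(np.array([1.0]), self.problem)
        assert np.isfinite(val) and val >= 1e6

    def test_ssa_backend_self_consistent(self):
        # SSA-generated data scored by the SSA backend at the generating
        # parameters: only sampling noise remains, and wrong parameters
        # score clearly worse
        from stocirc.fixtures import make_pseudo_data

        truth = self.template.copy_with(**{"km[0]": self.truth_km})
        ds, _ = make_pseudo_data(truth, [5.0, 15.0], n_samples=4000, seed=31)
        prob = CalibrationProblem(
            self.template, [FreeParameter("km[0]", 2.0, 50.0)], ds,
            simulator="ssa", ssa_runs=4000, budget=10, seed=3)
        c_truth = calibration_cost(np.array([np.log10(self.truth_km)]), prob)
        c_half = calibration_cost(np.array([np.log10(self.truth_km / 2)]), prob)
        assert 0 <= c_truth < 0.05
        assert c_half > 5 * c_truth


class TestFit:
    def test_single_parameter_recovered_within_ten_percent(self):
        template = sc.load_fixture("constitutive_1gene")
        truth = template.copy_with(**{"km[0]": 13.0})
        edges = np.linspace(0, 60, 31)
        ds = pide_dataset(truth, [1.0, 3.0, 8.0], edges, 64)
        res = CalibrationModel(CalibrationProblem(
            template, [FreeParameter("km[0]", 2.0, 50.0)], ds,
            simulator="pide", budget=60, seed=3, n_points=64)).fit()
        assert res.params["km[0]"] == pytest.approx(13.0, rel=0.10)
        assert (np.diff(res.optimresult.trace) <= 0).all()

    def test_only_identifiable_combination_constrained_by_stationary_data(self):
        # a single stationary snapshot pins the gamma shape a = km/gx, not
        # km and gx individually
        template = sc.load_fixture("constitutive_1gene")
        truth = template.copy_with(**{"km[0]": 15.0, "gx[0]": 1.5})  # a = 10
        edges = np.linspace(0, 60, 31)
        ds = pide_dataset(truth, [25.0], edges, 64)
        res = CalibrationModel(CalibrationProblem(
            template,
            [FreeParameter("km[0]", 2.0, 60.0), FreeParameter("gx[0]", 0.3, 5.0)],
            ds, simulator="pide", budget=80, seed=11, n_points=64)).fit()
        a_hat = res.params["km[0]"] / res.params["gx[0]"]
        assert a_hat == pytest.approx(10.0, rel=0.10)

    def test_zero_budget_returns_best_of_initial_sampling(self):
        template = sc.load_fixture("constitutive_1gene")
        edges = np.linspace(0, 60, 16)
        ds = pide_dataset(template, [2.0], edges, 48)
        res = CalibrationModel(CalibrationProblem(
            template, [FreeParameter("km[0]", 2.0, 50.0)], ds,
            budget=0, seed=1, n_points=48)).fit()
        assert np.isfinite(res.cost)
        assert res.optimresult.n_eval == 10

    def test_no_free_parameters_rejected(self):
        template = sc.load_fixture("constitutive_1gene")
        edges = np.linspace(0, 60, 16)
        ds = pide_dataset(template, [2.0], edges, 48)
        with pytest.raises(ValueError, match="free"):
            CalibrationModel(CalibrationProblem(template, [], ds)).fit()

    def test_summary_and_stderr(self):
        template = sc.load_fixture("constitutive_1gene")
        truth = template.copy_with(**{"km[0]": 13.0})
        edges = np.linspace(0, 60, 31)
        ds = pide_dataset(truth, [2.0], edges, 48)
        ds.n_samples = 5000
        res = CalibrationModel(CalibrationProblem(
            template, [FreeParameter("km[0]", 2.0, 50.0)], ds,
            budget=40, seed=2, n_points=48)).fit(compute_stderr=True)
        text = res.summary()
        assert "km[0]" in text and "log10" in text
        se = res._stderr
        assert se.shape == (1,) and (np.isnan(se) | (se > 0)).all()


class TestJointHistograms:
    def make_joint_dataset(self, truth, times, edges, n_points):
        grid = pide.make_grid(truth, n_points)
        fields = pide.solve(truth, pide.default_initial_field(truth, grid),
                            np.asarray(times, float))
        joints = []
        for f in fields:
            J = f.bin_masses_2d((0, 1), edges, edges)
            joints.append(J / J.sum())
        marg = [{0: J.sum(axis=1), 1: J.sum(axis=0)} for J in joints]
        return HistogramDataset(np.asarray(times, float), {0: edges, 1: edges},
                                marg, joint=joints, joint_genes=(0, 1))

    def test_joint_masses_sum_to_one(self, toggle):
        fld = pide.default_initial_field(toggle, n_points=48)
        edges = np.linspace(0, 64, 17)
        J = fld.bin_masses_2d((0, 1), edges, edges)
        assert J.sum() == pytest.approx(1.0, abs=1e-6)
        assert (J >= 0).all()
        # joint marginal matches the 1-D bin masses
        assert np.allclose(J.sum(axis=1), fld.bin_masses(0, edges), atol=1e-8)

    def test_joint_cost_vanishes_at_truth_and_discriminates(self, toggle):
        truth = toggle.copy_with(**{"km[0]": 20.0})
        edges = np.linspace(0, 80, 21)
        ds = self.make_joint_dataset(truth, [2.0, 6.0], edges, 48)
        prob = CalibrationProblem(
            toggle, [FreeParameter("km[0]", 4.0, 64.0)], ds,
            simulator="pide", budget=10, seed=0, n_points=48)
        c_truth = calibration_cost(np.array([np.log10(20.0)]), prob)
        c_off = calibration_cost(np.array([np.log10(40.0)]), prob)
        assert c_truth < 1e-4
        assert c_off > 100 * max(c_truth, 1e-8)

    def test_joint_io_roundtrip(self, tmp_path, toggle):
        edges = np.linspace(0, 80, 11)
        ds = self.make_joint_dataset(toggle, [2.0], edges, 32)
        path = tmp_path / "joint.tsv"
        ds.write_joint(path)
        back = HistogramDataset.read_joint(path)
        assert back.joint_genes == (0, 1)
        assert np.allclose(back.joint[0], ds.joint[0], atol=1e-9)
        assert np.allclose(back.bin_edges[0], edges)
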