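"""Maximum-likelihood calibration of circuit parameters from histogram data.

Observed data are histogram snapshots of protein levels at sampling times
(flow-cytometry style).  For a candidate parameter vector the model
distribution is simulated (PIDE solver by default, SSA ensemble optionally),
aggregated onto the data bins, and scored by the Kullback-Leibler divergence
summed over sampling times and observed genes.  For histogram data with
large sample counts, minimizing this KL cost is equivalent to maximizing
the multinomial likelihood up to an additive constant, which is why the
procedure is a maximum-likelihood surrogate.

The public surface follows the Model/Results convention:
``CalibrationModel(problem).fit()`` returns a :class:`CalibrationResults`
carrying estimates, the optimizer trace and a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import pide, ssa
from .circuit import GeneCircuit
from .optimize import MINLPProblem, OptimResult, minimize

__all__ = [
    "kl_divergence", "HistogramDataset", "CalibrationProblem",
    "CalibrationModel", "CalibrationResults", "calibration_cost", "fit",
]

EPS_FLOOR = 1e-12          # pseudo-mass floor for model bins (avoids log 0)
PENALTY_BASE = 1e6


def kl_divergence(p_data: np.ndarray, q_model: np.ndarray,
                  eps_floor: float = EPS_FLOOR) -> float:
    """KL(p || q) = sum_k p_k ln(p_k / q_k) in nats over shared bins.

    The model histogram is floored at ``eps_floor`` per bin (then
    renormalized) so empty model bins do not produce infinities.
    """
    p = np.asarray(p_data, dtype=float)
    q = np.asarray(q_model, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"histogram shapes differ: {p.shape} vs {q.shape}")
    q = np.maximum(q, eps_floor)
    q = q / q.sum()
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


@dataclass
class HistogramDataset:
    """Distribution snapshots of selected genes at sampling times.

    ``marginals[k][g]`` is the observed histogram of gene ``g`` at
    ``times[k]`` over ``bin_edges[g]``.  A 2-D joint per time can be supplied
    instead (``joint`` + ``joint_genes``).  Histograms must each sum to 1.
    """

    times: np.ndarray
    bin_edges: dict                      # gene index -> edges
    marginals: list                      # per time: {gene: masses}
    joint: Optional[list] = None         # per time: 2-D mass array
    joint_genes: Optional[tuple] = None
    n_samples: Optional[int] = None

    def __post_init__(self) -> None:
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        if len(self.marginals) != self.times.size:
            raise ValueError("need one marginal set per sampling time")
        for entry in self.marginals:
            for g, h in entry.items():
                h = np.asarray(h, dtype=float)
                if abs(h.sum() - 1.0) > 1e-9:
                    raise ValueError(f"histogram for gene {g} does not sum to 1")
                if h.size != len(self.bin_edges[g]) - 1:
                    raise ValueError(f"histogram/bin mismatch for gene {g}")
                entry[g] = h
        if self.joint is not None:
            if self.joint_genes is None or len(self.joint) != self.times.size:
                raise ValueError("joint histograms need joint_genes and one "
                                 "entry per time")
            for J in self.joint:
                if abs(np.asarray(J).sum() - 1.0) > 1e-9:
                    raise ValueError("joint histogram does not sum to 1")

    @property
    def genes(self) -> list:
        return sorted(self.bin_edges)

    def write_joint(self, path) -> None:
        """Long-format 2-D joints: time, bin_i, bin_j, mass (bin indices
        into the edge header lines)."""
        if self.joint is None:
            raise ValueError("dataset has no joint histograms")
        ga, gb = self.joint_genes
        with open(path, "w") as fh:
            fh.write(f"# joint_genes\t{ga}\t{gb}\n")
            for g in (ga, gb):
                fh.write(f"# edges_{g}\t"
                         + "\t".join(f"{v:.10g}" for v in self.bin_edges[g])
                         + "\n")
            fh.write("time\tbin_i\tbin_j\tmass\n")
            for k, t in enumerate(self.times):
                J = self.joint[k]
                for i in range(J.shape[0]):
                    for j in range(J.shape[1]):
                        fh.write(f"{t:g}\t{i}\t{j}\t{J[i, j]:.10g}\n")

    @classmethod
    def read_joint(cls, path) -> "HistogramDataset":
        edges = {}
        genes = None
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    parts = line[1:].strip().split("\t")
                    if parts[0] == "joint_genes":
                        genes = (int(parts[1]), int(parts[2]))
                    elif parts[0].startswith("edges_"):
                        edges[int(parts[0][6:])] = np.array(
                            [float(v) for v in parts[1:]])
                elif line.strip() and not line.startswith("time"):
                    rows.append([float(v) for v in line.split("\t")])
        data = np.array(rows)
        times = np.unique(data[:, 0])
        ga, gb = genes
        shape = (edges[ga].size - 1, edges[gb].size - 1)
        joints, marginals = [], []
        for t in times:
            sub = data[data[:, 0] == t]
            J = np.zeros(shape)
            J[sub[:, 1].astype(int), sub[:, 2].astype(int)] = sub[:, 3]
            joints.append(J)
            marginals.append({ga: J.sum(axis=1), gb: J.sum(axis=0)})
        return cls(times, edges, marginals, joint=joints, joint_genes=genes)

    def write(self, path) -> None:
        """Long-format delimited text: time, gene, bin_low, bin_high, mass."""
        rows = []
        for k, t in enumerate(self.times):
            for g, h in sorted(self.marginals[k].items()):
                e = self.bin_edges[g]
                for b, m in enumerate(h):
                    rows.append((t, g, e[b], e[b + 1], m))
        pd.DataFrame(rows, columns=["time", "gene", "bin_low", "bin_high", "mass"]) \
            .to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "HistogramDataset":
        df = pd.read_csv(path, sep="\t")
        times = np.sort(df["time"].unique())
        bin_edges = {}
        for g, sub in df.groupby("gene"):
            sub0 = sub[sub["time"] == times[0]].sort_values("bin_low")
            bin_edges[int(g)] = np.concatenate(
                [sub0["bin_low"].to_numpy(), sub0["bin_high"].to_numpy()[-1:]])
        marginals = []
        for t in times:
            entry = {}
            for g, sub in df[df["time"] == t].groupby("gene"):
                entry[int(g)] = sub.sort_values("bin_low")["mass"].to_numpy()
            marginals.append(entry)
        return cls(times, bin_edges, marginals)

    @classmethod
    def from_samples(cls, times, samples: np.ndarray, genes: Sequence[int],
                     bin_edges: dict) -> "HistogramDataset":
        """Bin raw per-run protein samples (n_runs, n_times, n_genes) onto a
        stated grid (dot-display ingestion; no density estimation)."""
        marginals = []
        for k in range(len(times)):
            entry = {}
            for g in genes:
                h, _ = np.histogram(samples[:, k, g], bins=bin_edges[g])
                entry[g] = h / h.sum()
            marginals.append(entry)
        return cls(np.asarray(times, float), dict(bin_edges), marginals,
                   n_samples=samples.shape[0])


@dataclass
class FreeParameter:
    """A searched circuit entry, e.g. key='km[0]' with bounds in natural
    units; rate-like parameters default to a log10 search scale."""

    key: str
    lower: float
    upper: float
    log_scale: bool = True

    def to_search(self, value: float) -> float:
        return math.log10(value) if self.log_scale else value

    def from_search(self, z: float) -> float:
        return 10.0 ** z if self.log_scale else z

    @property
    def search_bounds(self) -> tuple:
        if self.log_scale:
            if not (self.lower > 0 and self.upper > 0):
                raise ValueError(f"log-scale bounds for {self.key} must be > 0")
            return math.log10(self.lower), math.log10(self.upper)
        return self.lower, self.upper


@dataclass
class CalibrationProblem:
    """Fixed-topology estimation problem: template circuit, free parameters
    with bounds, dataset, simulator backend and optimizer budget."""

    template: GeneCircuit
    free: list                      # of FreeParameter
    dataset: HistogramDataset
    simulator: str = "pide"         # 'pide' | 'ssa'
    budget: int = 300
    seed: int = 0
    n_points: int = 64              # PIDE grid points per dimension
    dt: Optional[float] = None
    ssa_runs: int = 2000
    grid: Optional[pide.Grid] = None

    def __post_init__(self) -> None:
        if self.simulator not in ("pide", "ssa"):
            raise ValueError("simulator must be 'pide' or 'ssa'")
        keys = [f.key for f in self.free]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate free-parameter keys")
        for f in self.free:
            if not (np.isfinite(f.lower) and np.isfinite(f.upper)
                    and f.lower < f.upper):
                raise ValueError(f"bad bounds for {f.key}")

    def build_circuit(self, theta: np.ndarray) -> GeneCircuit:
        updates = {f.key: f.from_search(z) for f, z in zip(self.free, theta)}
        return self.template.copy_with(**updates)

    def search_bounds(self) -> tuple:
        lo, hi = zip(*(f.search_bounds for f in self.free))
        return np.array(lo), np.array(hi)


def _model_marginal_masses(problem: CalibrationProblem, circuit: GeneCircuit):
    """Model bin masses on the data bins, per (time, gene)."""
    ds = problem.dataset
    out = []
    if problem.simulator == "pide":
        grid = problem.grid if problem.grid is not None \
            else pide.make_grid(circuit, problem.n_points)
        P0 = pide.default_initial_field(circuit, grid)
        t_points = ds.times[ds.times > 0]
        fields = pide.solve(circuit, P0, t_points, dt=problem.dt) if t_points.size \
            else []
        by_time = dict(zip(t_points, fields))
        for k, t in enumerate(ds.times):
            fld = by_time.get(t, P0)
            entry = {}
            for g in ds.marginals[k]:
                m = fld.bin_masses(g, ds.bin_edges[g])
                entry[g] = m
            out.append(entry)
    else:
        ens = ssa.ensemble(circuit, ds.times, problem.ssa_runs,
                           seed=problem.seed + 7919)
        for k in range(ds.times.size):
            entry = {}
            for g in ds.marginals[k]:
                h, _ = np.histogram(ens.samples[:, k, g], bins=ds.bin_edges[g])
                tot = h.sum()
                entry[g] = h / tot if tot > 0 else h.astype(float)
            out.append(entry)
    return out


def _model_joint_masses(problem: CalibrationProblem, circuit: GeneCircuit):
    """Model 2-D joint bin masses on the data bins, per time."""
    ds = problem.dataset
    ga, gb = ds.joint_genes
    ea, eb = ds.bin_edges[ga], ds.bin_edges[gb]
    out = []
    if problem.simulator == "pide":
        grid = problem.grid if problem.grid is not None \
            else pide.make_grid(circuit, problem.n_points)
        P0 = pide.default_initial_field(circuit, grid)
        t_points = ds.times[ds.times > 0]
        fields = pide.solve(circuit, P0, t_points, dt=problem.dt) if t_points.size \
            else []
        by_time = dict(zip(t_points, fields))
        for t in ds.times:
            fld = by_time.get(t, P0)
            out.append(fld.bin_masses_2d((ga, gb), ea, eb))
    else:
        ens = ssa.ensemble(circuit, ds.times, problem.ssa_runs,
                           seed=problem.seed + 7919)
        for k in range(ds.times.size):
            h, _, _ = np.histogram2d(ens.samples[:, k, ga].astype(float),
                                     ens.samples[:, k, gb].astype(float),
                                     bins=[ea, eb])
            tot = h.sum()
            out.append(h / tot if tot > 0 else h)
    return out


def calibration_cost(theta: np.ndarray, problem: CalibrationProblem) -> float:
    """Sum of KL(data || model) over sampling times and observed genes.

    Simulation failures return a large finite penalty (base 1e6 plus a
    normalized distance-from-box-center term) so the optimizer sees an
    informative, finite landscape everywhere.
    """
    theta = np.asarray(theta, dtype=float)
    try:
        circuit = problem.build_circuit(theta)
        total = 0.0
        if problem.dataset.joint is not None:
            model_j = _model_joint_masses(problem, circuit)
            for k in range(problem.dataset.times.size):
                total += kl_divergence(problem.dataset.joint[k].ravel(),
                                       model_j[k].ravel())
        else:
            model = _model_marginal_masses(problem, circuit)
            for k in range(problem.dataset.times.size):
                for g, p_obs in problem.dataset.marginals[k].items():
                    total += kl_divergence(p_obs, model[k][g])
        if not np.isfinite(total):
            raise FloatingPointError
        return float(total)
    except Exception:
        lo, hi = problem.search_bounds()
        mid = (lo + hi) / 2
        off = np.mean(((theta - mid) / (hi - lo)) ** 2)
        return PENALTY_BASE * (1.0 + off)


class CalibrationModel:
    """Model object wrapping a calibration problem; ``fit()`` runs the
    global optimizer on the KL cost."""

    def __init__(self, problem: CalibrationProblem):
        self.problem = problem

    @classmethod
    def from_dataset(cls, template: GeneCircuit, dataset: HistogramDataset,
                     free: list, **options) -> "CalibrationModel":
        return cls(CalibrationProblem(template, free, dataset, **options))

    def cost(self, theta: np.ndarray) -> float:
        return calibration_cost(theta, self.problem)

    def fit(self, compute_stderr: bool = False) -> "CalibrationResults":
        prob = self.problem
        if not prob.free:
            raise ValueError("no free parameters to fit")
        lo, hi = prob.search_bounds()
        opt = minimize(MINLPProblem(
            objective=self.cost, lower=lo, upper=hi,
            budget=prob.budget, seed=prob.seed))
        res = CalibrationResults(self, opt)
        if compute_stderr:
            res.compute_stderr()
        return res


@dataclass
class CalibrationResults:
    """Estimates, cost trace and diagnostics of a calibration fit."""

    model: CalibrationModel
    optimresult: OptimResult
    _stderr: Optional[np.ndarray] = dc_field(default=None, repr=False)

    @property
    def theta(self) -> np.ndarray:
        return self.optimresult.x

    @property
    def params(self) -> dict:
        prob = self.model.problem
        return {f.key: f.from_search(z) for f, z in zip(prob.free, self.theta)}

    @property
    def cost(self) -> float:
        return self.optimresult.fun

    @property
    def circuit(self) -> GeneCircuit:
        return self.model.problem.build_circuit(self.theta)

    def compute_stderr(self, rel_step: float = 0.05) -> np.ndarray:
        """Curvature-based approximate standard errors.

        Central-difference diagonal Hessian of the KL cost, scaled by the
        dataset sample count when known (multinomial large-count asymptotics);
        cross-parameter correlations are ignored.  NaN where the local
        curvature is not positive.
        """
        prob = self.model.problem
        lo, hi = prob.search_bounds()
        n = prob.dataset.n_samples or 1
        f0 = self.cost
        se = np.full(self.theta.size, np.nan)
        for i in range(self.theta.size):
            h = rel_step * (hi[i] - lo[i])
            tp, tm = self.theta.copy(), self.theta.copy()
            tp[i] = min(tp[i] + h, hi[i])
            tm[i] = max(tm[i] - h, lo[i])
            fp = self.model.cost(tp)
            fm = self.model.cost(tm)
            d2 = (fp - 2 * f0 + fm) / ((tp[i] - self.theta[i]) * (self.theta[i] - tm[i])
                                       + 1e-300)
            if d2 > 0:
                se[i] = 1.0 / math.sqrt(n * d2)
        # errors are on the search scale (log10 for log-scale parameters)
        self._stderr = se
        return se

    def summary(self) -> str:
        prob = self.model.problem
        lines = [
            "Calibration results (KL cost, lower is better)",
            f"  simulator: {prob.simulator}   evaluations: {self.optimresult.n_eval}"
            f"   seed: {prob.seed}",
            f"  final cost: {self.cost:.6g} nats",
            "",
            f"{'parameter':<12}{'estimate':>14}{'std.err(search)':>18}"
            f"{'lower':>12}{'upper':>12}{'scale':>8}",
        ]
        se = self._stderr if self._stderr is not None \
            else np.full(len(prob.free), np.nan)
        for f, v, s in zip(prob.free, self.params.values(), se):
            lines.append(
                f"{f.key:<12}{v:>14.6g}{s:>18.4g}{f.lower:>12.4g}{f.upper:>12.4g}"
                f"{'log10' if f.log_scale else 'linear':>8}")
        return "\n".join(lines)


def fit(problem: CalibrationProblem, **kwargs) -> CalibrationResults:
    """Functional wrapper: fit a calibration problem."""
    return CalibrationModel(problem).fit(**kwargs)
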