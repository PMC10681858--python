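"""Automated circuit design as a mixed-integer program.

The decision vector concatenates free topology entries (integers in
{-1, 0, +1}), free Hill cooperativities (bounded integers) and free real
kinetic parameters (optionally searched on a log10 scale).  Behavioral
objectives score the decoded circuit: distance to a target (stationary or
time-resolved) distribution, a bimodality criterion over protein-level
domains, or oscillation robustness measured by the second peak of the
autocorrelation function of a stochastic protein trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np

from . import pide, ssa
from .circuit import GeneCircuit, KineticParameters, Topology
from .calibrate import kl_divergence, FreeParameter
from .optimize import MINLPProblem, OptimResult, minimize

__all__ = [
    "ObjectiveSpec", "DesignProblem", "DesignResults", "design",
    "encode", "decode", "autocorrelation", "autocorr_second_peak",
    "objective_target_stationary", "objective_target_dynamics",
    "objective_bimodality", "objective_oscillation", "register_objective",
]

PENALTY = 1e6
ACF_PROMINENCE = 0.01


# ---------------------------------------------------------------------------
# autocorrelation
# ---------------------------------------------------------------------------

def autocorrelation(series: np.ndarray, max_lag: int) -> np.ndarray:
    """Normalized autocorrelation R(0..max_lag), R(0) = 1 (FFT-based).

    Uses the biased estimator R(k) = sum_t (x_t - xbar)(x_{t+k} - xbar)
    normalized by the lag-0 term.  Returns zeros (R(0)=1 aside) for a
    constant series.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if max_lag >= n:
        raise ValueError("max_lag must be below the series length")
    x = x - x.mean()
    var = np.dot(x, x)
    out = np.zeros(max_lag + 1)
    out[0] = 1.0
    if var <= 0:
        return out
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[: max_lag + 1]
    return acov / acov[0]


def autocorr_second_peak(series: np.ndarray, burn_in: int = 0,
                         max_lag: Optional[int] = None,
                         prominence: float = ACF_PROMINENCE
                         ) -> tuple[float, Optional[int], bool]:
    """Height and lag of the first strict local maximum of R at positive lag.

    The zero-lag peak R(0)=1 is the trivial first peak; the returned one is
    the 'second peak' that measures oscillation robustness.  Peaks must rise
    by at least ``prominence`` above the preceding local minimum.  Returns
    ``(0.0, None, True)`` (degenerate flag) for constant series or when no
    peak exists.
    """
    x = np.asarray(series, dtype=float)[burn_in:]
    if max_lag is None:
        max_lag = x.size // 2
    if x.size <= 2 * max_lag:
        raise ValueError("series too short for the requested burn-in/max_lag")
    if np.ptp(x) == 0:
        return 0.0, None, True
    r = autocorrelation(x, max_lag)
    trough = r[0]
    for k in range(1, max_lag):
        if r[k] < trough:
            trough = r[k]
        if r[k] > r[k - 1] and r[k] > r[k + 1] and (r[k] - trough) >= prominence:
            return float(r[k]), int(k), False
    return 0.0, None, True


# ---------------------------------------------------------------------------
# decision encoding
# ---------------------------------------------------------------------------

@dataclass
class ObjectiveSpec:
    """Kind plus kind-specific payload for a design objective.

    kinds: 'target_stationary' (payload: target field), 'target_dynamics'
    (targets + times), 'bimodality' (domains, target_masses,
    min_mode_distance), 'oscillation_autocorr' (gene, n_samples, burn_in,
    sample_dt, seed), or any name registered via :func:`register_objective`.
    """

    kind: str
    payload: dict = dc_field(default_factory=dict)


@dataclass
class DesignProblem:
    """MINLP circuit-design problem.

    Every circuit slot is exactly one of: free integer (topology entries in
    ``free_topology``, cooperativities in ``free_coop``), free real
    (``free_params``, as :class:`FreeParameter`), or fixed (taken from
    ``fixed_topology`` / ``gene_params`` / ``edge_params``).
    ``edge_params[(i, j)] = (K, n)`` must cover every edge that can be
    nonzero in a decoded circuit.
    """

    n_genes: int
    objective: ObjectiveSpec
    fixed_topology: np.ndarray
    gene_params: dict                      # name -> length-n array
    edge_params: dict                      # (i, j) -> (K, n)
    free_topology: list = dc_field(default_factory=list)
    free_coop: list = dc_field(default_factory=list)   # [((i, j), lo, hi)]
    free_params: list = dc_field(default_factory=list)  # of FreeParameter
    budget: int = 500
    seed: int = 0
    solver_options: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fixed_topology = np.asarray(self.fixed_topology, dtype=int)
        free = set(map(tuple, self.free_topology))
        for e in free:
            self.fixed_topology[e] = 0     # free slots take values from z
        possible = free | set(map(tuple, zip(*np.nonzero(self.fixed_topology))))
        missing = possible - set(self.edge_params)
        if missing:
            raise ValueError(f"edge_params missing for possible edges {sorted(missing)}")

    # --- decision-vector layout: [topology ints | coop ints | reals] ---
    @property
    def dim(self) -> int:
        return len(self.free_topology) + len(self.free_coop) + len(self.free_params)

    def bounds(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        lo, hi, im = [], [], []
        for _ in self.free_topology:
            lo.append(-1); hi.append(1); im.append(True)
        for (_, a, b) in self.free_coop:
            lo.append(a); hi.append(b); im.append(True)
        for f in self.free_params:
            a, b = f.search_bounds
            lo.append(a); hi.append(b); im.append(False)
        return np.array(lo, float), np.array(hi, float), np.array(im, bool)


def decode(problem: DesignProblem, z: np.ndarray) -> GeneCircuit:
    """Decision vector -> validated circuit; (K, n) of absent edges are
    dropped, fixed slots always take their fixed values."""
    z = np.asarray(z, dtype=float)
    if z.size != problem.dim:
        raise ValueError(f"decision vector length {z.size}, expected {problem.dim}")
    nt = len(problem.free_topology)
    nc = len(problem.free_coop)
    T = problem.fixed_topology.copy()
    for k, e in enumerate(problem.free_topology):
        v = int(round(z[k]))
        if v not in (-1, 0, 1):
            raise ValueError(f"topology slot {e} out of domain: {z[k]}")
        T[tuple(e)] = v
    gp = {k: np.asarray(v, dtype=float).copy() for k, v in problem.gene_params.items()}
    topo = Topology(T)
    K = {e: float(problem.edge_params[e][0]) for e in topo.edges()}
    n = {e: float(problem.edge_params[e][1]) for e in topo.edges()}
    for k, (e, a, b) in enumerate(problem.free_coop):
        v = int(round(z[nt + k]))
        if not a <= v <= b:
            raise ValueError(f"cooperativity slot {e} out of bounds: {z[nt + k]}")
        if tuple(e) in n:
            n[tuple(e)] = float(v)
    overrides = {}
    for k, f in enumerate(problem.free_params):
        overrides[f.key] = f.from_search(z[nt + nc + k])
    params = KineticParameters(km=gp["km"], kx=gp["kx"], gm=gp["gm"],
                               gx=gp["gx"], eps=gp["eps"], K=K, n=n)
    circuit = GeneCircuit(topo, params)
    # apply free real overrides, skipping (K, n) of edges absent in T
    edges = set(topo.edges())
    applicable = {}
    for key, val in overrides.items():
        name = key.partition("[")[0]
        if name in ("K", "n"):
            i, j = (int(s) for s in key.partition("[")[2].rstrip("]").split(","))
            if (i, j) not in edges:
                continue
        applicable[key] = val
    return circuit.copy_with(**applicable) if applicable else circuit


def encode(problem: DesignProblem, circuit: GeneCircuit) -> np.ndarray:
    """Circuit -> decision vector over the free slots (round trip with
    :func:`decode` on those slots)."""
    z = np.empty(problem.dim)
    nt = len(problem.free_topology)
    nc = len(problem.free_coop)
    for k, e in enumerate(problem.free_topology):
        z[k] = circuit.topology.matrix[tuple(e)]
    for k, (e, a, b) in enumerate(problem.free_coop):
        z[nt + k] = circuit.params.n.get(tuple(e), a)
    p = circuit.params
    for k, f in enumerate(problem.free_params):
        name, _, rest = f.key.partition("[")
        idx = rest.rstrip("]")
        if name in ("K", "n"):
            e = tuple(int(s) for s in idx.split(","))
            val = getattr(p, name).get(e, problem.edge_params[e][0 if name == "K" else 1])
        else:
            val = getattr(p, name)[int(idx)]
        z[nt + nc + k] = f.to_search(val)
    return z


# ---------------------------------------------------------------------------
# objectives
# ---------------------------------------------------------------------------

def _cell_masses(field: pide.DistributionField) -> tuple[np.ndarray, list]:
    """Probability mass per grid cell (corner-averaged density x volume)."""
    v = field.values
    for ax in range(v.ndim):
        sl0 = [slice(None)] * v.ndim
        sl1 = [slice(None)] * v.ndim
        sl0[ax] = slice(0, -1)
        sl1[ax] = slice(1, None)
        v = 0.5 * (v[tuple(sl0)] + v[tuple(sl1)]) * field.grid.spacing[ax]
    centers = [0.5 * (a[1:] + a[:-1]) for a in field.grid.nodes]
    return v, centers


def _stationary_for(circuit: GeneCircuit, options: dict) -> pide.DistributionField:
    opts = dict(options)
    grid = opts.pop("grid", None)
    if grid is None:
        grid = pide.make_grid(circuit, opts.pop("n_points", 64))
    else:
        opts.pop("n_points", None)
    return pide.stationary(circuit, grid=grid, **opts)


def objective_target_stationary(circuit: GeneCircuit,
                                target: pide.DistributionField,
                                solver_options: Optional[dict] = None) -> float:
    """KL(target || model stationary), both aggregated to the target's grid
    cells.  Non-convergence returns the penalty value."""
    opts = dict(solver_options or {})
    opts["grid"] = target.grid
    try:
        model = _stationary_for(circuit, opts)
    except pide.PIDENonConvergence:
        return PENALTY
    pm, _ = _cell_masses(target)
    qm, _ = _cell_masses(model)
    return kl_divergence(pm.ravel() / pm.sum(), qm.ravel() / max(qm.sum(), 1e-300))


def objective_target_dynamics(circuit: GeneCircuit, targets: Sequence,
                              times: Sequence[float],
                              solver_options: Optional[dict] = None) -> float:
    """Sum over stated times of KL(target_t || solved_t) on the target grid."""
    opts = dict(solver_options or {})
    grid = targets[0].grid
    try:
        P0 = opts.pop("P0", None) or pide.default_initial_field(circuit, grid)
        fields = pide.solve(circuit, P0, np.asarray(times, float),
                            dt=opts.pop("dt", None))
    except Exception:
        return PENALTY
    total = 0.0
    for tgt, fld in zip(targets, fields):
        pm, _ = _cell_masses(tgt)
        qm, _ = _cell_masses(fld)
        total += kl_divergence(pm.ravel() / pm.sum(),
                               qm.ravel() / max(qm.sum(), 1e-300))
    return total


def _domain_mass(masses: np.ndarray, centers: list, box: Sequence) -> float:
    """Mass of cells whose center lies in the axis-aligned box
    ``[(lo_1, hi_1), ...]``."""
    mask = np.ones(masses.shape, dtype=bool)
    for ax, (lo, hi) in enumerate(box):
        c = centers[ax]
        sel = (c >= lo) & (c <= hi)
        shape = [1] * masses.ndim
        shape[ax] = c.size
        mask &= sel.reshape(shape)
    return float(masses[mask].sum())


def objective_bimodality(circuit: GeneCircuit, domains: Sequence,
                         target_masses: Sequence[float],
                         min_mode_distance: float = 0.0,
                         solver_options: Optional[dict] = None) -> float:
    """Domain-mass mismatch plus a hinge on the distance between the two
    largest strict local maxima of the stationary field.

    cost = sum_d |mass(domain_d) - target_d|
         + max(0, min_mode_distance - distance(top two modes));
    fields with fewer than two modes incur the full hinge.
    """
    try:
        fld = _stationary_for(circuit, dict(solver_options or {}))
    except pide.PIDENonConvergence:
        return PENALTY
    masses, centers = _cell_masses(fld)
    cost = 0.0
    for box, tgt in zip(domains, target_masses):
        cost += abs(_domain_mass(masses, centers, box) - tgt)
    maxima = fld.local_maxima()
    if len(maxima) >= 2:
        vals = np.array([fld.values[ix] for ix in maxima])
        top = np.argsort(vals)[::-1][:2]
        a = np.array([fld.grid.nodes[ax][maxima[top[0]][ax]]
                      for ax in range(fld.grid.ndim)])
        b = np.array([fld.grid.nodes[ax][maxima[top[1]][ax]]
                      for ax in range(fld.grid.ndim)])
        dist = float(np.linalg.norm(a - b))
    else:
        dist = 0.0
    cost += max(0.0, min_mode_distance - dist)
    return cost


def objective_oscillation(circuit: GeneCircuit, gene: int = 0,
                          n_samples: int = 20_000, burn_in: int = 2_000,
                          sample_dt: float = 0.5, seed: int = 0,
                          max_lag: Optional[int] = None) -> float:
    """Negative second-peak height of the protein autocorrelation from one
    fixed-seed SSA trajectory (deterministic per problem seed); degenerate
    trajectories are penalized."""
    t_grid = np.arange(1, n_samples + 1) * sample_dt
    try:
        ens = ssa.ensemble(circuit, t_grid, 1, seed=seed)
    except ssa.SSANumericalError:
        return PENALTY
    series = ens.samples[0, :, gene].astype(float)
    if max_lag is None:
        max_lag = min((n_samples - burn_in - 1) // 2, 400)
    height, _, degenerate = autocorr_second_peak(series, burn_in, max_lag)
    if degenerate and np.ptp(series[burn_in:]) == 0:
        return PENALTY
    return -height


_OBJECTIVES = {}


def register_objective(kind: str, fn) -> None:
    """Hook for user-supplied objective kinds (e.g. adaptation to external
    signals): ``fn(circuit, **payload) -> cost``."""
    _OBJECTIVES[kind] = fn


register_objective("target_stationary",
                   lambda c, **p: objective_target_stationary(c, **p))
register_objective("target_dynamics",
                   lambda c, **p: objective_target_dynamics(c, **p))
register_objective("bimodality", lambda c, **p: objective_bimodality(c, **p))
register_objective("oscillation_autocorr",
                   lambda c, **p: objective_oscillation(c, **p))


def evaluate_objective(problem: DesignProblem, circuit: GeneCircuit) -> float:
    spec = problem.objective
    if spec.kind not in _OBJECTIVES:
        raise ValueError(f"unknown objective kind '{spec.kind}'")
    payload = dict(spec.payload)
    if spec.kind in ("target_stationary", "target_dynamics", "bimodality"):
        payload.setdefault("solver_options", problem.solver_options)
    if spec.kind == "oscillation_autocorr":
        payload.setdefault("seed", problem.seed)
    return float(_OBJECTIVES[spec.kind](circuit, **payload))


@dataclass
class DesignResults:
    """Best decision vector and decoded circuit with the search trace."""

    problem: DesignProblem
    optimresult: OptimResult
    circuit: GeneCircuit

    @property
    def objective_value(self) -> float:
        return self.optimresult.fun

    def summary(self) -> str:
        lines = [
            "Automated design result",
            f"  objective: {self.problem.objective.kind}"
            f"   value: {self.objective_value:.6g}",
            f"  evaluations: {self.optimresult.n_eval}   seed: {self.problem.seed}",
            "  topology (rows: regulated gene; +1 activation, -1 repression):",
        ]
        for row in self.circuit.topology.matrix:
            lines.append("    " + " ".join(f"{v:+d}" if v else " 0" for v in row))
        return "\n".join(lines)

    def write(self, out_dir) -> None:
        import pathlib

        from .circuit import save_circuit

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_circuit(self.circuit, out / "best_circuit.yaml")
        np.savetxt(out / "trace.tsv", np.column_stack(
            [np.arange(1, self.optimresult.trace.size + 1),
             self.optimresult.trace]),
            fmt=("%d", "%.10g"), delimiter="\t", header="eval\tbest_so_far")
        (out / "report.txt").write_text(self.summary() + "\n")


def design(problem: DesignProblem) -> DesignResults:
    """Search the mixed decision space for the best-scoring circuit."""
    lo, hi, im = problem.bounds()
    if problem.dim == 0:
        circuit = decode(problem, np.empty(0))
        val = evaluate_objective(problem, circuit)
        opt = OptimResult(np.empty(0), val, 1, np.array([val]), problem.seed)
        return DesignResults(problem, opt, circuit)

    def f(z):
        return evaluate_objective(problem, decode(problem, z))

    opt = minimize(MINLPProblem(objective=f, lower=lo, upper=hi,
                                integer_mask=im, budget=problem.budget,
                                seed=problem.seed))
    return DesignResults(problem, opt, decode(problem, opt.x))
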