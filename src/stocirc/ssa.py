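"""Exact stochastic simulation (Gillespie direct method) of gene circuits.

One trajectory samples the jump process whose master equation the circuit
defines: exponential waiting times with rate equal to the total propensity,
reaction selection proportional to the individual propensities.  Ensembles
of independent trajectories yield empirical protein-count histograms that
converge to the solution of the master equation.

The inner event loop is JIT-compiled (numba) for the default
product-of-Hills input function; circuits with a user-registered input
function fall back to a pure-Python loop with identical semantics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .circuit import GeneCircuit, evaluate_input, stoichiometry

__all__ = ["SSAState", "Trajectory", "EnsembleHistogram", "simulate", "ensemble"]

_MAX_EVENTS_DEFAULT = 50_000_000


class SSANumericalError(RuntimeError):
    """Propensity overflow / NaN encountered during simulation."""


@dataclass
class SSAState:
    """Integer copy-number state (mRNA and protein per gene) at time t."""

    t: float
    mrna: np.ndarray
    x: np.ndarray

    def __post_init__(self) -> None:
        self.mrna = np.asarray(self.mrna, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=np.int64)
        if (self.mrna < 0).any() or (self.x < 0).any():
            raise ValueError("copy numbers must be nonnegative")
        if self.t < 0:
            raise ValueError("time must be nonnegative")

    @classmethod
    def zeros(cls, n_genes: int, t: float = 0.0) -> "SSAState":
        return cls(t, np.zeros(n_genes, np.int64), np.zeros(n_genes, np.int64))


@dataclass
class Trajectory:
    """Piecewise-constant time course: state after each reaction event."""

    times: np.ndarray          # event times, strictly increasing, times[0] = t0
    mrna: np.ndarray           # (n_events + 1, n_genes)
    x: np.ndarray              # (n_events + 1, n_genes)
    t_end: float
    seed: int

    @property
    def n_genes(self) -> int:
        return self.mrna.shape[1]

    def sample(self, t_grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """State on a grid: value at the largest event time <= t."""
        t_grid = np.asarray(t_grid, dtype=float)
        idx = np.searchsorted(self.times, t_grid, side="right") - 1
        idx = np.clip(idx, 0, len(self.times) - 1)
        return self.mrna[idx], self.x[idx]

    def to_frame(self, t_grid: Optional[np.ndarray] = None) -> pd.DataFrame:
        if t_grid is None:
            t, m, x = self.times, self.mrna, self.x
        else:
            m, x = self.sample(t_grid)
            t = np.asarray(t_grid, dtype=float)
        cols = {"time": t}
        for i in range(self.n_genes):
            cols[f"mRNA_{i + 1}"] = m[:, i]
        for i in range(self.n_genes):
            cols[f"X_{i + 1}"] = x[:, i]
        return pd.DataFrame(cols)

    def write(self, path, t_grid: Optional[np.ndarray] = None) -> None:
        """Delimited-text writer: columns time, mRNA_1..n, X_1..n."""
        self.to_frame(t_grid).to_csv(path, sep="\t", index=False)

    def plot(self, ax=None, genes=None, **kwargs):
        """Step plot of protein copy numbers over time."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for i in genes if genes is not None else range(self.n_genes):
            ax.step(self.times, self.x[:, i], where="post",
                    label=f"X_{i + 1}", **kwargs)
        ax.set_xlabel("time")
        ax.set_ylabel("protein copy number")
        ax.legend()
        return ax


@dataclass
class EnsembleHistogram:
    """Empirical protein histograms of an SSA ensemble at sampling times.

    ``marginals[k, g, :]`` is the normalized histogram of protein g at
    ``times[k]`` over ``bin_edges``; the raw per-run protein samples are kept
    so joint histograms over arbitrary bins can be formed on demand.
    """

    times: np.ndarray
    bin_edges: np.ndarray
    marginals: np.ndarray      # (n_times, n_genes, n_bins), each sums to 1
    n_runs: int
    samples: np.ndarray        # (n_runs, n_times, n_genes) protein counts
    mrna_samples: np.ndarray   # (n_runs, n_times, n_genes)

    def joint(self, t_index: int, genes: Sequence[int],
              bin_edges: Optional[Sequence[np.ndarray]] = None) -> tuple[np.ndarray, list]:
        """Joint histogram of selected genes at one sampling time."""
        data = self.samples[:, t_index, list(genes)]
        if bin_edges is None:
            bin_edges = [self.bin_edges] * len(genes)
        hist, edges = np.histogramdd(data.astype(float), bins=list(bin_edges))
        return hist / hist.sum(), edges

    def write(self, path) -> None:
        """Delimited text with a bin-edge header block (per-gene marginals)."""
        with open(path, "w") as fh:
            fh.write("# protein count histograms (rows: time x gene)\n")
            fh.write("# bin_edges\t" + "\t".join(f"{e:g}" for e in self.bin_edges) + "\n")
            fh.write(f"# n_runs\t{self.n_runs}\n")
            fh.write("time\tgene\t" + "\t".join(
                f"bin{k}" for k in range(self.marginals.shape[2])) + "\n")
            for k, t in enumerate(self.times):
                for g in range(self.marginals.shape[1]):
                    row = "\t".join(f"{v:.8g}" for v in self.marginals[k, g])
                    fh.write(f"{t:g}\t{g}\t{row}\n")


# ---------------------------------------------------------------------------
# JIT kernels (product-of-Hills input function)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _promoter_activity(T, Kn, nh, eps, x, c):
    ng = T.shape[0]
    for i in range(ng):
        prod = 1.0
        for j in range(ng):
            tij = T[i, j]
            if tij != 0:
                xn = x[j] ** nh[i, j]
                h = xn / (Kn[i, j] + xn)
                if tij < 0:
                    h = 1.0 - h
                prod *= h
        c[i] = eps[i] + (1.0 - eps[i]) * prod


@njit(cache=True)
def _ssa_grid(T, km, kx, gm, gx, eps, Kn, nh, m0, x0, t0, t_grid, seed, max_events):
    """One trajectory recorded on a grid. Returns (rec_m, rec_x, status, events).

    status: 0 ok, 1 nonfinite propensity, 2 event cap reached.
    """
    np.random.seed(seed)
    ng = km.size
    nt = t_grid.size
    m = m0.copy()
    x = x0.copy()
    t = t0
    rec_m = np.zeros((nt, ng), np.int64)
    rec_x = np.zeros((nt, ng), np.int64)
    a = np.zeros(4 * ng)
    c = np.zeros(ng)
    xf = np.zeros(ng)
    k = 0
    events = 0
    while k < nt:
        for i in range(ng):
            xf[i] = x[i]
        _promoter_activity(T, Kn, nh, eps, xf, c)
        atot = 0.0
        for i in range(ng):
            a[4 * i] = km[i] * c[i]
            a[4 * i + 1] = kx[i] * m[i]
            a[4 * i + 2] = gm[i] * m[i]
            a[4 * i + 3] = gx[i] * x[i]
            atot += a[4 * i] + a[4 * i + 1] + a[4 * i + 2] + a[4 * i + 3]
        if not np.isfinite(atot):
            return rec_m, rec_x, 1, events
        if atot <= 0.0:
            while k < nt:          # frozen state
                rec_m[k] = m
                rec_x[k] = x
                k += 1
            break
        t_next = t - math.log(np.random.random()) / atot
        while k < nt and t_grid[k] < t_next:
            rec_m[k] = m
            rec_x[k] = x
            k += 1
        t = t_next
        r = np.random.random() * atot
        cum = 0.0
        mu = 4 * ng - 1
        for q in range(4 * ng):
            cum += a[q]
            if r < cum:
                mu = q
                break
        gi = mu // 4
        ri = mu % 4
        if ri == 0:
            m[gi] += 1
        elif ri == 1:
            x[gi] += 1
        elif ri == 2:
            m[gi] -= 1
        else:
            x[gi] -= 1
        events += 1
        if events >= max_events:
            return rec_m, rec_x, 2, events
    return rec_m, rec_x, 0, events


@njit(cache=True)
def _ssa_events(T, km, kx, gm, gx, eps, Kn, nh, m0, x0, t0, t_end, seed, max_events):
    """One trajectory with the full event list. Returns (times, ms, xs, status)."""
    np.random.seed(seed)
    ng = km.size
    cap = 1024
    ts = np.empty(cap)
    ms = np.empty((cap, ng), np.int64)
    xs = np.empty((cap, ng), np.int64)
    m = m0.copy()
    x = x0.copy()
    t = t0
    ts[0] = t
    ms[0] = m
    xs[0] = x
    n_rec = 1
    a = np.zeros(4 * ng)
    c = np.zeros(ng)
    xf = np.zeros(ng)
    status = 0
    while True:
        for i in range(ng):
            xf[i] = x[i]
        _promoter_activity(T, Kn, nh, eps, xf, c)
        atot = 0.0
        for i in range(ng):
            a[4 * i] = km[i] * c[i]
            a[4 * i + 1] = kx[i] * m[i]
            a[4 * i + 2] = gm[i] * m[i]
            a[4 * i + 3] = gx[i] * x[i]
            atot += a[4 * i] + a[4 * i + 1] + a[4 * i + 2] + a[4 * i + 3]
        if not np.isfinite(atot):
            status = 1
            break
        if atot <= 0.0:
            break                   # frozen until t_end
        tau = -math.log(np.random.random()) / atot
        if t + tau > t_end:
            break
        t = t + tau
        r = np.random.random() * atot
        cum = 0.0
        mu = 4 * ng - 1
        for q in range(4 * ng):
            cum += a[q]
            if r < cum:
                mu = q
                break
        gi = mu // 4
        ri = mu % 4
        if ri == 0:
            m[gi] += 1
        elif ri == 1:
            x[gi] += 1
        elif ri == 2:
            m[gi] -= 1
        else:
            x[gi] -= 1
        if n_rec == cap:
            cap *= 2
            ts2 = np.empty(cap)
            ms2 = np.empty((cap, ng), np.int64)
            xs2 = np.empty((cap, ng), np.int64)
            ts2[:n_rec] = ts
            ms2[:n_rec] = ms
            xs2[:n_rec] = xs
            ts, ms, xs = ts2, ms2, xs2
        ts[n_rec] = t
        ms[n_rec] = m
        xs[n_rec] = x
        n_rec += 1
        if n_rec >= max_events:
            status = 2
            break
    return ts[:n_rec], ms[:n_rec], xs[:n_rec], status


@njit(cache=True)
def _ssa_ensemble(T, km, kx, gm, gx, eps, Kn, nh, m0, x0, t0, t_grid, seeds, max_events):
    n_runs = seeds.size
    ng = km.size
    nt = t_grid.size
    out_m = np.zeros((n_runs, nt, ng), np.int64)
    out_x = np.zeros((n_runs, nt, ng), np.int64)
    status = 0
    for r in range(n_runs):
        rm, rx, st, _ = _ssa_grid(T, km, kx, gm, gx, eps, Kn, nh,
                                  m0, x0, t0, t_grid, seeds[r], max_events)
        out_m[r] = rm
        out_x[r] = rx
        if st != 0:
            status = st
    return out_m, out_x, status


def _kernel_args(circuit: GeneCircuit):
    p = circuit.params
    ng = circuit.n_genes
    Kn = np.ones((ng, ng))
    nh = np.ones((ng, ng))
    for (i, j) in circuit.topology.edges():
        nh[i, j] = p.n[(i, j)]
        Kn[i, j] = p.K[(i, j)] ** p.n[(i, j)]
    return (circuit.topology.matrix.astype(np.int64), p.km, p.kx, p.gm, p.gx,
            p.eps, Kn, nh)


def _norm_seed(seed: int) -> int:
    return int(seed) % (2 ** 32 - 1)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def simulate(circuit: GeneCircuit, t_end: float,
             initial: Optional[SSAState] = None, seed: int = 0,
             max_events: int = _MAX_EVENTS_DEFAULT) -> Trajectory:
    """One exact trajectory up to ``t_end`` (direct Gillespie method).

    Deterministic given ``seed``.  The trajectory freezes when the total
    propensity hits zero, and formally extends to ``t_end``.
    """
    if initial is None:
        initial = SSAState.zeros(circuit.n_genes)
    if not t_end > initial.t:
        raise ValueError("t_end must exceed the initial time")
    if circuit.input_function == "product_of_hills":
        ts, ms, xs, status = _ssa_events(
            *_kernel_args(circuit), initial.mrna, initial.x, float(initial.t),
            float(t_end), _norm_seed(seed), max_events)
    else:
        ts, ms, xs, status = _simulate_python(circuit, initial, t_end, seed, max_events)
    if status == 1:
        raise SSANumericalError(
            f"non-finite propensity at state mRNA={ms[-1]}, X={xs[-1]}, t={ts[-1]:g}")
    if status == 2:
        raise SSANumericalError(f"event cap {max_events} reached at t={ts[-1]:g}")
    return Trajectory(np.asarray(ts), np.asarray(ms), np.asarray(xs),
                      float(t_end), int(seed))


def _simulate_python(circuit, initial, t_end, seed, max_events):
    """Reference-semantics fallback for non-default input functions."""
    rng = np.random.RandomState(_norm_seed(seed))
    nu = stoichiometry(circuit.n_genes)
    ng = circuit.n_genes
    m = initial.mrna.copy()
    x = initial.x.copy()
    t = float(initial.t)
    ts, ms, xs = [t], [m.copy()], [x.copy()]
    p = circuit.params
    status = 0
    while True:
        c = evaluate_input(circuit, x.astype(float))
        a = np.empty(4 * ng)
        a[0::4] = p.km * c
        a[1::4] = p.kx * m
        a[2::4] = p.gm * m
        a[3::4] = p.gx * x
        atot = a.sum()
        if not np.isfinite(atot):
            status = 1
            break
        if atot <= 0:
            break
        tau = -math.log(rng.random_sample()) / atot
        if t + tau > t_end:
            break
        t += tau
        mu = int(np.searchsorted(np.cumsum(a), rng.random_sample() * atot))
        state = np.concatenate([m, x]) + nu[mu]
        m, x = state[:ng], state[ng:]
        ts.append(t)
        ms.append(m.copy())
        xs.append(x.copy())
        if len(ts) >= max_events:
            status = 2
            break
    return np.array(ts), np.array(ms), np.array(xs), status


def _spawn_seeds(seed: int, n_runs: int) -> np.ndarray:
    """Per-run streams derived from the master seed (stable under any
    execution order)."""
    ss = np.random.SeedSequence(int(seed))
    return ss.generate_state(n_runs, dtype=np.uint32).astype(np.int64)


def ensemble(circuit: GeneCircuit, t_points: Sequence[float], n_runs: int,
             initial: Optional[SSAState] = None, seed: int = 0,
             bin_edges: Optional[np.ndarray] = None,
             max_events: int = _MAX_EVENTS_DEFAULT) -> EnsembleHistogram:
    """Histograms of protein counts from ``n_runs`` independent trajectories.

    Seeds for individual runs are derived deterministically from the master
    seed.  Default bins are unit-width integer bins covering the samples.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    t_points = np.asarray(t_points, dtype=float)
    if t_points.size == 0 or (np.diff(t_points) < 0).any():
        raise ValueError("t_points must be nonempty and nondecreasing")
    if initial is None:
        initial = SSAState.zeros(circuit.n_genes)
    if (t_points < initial.t).any():
        raise ValueError("t_points must not precede the initial time")
    seeds = _spawn_seeds(seed, n_runs)
    if circuit.input_function == "product_of_hills":
        out_m, out_x, status = _ssa_ensemble(
            *_kernel_args(circuit), initial.mrna, initial.x, float(initial.t),
            t_points, seeds, max_events)
        if status != 0:
            raise SSANumericalError("ensemble member failed (overflow or event cap)")
    else:
        out_m = np.zeros((n_runs, t_points.size, circuit.n_genes), np.int64)
        out_x = np.zeros_like(out_m)
        for r in range(n_runs):
            traj = simulate(circuit, float(t_points[-1]) + 1e-9, initial,
                            int(seeds[r]), max_events)
            out_m[r], out_x[r] = traj.sample(t_points)
    if bin_edges is None:
        top = max(int(out_x.max()) + 1, 1)
        bin_edges = np.arange(0, top + 1, dtype=float)
    bin_edges = np.asarray(bin_edges, dtype=float)
    nt, ng, nb = t_points.size, circuit.n_genes, bin_edges.size - 1
    marg = np.zeros((nt, ng, nb))
    for k in range(nt):
        for g in range(ng):
            h, _ = np.histogram(out_x[:, k, g], bins=bin_edges)
            marg[k, g] = h / h.sum() if h.sum() > 0 else h
    return EnsembleHistogram(t_points, bin_edges, marg, n_runs, out_x, out_m)
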