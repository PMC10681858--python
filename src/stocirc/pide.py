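"""Semi-Lagrangian solver for the protein-level master-equation approximation.

The protein copy-number distribution P(t, x) of an N-gene circuit is evolved
under a partial integro-differential equation combining, per gene i:

* a degradation drift  d/dx_i [ gx_i * x_i * P ]  — solved exactly along
  characteristics (semi-Lagrangian step with linear interpolation), and
* a transcription-burst jump term
  km_i * ( \\int_0^{x_i} beta_i(x_i - y) c_i(y, x_-i) P(t, y, x_-i) dy
           - c_i(x) P(t, x) ),
  where beta_i(y) = exp(-y/b_i)/b_i is the exponential burst-size density
  with mean b_i = kx_i/gm_i, integrated by trapezoidal quadrature.

The loss part of the jump term is required for probability conservation and
is always included.  Dimensions are handled by first-order operator
splitting (advection then jump, cycling genes in index order).  Dense tensor
grids limit the solver to at most 3 genes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .circuit import GeneCircuit, CircuitConfigError

__all__ = [
    "Grid", "DistributionField", "BurstKernel", "make_grid",
    "default_initial_field", "step", "solve", "stationary",
    "PIDENonConvergence", "write_field", "read_field",
]

MAX_PIDE_GENES = 3


class PIDENonConvergence(RuntimeError):
    def __init__(self, msg: str, last_change: float):
        super().__init__(msg)
        self.last_change = last_change


@dataclass(frozen=True)
class Grid:
    """Uniform tensor grid over protein levels, one axis per gene.

    Each axis starts at 0 and ends at its truncation level ``x_max_i``.
    """

    nodes: tuple

    def __post_init__(self) -> None:
        nodes = tuple(np.asarray(a, dtype=float) for a in self.nodes)
        for a in nodes:
            if a.size < 16:
                raise CircuitConfigError("each grid axis needs >= 16 points")
            if a[0] != 0.0 or (np.diff(a) <= 0).any():
                raise CircuitConfigError("grid nodes must start at 0 and increase")
        object.__setattr__(self, "nodes", nodes)

    @property
    def ndim(self) -> int:
        return len(self.nodes)

    @property
    def shape(self) -> tuple:
        return tuple(a.size for a in self.nodes)

    @property
    def spacing(self) -> tuple:
        return tuple(float(a[1] - a[0]) for a in self.nodes)

    @property
    def x_max(self) -> tuple:
        return tuple(float(a[-1]) for a in self.nodes)


def make_grid(circuit: GeneCircuit, n_points=128, safety_factor: float = 4.0) -> Grid:
    """Uniform grid truncated at safety_factor x the deterministic stationary
    mean km*kx/(gm*gx) of each gene evaluated at full promoter activity."""
    if circuit.n_genes > MAX_PIDE_GENES:
        raise CircuitConfigError(
            f"dense-grid solver supports at most {MAX_PIDE_GENES} genes")
    if not safety_factor > 0:
        raise CircuitConfigError("safety_factor must be > 0")
    if np.isscalar(n_points):
        n_points = [int(n_points)] * circuit.n_genes
    p = circuit.params
    means = p.km * p.kx / (p.gm * p.gx)
    axes = [np.linspace(0.0, float(safety_factor * means[i]), int(n_points[i]))
            for i in range(circuit.n_genes)]
    return Grid(tuple(axes))


def _trapz_mass(values: np.ndarray, grid: Grid) -> float:
    v = values
    for ax in reversed(range(grid.ndim)):
        v = np.trapezoid(v, grid.nodes[ax], axis=ax)
    return float(v)


@dataclass
class DistributionField:
    """Probability density over a tensor grid of protein levels at time t."""

    grid: Grid
    values: np.ndarray
    t: float = 0.0
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise CircuitConfigError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}")

    def mass(self) -> float:
        return _trapz_mass(self.values, self.grid)

    def normalize(self) -> "DistributionField":
        m = self.mass()
        if not m > 0:
            raise CircuitConfigError("cannot normalize a zero/negative-mass field")
        self.values = self.values / m
        return self

    def marginal(self, axis: int) -> tuple[np.ndarray, np.ndarray]:
        """1-D marginal density along one gene axis: (nodes, density)."""
        v = self.values
        for ax in reversed(range(self.grid.ndim)):
            if ax != axis:
                v = np.trapezoid(v, self.grid.nodes[ax], axis=ax)
        return self.grid.nodes[axis], v

    def mean(self) -> np.ndarray:
        out = np.empty(self.grid.ndim)
        for ax in range(self.grid.ndim):
            nodes, dens = self.marginal(ax)
            out[ax] = np.trapezoid(nodes * dens, nodes)
        return out

    def bin_masses(self, axis: int, bin_edges: np.ndarray) -> np.ndarray:
        """Integrate the marginal density of one gene over given bins
        (linear interpolation of the cumulative distribution)."""
        nodes, dens = self.marginal(axis)
        cdf = np.concatenate([[0.0], np.cumsum(np.diff(nodes) * 0.5 * (dens[1:] + dens[:-1]))])
        edges = np.clip(np.asarray(bin_edges, dtype=float), nodes[0], nodes[-1])
        at = np.interp(edges, nodes, cdf)
        return np.diff(at)

    def bin_masses_2d(self, axes: tuple, edges_a: np.ndarray,
                      edges_b: np.ndarray) -> np.ndarray:
        """Joint probability mass of two genes over rectangular bins.

        Integrates the 2-D marginal density via its cumulative integral
        (trapezoid along both axes) and inclusion-exclusion over the bin
        rectangles, with bilinear interpolation at the bin corners.
        """
        v = self.values
        for ax in reversed(range(self.grid.ndim)):
            if ax not in axes:
                v = np.trapezoid(v, self.grid.nodes[ax], axis=ax)
        if axes[0] > axes[1]:
            v = v.T          # rows follow axes[0], columns axes[1]
        xa, xb = self.grid.nodes[axes[0]], self.grid.nodes[axes[1]]
        ha, hb = xa[1] - xa[0], xb[1] - xb[0]
        # cumulative trapezoid along both axes -> F(x, y)
        ca = np.zeros((xa.size, xb.size))
        ca[1:, :] = np.cumsum(0.5 * ha * (v[1:, :] + v[:-1, :]), axis=0)
        F = np.zeros_like(ca)
        F[:, 1:] = np.cumsum(0.5 * hb * (ca[:, 1:] + ca[:, :-1]), axis=1)
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator((xa, xb), F, bounds_error=False,
                                         fill_value=None)
        ea = np.clip(np.asarray(edges_a, float), xa[0], xa[-1])
        eb = np.clip(np.asarray(edges_b, float), xb[0], xb[-1])
        A, B = np.meshgrid(ea, eb, indexing="ij")
        Fc = interp(np.stack([A.ravel(), B.ravel()], axis=1)).reshape(A.shape)
        masses = (Fc[1:, 1:] - Fc[:-1, 1:] - Fc[1:, :-1] + Fc[:-1, :-1])
        return np.clip(masses, 0.0, None)

    def local_maxima(self) -> list[tuple]:
        """Grid indices of strict local maxima (neighbors along axes)."""
        v = self.values
        mask = np.ones(v.shape, dtype=bool)
        for ax in range(v.ndim):
            lo = np.roll(v, 1, axis=ax)
            hi = np.roll(v, -1, axis=ax)
            first = [slice(None)] * v.ndim
            last = [slice(None)] * v.ndim
            first[ax] = 0
            last[ax] = -1
            lo[tuple(first)] = -np.inf
            hi[tuple(last)] = -np.inf
            mask &= (v > lo) & (v > hi)
        return [tuple(ix) for ix in np.argwhere(mask)]

    def plot(self, ax=None, **kwargs):
        """Quick-look plot (line for 1-D, filled contour for 2-D)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.grid.ndim == 1:
            ax.plot(self.grid.nodes[0], self.values, **kwargs)
            ax.set_xlabel("protein copy number")
            ax.set_ylabel("probability density")
        elif self.grid.ndim == 2:
            ax.contourf(self.grid.nodes[0], self.grid.nodes[1], self.values.T, **kwargs)
            ax.set_xlabel("protein 1")
            ax.set_ylabel("protein 2")
        else:
            raise NotImplementedError("plotting supports 1-D and 2-D fields")
        return ax


@dataclass(frozen=True)
class BurstKernel:
    """Exponential burst-size density beta(y) = exp(-y/b)/b, mean b = kx/gm."""

    b: float

    def density(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        out = np.where(y >= 0, np.exp(-np.clip(y, 0, None) / self.b) / self.b, 0.0)
        return out


def _burst_matrix(x: np.ndarray, b: float) -> np.ndarray:
    """Quadrature matrix L for the burst gain integral along one axis:
    (L f)_k ~= int_0^{x_k} beta(x_k - y) f(y) dy with beta exponential.

    Product-integration rule: f is taken piecewise linear between nodes and
    the exponential kernel is integrated exactly per cell, so the rule stays
    accurate (and mass-faithful: row sums are exactly 1 - exp(-x_k/b)) even
    when the grid spacing is comparable to the burst size b.
    """
    n = x.size
    h = float(x[1] - x[0])
    E = np.exp(-np.arange(n + 1) * (h / b))          # E[m] = exp(-m h / b)
    dE = E[:-1] - E[1:]                              # E(m-1) - E(m), index m-1
    A = (b / h) * dE - E[1:]                         # left-node weight, cell m
    B = dE - A                                       # right-node weight
    k = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    m = k - j
    L = np.zeros((n, n))
    sel = m >= 1
    L[sel] += A[m[sel] - 1]
    sel2 = (m >= 0) & (j >= 1)
    L[sel2] += B[m[sel2]]
    return L


# ---------------------------------------------------------------------------
# workspace: everything that depends only on (circuit, grid)
# ---------------------------------------------------------------------------

def promoter_activity_grid(circuit: GeneCircuit, grid: Grid) -> np.ndarray:
    """c_i evaluated at every tensor-grid node; shape (n_genes,) + grid.shape."""
    ng = circuit.n_genes
    p = circuit.params
    T = circuit.topology.matrix
    if circuit.input_function != "product_of_hills":
        from .circuit import evaluate_input

        mesh = np.meshgrid(*grid.nodes, indexing="ij")
        pts = np.stack([m.ravel() for m in mesh], axis=1)
        out = np.empty((ng, pts.shape[0]))
        for k, x in enumerate(pts):
            out[:, k] = evaluate_input(circuit, x)
        return out.reshape((ng,) + grid.shape)
    C = np.ones((ng,) + grid.shape)
    for (i, j) in circuit.topology.edges():
        K, nh = p.K[(i, j)], p.n[(i, j)]
        xj = grid.nodes[j]
        xn = xj ** nh
        Kn = K ** nh
        h = xn / (Kn + xn) if T[i, j] > 0 else Kn / (Kn + xn)
        shape = [1] * grid.ndim
        shape[j] = xj.size
        C[i] = C[i] * h.reshape(shape)
    return p.eps.reshape((ng,) + (1,) * grid.ndim) + \
        (1.0 - p.eps).reshape((ng,) + (1,) * grid.ndim) * C


class _Workspace:
    """Precomputed operators for stepping one circuit on one grid."""

    def __init__(self, circuit: GeneCircuit, grid: Grid):
        if circuit.n_genes != grid.ndim:
            raise CircuitConfigError("grid dimensionality must equal n_genes")
        if circuit.n_genes > MAX_PIDE_GENES:
            raise CircuitConfigError(
                f"dense-grid solver supports at most {MAX_PIDE_GENES} genes")
        self.circuit = circuit
        self.grid = grid
        self.C = promoter_activity_grid(circuit, grid)
        p = circuit.params
        self.jump_mats = [
            _burst_matrix(grid.nodes[i], float(p.burst_size[i]))
            for i in range(circuit.n_genes)
        ]
        # time-step rule: characteristic feet move ~half a cell at the outer
        # boundary (balances splitting error against interpolation error),
        # capped so the explicit burst update stays well inside stability
        self.dt_stable = min(
            min(0.5 / (float(p.gx[i]) * (grid.shape[i] - 1))
                for i in range(circuit.n_genes)),
            0.2 / float(p.km.max()),
        )
        self._adv_cache: dict = {}

    def _advection(self, i: int, h_t: float):
        """Interpolation stencil at the characteristic feet x*exp(gx*dt):
        4-point cubic Lagrange inside the grid, linear in boundary cells,
        zero beyond the truncation level."""
        key = (i, round(h_t, 15))
        if key not in self._adv_cache:
            x = self.grid.nodes[i]
            n = x.size
            dx = self.grid.spacing[i]
            factor = math.exp(self.circuit.params.gx[i] * h_t)
            pos = x * factor / dx
            idx = np.floor(pos).astype(int)
            frac = pos - idx
            inside = idx <= n - 2
            cubic = (idx >= 1) & (idx <= n - 3)
            i_lin = np.clip(idx, 0, n - 2)
            i_cub = np.clip(idx, 1, n - 3)
            t = frac
            cw = (
                -t * (t - 1) * (t - 2) / 6.0,
                (t + 1) * (t - 1) * (t - 2) / 2.0,
                -(t + 1) * t * (t - 2) / 2.0,
                (t + 1) * t * (t - 1) / 6.0,
            )
            self._adv_cache[key] = (factor, i_lin, frac, inside, cubic, i_cub, cw)
        return self._adv_cache[key]

    def substep(self, values: np.ndarray, h_t: float) -> np.ndarray:
        """One split step of length h_t: per gene, advection then jump."""
        p = self.circuit.params
        v = values
        for i in range(self.circuit.n_genes):
            # (a) exact advection along characteristics of the drift term
            factor, i_lin, frac, inside, cubic, i_cub, cw = self._advection(i, h_t)
            vi = np.moveaxis(v, i, -1)
            lin = vi[..., i_lin] * (1.0 - frac) + vi[..., i_lin + 1] * frac
            cub = (vi[..., i_cub - 1] * cw[0] + vi[..., i_cub] * cw[1]
                   + vi[..., i_cub + 1] * cw[2] + vi[..., i_cub + 2] * cw[3])
            # quasi-monotone limiter: keep the cubic value within the local
            # cell bounds so steep features (e.g. the boundary layer of a
            # strongly repressed gene at x=0) cannot produce over/undershoot
            lo = np.minimum(vi[..., i_lin], vi[..., i_lin + 1])
            hi = np.maximum(vi[..., i_lin], vi[..., i_lin + 1])
            adv = np.where(cubic, np.clip(cub, lo, hi), lin) * factor
            adv[..., ~inside] = 0.0
            v = np.moveaxis(adv, -1, i)
            # (b) burst gain minus loss, explicit Euler
            Ci = self.C[i]
            src = np.moveaxis(Ci * v, i, -1)
            gain = np.moveaxis(src @ self.jump_mats[i].T, -1, i)
            v = v + h_t * p.km[i] * (gain - Ci * v)
        return v


def default_initial_field(circuit: GeneCircuit, grid: Optional[Grid] = None,
                          n_points=128) -> DistributionField:
    """Product of per-gene gamma densities with shape km/gx and scale kx/gm
    (the stationary law of each gene at full promoter activity)."""
    if grid is None:
        grid = make_grid(circuit, n_points)
    p = circuit.params
    vals = np.ones(grid.shape)
    for i in range(circuit.n_genes):
        a = p.km[i] / p.gx[i]
        b = p.burst_size[i]
        x = grid.nodes[i].copy()
        if a < 1:  # density diverges at 0; evaluate just inside the cell
            x[0] = 0.25 * grid.spacing[i]
        dens = stats.gamma.pdf(x, a, scale=b)
        shape = [1] * grid.ndim
        shape[i] = x.size
        vals = vals * dens.reshape(shape)
    return DistributionField(grid, vals, 0.0).normalize()


def step(P: DistributionField, circuit: GeneCircuit, dt: float,
         renormalize: bool = True, workspace: Optional[_Workspace] = None
         ) -> DistributionField:
    """Advance the distribution by ``dt`` (one splitting step, with automatic
    substepping when ``dt`` exceeds the stability bound).

    The returned field carries ``diagnostics['mass_pre']`` (trapezoidal mass
    before clipping/renormalization, per substep, worst case) and
    ``diagnostics['clipped']`` (total negative mass removed).
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    ws = workspace if workspace is not None else _Workspace(circuit, P.grid)
    n_sub = 1
    if dt > ws.dt_stable:
        n_sub = int(math.ceil(dt / ws.dt_stable))
        if workspace is None:
            warnings.warn(
                f"dt={dt:g} exceeds stability bound {ws.dt_stable:g}; "
                f"substepping x{n_sub}", stacklevel=2)
    h_t = dt / n_sub
    v = P.values
    worst_mass = 1.0
    clipped = 0.0
    for _ in range(n_sub):
        v = ws.substep(v, h_t)
        m_pre = _trapz_mass(v, P.grid)
        if abs(m_pre - 1.0) > abs(worst_mass - 1.0):
            worst_mass = m_pre
        neg = v < 0
        if neg.any():
            clipped += -_trapz_mass(np.where(neg, v, 0.0), P.grid)
            v = np.where(neg, 0.0, v)
        if renormalize:
            v = v / _trapz_mass(v, P.grid)
    out = DistributionField(P.grid, v, P.t + dt)
    out.diagnostics = {"mass_pre": worst_mass, "clipped": clipped, "n_sub": n_sub}
    return out


def solve(circuit: GeneCircuit, P0: DistributionField, t_points: Sequence[float],
          dt: Optional[float] = None, renormalize: bool = True
          ) -> list[DistributionField]:
    """Snapshots of the distribution at ``t_points`` (deterministic).

    ``dt`` is subdivided so every snapshot time is hit exactly; default dt is
    the stability bound of the workspace.
    """
    t_points = np.asarray(t_points, dtype=float)
    if (np.diff(t_points) <= 0).any():
        raise ValueError("t_points must be strictly increasing")
    if t_points[0] < P0.t:
        raise ValueError("t_points must start at or after P0.t")
    ws = _Workspace(circuit, P0.grid)
    if dt is None:
        dt = ws.dt_stable
    out = []
    cur = DistributionField(P0.grid, P0.values.copy(), P0.t)
    for tp in t_points:
        span = tp - cur.t
        if span <= 0:
            out.append(DistributionField(cur.grid, cur.values.copy(), cur.t,
                                         dict(cur.diagnostics)))
            continue
        n_steps = max(1, int(math.ceil(span / dt - 1e-12)))
        h = span / n_steps
        for _ in range(n_steps):
            cur = step(cur, circuit, h, renormalize=renormalize, workspace=ws)
        cur.t = tp  # guard against float accumulation
        out.append(DistributionField(cur.grid, cur.values.copy(), tp,
                                     dict(cur.diagnostics)))
    return out


def stationary(circuit: GeneCircuit, dt: Optional[float] = None,
               tol: float = 1e-4, max_iter: int = 2_000_000,
               grid: Optional[Grid] = None, P0: Optional[DistributionField] = None,
               check_every: int = 50) -> DistributionField:
    """Iterate the solver to its fixed point.

    Convergence criterion: L1 change per unit time below ``tol``, measured
    every ``check_every`` steps.  Raises :class:`PIDENonConvergence` when
    ``max_iter`` steps are exhausted.
    """
    if not tol > 0:
        raise ValueError("tol must be positive")
    if P0 is None:
        P0 = default_initial_field(circuit, grid)
    ws = _Workspace(circuit, P0.grid)
    if dt is None:
        dt = ws.dt_stable
    cur = DistributionField(P0.grid, P0.values.copy(), P0.t)
    prev_vals = cur.values.copy()
    n_done = 0
    change = np.inf
    while n_done < max_iter:
        block = min(check_every, max_iter - n_done)
        for _ in range(block):
            cur = step(cur, circuit, dt, workspace=ws)
        n_done += block
        change = _trapz_mass(np.abs(cur.values - prev_vals), cur.grid) / (block * dt)
        if change < tol:
            cur.diagnostics["iterations"] = n_done
            cur.diagnostics["l1_change_rate"] = change
            return cur
        prev_vals = cur.values.copy()
    raise PIDENonConvergence(
        f"no stationary convergence in {max_iter} steps "
        f"(last L1 change rate {change:g} vs tol {tol:g})", change)


# ---------------------------------------------------------------------------
# text I/O for 1-D / 2-D fields
# ---------------------------------------------------------------------------

def write_field(P: DistributionField, path) -> None:
    """Delimited text: grid header block then density values (row-major)."""
    if P.grid.ndim > 2:
        raise NotImplementedError("text writer covers 1-D and 2-D fields")
    with open(path, "w") as fh:
        fh.write(f"# ndim\t{P.grid.ndim}\n# t\t{P.t:.12g}\n")
        for ax, nodes in enumerate(P.grid.nodes):
            fh.write(f"# axis{ax}\t" + "\t".join(f"{v:.12g}" for v in nodes) + "\n")
        if P.grid.ndim == 1:
            for v in P.values:
                fh.write(f"{v:.12g}\n")
        else:
            for row in P.values:
                fh.write("\t".join(f"{v:.12g}" for v in row) + "\n")


def read_field(path) -> DistributionField:
    axes = []
    t = 0.0
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                if parts[0] == "t":
                    t = float(parts[1])
                elif parts[0].startswith("axis"):
                    axes.append(np.array([float(v) for v in parts[1:]]))
            elif line:
                rows.append([float(v) for v in line.split("\t")])
    vals = np.array(rows)
    if len(axes) == 1:
        vals = vals.ravel()
    return DistributionField(Grid(tuple(axes)), vals, t)
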