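"""Global optimizer for box-bounded mixed-integer problems.

A compact scatter-search heuristic: a Latin-hypercube diversification phase
seeds a small reference set balancing quality and diversity; the set is then
improved by pairwise hyper-rectangle combinations (integer slots rounded,
ties broken at random), with stagnation-triggered regeneration and an
optional derivative-free polish of the incumbent over the real slots.
Everything is deterministic given the seed and the evaluation budget is
respected exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = ["MINLPProblem", "OptimResult", "minimize", "local_polish"]

PENALTY_VALUE = 1e10
STAGNATION_ROUNDS = 20


@dataclass
class MINLPProblem:
    """Box-bounded mixed-integer minimization problem.

    ``budget`` caps objective evaluations exactly; the sentinel ``budget=0``
    runs the diversification phase only.  ``integer_mask`` marks decision
    slots restricted to integers (bounds must be integral there).
    """

    objective: Callable[[np.ndarray], float]
    lower: np.ndarray
    upper: np.ndarray
    integer_mask: Optional[np.ndarray] = None
    budget: int = 1000
    seed: int = 0
    local_search: bool = True
    # heuristic hyperparameters (None -> dimension-based defaults)
    n_diverse: Optional[int] = None       # LHS diversification size (10*dim)
    refset_size: Optional[int] = None     # reference-set size (max(6, dim))
    stagnation_rounds: int = STAGNATION_ROUNDS

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if self.lower.shape != self.upper.shape or self.lower.ndim != 1:
            raise ValueError("bounds must be 1-D arrays of equal length")
        if not np.isfinite(self.lower).all() or not np.isfinite(self.upper).all():
            raise ValueError("bounds must be finite")
        if (self.lower >= self.upper).any():
            raise ValueError("need lower < upper componentwise")
        if self.integer_mask is None:
            self.integer_mask = np.zeros(self.lower.size, dtype=bool)
        self.integer_mask = np.asarray(self.integer_mask, dtype=bool)
        im = self.integer_mask
        if im.any() and not (
            np.allclose(self.lower[im], np.round(self.lower[im]))
            and np.allclose(self.upper[im], np.round(self.upper[im]))
        ):
            raise ValueError("integer slots need integral bounds")

    @property
    def dim(self) -> int:
        return self.lower.size


@dataclass
class OptimResult:
    """Best point found, with the best-so-far trace (one entry per call)."""

    x: np.ndarray
    fun: float
    n_eval: int
    trace: np.ndarray
    seed: int
    extras: dict = field(default_factory=dict)


class _Budget(Exception):
    pass


class _Counter:
    def __init__(self, objective, budget):
        self.objective = objective
        self.budget = budget
        self.n = 0
        self.trace: list[float] = []
        self.best_f = np.inf
        self.best_x: Optional[np.ndarray] = None

    def remaining(self) -> int:
        return self.budget - self.n

    def __call__(self, x: np.ndarray) -> float:
        if self.n >= self.budget:
            raise _Budget
        self.n += 1
        try:
            f = float(self.objective(np.asarray(x, dtype=float)))
            if not np.isfinite(f):
                f = PENALTY_VALUE
        except _Budget:
            raise
        except Exception:
            f = PENALTY_VALUE
        if f < self.best_f:
            self.best_f = f
            self.best_x = np.array(x, dtype=float)
        self.trace.append(self.best_f)
        return f


def _round_integers(x: np.ndarray, problem: MINLPProblem, rng) -> np.ndarray:
    x = np.clip(x, problem.lower, problem.upper)
    im = problem.integer_mask
    if im.any():
        v = x[im]
        lo = np.floor(v)
        frac = v - lo
        up = (frac > 0.5) | ((frac == 0.5) & (rng.random(v.size) < 0.5))
        x = x.copy()
        x[im] = np.clip(lo + up, problem.lower[im], problem.upper[im])
    return x


def _lhs(n: int, problem: MINLPProblem, rng) -> np.ndarray:
    """Latin-hypercube sample in the box, integers rounded."""
    d = problem.dim
    u = (rng.permuted(np.tile(np.arange(n), (d, 1)), axis=1).T + rng.random((n, d))) / n
    pts = problem.lower + u * (problem.upper - problem.lower)
    return np.array([_round_integers(p, problem, rng) for p in pts])


def _select_refset(pts, vals, b, rng):
    """Half best by value, half greedily maximizing min distance."""
    order = np.argsort(vals, kind="stable")
    nq = min(b - b // 2, len(order))
    chosen = list(order[:nq])
    rest = [i for i in order[nq:]]
    scale = np.ptp(pts, axis=0)
    scale[scale == 0] = 1.0
    while len(chosen) < b and rest:
        dmin = [min(np.linalg.norm((pts[i] - pts[c]) / scale) for c in chosen)
                for i in rest]
        pick = int(np.argmax(dmin))
        chosen.append(rest.pop(pick))
    return [pts[i].copy() for i in chosen], [vals[i] for i in chosen]


def minimize(problem: MINLPProblem) -> OptimResult:
    """Scatter-search minimization; deterministic given ``problem.seed``."""
    rng = np.random.default_rng(problem.seed)
    d = problem.dim
    n_init = problem.n_diverse if problem.n_diverse is not None else 10 * d
    budget = problem.budget if problem.budget > 0 else n_init
    init_only = problem.budget == 0
    counter = _Counter(problem.objective, budget)

    try:
        pts = _lhs(min(n_init, budget), problem, rng)
        vals = np.array([counter(p) for p in pts])
        if init_only:
            raise _Budget
        b = problem.refset_size if problem.refset_size is not None else max(6, d)
        ref_x, ref_f = _select_refset(pts, vals, min(b, len(pts)), rng)
        stagnant = 0
        while True:
            improved = False
            order = np.argsort(ref_f, kind="stable")
            for ii in order:
                for jj in order:
                    if ii == jj:
                        continue
                    xi, xj = ref_x[ii], ref_x[jj]
                    cand = xi + rng.uniform(-0.5, 1.5, d) * (xj - xi)
                    cand = _round_integers(cand, problem, rng)
                    f = counter(cand)
                    if f < ref_f[ii]:
                        ref_x[ii], ref_f[ii] = cand, f
                        improved = True
            if improved:
                stagnant = 0
            else:
                stagnant += 1
            if stagnant >= problem.stagnation_rounds:
                # regenerate the worst half from a fresh diversification set
                worst = np.argsort(ref_f, kind="stable")[len(ref_f) // 2:]
                fresh = _lhs(len(worst), problem, rng)
                for k, w in enumerate(worst):
                    f = counter(fresh[k])
                    ref_x[w], ref_f[w] = fresh[k].copy(), f
                stagnant = 0
            if problem.local_search and counter.remaining() <= max(
                    20 * int((~problem.integer_mask).sum()), budget // 10):
                break
        if problem.local_search and counter.best_x is not None:
            _polish(counter, counter.best_x.copy(), problem, counter.remaining())
        # spend any leftover budget on random exploration
        while counter.remaining() > 0:
            counter(_round_integers(
                problem.lower + rng.random(d) * (problem.upper - problem.lower),
                problem, rng))
    except _Budget:
        pass

    return OptimResult(
        x=counter.best_x, fun=counter.best_f, n_eval=counter.n,
        trace=np.asarray(counter.trace), seed=problem.seed,
    )


def _polish(f, x0, problem: MINLPProblem, max_evals: int):
    """Compass search over the real slots; integer slots stay fixed."""
    real = ~problem.integer_mask
    if not real.any() or max_evals <= 0:
        return
    lo, hi = problem.lower, problem.upper
    step = 0.1 * (hi - lo)
    x = x0.copy()
    fx = f(x)
    used = 1
    idx = np.flatnonzero(real)
    while used < max_evals and np.max(step[real] / (hi - lo)[real]) > 1e-10:
        moved = False
        for i in idx:
            for sgn in (+1.0, -1.0):
                if used >= max_evals:
                    return
                trial = x.copy()
                trial[i] = np.clip(x[i] + sgn * step[i], lo[i], hi[i])
                if trial[i] == x[i]:
                    continue
                ft = f(trial)
                used += 1
                if ft < fx:
                    x, fx = trial, ft
                    moved = True
                    break
        if not moved:
            step = step / 2.0


def local_polish(objective, x0: np.ndarray, lower, upper,
                 integer_mask: Optional[np.ndarray] = None,
                 max_evals: int = 200) -> tuple[np.ndarray, float]:
    """Standalone derivative-free polish: value never worse than f(x0),
    integer slots unchanged, at most ``max_evals`` objective calls."""
    x0 = np.asarray(x0, dtype=float)
    problem = MINLPProblem(objective, lower, upper, integer_mask,
                           budget=max(max_evals, 1), seed=0, local_search=True)
    if (x0 < problem.lower).any() or (x0 > problem.upper).any():
        raise ValueError("x0 must lie within the bounds")
    if max_evals <= 0:
        try:
            return x0, float(objective(x0))
        except Exception:
            return x0, PENALTY_VALUE
    counter = _Counter(problem.objective, max_evals)
    try:
        _polish(counter, x0.copy(), problem, max_evals)
    except _Budget:
        pass
    if counter.best_x is None:
        return x0, PENALTY_VALUE
    return counter.best_x, counter.best_f
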