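"""Gene-circuit data model: topology, kinetics and promoter input functions.

A circuit of ``N`` genes is described by an integer topology matrix ``T``
(``T[i, j] = +1`` if protein j activates gene i, ``-1`` if it represses it,
``0`` otherwise) together with per-gene kinetic rate constants and per-edge
regulation parameters.  Each gene follows the two-stage expression scheme

    promoter --km*c_i(X)--> mRNA_i --kx_i--> mRNA_i + X_i
    mRNA_i --gm_i--> 0,      X_i --gx_i--> 0

where ``c_i(X)`` is the dimensionless promoter activity (input function).
The default input function is a leaky product of Hill terms; alternative
families can be registered via :func:`register_input_function`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np
import yaml

__all__ = [
    "Topology",
    "KineticParameters",
    "GeneCircuit",
    "CircuitConfigError",
    "evaluate_input",
    "propensities",
    "stoichiometry",
    "load_circuit",
    "save_circuit",
    "register_input_function",
]


class CircuitConfigError(ValueError):
    """Raised when a circuit definition violates the model invariants."""


@dataclass(frozen=True)
class Topology:
    """Signed regulation matrix of an ``n_genes``-gene circuit."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=int)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise CircuitConfigError(f"topology must be square, got shape {m.shape}")
        if not np.isin(m, (-1, 0, 1)).all():
            raise CircuitConfigError("topology entries must be in {-1, 0, +1}")
        object.__setattr__(self, "matrix", m)

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    def edges(self) -> list[Tuple[int, int]]:
        """Nonzero entries (i, j): protein j regulates gene i."""
        rows, cols = np.nonzero(self.matrix)
        return list(zip(rows.tolist(), cols.tolist()))


@dataclass
class KineticParameters:
    """Per-gene rate constants and per-edge Hill regulation parameters.

    Units: ``km`` molecules/time, ``kx``, ``gm``, ``gx`` 1/time, ``eps``
    dimensionless leakage in [0, 1), ``K`` molecules, ``n`` (cooperativity)
    dimensionless >= 1.  Keys of ``K``/``n`` are edges ``(i, j)``.
    """

    km: np.ndarray
    kx: np.ndarray
    gm: np.ndarray
    gx: np.ndarray
    eps: np.ndarray
    K: Dict[Tuple[int, int], float] = field(default_factory=dict)
    n: Dict[Tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("km", "kx", "gm", "gx", "eps"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        sizes = {getattr(self, name).size for name in ("km", "kx", "gm", "gx", "eps")}
        if len(sizes) != 1:
            raise CircuitConfigError("per-gene parameter vectors must share one length")

    @property
    def n_genes(self) -> int:
        return self.km.size

    @property
    def burst_size(self) -> np.ndarray:
        """Mean translational burst size b_i = kx_i / gm_i."""
        return self.kx / self.gm

    def validate(self, topology: Topology) -> None:
        if self.n_genes != topology.n_genes:
            raise CircuitConfigError(
                f"parameters for {self.n_genes} genes, topology has {topology.n_genes}"
            )
        for name in ("km", "kx", "gm", "gx"):
            v = getattr(self, name)
            if not (v > 0).all():
                raise CircuitConfigError(f"rate '{name}' must be strictly positive")
        if not ((self.eps >= 0) & (self.eps < 1)).all():
            raise CircuitConfigError("leakage eps must lie in [0, 1)")
        edges = set(topology.edges())
        for label, table in (("K", self.K), ("n", self.n)):
            keys = {tuple(k) for k in table}
            if keys != edges:
                missing = edges - keys
                extra = keys - edges
                raise CircuitConfigError(
                    f"edge parameter '{label}' mismatch: missing {sorted(missing)}, "
                    f"spurious {sorted(extra)}"
                )
        for e in edges:
            if not self.K[e] > 0:
                raise CircuitConfigError(f"threshold K{e} must be > 0")
            if not self.n[e] >= 1:
                raise CircuitConfigError(f"cooperativity n{e} must be >= 1")


# ---------------------------------------------------------------------------
# input-function registry
# ---------------------------------------------------------------------------

InputFunction = Callable[["GeneCircuit", np.ndarray], np.ndarray]
_INPUT_FUNCTIONS: Dict[str, InputFunction] = {}


def register_input_function(name: str, fn: InputFunction) -> None:
    """Register an alternative promoter input-function family."""
    _INPUT_FUNCTIONS[name] = fn


def _product_of_hills(circuit: "GeneCircuit", x: np.ndarray) -> np.ndarray:
    T = circuit.topology.matrix
    p = circuit.params
    c = np.ones(circuit.n_genes)
    for (i, j) in circuit.topology.edges():
        K = p.K[(i, j)]
        nh = p.n[(i, j)]
        xn = x[j] ** nh
        Kn = K ** nh
        h = xn / (Kn + xn) if T[i, j] > 0 else Kn / (Kn + xn)
        c[i] *= h
    return p.eps + (1.0 - p.eps) * c


register_input_function("product_of_hills", _product_of_hills)


@dataclass
class GeneCircuit:
    """Topology plus kinetics: the single source of truth for all simulators."""

    topology: Topology
    params: KineticParameters
    names: Optional[Sequence[str]] = None
    input_function: str = "product_of_hills"

    def __post_init__(self) -> None:
        self.params.validate(self.topology)
        if self.names is not None and len(self.names) != self.n_genes:
            raise CircuitConfigError("names length must equal n_genes")
        if self.input_function not in _INPUT_FUNCTIONS:
            raise CircuitConfigError(f"unknown input function '{self.input_function}'")

    @property
    def n_genes(self) -> int:
        return self.topology.n_genes

    @property
    def n_reactions(self) -> int:
        return 4 * self.n_genes

    def gene_names(self) -> list[str]:
        return list(self.names) if self.names else [f"g{i}" for i in range(self.n_genes)]

    # convenience wrappers
    def input(self, x: np.ndarray) -> np.ndarray:
        return evaluate_input(self, x)

    def copy_with(self, **updates: Dict) -> "GeneCircuit":
        """Return a circuit with selected kinetic entries replaced.

        Keys: per-gene ``"km[i]"`` etc., per-edge ``"K[i,j]"`` / ``"n[i,j]"``.
        """
        p = self.params
        new = KineticParameters(
            km=p.km.copy(), kx=p.kx.copy(), gm=p.gm.copy(), gx=p.gx.copy(),
            eps=p.eps.copy(), K=dict(p.K), n=dict(p.n),
        )
        for key, value in updates.items():
            name, idx = _parse_param_key(key)
            if name in ("K", "n"):
                table = getattr(new, name)
                if idx not in table:
                    raise CircuitConfigError(f"no edge {idx} for parameter '{key}'")
                table[idx] = float(value)
            else:
                getattr(new, name)[idx] = float(value)
        return GeneCircuit(self.topology, new, self.names, self.input_function)


def _parse_param_key(key: str) -> Tuple[str, object]:
    name, _, rest = key.partition("[")
    idx = rest.rstrip("]")
    if name in ("km", "kx", "gm", "gx", "eps"):
        return name, int(idx)
    if name in ("K", "n"):
        i, j = (int(t) for t in idx.split(","))
        return name, (i, j)
    raise CircuitConfigError(f"unrecognized parameter key '{key}'")


def evaluate_input(circuit: GeneCircuit, x: np.ndarray) -> np.ndarray:
    """Promoter activities c(x) in [eps, 1] at protein levels ``x``.

    Unregulated genes have c_i = 1 (empty product).  Raises on negative x.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (circuit.n_genes,):
        raise CircuitConfigError(f"x must have shape ({circuit.n_genes},), got {x.shape}")
    if (x < 0).any():
        raise ValueError("protein levels must be nonnegative")
    return _INPUT_FUNCTIONS[circuit.input_function](circuit, x)


def stoichiometry(n_genes: int) -> np.ndarray:
    """Stoichiometry matrix, one row per reaction over (mRNA_1..n, X_1..n).

    Row order per gene i: transcription, translation, mRNA degradation,
    protein degradation.  Each row changes exactly one species by +/-1.
    """
    nu = np.zeros((4 * n_genes, 2 * n_genes), dtype=np.int64)
    for i in range(n_genes):
        nu[4 * i + 0, i] = +1          # 0 -> mRNA_i
        nu[4 * i + 1, n_genes + i] = +1  # mRNA_i -> mRNA_i + X_i
        nu[4 * i + 2, i] = -1          # mRNA_i -> 0
        nu[4 * i + 3, n_genes + i] = -1  # X_i -> 0
    return nu


def propensities(circuit: GeneCircuit, mrna: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Reaction propensities a(state), length 4*n_genes, same row order
    as :func:`stoichiometry`."""
    mrna = np.asarray(mrna, dtype=float)
    x = np.asarray(x, dtype=float)
    if (mrna < 0).any() or (x < 0).any():
        raise ValueError("copy numbers must be nonnegative")
    p = circuit.params
    c = evaluate_input(circuit, x)
    a = np.empty(4 * circuit.n_genes)
    a[0::4] = p.km * c
    a[1::4] = p.kx * mrna
    a[2::4] = p.gm * mrna
    a[3::4] = p.gx * x
    return a


# ---------------------------------------------------------------------------
# serialization (YAML config, the single ingestion path)
# ---------------------------------------------------------------------------

def circuit_to_dict(circuit: GeneCircuit) -> dict:
    p = circuit.params
    return {
        "n_genes": circuit.n_genes,
        "topology": circuit.topology.matrix.tolist(),
        "genes": [
            {
                "km": float(p.km[i]), "kx": float(p.kx[i]), "gm": float(p.gm[i]),
                "gx": float(p.gx[i]), "eps": float(p.eps[i]),
            }
            for i in range(circuit.n_genes)
        ],
        "edges": [
            {"i": i, "j": j, "K": float(p.K[(i, j)]), "n": float(p.n[(i, j)])}
            for (i, j) in circuit.topology.edges()
        ],
        "names": circuit.gene_names(),
        "input_function": circuit.input_function,
    }


def circuit_from_dict(cfg: dict) -> GeneCircuit:
    try:
        n_genes = int(cfg["n_genes"])
        topo = Topology(np.asarray(cfg["topology"], dtype=int))
        if topo.n_genes != n_genes:
            raise CircuitConfigError("key 'topology': size does not match 'n_genes'")
        genes = cfg["genes"]
        if len(genes) != n_genes:
            raise CircuitConfigError("key 'genes': need one block per gene")
        params = KineticParameters(
            km=[g["km"] for g in genes],
            kx=[g["kx"] for g in genes],
            gm=[g["gm"] for g in genes],
            gx=[g["gx"] for g in genes],
            eps=[g.get("eps", 0.0) for g in genes],
            K={(int(e["i"]), int(e["j"])): float(e["K"]) for e in cfg.get("edges", [])},
            n={(int(e["i"]), int(e["j"])): float(e["n"]) for e in cfg.get("edges", [])},
        )
        return GeneCircuit(
            topo, params, cfg.get("names"),
            cfg.get("input_function", "product_of_hills"),
        )
    except KeyError as exc:
        raise CircuitConfigError(f"missing circuit config key {exc}") from exc


def load_circuit(path) -> GeneCircuit:
    """Load and validate a circuit from a YAML config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise CircuitConfigError(f"{path}: not a mapping")
    return circuit_from_dict(cfg)


def save_circuit(circuit: GeneCircuit, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(circuit_to_dict(circuit), fh, sort_keys=False)
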