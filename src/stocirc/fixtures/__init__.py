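"""Bundled example circuits and a synthetic pseudo-data generator.

The three fixture circuits cover the canonical stochastic behaviors:
a constitutive gene (analytically tractable gamma stationary law), a
toggle switch (bimodality) and a repressilator (noisy oscillations).
They ship as YAML configs so every pipeline is exercisable without
external data.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .. import ssa
from ..circuit import GeneCircuit, circuit_from_dict
from ..calibrate import HistogramDataset

__all__ = ["FIXTURE_NAMES", "load_fixture", "fixture_path", "make_pseudo_data"]

FIXTURE_NAMES = ("constitutive_1gene", "toggle_switch", "repressilator")


def fixture_path(name: str):
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture '{name}'; choose from {FIXTURE_NAMES}")
    return resources.files(__package__) / f"{name}.yaml"


def load_fixture(name: str) -> GeneCircuit:
    import yaml

    with fixture_path(name).open() as fh:
        return circuit_from_dict(yaml.safe_load(fh))


def _perturbed(circuit: GeneCircuit, perturbation: float, rng) -> GeneCircuit:
    """Multiplicative log-uniform kick exp(U(-p, p)) on all rate constants
    and thresholds; the perturbed values are the recovery ground truth."""
    if perturbation == 0:
        return circuit
    updates = {}
    for name in ("km", "kx", "gm", "gx"):
        vec = getattr(circuit.params, name)
        for i in range(circuit.n_genes):
            updates[f"{name}[{i}]"] = float(
                vec[i] * np.exp(rng.uniform(-perturbation, perturbation)))
    for (i, j) in circuit.topology.edges():
        updates[f"K[{i},{j}]"] = float(
            circuit.params.K[(i, j)]
            * np.exp(rng.uniform(-perturbation, perturbation)))
    return circuit.copy_with(**updates)


def make_pseudo_data(circuit: GeneCircuit, t_points, n_samples: int = 1000,
                     bins: int = 40, seed: int = 0, perturbation: float = 0.0,
                     genes=None) -> tuple[HistogramDataset, GeneCircuit]:
    """Synthetic histogram time series from an SSA ensemble.

    Returns (dataset, ground-truth circuit); with ``perturbation > 0`` the
    generating circuit is a multiplicatively kicked copy of the input and is
    what a calibration run should recover.  Deterministic given ``seed``.
    """
    t_points = np.atleast_1d(np.asarray(t_points, dtype=float))
    if t_points.size == 0:
        raise ValueError("t_points must be nonempty")
    if n_samples < 100:
        raise ValueError("need at least 100 samples for a histogram dataset")
    rng = np.random.default_rng(seed)
    truth = _perturbed(circuit, perturbation, rng)
    if genes is None:
        genes = list(range(circuit.n_genes))
    p = truth.params
    means = p.km * p.kx / (p.gm * p.gx)
    if np.isscalar(bins):
        bin_edges = {g: np.linspace(0.0, 4.0 * float(means[g]), int(bins) + 1)
                     for g in genes}
    else:
        bin_edges = {g: np.asarray(bins[g], dtype=float) for g in genes}
    ens = ssa.ensemble(truth, t_points, n_samples,
                       seed=int(rng.integers(2 ** 31 - 1)))
    # clip stray samples above the stated grid into the top bin
    samples = ens.samples.astype(float).copy()
    for g in genes:
        top = bin_edges[g][-1]
        samples[:, :, g] = np.minimum(samples[:, :, g], top - 1e-9)
    ds = HistogramDataset.from_samples(t_points, samples, genes, bin_edges)
    return ds, truth
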