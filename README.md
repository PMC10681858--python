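# stocirc

Stochastic simulation, model calibration and automated design of gene
regulatory circuits.

## The problem

Gene expression in bacteria and yeast is noisy: mRNA copy numbers are low,
proteins are produced in bursts, and the behavior of a synthetic circuit —
whether a toggle switch commits to one state, whether a repressilator keeps
oscillating — is a property of a *probability distribution*, not of a single
deterministic trajectory. Designing or calibrating circuits in this regime
requires simulating those distributions fast enough to sit inside an
optimization loop, where a plain Gillespie ensemble is usually too slow.

`stocirc` provides both routes behind one circuit definition:

* **SSA** — the exact Gillespie direct method for the reaction network of an
  N-gene circuit (transcription, translation, degradation of mRNA and
  protein; 4N reactions), with a JIT-compiled kernel and reproducible
  ensembles.
* **Distribution solver** — a semi-Lagrangian scheme for the protein-level
  master-equation approximation

  $$\frac{\partial P}{\partial t}(t,X)=\sum_{i=1}^{N}
  \frac{\partial}{\partial X_i}\bigl[\gamma_{x_i} X_i P(t,X)\bigr]
  +\sum_{i=1}^{N} k_{m_i}\Bigl(\int_0^{X_i}\beta_i(X_i-Y_i)\,c_i(Y)\,
  P(t,Y)\,dY_i \;-\; c_i(X)\,P(t,X)\Bigr),$$

  with exponential burst kernel $\beta_i(y)=e^{-y/b_i}/b_i$, burst size
  $b_i=k_{x_i}/\gamma_{m_i}$, and a leaky product-of-Hills promoter input
  function $c_i(X)$. It returns the whole distribution over time and its
  stationary limit, in a fraction of the cost of an equivalent ensemble.

On top of the simulators:

* **Calibration** (`CalibrationModel.fit()`) — maximum-likelihood estimation
  of circuit parameters from histogram time series (e.g. flow-cytometry
  snapshots), minimizing the summed Kullback–Leibler divergence
  $\sum_t D_{\mathrm{KL}}(p^{\mathrm{data}}_t\,\|\,p^{\mathrm{model}}_t)$,
  which for large-count histogram data is the multinomial likelihood up to a
  constant.
* **Automated design** (`design()`) — mixed-integer global search over
  topology entries (−1/0/+1), integer cooperativities and real rate
  constants against behavioral objectives: target (stationary or
  time-resolved) distributions, bimodality with domain probabilities and
  mode distance, or oscillation robustness measured by the second peak of
  the protein autocorrelation function.
* **Global optimizer** — a self-contained scatter-search heuristic for
  box-bounded mixed-integer problems (Latin-hypercube diversification,
  reference-set combination, derivative-free polish), used by both.

Three fixture circuits ship as YAML configs — a constitutive gene, a
bimodal toggle switch and an oscillating repressilator — together with a
synthetic pseudo-data generator, so every pipeline runs without external
data.

## Worked example

```python
import numpy as np
import stocirc as sc
from stocirc import pide

toggle = sc.load_fixture("toggle_switch")   # 2 genes, mutual repression
st = pide.stationary(toggle, grid=pide.make_grid(toggle, 96), tol=1e-5)
print("stationary mean protein levels:", np.round(st.mean(), 2))
for ix in sorted(st.local_maxima(), key=lambda ix: -st.values[ix])[:2]:
    xy = tuple(round(float(st.grid.nodes[a][ix[a]]), 1) for a in range(2))
    print(f"mode at (X1, X2) = {xy}, density {st.values[ix]:.4f}")

from stocirc.design import autocorr_second_peak
rep = sc.load_fixture("repressilator")
x = sc.ensemble(rep, np.arange(1, 20001) * 0.5, 1, seed=5).samples[0, :, 0]
h, lag, _ = autocorr_second_peak(x.astype(float), burn_in=2000, max_lag=400)
print(f"repressilator ACF second peak: height {h:.2f} at lag {lag}")
```

prints

```
stationary mean protein levels: [6.73 6.73]
mode at (X1, X2) = (0.7, 14.1), density 0.0208
mode at (X1, X2) = (14.1, 0.7), density 0.0208
repressilator ACF second peak: height 0.41 at lag 12
```

The toggle's stationary law has two symmetric modes — one gene high
(≈14 molecules) while its partner is repressed to ≈1 — and the
repressilator's protein trajectory is genuinely oscillatory: its
autocorrelation rebounds to 0.41 one period (6 time units) after lag zero.

The same workflows are available from the shell:

```bash
stocirc simulate  --circuit src/stocirc/fixtures/toggle_switch.yaml \
                  --t-end 40 --backend pide --out out/
stocirc make-data --circuit src/stocirc/fixtures/constitutive_1gene.yaml \
                  --times 3,8 --n-samples 1000 --seed 5 --out data/
stocirc calibrate --problem problem.yaml --out fit/
stocirc design    --problem design.yaml  --out best/
```

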