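# Methods

## Model

A circuit of N genes is a signed topology matrix T (T[i,j] = +1 if protein
j activates gene i, −1 if it represses, 0 otherwise) plus kinetic
parameters. Each gene follows the two-stage expression network with
propensities

| reaction            | propensity        |
|---------------------|-------------------|
| ∅ → mRNA_i          | km_i · c_i(X)     |
| mRNA_i → mRNA_i+X_i | kx_i · mRNA_i     |
| mRNA_i → ∅          | γm_i · mRNA_i     |
| X_i → ∅             | γx_i · X_i        |

Units: km in molecules/time; kx, γm, γx in 1/time; the time unit is set by
the protein degradation rate (fixtures use γx = 1, so one time unit is one
protein lifetime).

The promoter input function is a leaky product of Hill terms,

c_i(X) = ε_i + (1 − ε_i) · Π_{j: T[i,j]≠0} h_ij(X_j),

with h_ij = X_j^n / (K^n + X_j^n) for activation and K^n / (K^n + X_j^n)
for repression. ε_i ∈ [0,1) is the promoter leakage. This family is one
common choice among several (a sum-of-Hills variant behaves differently
for multi-input promoters); it is registered under the name
`product_of_hills` and alternatives can be added via
`register_input_function`, which both simulators honor. Unregulated genes
have c_i ≡ 1 (empty product). Time-varying or extrinsic-noise inputs can be
supported through the same hook; no distribution for them ships with the
package.

### Exact simulation

`ssa.simulate` is the Gillespie direct method: exponential waiting time at
the total propensity, linear search for the reaction index. At 4N reactions
per circuit a linear search is not a bottleneck and keeps the kernel
trivially verifiable. Ensembles derive per-run seeds from a master seed via
`numpy.random.SeedSequence`, so results do not depend on execution order.
Identical (circuit, seed) gives bitwise-identical trajectories.

### Distribution dynamics

The protein-level density P(t, X) evolves under a drift term (protein
degradation) plus, per gene, a burst-jump integral term with gain and loss
parts:

∂P/∂t = Σ_i ∂/∂X_i[γx_i X_i P] + Σ_i km_i ( ∫_0^{X_i} β_i(X_i−Y_i) c_i(Y)
P(t, Y) dY_i − c_i(X) P(t, X) ).

The loss part is required for probability conservation and is always
included. β_i is the exponential burst-size density with mean
b_i = kx_i/γm_i, the continuum limit of geometric translational bursts in
the fast-mRNA regime of the two-stage network.

Numerical scheme (per time step, first-order operator splitting, genes in
index order; advection then jump):

1. **Advection** is solved exactly along characteristics:
   P(t+dt, x) = e^{γx dt} P(t, x e^{γx dt}), with the foot value obtained by
   4-point cubic Lagrange interpolation on the uniform grid (linear in the
   two boundary cells, zero beyond the truncation level). A quasi-monotone
   limiter clamps the cubic value to the bounds of the enclosing linear
   stencil; this eliminates over/undershoot entirely — no negative mass is
   ever created by advection — at no measurable accuracy cost on smooth
   densities. Linear interpolation without the cubic correction was
   measured to add O(h²/dt) numerical diffusion that dominates the error
   at small time steps (L1 error 0.055 vs 0.006 on the 200-point 1-gene
   benchmark).
2. **Jump term** by explicit Euler. The gain integral uses a
   product-integration rule: the density is taken piecewise linear between
   nodes and the exponential kernel is integrated exactly per cell, giving
   a precomputed lower-triangular matrix per gene whose rows sum to
   exactly 1 − e^{−x/b}. Sampling the kernel at nodes with trapezoid
   weights instead overestimates the gain by ≈8% when the grid spacing
   equals the burst size (and caused ~1e−3/step mass drift on the toggle
   fixture); the product rule removes that bias at identical O(n²) cost.
   An FFT path would only apply if c_i(y) were constant along the
   integration axis, which regulation generally breaks.
3. Tiny negatives (none observed since the limiter) are clipped and the
   field renormalized to unit trapezoidal mass. Renormalization can be
   disabled for conservation tests; the pre-normalization mass and clipped
   mass of every step are reported in `diagnostics`.

**Grid.** Uniform per gene, from 0 to safety_factor × km·kx/(γm·γx)
(the deterministic mean at full activity), default safety factor 4.
Recommended resolutions for the fixtures: 200 points (constitutive), 96²
(toggle), 64³ with safety factor 2.5 (repressilator). Grid spacing should
not exceed the burst size b by much; the 3-gene default trades this off
against the O(n³) tensor grid. Dense tensor grids cap the solver at 3
genes; higher dimensions are refused with a clear error.

**Time step.** dt = min(0.5 / max_i(γx_i (n_i − 1)), 0.2 / max_i km_i):
characteristic feet move about half a cell at the outer boundary and the
explicit burst update stays well inside stability. The error in dt is
U-shaped (splitting error grows with dt, interpolation diffusion grows as
dt shrinks); this rule sits near the measured optimum. Calls requesting a
larger dt are substepped automatically with a warning.

**Stationary solver.** Repeated stepping from an initial field (default: a
product of per-gene Gamma(km/γx, kx/γm) densities, the single-gene
stationary law at full activity) until the L1 change per unit time falls
below `tol` (default 1e−4), measured every 50 steps; non-convergence within
`max_iter` raises an error carrying the last change rate.

**Validation.** For a constitutive gene the stationary law is
Gamma(a = km/γx, scale b = kx/γm) in closed form. The solver reproduces it
to L1 ≈ 0.006 on a 200-point grid (error falls monotonically with grid
refinement), and the discrete operator moves the exact gamma density at a
rate consistent with discretization error only.

### What the continuum model does and does not capture

The protein-only bursting reduction neglects molecular shot noise: its
stationary Fano factor is b, whereas the exact two-stage network has
1 + kx/(γm + γx) (derived by closing the moment equations, which are exact
here because all propensities are linear). At the constitutive fixture
(b = 1) this is a factor ~1.8 in variance and shows up as a ≈0.1-nat KL
gap between large SSA ensembles and the solved distribution — model
structure, not sampling error (independent 10⁵-sample ensembles agree with
each other to <0.01 nats). The gap shrinks as bursts grow (b ≫ 1) and as
mRNA turnover gets fast relative to protein turnover. The toggle fixture's
cross-simulator KL at matched bins is ≈0.03. Conclusions drawn from the
distribution solver at copy numbers of order one should be checked against
the SSA.

## Calibration

Data are histogram snapshots (1-D marginals per observed gene, optionally a
2-D joint) at stated sampling times; raw samples are binned onto a stated
grid (no kernel density estimation). The cost of a candidate parameter
vector is Σ_times Σ_genes KL(data ‖ model), with model bin masses obtained
by integrating the solved density over the data bins (piecewise-linear CDF)
or, with the SSA backend, by binning ensemble samples. Model bins are
floored at 1e−12 and renormalized to avoid log 0 — standard smoothing with
negligible bias at these bin counts. Failed or non-finite simulations
return a finite penalty (1e6 plus a normalized distance-from-box-center
term) so the optimizer's landscape stays informative.

Rates are searched on log10 scale by default (they span decades);
cooperativities linearly. Both simulators start each candidate from its own
default initial field, so a dataset generated by the model at the true
parameters gives exactly zero cost at the truth — the convention a
synthetic-recovery experiment needs; for real data the initial condition
should be set to the experimental one.

`CalibrationResults.compute_stderr` gives curvature-based approximate
standard errors on the search scale (central-difference diagonal Hessian of
the KL cost scaled by the dataset sample count — multinomial large-count
asymptotics). It ignores parameter correlations; for serious uncertainty
quantification use profile costs instead.

Identifiability matters more than optimizer budget: a single stationary
snapshot of the constitutive gene constrains only a = km/γx, not km and γx
separately (the tests assert exactly this). Transient sampling times break
such degeneracies.

## Automated design

The decision vector concatenates free topology entries (integers in
{−1,0,+1}), free cooperativities (bounded integers, default range 1–4, the
physically sensible span for transcription-factor multimerization) and free
real parameters (log10 where rate-like). Decoding drops the (K, n) pair of
any edge whose topology entry is 0. Objectives:

* `target_stationary` / `target_dynamics` — KL(target ‖ model) on the
  target's own grid, summed over times for the dynamic variant.
* `bimodality` — Σ_domains |mass(domain) − target| plus a hinge
  max(0, min_mode_distance − distance between the two largest strict local
  maxima); fields with fewer than two maxima incur the full hinge.
* `oscillation_autocorr` — minus the height of the second autocorrelation
  peak (the first strict local maximum at positive lag; R(0) = 1 is the
  trivial first peak) of a single fixed-seed SSA protein trajectory,
  default 20 000 samples at interval 0.5 with 2 000 samples burn-in. One
  fixed-seed trajectory rather than an ensemble keeps the objective cheap
  and deterministic; the price is seed-dependence of the objective surface,
  acceptable because peak heights of sustained oscillators are large
  against that noise. Peaks need prominence ≥ 0.01 over the preceding
  trough to exclude noise wiggles. The autocorrelation estimator is
  FFT-based and agrees with the direct O(n·lag) sum to 1e−10.
* An "adaptation to external signals" objective is deliberately absent (no
  standard payload to encode); `register_objective` accepts user-supplied
  kinds.

## Global optimizer

A compact scatter search for box-bounded MINLPs: Latin-hypercube
diversification (10·dim points), a reference set of max(6, dim) members
balancing quality and greedy max–min diversity, pairwise hyper-rectangle
combinations with per-coordinate U(−0.5, 1.5) extrapolation, integer slots
rounded (ties broken at random), greedy replacement, regeneration of the
worst half after 20 stagnant rounds, and a compass-search polish of the
incumbent over real slots near the end of the budget. The evaluation budget
is respected exactly and every run is deterministic given its seed. This is
a deliberately small heuristic — no multistart, no gradient-based local
solvers — sized for the ≤ 15-dimensional problems circuit design produces
here; hyperparameters above are the defaults and are constructor arguments.
Budget 0 is a sentinel meaning "diversification only".

## Fixtures and pseudo-data

Fixture parameters were chosen to exhibit the canonical behaviors and to
keep the continuum solver in its domain of validity:

* `constitutive_1gene` — km=10, kx=5, γm=5, γx=1 (a=10, b=1): tractable
  gamma stationary law, means km/γm = 2 (mRNA) and 10 (protein).
* `toggle_switch` — symmetric mutual repression, km=16, K=3, n=2, ε=0.05:
  bimodal stationary law with well-separated modes. The leakage is set so
  the repressed state's effective gamma shape ε·km/γx stays near 1 — a
  bounded density at X=0, which the continuum representation handles
  cleanly (smaller ε gives an integrable singularity at zero that any
  grid-based scheme resolves poorly).
* `repressilator` — 3-gene repression ring, km=25, kx=20, γm=5, γx=1, K=40,
  n=4, ε=0.02: sustained noisy oscillations (deterministic secant condition
  marginally satisfied; the stochastic system oscillates robustly), ACF
  second peak ≈ 0.4 at one period.

`make_pseudo_data` draws an SSA ensemble at stated times (default bins: 40
uniform bins up to 4× the deterministic mean) and optionally applies a
multiplicative log-uniform kick exp(U(−p, p)) to all rate constants and
thresholds first, returning the kicked circuit as ground truth for
recovery experiments. It emulates idealized snapshot data: independent
samples, no measurement noise, no gating or autofluorescence background as
in real cytometry — recovery results on it demonstrate identifiability and
optimizer adequacy, not robustness to instrument effects.

## Problem sizes used in the shipped checks

Chosen as comfortable desk-scale settings: stationary-law benchmark on 200
grid points; toggle cross-simulator check with 10⁴ SSA runs against a 96²
grid at t=30 with width-2 bins; recovery experiments with 60 (one free
parameter) and 350 (three free parameters) cost evaluations on 64- and
48²-point grids; design recovery with an 81-topology exhaustive oracle at
32² resolution and a 120-evaluation search; oscillation metrics from
20 000-sample trajectories.

## Known limitations

* Dense tensor grids limit the distribution solver to 3 genes.
* The continuum solver's discreteness gap at b ≈ 1 (above).
* First-order splitting: halving dt roughly halves the transient error;
  stationary answers are much less sensitive.
* KL calibration ignores multinomial sampling-noise weighting across bins;
  no profile likelihoods or confidence intervals beyond the curvature
  approximation.
* The oscillation objective scores a single seed's trajectory; rugged for
  near-threshold oscillators.
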