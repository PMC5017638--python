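# Methods

## The model

Each brain region is a Wilson-Cowan neural-mass oscillator: a pair of
population firing rates, excitatory `E_j` and inhibitory `I_j`, obeying

    tau dE_j/dt = -E_j + (S_e_max - E_j) * S_e( c1 E_j - c2 I_j
                    + c5 * sum_k A_jk E_k(t - tau_d_jk) + P_j(t) ) + sigma w_j(t)
    tau dI_j/dt = -I_j + (S_i_max - I_j) * S_i( c3 E_j - c4 I_j ) + sigma v_j(t)

with the shifted sigmoid `S(x) = 1/(1+exp(-a(x-theta))) - 1/(1+exp(a theta))`
(so `S(0)=0`).  Defaults: `tau = 8 ms`, `c1..c4 = 16, 12, 15, 3`,
`a_e = 1.3`, `a_i = 2`, `theta_e = 4`, `theta_i = 3.7`, `sigma = 1e-5`,
`w, v ~ N(0,1)` redrawn every step.  Regions couple only through their
excitatory populations, weighted by the structural matrix `A` and lagged by
conduction delays `tau_d = distance / 10 mm/ms`.  A single uncoupled unit is
tristable in the constant drive `P`: quiescent low fixed point (`P = 0`),
beta-band limit cycle (`P = 1.25`), saturated high fixed point (`P = 2.5`).
Stimulation of a region is a constant current step `P_j = 1.25` over a 1 s
window.

Choices the equations leave open:

* **Rate ceilings** `S_e_max`, `S_i_max` default to the sigmoid suprema
  `1 - 1/(1+exp(a theta))` (~0.9945 and ~0.9994), the classical refractory
  convention that keeps rates inside `[0, S_max)`.  Both are configurable.
* **Noise** is additive per integration step inside the right-hand side
  (`sigma * N(0,1)`, no `sqrt(dt)` scaling).  This reads the model statement
  literally rather than as an Ito SDE; with `sigma = 1e-5` the distinction
  is immaterial for every statistic computed here.  `noise_mode="sqrt_dt"`
  switches to Euler-Maruyama scaling.

## Numerics

Fixed-step forward Euler at `dt = 0.1 ms` with a ring history buffer for the
delayed excitatory rates.  Delays are quantized to integer steps with
round-half-to-even; history before `t = 0` is pre-filled with the initial
condition `E = I = 0.1`.  Preconditions: `dt <= tau/10` and `dt` no larger
than the smallest positive delay between connected regions.  All noise flows
through one `numpy` generator per simulation, so a (network, parameters,
protocol, seed, dt) tuple reproduces trajectories bit for bit.  Adaptive
solvers are ruled out by the delays and the per-step noise; correctness of
the fixed step is checked by a step-halving test in the fixed-point regime
(endpoint shift < 1e-3 when `dt` is halved).

One accuracy consequence matters for headline numbers: the `P = 1.25` limit
cycle of the continuum equations runs at 25.0 Hz (reference adaptive
integration at tolerance 1e-10).  Forward Euler underestimates the frequency
by an amount that grows with the step (23.4 Hz at 0.1 ms, ~22 Hz at 0.2 ms,
~19 Hz at 0.5 ms).  The package reports what it computes at its stated
`dt = 0.1 ms`: ~23.4 Hz, between the coarse-step and continuum values.

## Synthetic connectomes

Real inputs to this kind of study are deterministic-tractography streamline
counts between ~83 parcellated regions, normalized by region volume.  The
generator emulates their summary statistics:

* **Block structure.**  Regions belong to four coarse systems
  (sensory/association 40 %, higher-order cognitive 25 %, default mode 17 %,
  subcortical 18 %).  Edges are independent Bernoulli draws with per-block
  probabilities; the default profile makes subcortex by far the densest
  block (0.412 within), default mode next (0.257), everything else sparse
  (0.025-0.137), matching the empirical ordering for this parcellation scale.
* **Weights.**  Positive edges get log-normal "streamline counts"
  (`mu = 0`, `sigma = 0.6`), divided by the summed volumes of the two
  endpoint regions (volumes are log-normal, unit scale).  The matrix is then
  rescaled so its spectral radius equals `weight_scale` (default 9.75) times
  a per-seed log-normal jitter (SD 0.06).  The rescaling is the synthetic
  analogue of tractography's fixed total streamline count per subject, which
  pins every subject's matrix to a common overall magnitude; the jitter
  carries the residual inter-individual variation.  The default value places
  the coupled model's oscillatory transition inside the standard sweep range
  `c5 in [1.0, 1.5]` (empirically 1.15-1.35 across seeds at N = 83).  The
  weight spread (`sigma = 0.6`) keeps hubs (max/median weighted degree > 2,
  typically 3-6) while letting the transition recruit most regions at once;
  much heavier tails concentrate activity on a single module and blur the
  collective jump.
* **Geometry.**  System cluster centres are placed in a 140 mm cube with
  same-system regions scattered around them (SD 18 mm), a minimum pairwise
  separation of 5 mm, giving conduction delays of 0.5-19 ms at 10 m/s —
  the physiological range for long-range myelinated fibres.

What the generator does *not* emulate: spatially decaying connection
probability, hemispheric symmetry, measured region volumes, or any
individual subject's topology.  Tests passing on these networks show that
the machinery behaves correctly under realistic summary statistics, not that
any particular empirical connectome would yield the same numbers.

## Linear network control

The structural matrix is read as a discrete-time linear propagator after
stabilization `A_norm = A / (1 + lambda_max(A))` (spectral radius < 1 by
construction; the divisor is configurable via an extra margin `epsilon`).
Per region `i`, with `B = e_i` ("control nodes one at a time"):

* **Average controllability** = `Trace(W)` where `A W A^T - W + B B^T = 0`
  (exact discrete Lyapunov solve, O(N^3)); the truncated series
  `sum_t A^t B B^T (A^t)^T` is kept as an independent test oracle.
* **Modal controllability** `phi_i = sum_j (1 - lambda_j^2) v_ij^2` from the
  orthonormal eigendecomposition of `A_norm`; asymmetric input is rejected
  rather than silently reduced to a Schur form, since undirected connectomes
  are always symmetric.  The eigenvalues are those of the *stabilized*
  matrix, consistent with the propagator the Gramian uses.
* **Steady-state response** `x* = (I - A_norm)^{-1} e_i u`, the linear
  analogue of constant-current stimulation, summarized by `max(x*)` and
  `mean(x*)`.

## Functional states and effect statistics

The functional state of a simulation window is the matrix of pairwise
maximum normalized cross-correlations of the excitatory traces: Pearson
correlation at every signed lag up to 250 ms on a 1 s window, maximized over
lags.  The maximum is over *signed* values (these oscillators synchronize
positively; an `use_abs` switch exists).  Each lag's correlation is exact
over the overlapping samples (moments from prefix sums, cross-products via
FFT), so the matrix is symmetric with unit diagonal by construction.
Zero-variance traces (possible only in noise-free runs frozen at a fixed
point) yield FC entries of 0 with a warning instead of NaN.  Maxima landing
on a boundary lag are recorded in `boundary_pairs`.

Comparing the state before stimulation with the state during it:

* **functional effect** — mean |change| over unordered off-diagonal pairs;
* **structural effect** — `corr2(A, fc_during) - corr2(A, fc_before)` with
  `corr2` the Pearson correlation over upper-triangle off-diagonal entries
  (the uninformative diagonals — 0 in A, 1 in FC — are excluded; a flag
  restores the full-matrix convention);
* **fractional activation** — fraction of pairs with |change| strictly above
  a threshold (default 0.6; 0.2 and 0.4 behave consistently, see the
  monotonicity tests).

These satisfy `functional_effect >= threshold * fractional_activation` and
joint-permutation invariance, both enforced by property tests.

## Experiments

**Transition sweep.**  For `c5` on 1.0:0.05:1.5, a 2 s no-stimulation
simulation (first second discarded) records each region's mean excitatory
rate.  The transition is the first grid point whose across-region median
mean-rate exceeds 3x the previous point's median *and* where more than half
the regions exceed a rate floor of 0.05 — an explicit operationalization of
"a sudden jump in rate across most regions".  Both knobs are configurable;
the jump factor alone is insufficient (noise-level medians can triple), the
majority condition alone would fire on single-module activation.  The
operating point for stimulation is the grid point immediately before the
transition.  Near the low state the dynamics are bistable, so the detected
point is specific to the initial condition `E = I = 0.1` and the 1 s
settling window — the same protocol used for the stimulation runs.

**Stimulation campaign.**  Per region: 3 s simulation at the operating
coupling — 1 s settling (discarded), 1 s stimulation-free window, 1 s with
`P = 1.25` into the target region; FC computed per window; the three effect
statistics per region; Spearman rank correlations among
{average/modal controllability, degree, functional effect, structural
effect, fractional activation}; per-system means and standard errors
(SEM = SD/sqrt(n)) and the system-pair edge-density table (within-system
pairs counted as n(n-1)/2).  Per-region simulations draw independent child
seeds from the campaign seed, so the campaign is reproducible end to end
from (network seed, campaign seed).

**Reproducibility (ICC).**  For an I-subjects x J-scans table, two-way
ANOVA mean squares (subjects RMS, scans SMS, error EMS) feed

    ICC_B = J (SMS - EMS) / (J SMS + I RMS + (IJ - I - J) EMS)
    ICC_W = I (RMS - EMS) / (J SMS + I RMS + (IJ - I - J) EMS)

`ICC_W` is the within-subject reproducibility (high when repeat scans agree,
because the between-subject mean square then dominates the error term);
`ICC_B` is high only when different subjects agree.  `var_between` is the
variance of per-subject means, `var_within` the mean per-subject variance.
A constant table makes both ICCs 0/0 and is flagged degenerate.  Balanced
designs only — the mean-square decomposition assumes no missing cells.

## Problem sizes

Default test and example sizes are chosen so each analysis runs in seconds
to a few minutes on a single core: full-size (N = 83) networks for
generation, controllability and transition sweeps; N = 60 for the
sign-structure stimulation campaign; N = 10-20 single-system networks for
pipeline property tests.  All analyses scale to N = 83 unchanged (the
campaign is O(N^2) per region in both simulation and FC).

## Known limitations

* Forward Euler biases limit-cycle frequencies low by a few percent at
  `dt = 0.1 ms` (see Numerics); statistics built on correlations and rate
  jumps are insensitive to this, but absolute frequencies inherit it.
* The transition detector reports the first grid point satisfying its rule;
  on grids that start above the true transition it reports "not found"
  rather than extrapolating below the grid.
* Synthetic connectomes reproduce block densities, weight skew, and delay
  ranges — not the fine topology of measured brains; quantitative effect
  sizes (e.g. exact rank-correlation magnitudes) on real connectomes will
  differ from those on synthetic ones.
* Heterogeneous per-region parameters, conduction-velocity distributions,
  and multi-node control inputs are out of scope by design.
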