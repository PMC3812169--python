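# Methods

This note records the model definition, the derivations behind the analytic
layer, the numerical choices, and the validation strategy. Everything here is
implemented in `src/stemtunnel/` and exercised by `tests/`.

## 1. Model definition

| symbol | meaning | range |
|---|---|---|
| `N` | total number of cells (stem + TA), constant | positive integer |
| `S_target` | expected stem-cell number; `0` = homogeneous mode | `0 ≤ S_target < N` |
| `x_S`, `x_D` | stem fraction `S_target/N` and TA fraction `1 − x_S` | sum to 1 |
| `nu` | probability a stem division is symmetric | `[0, 1]` |
| `r` | relative fitness of one-hit mutants (wild type 1) | `> 0` |
| `u1`, `u2` | per-division probabilities of the first / second hit | `[0, 1]` |
| `p_stem` | P(mutation of an asymmetric division lands in the stem daughter) | `[0, 1/2]` |
| `T_max` | horizon in elementary updates (default `10 N²`) | positive integer |

**Elementary update.** One TA cell dies uniformly at random (in homogeneous
mode: any cell); then a divider is chosen among the `N − 1` remaining cells
with probability proportional to fitness (`1` for wild type, `r` for one-hit
mutants). TA dividers copy themselves, mutating with probability `u1` (wild
type) or producing the absorbing double hit with probability `u2` (one-hit
mutants). Stem dividers divide symmetrically with probability `nu` —
proliferation (two stem daughters) with probability
`clamp(1 − S/(2 S_target), 0, 1)`, else differentiation (two TA daughters) —
and asymmetrically otherwise. A mutation at a wild-type division makes
exactly one daughter a one-hit mutant; at an asymmetric division it lands in
the stem daughter with probability `p_stem`. A "generation" is `N` updates.

Corner case: if no TA cell exists the removal step is skipped for that
update (prevents deadlock in extreme corners; unreachable from the standard
start). The homeostatic control law gives equal proliferation /
differentiation odds exactly at `S = S_target`. Its exact stationary mean
lies slightly below `S_target` (the up/down rates `S(1 − S/2S_t)` and
`S·S/2S_t` are not symmetric in `S`); the test suite checks the simulated
time average against the exact birth–death stationary mean, not against
`S_target` itself.

## 2. Reduced Markov chain

For rare mutants the system is summarized by `(m, n)` = (one-hit stem, one-hit
TA counts) with compartment sizes pinned at `S = S_target`, `D = N − S`.
`transition_probabilities(m, n, params)` enumerates the exact event tree of
one elementary update (which cell died, who divides, division type, mutation
placement) and classifies the outcomes into five classes —
`n → n+1`, `n → n−1`, `(m,n) → (m−1, n+2)`, `m → m+1`, absorption `E` — plus
a `stay` complement and a small `other` class for compound outcomes.

**Symmetric-pair bookkeeping.** In the constant-`S` reduced picture a
symmetric differentiation must be balanced by a symmetric proliferation, so a
symmetric event occupies *two* elementary updates; all symmetric terms
therefore carry a factor `1/2`, and both members of the pair are taken to be
fitness-weighted draws from the stem pool. This convention makes a neutral
mutant stem lineage exactly critical for every `r` (fitness factors out of
the stem-lineage dynamics) and is validated against the agent-based simulator
(the aggregate three-layer agreement below, plus one-step frequency checks).
At homeostatic equilibrium the analytic factor `1/2` coincides numerically
with the control law's proliferation probability `1/2`, which is why one-step
simulator frequencies match the per-update class probabilities at
equilibrium states; compound pair outcomes (`other`) span two updates and are
only comparable as pooled mass.

## 3. Lineage ODEs and the tunneling rate

Let `y_D(t)` (`y_S(t)`) be the probability that the descendant lineage of a
single one-hit TA (stem) cell present at time 0 has produced a double hit by
time `t`, and `q = 1 − y`. Backward (generating-function) arguments over one
elementary update give

```
dq_D/dt = (1 − q_D)/D + (r/N) [ (1 − u2) q_D² − q_D ]
dq_S/dt = (r/N) [ (1−nu) ((1−u2) q_S q_D − q_S)
                + (nu/2) ((1−u2) q_D² − q_S)
                + (nu/2) ((1−u2) q_S² − q_S) ]
```

with `q(0) = 1`. One-hit mutants are injected by wild-type divisions at
per-update source rates

```
a_S = u1 x_S [ (1−nu) p_stem + nu/2 ]
a_D = u1 [ x_D + x_S ( (1−nu)(1−p_stem) + nu/2 ) ]
```

and the cumulative hazard splits into stem and TA channels,
`P(hit by t) = 1 − exp( −∫₀ᵗ (a_S y_S + a_D y_D) ds )`. At `p_stem = 1/2`
the TA source (and hence the TA channel) is exactly independent of `nu`.

**Stationary saturation.** The late-time plateaus `beta = y_D(∞)` and
`alpha = y_S(∞)` satisfy two quadratics. With `c = r x_D`:

```
−c(1−u2) β² + (c(1−2u2) − 1) β + c u2 = 0        (TA lineage)
(nu/2)(1−u2) q² + [ (1−nu)((1−u2)q_D − 1) − nu ] q + (nu/2)(1−u2) q_D² = 0,
q = 1 − alpha, q_D = 1 − beta                     (stem lineage)
```

We take the exact stable roots (the root reached by the flow from `y = 0`)
in closed form rather than by damped fixed-point iteration: near neutrality
the iteration's contraction factor is `1 − O(√u2)` and would need ~`1e8`
steps at `u2 = 1e-7`. The per-update tunneling rate is then
`R_total = R_S + R_D = a_S alpha + a_D beta`, and the first-hit time is
asymptotically exponential with mean `1/R_total` (checked against the
simulator, including unit coefficient of variation at small rates). In the
neutral homogeneous limit the rate reduces to the classical tunneling closed
form `u1 √u2` per update, i.e. `N u1 √u2` per generation — an independent
check on the whole derivation.

## 4. Asymptotic regimes

The exact quadratics admit six closed-form limits, organized on two axes:
criticality of the TA lineage (`A` critical `|1−c| ≪ √(u2 c)`,
`beta = √(u2 c)`; `B` subcritical, `beta = c u2/(1−c)`; `C` supercritical,
`beta = 1 − 1/c`) and dominance of symmetric stem divisions against
`g = u2 + beta` (`1`: `nu ≫ 2g`, `alpha = √(2g/nu)`; `2`: `nu ≪ g`,
`alpha = 1`). `regime_classify` uses a margin of 3 on each inequality and
returns `"none"` between regimes. Deep inside each regime the closed form is
within 10% of the exact rate; at the dominance boundary `nu = 2g` the `1X`
and `2X` forms coincide exactly (`√(2g/nu) = 1`).

## 5. Architecture optimization (closed forms)

All are small-`u2` asymptotics of the exact rate, kept honest by numeric
optimizers (golden-section argmin, Brent root-finding) on the same rate
function:

- **Reduction factor** `R_S(nu=0)/R_S(nu=1) = alpha_asym/alpha_sym ≈ 1/√(2g)`
  — symmetric divisions slow stem-channel double-hit production by orders of
  magnitude (e.g. ≈ 224 at `u2 = 1e-7`, `x_S = 0.01`).
- **Optimal stem fraction** (`nu = 1`): `x_S* = 2 u2^{1/3}` for neutral
  mutants, `x_S* = 2(r−1)` for weakly advantageous ones
  (`u2^{1/3} ≪ r−1 ≪ 1`); no interior optimum for `r < 1` (keep the stem
  pool minimal). The minima are shallow.
- **Equal-contribution threshold** (`R_S = R_D`): for `nu > 0`,
  `x_S = (nu u2/2)^{1/3} σ_S^{−2/3} x_D^{4/3}` with
  `σ_S = (1−nu) p_stem + nu/2`; for `nu = 0` the threshold sits exactly at
  the criticality crossover and solving `p x_S = beta` with the marginal
  quadratic `beta² + x_S beta − u2 = 0` gives
  `x_S = √( u2 / (p_stem (1 + p_stem)) )`. The threshold grows with `u2`.
- **Optimal symmetry fraction** `nu*`: argmin over `nu` of the fixed-horizon
  hit probability (grid of ≥101 points + parabolic refinement). Unbiased
  mutations (`p_stem = 1/2`) give `nu* = 1`; a perfect immortal strand
  (`p_stem = 0`) gives `nu* = 0`; intermediate biases produce interior
  optima.

## 6. Lineage weights

At homeostatic equilibrium each division of a symmetric mutant-stem lineage
adds or removes one member with equal probability — a critical branching
walk absorbed at extinction. Half of all lineages die at the first division
and only `1/M` ever reach size `M` (gambler's ruin). The lineage "weight"
(cumulative size over division events) is a martingale, so its *mean* equals
the asymmetric reference `k` exactly; the protective effect is
distributional: the typical (median) symmetric lineage weighs far less than
`k`, with the mean balanced only by rare long-lived clones. The test asserts
the sampled mean never exceeds `1 + 3·(batch SD)`.

## 7. Numerical choices

- **ODEs:** `scipy.integrate.solve_ivp`, LSODA, `rtol = 1e-8`,
  `atol = 1e-14`, dense output. Four states: `(q_D, q_S)` plus the two
  channel hazard integrals.
- **Oracle:** dense transition matrix of the truncated chain on
  `{0..m_cap} × {0..n_cap} ∪ {E}` (defaults `min(S,15)`, `min(D,60)`),
  iterated `t` steps; boundary occupancy above `1e-6` warns and above `1e-3`
  errors, counted only where the caps actually truncate the state space.
- **Simulator:** numba-JIT kernels (~`1e7` updates/s); a pure-Python
  `abm_step` defines the reference semantics and is compared
  distributionally against the kernel. Seeds derive from
  `numpy.random.SeedSequence(master).spawn`, so every stochastic API is
  bit-reproducible given its `master_seed`.
- **Optimizers:** golden-section (`tol 1e-4`) on `(1/N, 1 − 1/N)`; Brent
  root-finding (`xtol 1e-6`); all deterministic.

## 8. Validation strategy and limitations

Three independent layers — agent-based simulation, the ODE/stationary
theory, and the truncated-chain oracle — are compared on a small tissue
(`N = 30`, `S = 6`, `u1 = u2 = 1e-2`), where they agree within 0.05 absolute
and 3 batch-SD for `nu ∈ {0, 0.5, 1}`. Known limitations:

- The analytic layer assumes rare mutants and constant compartment sizes;
  at large mutation rates (`u ~ 1e-2`) it deviates from the simulator by a
  few percent (bounded by the oracle agreement above).
- The closed-form regime and optimizer formulas are leading-order
  asymptotics, valid deep inside their stated inequality margins.
- Double-hit cells are absorbing: no post-initiation clonal dynamics.
- No spatial structure, niche geometry, or cell-cycle timing.
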