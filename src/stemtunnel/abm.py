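"""Agent-based generalized Moran process for two-hit mutant generation.

One elementary update = (1) random removal of a TA cell (of any cell in the
homogeneous mode), (2) fitness-weighted choice of a divider among the
remaining cells, (3) the division outcome tree: TA divisions replace the dead
cell, wild-type stem cells divide symmetrically (proliferation vs
differentiation steered by the homeostatic control law) or asymmetrically,
and every division can mutate (``u1`` on wild type, ``u2`` -> absorbing
double hit on one-hit mutants).

A pure-Python :func:`abm_step` carries the reference semantics used by the
unit tests; the batch runners use an equivalent numba kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .params import ModelParams, PopulationState, proliferation_probability, validate

COMPARTMENT_NONE = "none"
COMPARTMENT_STEM = "stem"
COMPARTMENT_TA = "TA"
_COMP_NAMES = (COMPARTMENT_NONE, COMPARTMENT_STEM, COMPARTMENT_TA)


@dataclass
class RunResult:
    """Outcome of a single run to absorption or the horizon ``T_max``."""

    hit: bool
    t_updates: int
    state: PopulationState
    compartment_of_hit: str  # "stem" | "TA" | "none", by the dividing parent


@dataclass
class BatchSummary:
    """Monte-Carlo hit-probability estimate with batch-wise dispersion."""

    n_batches: int
    runs_per_batch: int
    p_hat: float
    sd: float
    batch_fractions: np.ndarray


def abm_step(state: PopulationState, params: ModelParams, rng: np.random.Generator) -> PopulationState:
    """Perform one elementary update in place and return the state.

    On a second hit the counts are left as of just after the removal step and
    ``state.hit`` is set; the process must not be stepped further.
    """
    if state.hit:
        raise ValueError("abm_step called on an absorbed state")
    p = params
    # 1) death: one TA cell at random (skipped in the no-TA corner)
    D = state.D0 + state.D1
    if D > 0:
        if rng.random() < state.D0 / D:
            state.D0 -= 1
        else:
            state.D1 -= 1
    # 2) fitness-weighted divider among the remaining cells
    w_s0 = float(state.S0)
    w_s1 = p.r * state.S1
    w_d0 = float(state.D0)
    w_d1 = p.r * state.D1
    u = rng.random() * (w_s0 + w_s1 + w_d0 + w_d1)
    state.t_updates += 1
    if u < w_d0:  # wild-type TA divides
        if rng.random() < p.u1:
            state.D1 += 1
        else:
            state.D0 += 1
    elif u < w_d0 + w_d1:  # one-hit TA divides
        if rng.random() < p.u2:
            state.hit = True
        else:
            state.D1 += 1
    elif u < w_d0 + w_d1 + w_s0:  # wild-type stem divides
        if rng.random() < p.nu:  # symmetric
            if rng.random() < proliferation_probability(state.S, p.S_target):
                if rng.random() < p.u1:
                    state.S1 += 1
                else:
                    state.S0 += 1
            else:  # differentiation: the stem is replaced by two TA cells
                state.S0 -= 1
                if rng.random() < p.u1:
                    state.D1 += 1
                    state.D0 += 1
                else:
                    state.D0 += 2
        else:  # asymmetric: one TA daughter
            if rng.random() < p.u1:
                if rng.random() < p.p_stem:
                    state.S0 -= 1
                    state.S1 += 1
                    state.D0 += 1
                else:
                    state.D1 += 1
            else:
                state.D0 += 1
    else:  # one-hit stem divides
        if rng.random() < p.nu:  # symmetric
            if rng.random() < proliferation_probability(state.S, p.S_target):
                if rng.random() < p.u2:
                    state.hit = True
                else:
                    state.S1 += 1
            else:
                if rng.random() < p.u2:
                    state.hit = True
                else:
                    state.S1 -= 1
                    state.D1 += 2
        else:  # asymmetric
            if rng.random() < p.u2:
                state.hit = True
            else:
                state.D1 += 1
    return state


@njit(cache=False)
def _run_kernel(N, S_target, nu, r, u1, u2, p_stem, t_max, seed):  # pragma: no cover
    np.random.seed(seed)
    S0 = S_target
    S1 = 0
    D0 = N - S_target
    D1 = 0
    comp = 0
    hit = False
    t = 0
    while t < t_max:
        D = D0 + D1
        if D > 0:
            if np.random.random() * D < D0:
                D0 -= 1
            else:
                D1 -= 1
        w_d0 = float(D0)
        w_d1 = r * D1
        w_s0 = float(S0)
        w_s1 = r * S1
        u = np.random.random() * (w_s0 + w_s1 + w_d0 + w_d1)
        t += 1
        if u < w_d0:
            if np.random.random() < u1:
                D1 += 1
            else:
                D0 += 1
        elif u < w_d0 + w_d1:
            if np.random.random() < u2:
                hit = True
                comp = 2
            else:
                D1 += 1
        elif u < w_d0 + w_d1 + w_s0:
            if np.random.random() < nu:
                S = S0 + S1
                prolif = min(1.0, max(0.0, 1.0 - S / (2.0 * S_target)))
                if np.random.random() < prolif:
                    if np.random.random() < u1:
                        S1 += 1
                    else:
                        S0 += 1
                else:
                    S0 -= 1
                    if np.random.random() < u1:
                        D1 += 1
                        D0 += 1
                    else:
                        D0 += 2
            else:
                if np.random.random() < u1:
                    if np.random.random() < p_stem:
                        S0 -= 1
                        S1 += 1
                        D0 += 1
                    else:
                        D1 += 1
                else:
                    D0 += 1
        else:
            if np.random.random() < nu:
                S = S0 + S1
                prolif = min(1.0, max(0.0, 1.0 - S / (2.0 * S_target)))
                if np.random.random() < prolif:
                    if np.random.random() < u2:
                        hit = True
                        comp = 1
                    else:
                        S1 += 1
                else:
                    if np.random.random() < u2:
                        hit = True
                        comp = 1
                    else:
                        S1 -= 1
                        D1 += 2
            else:
                if np.random.random() < u2:
                    hit = True
                    comp = 1
                else:
                    D1 += 1
        if hit:
            break
    return hit, t, S0, S1, D0, D1, comp


@njit(cache=False)
def _moran_fixation_kernel(N, r, seed):  # pragma: no cover
    """Homogeneous Moran run without mutation: 1 if a single r-mutant fixes."""
    np.random.seed(seed)
    wt = N - 1
    mut = 1
    while wt > 0 and mut > 0:
        # death uniform among all, division fitness-weighted among remaining
        if np.random.random() * (wt + mut) < wt:
            wt -= 1
        else:
            mut -= 1
        if np.random.random() * (wt + r * mut) < wt:
            wt += 1
        else:
            mut += 1
    return mut > 0


def _seed_ints(master_seed: int, n: int) -> np.ndarray:
    """Derive ``n`` independent 32-bit seeds deterministically."""
    children = np.random.SeedSequence(master_seed).spawn(n)
    return np.array([c.generate_state(1, np.uint32)[0] for c in children], dtype=np.uint32)


def run_until_double_hit(params: ModelParams, seed: int) -> RunResult:
    """Run one realization from the all-wild-type start to absorption or T_max."""
    p = validate(params)
    hit, t, S0, S1, D0, D1, comp = _run_kernel(
        p.N, p.S_target, p.nu, p.r, p.u1, p.u2, p.p_stem, p.T_max, np.uint32(seed)
    )
    state = PopulationState(S0=S0, S1=S1, D0=D0, D1=D1, t_updates=t, hit=bool(hit))
    return RunResult(hit=bool(hit), t_updates=int(t), state=state,
                     compartment_of_hit=_COMP_NAMES[comp])


def run_hit_times(params: ModelParams, n_runs: int, master_seed: int) -> tuple[np.ndarray, np.ndarray]:
    """First-hit times (in updates) for ``n_runs`` runs.

    Returns ``(times, hit_mask)``; censored runs report ``T_max``.
    """
    p = validate(params)
    seeds = _seed_ints(master_seed, n_runs)
    times = np.empty(n_runs, dtype=np.int64)
    hits = np.empty(n_runs, dtype=bool)
    for i, s in enumerate(seeds):
        hit, t, *_ = _run_kernel(p.N, p.S_target, p.nu, p.r, p.u1, p.u2, p.p_stem, p.T_max, s)
        times[i] = t
        hits[i] = hit
    return times, hits


def estimate_hit_probability(params: ModelParams, runs_per_batch: int = 1000,
                             n_batches: int = 10, master_seed: int = 0) -> BatchSummary:
    """Batched Monte-Carlo estimate of P(double hit by T_max).

    ``p_hat`` is the mean of per-batch hit fractions, ``sd`` their standard
    deviation (ddof=1); the default 10 x 1000 batch structure mirrors the
    standard experiment design. Bit-reproducible for a fixed ``master_seed``.
    """
    if runs_per_batch < 1 or n_batches < 2:
        raise ValueError("need runs_per_batch >= 1 and n_batches >= 2")
    p = validate(params)
    seeds = _seed_ints(master_seed, runs_per_batch * n_batches)
    fractions = np.empty(n_batches)
    k = 0
    for b in range(n_batches):
        nhit = 0
        for _ in range(runs_per_batch):
            hit, *_ = _run_kernel(p.N, p.S_target, p.nu, p.r, p.u1, p.u2,
                                  p.p_stem, p.T_max, seeds[k])
            k += 1
            nhit += int(hit)
        fractions[b] = nhit / runs_per_batch
    return BatchSummary(
        n_batches=n_batches,
        runs_per_batch=runs_per_batch,
        p_hat=float(fractions.mean()),
        sd=float(fractions.std(ddof=1)),
        batch_fractions=fractions,
    )


def moran_fixation_fraction(N: int, r: float, n_runs: int, master_seed: int = 0) -> float:
    """Empirical fixation probability of one r-mutant in the homogeneous model."""
    seeds = _seed_ints(master_seed, n_runs)
    return float(np.mean([_moran_fixation_kernel(N, r, s) for s in seeds]))
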