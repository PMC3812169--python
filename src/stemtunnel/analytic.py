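"""Reduced Markov chain and tunneling-rate theory.

The analytic layer replaces the fluctuating stem count of the simulator by a
constant-compartment Markov chain on ``(m, n)`` = (one-hit stem, one-hit TA)
counts with an absorbing double-hit state ``E``.  To keep the stem count
constant, symmetric divisions come in differentiation + proliferation pairs
combined with two TA deaths; such a paired event lasts two elementary
updates on the biological clock, so every symmetric term carries a factor
1/2 per elementary update.  Both members of the pair are fitness-chosen
among the stem cells, which keeps a mutant stem lineage exactly critical for
every fitness value r (r only rescales its clock), in agreement with the
agent-based rule "divide at rate r, then proliferate or differentiate with
equal probability".

Lineage generating-function analysis gives, per elementary update, the
probabilities ``y_D(t)`` / ``y_S(t)`` that a lineage founded by one mutant
TA / stem cell has produced a double hit within ``t`` updates:

    dq_D/dt = (1 - q_D)/D + (r/N) [(1-u2) q_D^2 - q_D],          q = 1 - y
    dq_S/dt = (r/N) [ (1-nu)((1-u2) q_S q_D - q_S)
                      + (nu/2)((1-u2) q_D^2 - q_S)
                      + (nu/2)((1-u2) q_S^2 - q_S) ]

with q(0) = 1.  New one-hit mutants arise from the wild-type background at
rates ``a_D = u1 [x_D + x_S((1-nu)(1-p) + nu/2)]`` (TA) and
``a_S = u1 x_S [(1-nu) p + nu/2]`` (stem), where ``p = p_stem`` generalizes
the mutation assignment of asymmetric divisions (immortal-strand bias), and

    P_hit(t) = 1 - exp( - int_0^t [a_D y_D + a_S y_S] ds ).

The saturation values ``beta = y_D(inf)`` and ``alpha = y_S(inf)`` solve the
stationary (quadratic) system and assemble the tunneling rate
``R = a_S alpha + a_D beta`` per elementary update, split into the stem
(``R_S``) and TA (``R_D``) production channels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .params import ModelParams, validate


@dataclass(frozen=True)
class MutantState:
    """Reduced chain state: m one-hit stem cells, n one-hit TA cells."""

    m: int = 0
    n: int = 0
    absorbed: bool = False


@dataclass
class TransitionSet:
    """One-update transition probabilities out of ``(m, n)``.

    ``other`` collects composite moves outside the five canonical classes
    (second order in mutant numbers or mutation rates); the oracle folds it
    into ``stay``.
    """

    n_up: float       # (m, n)   -> (m, n+1)
    n_down: float     # (m, n)   -> (m, n-1)
    diff_pair: float  # (m, n)   -> (m-1, n+2)
    m_up: float       # (m, n)   -> (m+1, n)
    hit: float        # (m, n)   -> E
    other: float

    @property
    def stay(self) -> float:
        return 1.0 - (self.n_up + self.n_down + self.diff_pair
                      + self.m_up + self.hit + self.other)

    def as_dict(self) -> dict:
        return {"n_up": self.n_up, "n_down": self.n_down, "diff_pair": self.diff_pair,
                "m_up": self.m_up, "hit": self.hit, "other": self.other,
                "stay": self.stay}


def sources(params: ModelParams) -> tuple[float, float]:
    """Per-update rates (a_S, a_D) of one-hit mutant creation from wild type."""
    p = params
    xS, xD = p.x_S, p.x_D
    a_S = p.u1 * xS * ((1.0 - p.nu) * p.p_stem + 0.5 * p.nu)
    a_D = p.u1 * (xD + xS * ((1.0 - p.nu) * (1.0 - p.p_stem) + 0.5 * p.nu))
    return a_S, a_D


def transition_probabilities(m: int, n: int, params: ModelParams) -> TransitionSet:
    """Exact event-tree enumeration of the reduced chain's one-update moves.

    The enumeration follows the elementary update (one TA death, then a
    fitness-weighted division among the survivors) with symmetric stem events
    treated as half-rate differentiation/proliferation pairs (two TA deaths,
    proliferator fitness-chosen among the remaining stems).
    """
    p = validate(params)
    S, D = p.S_target, p.N - p.S_target
    if m < 0 or n < 0 or m > S or n > D:
        raise ValueError("state outside 0<=m<=S, 0<=n<=D")
    r, nu, u1, u2, ps = p.r, p.nu, p.u1, p.u2, p.p_stem
    s0 = S - m

    acc = {"n_up": 0.0, "n_down": 0.0, "diff_pair": 0.0, "m_up": 0.0,
           "hit": 0.0, "other": 0.0}

    def put(prob, dm, dn, absorbed=False):
        if prob <= 0.0:
            return
        if absorbed:
            acc["hit"] += prob
        elif (dm, dn) == (0, 1):
            acc["n_up"] += prob
        elif (dm, dn) == (0, -1):
            acc["n_down"] += prob
        elif (dm, dn) == (-1, 2):
            acc["diff_pair"] += prob
        elif (dm, dn) == (1, 0):
            acc["m_up"] += prob
        elif (dm, dn) != (0, 0):
            acc["other"] += prob
        # (0, 0) non-absorbed contributes to stay implicitly

    # first death branches: (probability, dn from the death, post-death d0, post-death n)
    deaths = []
    if D - n > 0:
        deaths.append(((D - n) / D, 0, D - n - 1, n))
    if n > 0:
        deaths.append((n / D, -1, D - n, n - 1))

    for pd, dn0, d0x, nx in deaths:
        W = s0 + r * m + d0x + r * nx
        if W <= 0:
            continue
        # --- TA divisions ---
        pr = pd * d0x / W            # wild-type TA divides
        put(pr * (1 - u1), 0, dn0)           # faithful: replaces a TA; net dn0
        put(pr * u1, 0, dn0 + 1)             # mutant daughter
        pr = pd * r * nx / W         # one-hit TA divides
        put(pr * u2, 0, 0, absorbed=True)
        put(pr * (1 - u2), 0, dn0 + 1)
        # --- asymmetric stem divisions ---
        pr = pd * (1 - nu) * s0 / W  # wild-type stem, asymmetric
        put(pr * (1 - u1), 0, dn0)
        put(pr * u1 * ps, 1, dn0)            # stem daughter mutates
        put(pr * u1 * (1 - ps), 0, dn0 + 1)  # TA daughter mutates
        pr = pd * (1 - nu) * r * m / W  # one-hit stem, asymmetric
        put(pr * u2, 0, 0, absorbed=True)
        put(pr * (1 - u2), 0, dn0 + 1)
        # --- symmetric pairs (half rate per elementary update) ---
        if nu > 0.0 and S >= 2 and d0x + nx > 0:
            Dpool = d0x + nx
            sec = [(d0x / Dpool, 0), (nx / Dpool, -1)]  # second TA death
            for x_is_mut in (False, True):
                if x_is_mut:
                    base = 0.5 * pd * nu * r * m / W
                    w_wt, w_mut = s0, r * (m - 1)
                else:
                    base = 0.5 * pd * nu * s0 / W
                    w_wt, w_mut = s0 - 1, r * m
                if base <= 0.0:
                    continue
                Wp = w_wt + w_mut
                if Wp <= 0:
                    continue  # no partner stem available
                for p2, dn2 in sec:
                    for y_is_mut, py in ((False, w_wt / Wp), (True, w_mut / Wp)):
                        b = base * p2 * py
                        if b <= 0.0:
                            continue
                        # differentiator X outcomes
                        if x_is_mut:
                            x_out = [(u2, None), (1 - u2, (-1, 2))]
                        else:
                            x_out = [(u1, (0, 1)), (1 - u1, (0, 0))]
                        # proliferator Y outcomes
                        if y_is_mut:
                            y_out = [(u2, None), (1 - u2, (1, 0))]
                        else:
                            y_out = [(u1, (1, 0)), (1 - u1, (0, 0))]
                        for px_, dx in x_out:
                            for py_, dy in y_out:
                                q = b * px_ * py_
                                if dx is None or dy is None:
                                    put(q, 0, 0, absorbed=True)
                                else:
                                    put(q, dx[0] + dy[0],
                                        dn0 + dn2 + dx[1] + dy[1])
    return TransitionSet(**acc)


@dataclass
class AuxiliarySolution:
    """Lineage hit probabilities over time plus their saturation analysis."""

    t: np.ndarray
    y_D: np.ndarray
    y_S: np.ndarray
    C_D: float          # saturation value of y_D (stable fixed point, = beta)
    C_S: float          # saturation value of y_S (= alpha)
    t_lin: float        # end of y_D's linear stage: C_D / (r u2 / N)
    R_total: float = 0.0
    R_S: float = 0.0
    R_D: float = 0.0
    hit_prob: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"t": self.t, "y_D": self.y_D, "y_S": self.y_S,
                             "hit_prob": self.hit_prob})


def _beta_quad(c: float, u2: float) -> float:
    """Stable fixed point of the TA-lineage Riccati equation (flow from 0).

    ``c = r x_D`` is the criticality parameter of a mutant TA lineage.
    """
    if u2 == 0.0 or c == 0.0:
        return 0.0
    # -c(1-u2) b^2 + (c(1-2u2) - 1) b + c u2 = 0 ; unique positive root
    A = -c * (1.0 - u2)
    B = c * (1.0 - 2.0 * u2) - 1.0
    C = c * u2
    if A == 0.0:  # u2 == 1
        return min(1.0, -C / B) if B != 0 else 1.0
    disc = B * B - 4.0 * A * C
    sq = math.sqrt(disc)
    q = -(B + math.copysign(sq, B)) / 2.0
    roots = [q / A]
    if q != 0.0:
        roots.append(C / q)
    pos = [x for x in roots if x > 0.0]
    return min(min(pos), 1.0) if pos else 0.0


def _alpha_quad(nu: float, u2: float, beta: float) -> float:
    """Stable fixed point of the stem-lineage equation given beta."""
    if u2 == 0.0 and beta == 0.0:
        return 0.0
    if nu == 0.0:
        # purely asymmetric mutant stem: persists forever, hits with prob 1
        return 1.0
    qD = 1.0 - beta
    a = 0.5 * nu * (1.0 - u2)
    b = (1.0 - nu) * ((1.0 - u2) * qD - 1.0) - nu
    c0 = 0.5 * nu * (1.0 - u2) * qD * qD
    disc = b * b - 4.0 * a * c0
    q_minus = 2.0 * c0 / (-b + math.sqrt(max(disc, 0.0)))
    return min(max(1.0 - q_minus, 0.0), 1.0)


def rate_components(x_S: float, nu: float, r: float, u1: float, u2: float,
                    p_stem: float = 0.5) -> tuple[float, float, float]:
    """(R_total, R_S, R_D) per elementary update, for a continuous stem fraction.

    The continuous-fraction form used by the tissue optimizers; the
    params-based :func:`tunneling_rate` wraps it.
    """
    x_D = 1.0 - x_S
    beta = _beta_quad(r * x_D, u2)
    alpha = _alpha_quad(nu, u2, beta) if x_S > 0 else 0.0
    a_S = u1 * x_S * ((1.0 - nu) * p_stem + 0.5 * nu)
    a_D = u1 * (x_D + x_S * ((1.0 - nu) * (1.0 - p_stem) + 0.5 * nu))
    R_S = a_S * alpha
    R_D = a_D * beta
    return R_S + R_D, R_S, R_D


def lineage_saturation(params: ModelParams) -> tuple[float, float]:
    """(alpha, beta): ultimate hit probabilities of one mutant stem / TA lineage."""
    p = validate(params)
    beta = _beta_quad(p.r * p.x_D, p.u2)
    alpha = _alpha_quad(p.nu, p.u2, beta) if p.S_target > 0 else 0.0
    return alpha, beta


def tunneling_rate(params: ModelParams) -> tuple[float, float, float]:
    """Tunneling rate per elementary update: (R_total, R_S, R_D).

    ``R_S = a_S alpha`` counts double hits produced by stem divisions,
    ``R_D = a_D beta`` those produced by TA divisions; the waiting time to
    the first double hit is asymptotically exponential with mean
    ``1 / R_total`` updates.
    """
    p = validate(params)
    return rate_components(p.x_S, p.nu, p.r, p.u1, p.u2, p.p_stem)


def _rhs(params: ModelParams):
    p = params
    N, D = p.N, p.N - p.S_target
    r, nu, u2 = p.r, p.nu, p.u2
    a_S, a_D = sources(p)

    def f(t, y):
        qD, qS = y[0], y[1]
        dqD = (1.0 - qD) / D + (r / N) * ((1.0 - u2) * qD * qD - qD)
        if p.S_target > 0:
            dqS = (r / N) * ((1.0 - nu) * ((1.0 - u2) * qS * qD - qS)
                             + 0.5 * nu * ((1.0 - u2) * qD * qD - qS)
                             + 0.5 * nu * ((1.0 - u2) * qS * qS - qS))
        else:
            dqS = 0.0
        # cumulative hazards of the stem and TA production channels
        return (dqD, dqS, a_S * (1.0 - qS), a_D * (1.0 - qD))

    return f


def _integrate(params: ModelParams, t_end: float):
    sol = solve_ivp(_rhs(params), (0.0, float(t_end)), (1.0, 1.0, 0.0, 0.0),
                    method="LSODA", rtol=1e-8, atol=1e-14, dense_output=True)
    if not sol.success:
        raise RuntimeError(f"auxiliary ODE integration failed near t={sol.t[-1]:g}: "
                           f"{sol.message}")
    return sol


def solve_auxiliary_odes(params: ModelParams, t_grid=None) -> AuxiliarySolution:
    """Integrate the lineage ODEs on ``t_grid`` (elementary updates from 0).

    ``t_grid`` defaults to 200 evenly spaced points on [0, T_max].
    """
    p = validate(params)
    if t_grid is None:
        t_grid = np.linspace(0.0, float(p.T_max), 200)
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t[0] != 0.0 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be increasing and start at 0")
    sol = _integrate(p, t[-1] if t[-1] > 0 else 1.0)
    vals = sol.sol(t)
    y_D = np.clip(1.0 - vals[0], 0.0, 1.0)
    y_S = np.clip(1.0 - vals[1], 0.0, 1.0)
    hit = 1.0 - np.exp(-(vals[2] + vals[3]))
    alpha, beta = lineage_saturation(p)
    slope0 = p.r * p.u2 / p.N
    t_lin = beta / slope0 if slope0 > 0 else math.inf
    R, R_S, R_D = tunneling_rate(p)
    return AuxiliarySolution(t=t, y_D=y_D, y_S=y_S, C_D=beta, C_S=alpha,
                             t_lin=t_lin, R_total=R, R_S=R_S, R_D=R_D,
                             hit_prob=hit)


def hit_probability(t, params: ModelParams, channel: str = "total"):
    """P(double-hit mutant produced within t elementary updates), from (0,0).

    Accepts a scalar or array ``t``; non-decreasing in ``t`` and in [0, 1].
    ``channel`` restricts the hazard to one production route: "total"
    (default), "stem" (mutations in stem lineages only) or "TA".
    """
    p = validate(params)
    if channel not in ("total", "stem", "TA"):
        raise ValueError("channel must be 'total', 'stem' or 'TA'")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    t_end = float(t_arr.max())
    if t_end == 0.0 or p.u1 == 0.0:
        out = np.zeros_like(t_arr)
    else:
        sol = _integrate(p, t_end)
        vals = sol.sol(t_arr)
        hazard = {"total": vals[2] + vals[3], "stem": vals[2], "TA": vals[3]}[channel]
        out = np.clip(1.0 - np.exp(-hazard), 0.0, 1.0)
    return float(out[0]) if np.isscalar(t) or np.asarray(t).ndim == 0 else out


def exact_absorption_oracle(params: ModelParams, t: int,
                            m_cap: int | None = None,
                            n_cap: int | None = None) -> float:
    """Absorption probability by update ``t`` from (0, 0) on the truncated chain.

    Builds the full discrete-time chain on {0..m_cap} x {0..n_cap} + E from
    :func:`transition_probabilities` and iterates the distribution.  Raises if
    occupancy at the truncation boundary ever exceeds 1e-3 and warns above
    1e-6 (caps too small for the requested horizon).
    """
    p = validate(params)
    S, D = p.S_target, p.N - p.S_target
    if m_cap is None:
        m_cap = min(S, 15)
    if n_cap is None:
        n_cap = min(D, 60)
    if m_cap > S or n_cap > D:
        raise ValueError("caps exceed compartment sizes")
    M, Nn = m_cap + 1, n_cap + 1
    nstate = M * Nn

    def idx(m, n):
        return m * Nn + n

    T = np.zeros((nstate, nstate))
    to_E = np.zeros(nstate)
    for m in range(M):
        for n in range(Nn):
            ts = transition_probabilities(m, n, p)
            i = idx(m, n)
            moves = [(ts.n_up, m, n + 1), (ts.n_down, m, n - 1),
                     (ts.diff_pair, m - 1, n + 2), (ts.m_up, m + 1, n)]
            stay_extra = ts.other
            for pr, mm, nn in moves:
                if pr <= 0:
                    continue
                if 0 <= mm < M and 0 <= nn < Nn:
                    T[idx(mm, nn), i] += pr
                else:
                    stay_extra += pr  # clamp at the truncation boundary
            to_E[i] = ts.hit
            T[i, i] += ts.stay + stay_extra
    dist = np.zeros(nstate)
    dist[idx(0, 0)] = 1.0
    absorbed = 0.0
    # occupancy is only an error signal where the cap actually truncates the
    # physical state space
    boundary = np.zeros(nstate, dtype=bool)
    if n_cap < D:
        for m in range(M):
            boundary[idx(m, n_cap)] = True
    if m_cap < S:
        for n in range(Nn):
            boundary[idx(m_cap, n)] = True
    max_boundary = 0.0
    for _ in range(int(t)):
        absorbed += float(to_E @ dist)
        dist = T @ dist
        b = float(dist[boundary].sum())
        if b > max_boundary:
            max_boundary = b
    if max_boundary > 1e-3:
        raise ValueError(f"truncation caps too small: boundary mass {max_boundary:.2e}")
    if max_boundary > 1e-6:
        warnings.warn(f"boundary occupancy reached {max_boundary:.2e}",
                      RuntimeWarning, stacklevel=2)
    return absorbed
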