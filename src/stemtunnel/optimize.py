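"""Tissue-architecture optimization built on the tunneling-rate theory.

Answers the design questions the rate formulas pose: how much slower do
symmetrically dividing stem cells produce double-hit mutants, which stem
fraction minimizes the rate, when do TA cells out-produce stem cells, and
which division symmetry is optimal once the immortal-DNA-strand bias
``p_stem`` is switched on.  All outputs are deterministic.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq

from .params import ModelParams, validate
from .analytic import rate_components, hit_probability


def reduction_factor(params: ModelParams) -> float:
    """Stem-channel rate ratio R_S(nu=0) / R_S(nu=1), all else fixed.

    Measures how many-fold slower purely symmetric stem divisions produce
    double-hit mutants in the stem compartment than purely asymmetric ones;
    >= 1 whenever the one-hit mutation assignment is unbiased.  Defined as 1
    when both rates vanish (u1 = 0).
    """
    p = validate(params)
    if p.p_stem != 0.5:
        raise ValueError("reduction_factor is defined for unbiased mutations (p_stem=1/2)")
    _, rs_asym, _ = rate_components(p.x_S, 0.0, p.r, p.u1, p.u2, p.p_stem)
    _, rs_sym, _ = rate_components(p.x_S, 1.0, p.r, p.u1, p.u2, p.p_stem)
    if rs_sym == 0.0:
        return 1.0
    return rs_asym / rs_sym


def _golden_min(f, lo: float, hi: float, tol: float = 1e-4) -> float:
    """Plain golden-section argmin of a unimodal f on [lo, hi]."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while (b - a) > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


def optimal_stem_fraction(params: ModelParams, mode: str = "numeric") -> float:
    """Stem fraction minimizing the tunneling rate (symmetric model, nu = 1).

    ``numeric`` minimizes R_total over x_S in (1/N, 1 - 1/N) by golden-
    section search; for sufficiently disadvantageous one-hit mutants the rate
    is increasing in x_S and the search returns the lower boundary (keep the
    stem pool as small as possible).  ``closed_form`` evaluates the small-u2
    asymptotics: ``x_S* = 2 u2^(1/3)`` for neutral mutants (r = 1) and
    ``x_S* = 2 (r - 1)`` for weakly advantageous ones
    (u2^(1/3) << r - 1 << 1); there is no interior optimum for r < 1.
    """
    p = validate(params)
    if p.nu != 1.0:
        raise ValueError("stem-fraction optimization assumes the symmetric model (nu=1)")
    if mode == "closed_form":
        if p.r < 1.0:
            raise ValueError("no interior optimum for disadvantageous mutants (r < 1)")
        if p.r == 1.0:
            return 2.0 * p.u2 ** (1.0 / 3.0)
        return 2.0 * (p.r - 1.0)
    if mode != "numeric":
        raise ValueError("mode must be 'closed_form' or 'numeric'")
    lo, hi = 1.0 / p.N, 1.0 - 1.0 / p.N

    def f(x):
        return rate_components(x, 1.0, p.r, p.u1, p.u2, p.p_stem)[0]

    return _golden_min(f, lo, hi)


def contribution_threshold(params: ModelParams, mode: str = "numeric") -> float:
    """Stem fraction at which stem and TA cells contribute equally (R_S = R_D).

    Below the threshold the (much more numerous) TA cells dominate double-hit
    production.  ``numeric`` root-solves R_S(x_S) = R_D(x_S) on
    (1/N, 1 - 1/N); ``approx`` evaluates the small-u2 asymptotic
    ``x_S = (nu u2 / 2)^(1/3) sigma_S^(-2/3) x_D^(4/3)`` with
    ``sigma_S = (1-nu) p_stem + nu/2`` (and its nu = 0 analogue
    ``x_S = sqrt(u2 / (p_stem (1 + p_stem)))``, where the TA lineage is
    marginally critical), refined once in x_D.
    """
    p = validate(params)

    def g(x):
        _, rs, rd = rate_components(x, p.nu, p.r, p.u1, p.u2, p.p_stem)
        return rs - rd

    if mode == "numeric":
        lo, hi = 1.0 / p.N, 1.0 - 1.0 / p.N
        if g(lo) * g(hi) > 0:
            raise ValueError("no threshold in range")
        return float(brentq(g, lo, hi, xtol=1e-6))
    if mode != "approx":
        raise ValueError("mode must be 'approx' or 'numeric'")
    if p.nu == 0.0:
        if p.p_stem == 0.0:
            raise ValueError("no threshold: stem channel is off (nu=0, p_stem=0)")
        # at the nu = 0 threshold the TA lineage is marginally critical
        # (1 - c ~ x_S ~ sqrt(u2)); solving p x_S = beta with the marginal
        # quadratic beta^2 + x_S beta - u2 = 0 gives this closed form
        return math.sqrt(p.u2 / (p.p_stem * (1.0 + p.p_stem)))
    sigma_s = (1.0 - p.nu) * p.p_stem + 0.5 * p.nu
    x0 = (p.nu * p.u2 / 2.0) ** (1.0 / 3.0) * sigma_s ** (-2.0 / 3.0)
    return x0 * (1.0 - x0) ** (4.0 / 3.0)


def optimal_nu(params: ModelParams, horizon: float | None = None,
               n_grid: int = 101, objective: str = "total") -> float:
    """Symmetric-division fraction minimizing P(double hit by ``horizon``).

    Scans ``nu`` on a uniform grid of ``n_grid`` >= 101 points and refines an
    interior minimum by parabolic interpolation.  ``horizon`` defaults to
    ``10 N`` generations (``10 N^2`` elementary updates).  With unbiased
    mutation assignment (p_stem = 1/2) the optimum is fully symmetric
    (nu* = 1); with a perfect immortal strand (p_stem = 0) it is fully
    asymmetric (nu* = 0); intermediate biases can favor a mixture.
    ``objective="stem"`` restricts the objective to double hits produced in
    stem lineages.
    """
    p = validate(params)
    if n_grid < 101:
        raise ValueError("n_grid must be at least 101")
    if horizon is None:
        horizon = 10.0 * p.N * p.N
    channel = {"total": "total", "stem": "stem"}[objective]
    nus = np.linspace(0.0, 1.0, n_grid)
    vals = np.array([hit_probability(horizon, p.with_(nu=float(v)), channel=channel)
                     for v in nus])
    i = int(np.argmin(vals))
    if i == 0 or i == n_grid - 1:
        return float(nus[i])
    # parabolic refinement through the three bracketing grid points
    x0, x1, x2 = nus[i - 1], nus[i], nus[i + 1]
    f0, f1, f2 = vals[i - 1], vals[i], vals[i + 1]
    denom = (f0 - 2.0 * f1 + f2)
    if denom <= 0:
        return float(x1)
    return float(x1 + 0.5 * (x2 - x1) * (f0 - f2) / (2.0 * denom))
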