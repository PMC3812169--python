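"""Asymptotic regimes of the tunneling-rate system.

The stationary lineage quantities alpha (stem) and beta (TA) admit six
closed-form limits, organized along two axes:

* criticality of the TA lineage, measured by ``c = r x_D`` (birth weight of
  a mutant TA relative to its death rate; ``c`` reduces to ``r`` when the
  stem fraction is small):

  - **A** critical, ``|1 - c| << sqrt(u2 c)``:   ``beta = sqrt(u2 c)``
  - **B** subcritical, ``1 - c >> sqrt(u2 c)``:  ``beta = c u2 / (1 - c)``
  - **C** supercritical, ``c - 1 >> sqrt(u2 c)``: ``beta = 1 - 1/c``

* dominance of symmetric divisions in the mutant stem lineage, measured by
  ``nu`` against ``g = u2 + beta``:

  - **1** mixed/symmetric, ``nu >> 2 g``:  ``alpha = sqrt(2 g / nu)``
  - **2** asymmetric, ``nu << g``:         ``alpha = 1``

so e.g. regime "1B" combines a subcritical TA lineage with symmetric-
dominated stem dynamics.  Each approximation is a small-``u2`` asymptotic of
the exact quadratic system; deep inside the stated inequalities it agrees
with the numeric solution to better than 10%.
"""

from __future__ import annotations

import math

from .params import ModelParams, validate
from .analytic import lineage_saturation, sources

REGIMES = ("1A", "1B", "1C", "2A", "2B", "2C")

_MARGIN = 3.0  # classification margin; "none" between regimes


def _beta_branch(letter: str, c: float, u2: float) -> float:
    if u2 == 0.0:
        return 0.0
    if letter == "A":
        return math.sqrt(u2 * c)
    if letter == "B":
        return c * u2 / (1.0 - c)
    if letter == "C":
        return 1.0 - 1.0 / c
    raise ValueError(f"unknown regime letter {letter!r}")


def regime_classify(params: ModelParams, margin: float = _MARGIN) -> str:
    """Return the regime id of ``params`` or ``"none"`` between regimes."""
    p = validate(params)
    c = p.r * p.x_D
    u2 = p.u2
    if u2 <= 0.0 or c <= 0.0:
        return "none"
    s0 = math.sqrt(u2 * c)
    delta = 1.0 - c
    if abs(delta) <= s0 / margin:
        letter = "A"
    elif delta >= margin * s0:
        letter = "B"
    elif delta <= -margin * s0:
        letter = "C"
    else:
        return "none"
    g = u2 + _beta_branch(letter, c, u2)
    if p.nu >= margin * 2.0 * g:
        num = "1"
    elif p.nu <= g / margin:
        num = "2"
    else:
        return "none"
    return num + letter


def regime_approximation(params: ModelParams, regime: str) -> tuple[float, float, float]:
    """Closed-form (alpha, beta, R) for one of the six regimes.

    Returns zeros when ``u1 = 0`` (no one-hit mutants are ever produced, so
    no lineage quantity is realized).
    """
    p = validate(params)
    if regime not in REGIMES:
        raise ValueError(f"regime must be one of {REGIMES}")
    if p.u1 == 0.0:
        return 0.0, 0.0, 0.0
    c = p.r * p.x_D
    beta = _beta_branch(regime[1], c, p.u2)
    g = p.u2 + beta
    if regime[0] == "1":
        alpha = math.sqrt(2.0 * g / p.nu) if p.nu > 0 else math.inf
    else:
        alpha = 1.0
    a_S, a_D = sources(p)
    return alpha, beta, a_S * alpha + a_D * beta


def regime_relative_error(params: ModelParams, regime: str | None = None) -> float:
    """|R_approx - R_numeric| / R_numeric for the (classified) regime."""
    p = validate(params)
    if regime is None:
        regime = regime_classify(p)
        if regime == "none":
            raise ValueError("parameters do not fall inside a regime")
    alpha, beta = lineage_saturation(p)
    a_S, a_D = sources(p)
    r_num = a_S * alpha + a_D * beta
    _, _, r_app = regime_approximation(p, regime)
    return abs(r_app - r_num) / r_num
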