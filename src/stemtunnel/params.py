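"""Parameters, state containers and the homeostatic control law.

The tissue is a constant-size population of ``N`` cells split into a stem
compartment (expected size ``S_target``) and a transit-amplifying (TA)
compartment.  Stem cells divide symmetrically with probability ``nu`` and
asymmetrically otherwise; one-hit mutants carry relative fitness ``r``;
``u1`` and ``u2`` are the per-division probabilities of acquiring the first
and second hit of a tumor-suppressor gene.  ``p_stem`` biases where the
mutation of an asymmetric stem division lands (``1/2`` = unbiased,
``0`` = perfect immortal DNA strand: the stem daughter never mutates).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set of the two-compartment two-hit model.

    Attributes
    ----------
    N : int
        Total population size (stem + TA), held constant by the Moran update.
    S_target : int
        Expected number of stem cells. ``S_target = 0`` selects the
        homogeneous (compartment-free) Moran mode.
    nu : float
        Proportion of symmetric stem-cell divisions, in ``[0, 1]``.
    r : float
        Relative fitness of one-hit mutants (wild type is 1).
    u1, u2 : float
        Per-division probabilities of the first and second hit.
    p_stem : float
        Probability that a mutation arising at an asymmetric stem division
        is assigned to the stem daughter, in ``[0, 1/2]``.
    T_max : int
        Maximum number of elementary updates per simulated run.
    """

    N: int
    S_target: int
    nu: float
    r: float = 1.0
    u1: float = 1e-4
    u2: float = 1e-4
    p_stem: float = 0.5
    T_max: int = 0  # 0 -> default 10*N*N set by validate()

    @property
    def x_S(self) -> float:
        """Stem fraction S_target / N."""
        return self.S_target / self.N

    @property
    def x_D(self) -> float:
        """TA fraction 1 - x_S."""
        return 1.0 - self.S_target / self.N

    @property
    def D(self) -> int:
        """Number of TA cells in the constant-compartment (analytic) view."""
        return self.N - self.S_target

    @property
    def homogeneous(self) -> bool:
        return self.S_target == 0

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ModelParams":
        return validate(cls(**json.loads(text)))

    def with_(self, **kw) -> "ModelParams":
        """Return a validated copy with the given fields replaced."""
        return validate(replace(self, **kw))


def validate(params: ModelParams) -> ModelParams:
    """Check every model invariant; return the (possibly completed) params.

    ``T_max = 0`` is filled in with the default horizon of ``10 * N**2``
    elementary updates (ten generations of N-update generations).
    """
    p = params
    if not (isinstance(p.N, (int,)) and p.N > 0):
        raise ValueError("N must be a positive integer")
    if not (isinstance(p.S_target, (int,)) and p.S_target >= 0):
        raise ValueError("S_target must be a non-negative integer")
    if not p.S_target < p.N:
        raise ValueError("S_target < N required")
    if not (0.0 <= p.nu <= 1.0):
        raise ValueError("nu out of [0,1]")
    if not p.r > 0:
        raise ValueError("r must be positive")
    if not (0.0 <= p.u1 <= 1.0):
        raise ValueError("u1 out of [0,1]")
    if not (0.0 <= p.u2 <= 1.0):
        raise ValueError("u2 out of [0,1]")
    if not (0.0 <= p.p_stem <= 0.5):
        raise ValueError("p_stem out of [0,1/2]")
    if p.T_max == 0:
        p = replace(p, T_max=10 * p.N * p.N)
    if not (isinstance(p.T_max, int) and p.T_max > 0):
        raise ValueError("T_max must be a positive integer")
    return p


def proliferation_probability(S: int, S_target: int) -> float:
    """Probability that a symmetric stem division is a proliferation.

    Linear restoring feedback ``clamp(1 - S / (2 S_target), 0, 1)``: equal
    proliferation / differentiation odds exactly at ``S = S_target``, full
    proliferation at ``S = 0`` and full differentiation at ``S >= 2 S_target``.
    """
    if S_target == 0:
        raise ValueError("proliferation_probability undefined in homogeneous mode")
    if S < 0:
        raise ValueError("S must be non-negative")
    return min(1.0, max(0.0, 1.0 - S / (2.0 * S_target)))


@dataclass
class PopulationState:
    """Agent-based state: counts of the four cell classes.

    ``S0/S1`` wild-type / one-hit stem cells, ``D0/D1`` wild-type / one-hit
    TA cells, ``t_updates`` elapsed elementary updates, ``hit`` whether a
    double-hit mutant has been created (absorbing).
    """

    S0: int
    S1: int
    D0: int
    D1: int
    t_updates: int = 0
    hit: bool = False

    @property
    def S(self) -> int:
        return self.S0 + self.S1

    @property
    def D(self) -> int:
        return self.D0 + self.D1

    @property
    def total(self) -> int:
        return self.S0 + self.S1 + self.D0 + self.D1

    @classmethod
    def initial(cls, params: ModelParams) -> "PopulationState":
        """All-wild-type start with S = S_target, D = N - S_target."""
        return cls(S0=params.S_target, S1=0, D0=params.N - params.S_target, D1=0)
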