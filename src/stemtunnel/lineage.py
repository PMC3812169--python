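"""Mutant stem-cell lineage weights under symmetric divisions.

At homeostatic equilibrium every division of a symmetrically dividing mutant
stem cell either proliferates (+1 lineage member) or differentiates out
(-1), with equal probability: a critical birth-death chain started from a
single founder.  Its cumulative size over division events -- the lineage
"weight", a proxy for the opportunity to catch a second hit -- is compared
with the weight of an asymmetrically dividing lineage, which deterministically
keeps exactly one mutant stem cell and so has weight k after k divisions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class LineageTrajectory:
    """Sizes and weights of one simulated lineage over K division events."""

    sizes: np.ndarray   # size after k = 0..K events; size[0] = 1; absorbing at 0
    W_sym: np.ndarray   # cumulative sum of sizes after each event
    W_asym: np.ndarray  # = k, the asymmetric reference


def _simulate_sizes(K: int, n_reps: int, rng: np.random.Generator) -> np.ndarray:
    """(n_reps, K+1) array of critical +-1 random-walk sizes, absorbed at 0."""
    sizes = np.ones((n_reps, K + 1), dtype=np.int64)
    steps = rng.integers(0, 2, size=(n_reps, K)) * 2 - 1
    for k in range(1, K + 1):
        prev = sizes[:, k - 1]
        nxt = prev + steps[:, k - 1]
        nxt[prev == 0] = 0
        sizes[:, k] = nxt
    return sizes


def simulate_lineage(K: int, rng: np.random.Generator) -> LineageTrajectory:
    """Simulate one mutant stem lineage over K division events."""
    if K < 1:
        raise ValueError("K must be >= 1")
    sizes = _simulate_sizes(K, 1, rng)[0]
    return LineageTrajectory(
        sizes=sizes,
        W_sym=np.cumsum(sizes) - sizes[0],  # weight accrued by the k-th event
        W_asym=np.arange(K + 1, dtype=np.int64),
    )


def extinction_fraction_after_first_division(n_reps: int, master_seed: int = 0) -> float:
    """Fraction of lineages that differentiate out at the very first division."""
    rng = np.random.default_rng(master_seed)
    first = rng.integers(0, 2, size=n_reps)
    return float(np.mean(first == 0))


def reach_probability(M: int, n_reps: int, master_seed: int = 0) -> float:
    """P(lineage size reaches M before extinction); gambler's ruin gives 1/M."""
    rng = np.random.default_rng(master_seed)
    reached = 0
    block = 10_000
    done = 0
    while done < n_reps:
        nb = min(block, n_reps - done)
        size = np.ones(nb, dtype=np.int64)
        active = np.ones(nb, dtype=bool)
        while active.any():
            steps = rng.integers(0, 2, size=int(active.sum())) * 2 - 1
            size[active] += steps
            hit_top = active & (size >= M)
            reached += int(hit_top.sum())
            active &= (size > 0) & (size < M)
        done += nb
    return reached / n_reps


def weight_ratio(K: int, n_reps: int, n_batches: int,
                 master_seed: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-division mean and SD of W_sym(k) / W_asym(k) over batches.

    Returns ``(k, mean_ratio, sd)`` for k = 0..K, with the k = 0 ratio
    defined as 1 (both weights reduce to the founder's presence).  The
    lineage size is a martingale, so the mean symmetric weight never exceeds
    the asymmetric reference beyond sampling noise, while the typical
    (median) weight falls far below it: half the lineages differentiate out
    at the very first division and only rare long-lived lineages balance the
    mean.  Deterministic for a fixed ``master_seed``.
    """
    if K < 1 or n_reps < 1 or n_batches < 2:
        raise ValueError("need K >= 1, n_reps >= 1, n_batches >= 2")
    rng = np.random.default_rng(master_seed)
    k = np.arange(K + 1)
    batch_means = np.empty((n_batches, K + 1))
    for b in range(n_batches):
        sizes = _simulate_sizes(K, n_reps, rng)
        w_sym = np.cumsum(sizes, axis=1) - 1  # weight accrued by event k
        ratio = np.empty((n_reps, K + 1))
        ratio[:, 0] = 1.0
        ratio[:, 1:] = w_sym[:, 1:] / k[1:]
        batch_means[b] = ratio.mean(axis=0)
    return k, batch_means.mean(axis=0), batch_means.std(axis=0, ddof=1)


def extinction_probability_by(K: int, n_reps: int, master_seed: int = 0) -> np.ndarray:
    """Empirical P(extinct by division k), k = 0..K; monotone, -> 1 as k grows."""
    rng = np.random.default_rng(master_seed)
    sizes = _simulate_sizes(K, n_reps, rng)
    return (sizes == 0).mean(axis=0)
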