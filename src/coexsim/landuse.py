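"""Land-use-change mortality.

The yearly fraction of local diversity lost to land conversion is a curve in
the fraction of primary + secondary land lost that step (P_LUC), shaped by a
single parameter S_LUC in [-1, 1]:

    R_1 = 1 - |S_LUC|,  R_2 = sign(S_LUC)
    loss = 1 - (1 - P_LUC)^R_1   if R_2 = -1
    loss = P_LUC^R_1             if R_2 = +1  (or S_LUC = 0, where both
                                              branches reduce to the identity)

S_LUC = 0 is the linear response; S_LUC -> 1 approaches full diversity loss
for any positive habitat loss; S_LUC -> -1 approaches invariance even under
complete habitat loss.  P_LUC = 0 always yields zero loss (no conversion
event, even in the S_LUC = 1 limit where the raw power expression would give
P^0 = 1).

Which species die is controlled by V_LUC in [0, 1]: species are ranked by
decreasing body mass, the ranking is shuffled by floor(V_LUC * S) random
transpositions, and the first n casualties are taken from the top — V_LUC = 0
always kills the largest species, V_LUC = 1 approaches random selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["LandUseParams", "loss_fraction", "select_landuse_casualties", "realized_loss_count"]


@dataclass
class LandUseParams:
    S_LUC: float = 0.0
    V_LUC: float = 0.0

    def __post_init__(self):
        if not -1.0 <= self.S_LUC <= 1.0:
            raise ValueError("S_LUC must lie in [-1, 1]")
        if not 0.0 <= self.V_LUC <= 1.0:
            raise ValueError("V_LUC must lie in [0, 1]")


def loss_fraction(P_LUC: float, S_LUC: float) -> float:
    """Fraction of local diversity lost given habitat-loss fraction P_LUC."""
    if not 0.0 <= P_LUC <= 1.0:
        raise ValueError("P_LUC must lie in [0, 1]")
    if not -1.0 <= S_LUC <= 1.0:
        raise ValueError("S_LUC must lie in [-1, 1]")
    if P_LUC == 0.0:
        return 0.0
    r1 = 1.0 - abs(S_LUC)
    if S_LUC < 0:
        return 1.0 - (1.0 - P_LUC) ** r1
    return P_LUC**r1


def realized_loss_count(loss: float, S: int, rng: np.random.Generator) -> int:
    """Casualty count from a fractional loss with stochastic rounding of the
    remainder, avoiding systematic bias in small communities."""
    expected = loss * S
    n = int(math.floor(expected))
    if rng.random() < expected - n:
        n += 1
    return min(n, S)


def select_landuse_casualties(
    masses: np.ndarray,
    ids: np.ndarray,
    n_loss: int,
    V_LUC: float,
    rng: np.random.Generator,
) -> list[int]:
    """Pick land-use casualties with a tunable body-size bias.

    ``masses`` and ``ids`` are aligned; returns the ids of the first
    ``n_loss`` entries of the mass-sorted, transposition-shuffled list.
    """
    S = len(ids)
    if not 0 <= n_loss <= S:
        raise ValueError("n_loss must lie in [0, S]")
    if n_loss == 0:
        return []
    order = np.argsort(-np.asarray(masses, dtype=float), kind="stable")
    ranked = np.asarray(ids)[order].copy()
    swaps = int(math.floor(V_LUC * S))
    for _ in range(swaps):
        i, j = rng.integers(0, S, size=2)
        ranked[i], ranked[j] = ranked[j], ranked[i]
    return [int(i) for i in ranked[:n_loss]]
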