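"""Local food-web assembly and network state.

A directed link runs from resource i to consumer j when three rules hold:
(i) trophic ordering — the consumer's trophic level strictly exceeds the
resource's and the resource lies within the consumer's trophic breadth;
(ii) the resource:consumer body-mass ratio falls strictly inside the
taxon-pair-specific window (l_l, l_u); (iii) normalized phenotype
compatibility exceeds the threshold c_f (0.55 by default).  Compatibility is
then readjusted to w = 1 - (1 - c_f)/(1 - 0.55) and stored as the link
weight.

Competition for a resource is encoded by the rescaled matrix A': each row
entry is divided by the row's total consumer pressure and multiplied by its
original value, A'_ij = A_ij^2 / sum_j A_ij.  Column sums of A' measure the
resource availability of a consumer, row sums the consumer pressure on a
resource; the coextinction thresholds are the extremes of these quantities at
the time the web is assembled (and are refrozen once after burn-in), so a
freshly built web is at equilibrium by construction.

Connectance uses n^2 in the denominator because no interaction (including
cannibalistic self-links, which the strict trophic ordering happens to
forbid) is excluded a priori.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .species import RatioLimits, SpeciesPool, TraitMatrix, VirtualSpecies, TAXON_INDEX

__all__ = [
    "C_F_DEFAULT",
    "FoodWeb",
    "link_allowed",
    "rescale_link_weight",
    "build_web",
    "rescale_matrix",
    "compute_thresholds",
    "web_metrics",
]

C_F_DEFAULT = 0.55

#: sentinels for webs where a threshold can never trigger
THETA_CONSUMER_NEVER = -np.inf
THETA_RESOURCE_NEVER = np.inf


@dataclass
class FoodWeb:
    """Weighted directed web over a subset of the pool.

    ``idx`` holds pool species ids in community order; ``A[i, j]`` is the
    weight of the resource i -> consumer j link; ``A_prime`` the
    competition-rescaled matrix.
    """

    idx: np.ndarray
    basal: np.ndarray
    A: np.ndarray
    A_prime: np.ndarray = field(default=None)  # type: ignore[assignment]
    theta_consumer: float = THETA_CONSUMER_NEVER
    theta_resource: float = THETA_RESOURCE_NEVER
    frozen: bool = False

    @property
    def n(self) -> int:
        return len(self.idx)

    def availability(self) -> np.ndarray:
        """Resource availability per consumer: column sums of A'."""
        return self.A_prime.sum(axis=0) if self.n else np.empty(0)

    def pressure(self) -> np.ndarray:
        """Consumer pressure per resource: row sums of A'."""
        return self.A_prime.sum(axis=1) if self.n else np.empty(0)


def rescale_matrix(A: np.ndarray) -> np.ndarray:
    """Competition rescaling: A'_ij = A_ij * (A_ij / S_i) with S_i the total
    consumer pressure on resource i; rows with S_i = 0 stay all-zero."""
    A = np.asarray(A, dtype=float)
    if A.size == 0:
        return A.copy()
    S = A.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(S > 0, A * A / np.where(S > 0, S, 1.0), 0.0)
    return out


def rescale_link_weight(c_f: float, c_thresh: float = C_F_DEFAULT) -> float:
    """Linear readjustment of functional compatibility onto [0, 1]:
    0 at the threshold, 1 at perfect compatibility."""
    if c_f < c_thresh:
        raise ValueError(f"compatibility {c_f} below link threshold {c_thresh}")
    return 1.0 - (1.0 - c_f) / (1.0 - c_thresh)


def link_allowed(
    resource: VirtualSpecies,
    consumer: VirtualSpecies,
    limits: RatioLimits,
    tm: TraitMatrix,
    c_thresh: float = C_F_DEFAULT,
) -> tuple[bool, float]:
    """Scalar form of the three link rules; returns (allowed, compatibility)."""
    from .species import phenotype_compatibility

    c_f = phenotype_compatibility(resource.phenotype, consumer.phenotype, tm)
    if not (
        consumer.trophic_level > resource.trophic_level
        and resource.trophic_level >= consumer.trophic_breadth_floor
    ):
        return False, c_f
    ll, lu = limits.lookup(resource.taxon, consumer.taxon)
    ratio = resource.body_mass / consumer.body_mass
    if not (ll < ratio < lu):  # strictly inside the window
        return False, c_f
    return c_f > c_thresh, c_f


def _link_weights(
    pool: SpeciesPool,
    members: np.ndarray,
    limits: RatioLimits,
    tm: TraitMatrix,
    c_thresh: float,
) -> np.ndarray:
    """Vectorized link weights for a community (rows resources, cols consumers)."""
    n = len(members)
    if n == 0:
        return np.zeros((0, 0))
    tl = pool.tl[members]
    floor = pool.floor[members]
    mass = pool.mass[members]
    tax = pool.taxon_idx[members]

    trophic_ok = (tl[None, :] > tl[:, None]) & (tl[:, None] >= floor[None, :])
    ratio = mass[:, None] / mass[None, :]
    ll = limits.ll[tax[:, None], tax[None, :]]
    lu = limits.lu[tax[:, None], tax[None, :]]
    mass_ok = (ratio > ll) & (ratio < lu)

    c = pool.counts[members]
    raw = c @ tm.M @ c.T
    compat = np.clip((raw - tm.norm_min) / (tm.norm_max - tm.norm_min), 0.0, 1.0)

    allowed = trophic_ok & mass_ok & (compat > c_thresh)
    weights = np.where(allowed, 1.0 - (1.0 - compat) / (1.0 - c_thresh), 0.0)
    return weights


def compute_thresholds(web: FoodWeb) -> tuple[float, float]:
    """Extremes of the rescaled sums at the time of computation.

    theta_consumer is the minimum resource availability over *non-basal*
    nodes (basal nodes legitimately have zero vertebrate-resource
    availability); theta_resource the maximum pressure over resources with at
    least one consumer.  Sentinels mean "never triggers".
    """
    if web.n == 0:
        return THETA_CONSUMER_NEVER, THETA_RESOURCE_NEVER
    avail = web.availability()
    press = web.pressure()
    nonbasal = ~web.basal
    theta_c = float(avail[nonbasal].min()) if nonbasal.any() else THETA_CONSUMER_NEVER
    consumed = web.A.sum(axis=1) > 0
    theta_r = float(press[consumed].max()) if consumed.any() else THETA_RESOURCE_NEVER
    return theta_c, theta_r


def build_web(
    members: np.ndarray | list[int],
    pool: SpeciesPool,
    limits: RatioLimits,
    tm: TraitMatrix,
    c_thresh: float = C_F_DEFAULT,
) -> FoodWeb:
    """Assemble a web from a species-id list, dropping non-basal species with
    no resource link (iterated to a fixed point, since a drop can strand its
    consumers).  Basal species always participate.  Thresholds are computed
    for the assembled web (not frozen)."""
    members = np.asarray(sorted(members), dtype=int)
    W = _link_weights(pool, members, limits, tm, c_thresh)
    keep = np.ones(len(members), dtype=bool)
    basal = pool.basal[members]
    while True:
        incoming = (W * keep[:, None]).sum(axis=0) > 0
        drop = keep & ~basal & ~incoming
        if not drop.any():
            break
        keep &= ~drop
    members = members[keep]
    A = W[np.ix_(keep, keep)]
    web = FoodWeb(idx=members, basal=basal[keep], A=A)
    web.A_prime = rescale_matrix(A)
    web.theta_consumer, web.theta_resource = compute_thresholds(web)
    return web


def subset_web(web: FoodWeb, keep: np.ndarray) -> FoodWeb:
    """Surviving sub-web after removals: link rules are deterministic and
    pairwise, so the survivor web is the plain submatrix with A' recomputed.
    Frozen thresholds are carried over unchanged."""
    A = web.A[np.ix_(keep, keep)]
    out = FoodWeb(
        idx=web.idx[keep],
        basal=web.basal[keep],
        A=A,
        theta_consumer=web.theta_consumer,
        theta_resource=web.theta_resource,
        frozen=web.frozen,
    )
    out.A_prime = rescale_matrix(A)
    return out


def reachable_from_basal(A: np.ndarray, basal: np.ndarray) -> np.ndarray:
    """Nodes with a directed path from some basal node (basal included)."""
    reach = basal.copy()
    adj = A > 0
    while True:
        new = reach | (adj[reach, :].any(axis=0) if reach.any() else reach)
        if (new == reach).all():
            return reach
        reach = new


def web_metrics(web: FoodWeb | None, pool: SpeciesPool) -> dict:
    """Structural summary: richness, edges, connectance (E/n^2), diameter on
    the undirected projection (max finite shortest path within components),
    fraction of nodes in the largest weakly connected component, and
    mean/max trophic level and body mass.  Empty webs report zeros."""
    if web is None or web.n == 0:
        return dict(
            richness=0, edges=0, connectance=0.0, diameter=0, lwcc_fraction=0.0,
            mean_tl=0.0, max_tl=0.0, mean_mass=0.0, max_mass=0.0,
            mean_log_mass=0.0,
        )
    n = web.n
    adj = web.A > 0
    edges = int(adj.sum())
    und = csr_matrix(adj | adj.T)
    n_comp, labels = connected_components(und, directed=False)
    lwcc = int(np.bincount(labels).max())
    dist = shortest_path(und, method="D", directed=False, unweighted=True)
    finite = dist[np.isfinite(dist)]
    diameter = int(finite.max()) if finite.size else 0
    tl = pool.tl[web.idx]
    mass = pool.mass[web.idx]
    return dict(
        richness=n,
        edges=edges,
        connectance=edges / n**2,
        diameter=diameter,
        lwcc_fraction=lwcc / n,
        mean_tl=float(tl.mean()),
        max_tl=float(tl.max()),
        mean_mass=float(mass.mean()),
        max_mass=float(mass.max()),
        # masses are log-normal over several orders of magnitude, so the
        # community size structure is summarized on the log scale as well
        mean_log_mass=float(np.log(mass).mean()),
    )
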