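"""Coextinction cascades and colonizer adjudication.

After primary losses are removed from a web, extinctions propagate until a
fixed point.  Within one sweep the three criteria are evaluated against the
same rescaled-matrix snapshot and all marked species are removed
simultaneously:

* bottom_up — a non-basal consumer whose resource availability (column sum of
  A') falls below the frozen consumer threshold;
* top_down — a resource whose consumer pressure (row sum of A') exceeds the
  frozen resource threshold (overconsumption);
* disconnected — a non-basal species with no remaining directed path from any
  basal node.

A species matching several criteria in the same sweep is tagged with the
first in the order above.  Since every sweep either removes at least one node
or stops, the cascade terminates in at most n sweeps.

Colonizers enter through the same machinery: the web is rebuilt with the
candidate included, under the *frozen* resident thresholds (thresholds are
never recomputed on colonization).  Basal colonizers are always admitted but
the locality's basal richness cap is then enforced by removing the
climatically least-suited basal species (ties broken against the most recent
arrival).
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .foodweb import FoodWeb, build_web, rescale_matrix, reachable_from_basal, subset_web
from .species import RatioLimits, SpeciesPool, TraitMatrix

__all__ = ["cascade", "settle", "try_colonize", "REJECTED", "ACCEPTED", "ACCEPTED_WITH_CASCADE"]

REJECTED = "rejected"
ACCEPTED = "accepted"
ACCEPTED_WITH_CASCADE = "accepted_with_cascade"

BOTTOM_UP = "bottom_up"
TOP_DOWN = "top_down"
DISCONNECTED = "disconnected"

#: numerical tie guard: the node whose availability (pressure) *defines* a
#: threshold sits exactly on it and is the equilibrium anchor; re-summation in
#: a different association order must not flip that equality into a violation
EPS = 1e-9


def _sweep_marks(A: np.ndarray, basal: np.ndarray, theta_c: float, theta_r: float):
    """One-sweep extinction marks against a fresh A' snapshot."""
    Ap = rescale_matrix(A)
    avail = Ap.sum(axis=0)
    press = Ap.sum(axis=1)
    bottom = ~basal & (avail < theta_c - EPS)
    top = press > theta_r + EPS
    disc = ~basal & ~reachable_from_basal(A, basal)
    return bottom, top, disc


def settle(web: FoodWeb) -> tuple[FoodWeb, dict[int, str]]:
    """Iterate extinction sweeps on a web until no criterion fires.

    Returns the surviving web (A' recomputed, thresholds carried over) and a
    {species_id: cause} map for every coextinct species.
    """
    causes: dict[int, str] = {}
    alive = np.ones(web.n, dtype=bool)
    ids, basal_all = web.idx, web.basal
    A_full = web.A
    while alive.any():
        sub = np.flatnonzero(alive)
        A = A_full[np.ix_(sub, sub)]
        bottom, top, disc = _sweep_marks(
            A, basal_all[sub], web.theta_consumer, web.theta_resource
        )
        marked = bottom | top | disc
        if not marked.any():
            break
        for k in np.flatnonzero(marked):
            sid = int(ids[sub[k]])
            causes[sid] = BOTTOM_UP if bottom[k] else (TOP_DOWN if top[k] else DISCONNECTED)
        alive[sub[marked]] = False
    return subset_web(web, alive), causes


def cascade(
    web: FoodWeb, primary_losses
) -> tuple[FoodWeb, set[int], dict[int, str]]:
    """Remove primary losses from the web and propagate coextinctions.

    Returns (surviving web, coextinct ids, cause per coextinct id).  Species
    in ``primary_losses`` absent from the web are ignored (they may already
    have failed to participate).
    """
    losses = set(int(s) for s in primary_losses)
    keep = np.array([int(i) not in losses for i in web.idx], dtype=bool)
    out, causes = settle(subset_web(web, keep))
    return out, set(causes), causes


def _enforce_basal_cap(
    web: FoodWeb,
    basal_cap: int,
    ext_of: Callable[[np.ndarray], np.ndarray],
    arrival_of: Callable[[np.ndarray], np.ndarray],
) -> tuple[FoodWeb, list[int]]:
    """Remove excess basal species in increasing order of climatic suitability
    (highest combined extinction probability first; ties: most recent arrival
    first).  Returns the trimmed web and the removed ids (outcompeted)."""
    basal_ids = web.idx[web.basal]
    excess = len(basal_ids) - basal_cap
    if excess <= 0:
        return web, []
    ext = ext_of(basal_ids)
    arr = arrival_of(basal_ids)
    # lexsort: primary key ext desc, secondary arrival desc (newest first)
    order = np.lexsort((-arr, -ext))
    removed = [int(i) for i in basal_ids[order[:excess]]]
    keep = np.array([int(i) not in set(removed) for i in web.idx], dtype=bool)
    return subset_web(web, keep), removed


def try_colonize(
    web: FoodWeb,
    colonizer_id: int,
    pool: SpeciesPool,
    limits: RatioLimits,
    tm: TraitMatrix,
    c_thresh: float,
    basal_cap: int,
    ext_of: Callable[[np.ndarray], np.ndarray],
    arrival_of: Callable[[np.ndarray], np.ndarray],
) -> tuple[str, FoodWeb, dict[int, str]]:
    """Adjudicate a climatically accepted colonizer's entry into a local web.

    Returns (outcome, new web, causes) where causes maps each removed
    *resident* (or the colonizer itself) to outcompeted/bottom_up/top_down/
    disconnected.  The web's frozen thresholds are reused unchanged.
    """
    cid = int(colonizer_id)
    if cid in set(int(i) for i in web.idx):
        return REJECTED, web, {}
    members = np.append(web.idx, cid)
    rebuilt = build_web(members, pool, limits, tm, c_thresh)
    # keep the resident equilibrium thresholds, not the rebuilt ones
    rebuilt.theta_consumer = web.theta_consumer
    rebuilt.theta_resource = web.theta_resource
    rebuilt.frozen = web.frozen

    causes: dict[int, str] = {}
    if pool.basal[cid]:
        trimmed, outcompeted = _enforce_basal_cap(rebuilt, basal_cap, ext_of, arrival_of)
        for sid in outcompeted:
            causes[sid] = "outcompeted"
        settled, casc = settle(trimmed)
        causes.update(casc)
        entered = cid in set(int(i) for i in settled.idx)
        if not causes:
            return (ACCEPTED if entered else REJECTED), settled, {}
        if not entered and set(causes) == {cid}:
            # net no-op: the colonizer alone was displaced right back out
            return REJECTED, settled, {}
        return ACCEPTED_WITH_CASCADE, settled, causes

    if cid not in set(int(i) for i in rebuilt.idx):
        # gained no resource link: entry fails, resident web untouched
        return REJECTED, web, {}
    settled, casc = settle(rebuilt)
    if not casc:
        return ACCEPTED, settled, {}
    return ACCEPTED_WITH_CASCADE, settled, casc
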