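"""World-scale experiment orchestration.

The world is a lattice of localities, each holding a community of virtual
species (with per-population niche state) and, in the coextinction arm, a
weighted food web.  A run proceeds as:

1. populate — seed round(species_per_cell * u) random pool species per cell,
   keep those whose combined extinction probability stays below the cutoff
   for every month of the calibration window, assemble the web and keep only
   participants; record the basal richness cap.
2. burn-in — a dispersal-only phase (climate filter on the calibration
   window) giving communities biogeographic structure; webs are rebuilt every
   ``rebuild_every`` steps with the basal cap enforced; at the end thresholds
   are recomputed once and frozen.
3. forcing years — each year: 12 monthly climate-mortality sweeps (immune
   below the cutoff, Bernoulli above it), the yearly land-use casualty draw,
   the adaptation lottery, then one cascade pass over all of the year's
   primary losses (coextinction arm) while the control arm applies the same
   primary removals with no network, a dispersal round, and metrics.

Both arms start from the same post-burn-in snapshot and consume identically
seeded random streams, so arm differences on one replicate are paired.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cascade import ACCEPTED_WITH_CASCADE, REJECTED, cascade, try_colonize
from .config import SimConfig
from .fixtures import TraitTables
from .foodweb import FoodWeb, build_web, compute_thresholds, web_metrics
from .gridio import GridSeries, LandUseSeries
from .landuse import loss_fraction, realized_loss_count, select_landuse_casualties
from .niche import axis_from_params, combined_ext_params, params_array, shift_niche
from .species import SpeciesPool, derive_ratio_limits, make_species_pool, make_trait_matrix

__all__ = [
    "Community",
    "World",
    "populate",
    "burn_in",
    "step_year",
    "run_arm",
    "run_experiment",
    "coextinction_effect",
    "CAUSES",
]

log = logging.getLogger(__name__)

CAUSES = ("climate", "landuse", "outcompeted", "bottom_up", "top_down", "disconnected")

COEXT = "coext"
CONTROL = "control"


class StreamSet:
    """Named random streams keyed by (process, cell, time).

    Both arms of a replicate are handed StreamSets built from the same base
    entropy, so primary-extinction draws (climate mortality, land-use
    casualties, adaptation lotteries, dispersal attempts) are identical
    wherever the two arms' communities still coincide: arm differences are
    then structural (network effects), not sampling noise.  Mortality and
    adaptation draws are indexed by pool species id, which keeps them paired
    even after community membership diverges.
    """

    MORTALITY, LANDUSE, ADAPTATION, DISPERSAL = 1, 2, 3, 4

    def __init__(self, base_entropy):
        self.base = tuple(int(x) for x in base_entropy)

    def _gen(self, *key) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.base + key))

    def mortality(self, cell: int, month_abs: int) -> np.random.Generator:
        return self._gen(self.MORTALITY, cell, month_abs)

    def landuse(self, cell: int, year: int) -> np.random.Generator:
        return self._gen(self.LANDUSE, cell, year)

    def adaptation(self, cell: int, year: int) -> np.random.Generator:
        return self._gen(self.ADAPTATION, cell, year)

    def dispersal(self, cell: int, year: int, month: int = 0) -> np.random.Generator:
        return self._gen(self.DISPERSAL, cell, year, month)


@dataclass
class Community:
    """Per-cell community state; ``idx`` is kept sorted ascending and the
    per-population niche parameter arrays stay aligned with it."""

    idx: np.ndarray
    nT: np.ndarray
    nP: np.ndarray
    arrival: np.ndarray
    web: FoodWeb | None = None
    basal_cap: int = 0
    richness_cap: int = 0
    initial_richness: int = 0
    initial_nonbasal: int = 0

    @property
    def n(self) -> int:
        return len(self.idx)

    def positions(self, ids: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.idx, ids)

    def has(self, sid: int) -> bool:
        pos = np.searchsorted(self.idx, sid)
        return pos < self.n and self.idx[pos] == sid

    def remove(self, ids) -> None:
        ids = np.asarray(sorted(set(int(i) for i in ids)), dtype=int)
        if ids.size == 0:
            return
        keep = ~np.isin(self.idx, ids)
        self.idx = self.idx[keep]
        self.nT = self.nT[keep]
        self.nP = self.nP[keep]
        self.arrival = self.arrival[keep]

    def add(self, sid: int, nT_row: np.ndarray, nP_row: np.ndarray, arrival: int) -> None:
        pos = int(np.searchsorted(self.idx, sid))
        self.idx = np.insert(self.idx, pos, sid)
        self.nT = np.insert(self.nT, pos, nT_row, axis=0)
        self.nP = np.insert(self.nP, pos, nP_row, axis=0)
        self.arrival = np.insert(self.arrival, pos, arrival)

    def restrict_to(self, ids: np.ndarray) -> None:
        """Subset to ``ids`` (must be a subset of the current members)."""
        keep = np.isin(self.idx, ids)
        self.idx = self.idx[keep]
        self.nT = self.nT[keep]
        self.nP = self.nP[keep]
        self.arrival = self.arrival[keep]


@dataclass
class World:
    config: SimConfig
    climate_T: GridSeries
    climate_P: GridSeries
    landuse: LandUseSeries
    tables: TraitTables
    pool: SpeciesPool | None = None
    tm: object = None
    limits: object = None
    cells: list = field(default_factory=list)
    phase: str = "new"
    arrival_counter: int = 0
    std_T: float = 1.0
    std_P: float = 1.0
    _rings: dict = field(default_factory=dict)

    @property
    def nrows(self) -> int:
        return self.climate_T.nrows

    @property
    def ncols(self) -> int:
        return self.climate_T.ncols

    @property
    def n_cells(self) -> int:
        return self.climate_T.n_cells

    @property
    def calibration_year_span(self) -> int:
        return self.config.calibration_months // 12

    @property
    def forcing_start_year(self) -> int:
        return self.climate_T.start_year + self.calibration_year_span

    def rings(self, cell: int) -> dict[int, np.ndarray]:
        """Cells binned by rounded Euclidean grid distance from ``cell``."""
        if cell not in self._rings:
            r0, c0 = divmod(cell, self.ncols)
            rows, cols = divmod(np.arange(self.n_cells), self.ncols)
            d = np.round(np.hypot(rows - r0, cols - c0)).astype(int)
            out: dict[int, np.ndarray] = {}
            for rd in np.unique(d):
                if rd > 0:
                    out[int(rd)] = np.flatnonzero(d == rd)
            self._rings[cell] = out
        return self._rings[cell]

    def clone_for_arm(self) -> "World":
        """Copy mutable state (communities, counters); share read-only inputs."""
        new = copy.copy(self)
        new.cells = [copy.deepcopy(c) for c in self.cells]
        return new


def build_world(
    tables: TraitTables,
    climate_T: GridSeries,
    climate_P: GridSeries,
    landuse: LandUseSeries,
    config: SimConfig,
    rng: np.random.Generator,
) -> World:
    """Create the species pool, trait matrix and ratio limits for one
    replicate and wrap them with the forcing series."""
    world = World(config, climate_T, climate_P, landuse, tables)
    world.tm = make_trait_matrix(rng, config.norm_pairs)
    world.limits = derive_ratio_limits(tables.interactions, config.ratio_min_records)
    counts = {t: int(n) for t, n in config.pool_counts.items()}
    world.pool = make_species_pool(tables.niche, tables.trophic, counts, rng, config.p_thresh)
    cal = config.calibration_months
    world.std_T = float(climate_T.data[:cal].std()) or 1.0
    world.std_P = float(climate_P.data[:cal].std()) or 1.0
    return world


# ---------------------------------------------------------------------------
# seeding and burn-in
# ---------------------------------------------------------------------------


def _passes_calibration(world: World, cand: np.ndarray, nT, nP, cell: int) -> np.ndarray:
    """True where the combined extinction probability stays strictly below the
    cutoff for every month of the calibration window."""
    cfg = world.config
    ok = np.ones(len(cand), dtype=bool)
    for m in range(cfg.calibration_months):
        t = world.climate_T.data[m, cell]
        p = world.climate_P.data[m, cell]
        ok &= combined_ext_params(nT, nP, t, p) < cfg.p_ext_cutoff
        if not ok.any():
            break
    return ok


def populate(world: World, rng: np.random.Generator) -> World:
    cfg = world.config
    pool = world.pool
    seed_year = world.forcing_start_year - 1
    u = world.landuse.at(seed_year)
    world.cells = []
    for cell in range(world.n_cells):
        n_cand = int(round(cfg.species_per_cell * u[cell]))
        n_cand = min(n_cand, len(pool))
        if n_cand == 0:
            world.cells.append(_empty_community())
            continue
        cand = np.sort(rng.choice(len(pool), size=n_cand, replace=False))
        ok = _passes_calibration(world, cand, pool.nT[cand], pool.nP[cand], cell)
        members = cand[ok]
        web = build_web(members, pool, world.limits, world.tm, cfg.c_f_thresh)
        comm = Community(
            idx=web.idx.copy(),
            nT=pool.nT[web.idx].copy(),
            nP=pool.nP[web.idx].copy(),
            arrival=np.zeros(len(web.idx), dtype=int),
            web=web,
            basal_cap=int(web.basal.sum()),
        )
        world.cells.append(comm)
    world.phase = "seeded"
    return world


def _empty_community() -> Community:
    return Community(
        idx=np.empty(0, dtype=int),
        nT=np.empty((0, 7)),
        nP=np.empty((0, 7)),
        arrival=np.empty(0, dtype=int),
        web=None,
    )


def _calibration_mean(world: World, cell: int) -> tuple[float, float]:
    cal = world.config.calibration_months
    return (
        float(world.climate_T.data[:cal, cell].mean()),
        float(world.climate_P.data[:cal, cell].mean()),
    )


def _rebuild_cell(world: World, cell: int) -> None:
    """Rebuild one cell's web from its community, enforcing the basal cap
    (excess basal species removed in increasing calibration suitability) and
    dropping non-participants."""
    comm = world.cells[cell]
    pool = world.pool
    if comm.n == 0:
        comm.web = None
        return
    basal_mask = pool.basal[comm.idx]
    excess = int(basal_mask.sum()) - comm.basal_cap
    if excess > 0:
        t, p = _calibration_mean(world, cell)
        ext = combined_ext_params(comm.nT, comm.nP, t, p)
        order = np.lexsort((-comm.arrival, -ext))
        basal_pos = order[basal_mask[order]]
        comm.remove(comm.idx[basal_pos[:excess]])
    web = build_web(comm.idx, pool, world.limits, world.tm, world.config.c_f_thresh)
    comm.web = web
    comm.restrict_to(web.idx)


def _dispersal_attempt_burnin(world: World, cell: int, rng: np.random.Generator) -> None:
    comm = world.cells[cell]
    if comm.n == 0:
        return
    k = int(rng.integers(comm.n))
    sid = int(comm.idx[k])
    d = 1.0 + rng.lognormal(0.0, 1.0)
    ring = world.rings(cell).get(int(round(d)))
    if ring is None:
        return  # no cell at that distance: attempt silently fails
    target = int(ring[rng.integers(len(ring))])
    tcomm = world.cells[target]
    if tcomm.has(sid):
        return
    nT_row, nP_row = comm.nT[k], comm.nP[k]
    ok = _passes_calibration(world, np.array([sid]), nT_row[None], nP_row[None], target)
    if not ok[0]:
        return
    world.arrival_counter += 1
    tcomm.add(sid, nT_row.copy(), nP_row.copy(), world.arrival_counter)


def burn_in(world: World, rng: np.random.Generator, steps: int | None = None) -> World:
    """Dispersal-only burn-in; freezes coextinction thresholds at the end."""
    cfg = world.config
    steps = cfg.burn_in_steps if steps is None else steps
    for step in range(steps):
        for cell in range(world.n_cells):
            _dispersal_attempt_burnin(world, cell, rng)
        if (step + 1) % cfg.rebuild_every == 0:
            for cell in range(world.n_cells):
                _rebuild_cell(world, cell)
    for cell in range(world.n_cells):
        _rebuild_cell(world, cell)
        comm = world.cells[cell]
        if comm.web is not None:
            comm.web.theta_consumer, comm.web.theta_resource = compute_thresholds(comm.web)
            comm.web.frozen = True
        comm.richness_cap = comm.n
        comm.initial_richness = comm.n
        comm.initial_nonbasal = int((~world.pool.basal[comm.idx]).sum())
    world.phase = "burned_in"
    return world


# ---------------------------------------------------------------------------
# forcing years
# ---------------------------------------------------------------------------


def _year_mean_conditions(world: World, year: int) -> tuple[np.ndarray, np.ndarray]:
    return world.climate_T.year_mean(year), world.climate_P.year_mean(year)


def _control_enforce_cap(
    world, cell, tallies, events, year, t, p
) -> None:
    comm = world.cells[cell]
    excess = comm.n - comm.richness_cap
    if excess <= 0:
        return
    ext = combined_ext_params(comm.nT, comm.nP, t, p)
    order = np.lexsort((-comm.arrival, -ext))
    doomed = comm.idx[order[:excess]]
    for sid in doomed:
        tallies[cell]["outcompeted"] += 1
        events.append((year, cell, int(sid), "outcompeted"))
    comm.remove(doomed)


def _dispersal_round(world, arm, year, streams, tallies, gains, events, month=0) -> None:
    cfg = world.config
    pool = world.pool
    t_mean, p_mean = _year_mean_conditions(world, year)
    for cell in range(world.n_cells):
        comm = world.cells[cell]
        if comm.n == 0:
            continue
        rng = streams.dispersal(cell, year, month)
        k = int(rng.integers(comm.n))
        sid = int(comm.idx[k])
        d = 1.0 + rng.lognormal(0.0, 1.0)
        ring = world.rings(cell).get(int(round(d)))
        if ring is None:
            continue
        target = int(ring[rng.integers(len(ring))])
        tcomm = world.cells[target]
        if tcomm.has(sid):
            continue
        nT_row, nP_row = comm.nT[k].copy(), comm.nP[k].copy()
        ext_col = float(
            combined_ext_params(nT_row[None], nP_row[None], t_mean[target], p_mean[target])[0]
        )
        if rng.random() < ext_col:
            continue  # climatic acceptance draw failed
        world.arrival_counter += 1
        arrival = world.arrival_counter

        if arm == CONTROL:
            tcomm.add(sid, nT_row, nP_row, arrival)
            gains[target] += 1
            _control_enforce_cap(
                world, target, tallies, events, year, t_mean[target], p_mean[target]
            )
            continue

        web = tcomm.web
        if web is None or tcomm.basal_cap == 0 and pool.basal[sid]:
            continue

        def ext_of(ids, _t=t_mean[target], _p=p_mean[target], _tc=tcomm,
                   _sid=sid, _nT=nT_row, _nP=nP_row):
            nT = np.empty((len(ids), 7))
            nP = np.empty((len(ids), 7))
            for i, q in enumerate(ids):
                if int(q) == _sid:
                    nT[i], nP[i] = _nT, _nP
                else:
                    pos = int(_tc.positions(np.array([q]))[0])
                    nT[i], nP[i] = _tc.nT[pos], _tc.nP[pos]
            return combined_ext_params(nT, nP, _t, _p)

        def arrival_of(ids, _tc=tcomm, _sid=sid, _arr=arrival):
            out = np.empty(len(ids), dtype=int)
            for i, q in enumerate(ids):
                out[i] = _arr if int(q) == _sid else int(
                    _tc.arrival[int(_tc.positions(np.array([q]))[0])]
                )
            return out

        outcome, new_web, causes = try_colonize(
            web, sid, pool, world.limits, world.tm, cfg.c_f_thresh,
            tcomm.basal_cap, ext_of, arrival_of,
        )
        if outcome == REJECTED and not causes:
            # the resident web may still have been pruned in the basal branch
            if new_web is not web:
                tcomm.web = new_web
                tcomm.restrict_to(new_web.idx)
            continue
        # apply the new web: survivors keep their niche rows, colonizer gets its own
        entered = any(int(i) == sid for i in new_web.idx)
        if entered:
            tcomm.add(sid, nT_row, nP_row, arrival)
            gains[target] += 1
        for rid, cause in causes.items():
            if rid == sid and not entered:
                continue  # colonizer removed by its own entry cascade
            tallies[target][cause] += 1
            events.append((year, target, int(rid), cause))
        tcomm.web = new_web
        tcomm.restrict_to(new_web.idx)


def step_year(world: World, arm: str, year: int, streams: StreamSet):
    """Advance one forcing year; returns per-cell metric records."""
    cfg = world.config
    pool = world.pool
    n_pool = len(pool)
    tallies = [dict.fromkeys(CAUSES, 0) for _ in range(world.n_cells)]
    gains = [0] * world.n_cells
    pending: list[set[int]] = [set() for _ in range(world.n_cells)]
    events: list[tuple] = []

    # (1) monthly climate mortality (draws indexed by pool id for pairing)
    for month in range(1, 13):
        t_row = world.climate_T.at(year, month)
        p_row = world.climate_P.at(year, month)
        m_abs = world.climate_T.month_index(year, month)
        for cell in range(world.n_cells):
            comm = world.cells[cell]
            if comm.n == 0:
                continue
            ext = combined_ext_params(comm.nT, comm.nP, t_row[cell], p_row[cell])
            mortal = ext > cfg.p_ext_cutoff
            if not mortal.any():
                continue
            draws = streams.mortality(cell, m_abs).random(n_pool)[comm.idx]
            dead = mortal & (draws < ext)
            if not dead.any():
                continue
            doomed = comm.idx[dead]
            for sid in doomed:
                tallies[cell]["climate"] += 1
                events.append((year, cell, int(sid), "climate"))
            pending[cell].update(int(s) for s in doomed)
            comm.remove(doomed)
        if cfg.dispersal == "monthly":
            _dispersal_round(world, arm, year, streams, tallies, gains, events, month)

    # (2) yearly land-use casualties
    u_now = world.landuse.at(year)
    u_prev = world.landuse.at(year - 1)
    for cell in range(world.n_cells):
        comm = world.cells[cell]
        if comm.n == 0 or u_prev[cell] <= 0:
            continue
        p_luc = float(np.clip((u_prev[cell] - u_now[cell]) / u_prev[cell], 0.0, 1.0))
        loss = loss_fraction(p_luc, cfg.S_LUC)
        lrng = streams.landuse(cell, year)
        n_loss = realized_loss_count(loss, comm.n, lrng)
        if n_loss == 0:
            continue
        doomed = select_landuse_casualties(
            pool.mass[comm.idx], comm.idx, n_loss, cfg.V_LUC, lrng
        )
        for sid in doomed:
            tallies[cell]["landuse"] += 1
            events.append((year, cell, int(sid), "landuse"))
        pending[cell].update(doomed)
        comm.remove(doomed)

    # (3) adaptation lottery: shift toward the preceding year's local means
    if cfg.p_adp > 0:
        t_prev, p_prev = _year_mean_conditions(world, year - 1)
        for cell in range(world.n_cells):
            comm = world.cells[cell]
            if comm.n == 0:
                continue
            adraws = streams.adaptation(cell, year).random(n_pool)[comm.idx]
            hits = np.flatnonzero(adraws < cfg.p_adp)
            for k in hits:
                sid = int(comm.idx[k])
                ax_t = axis_from_params(comm.nT[k], cfg.p_thresh)
                ax_p = axis_from_params(comm.nP[k], cfg.p_thresh)
                new_t, new_p = shift_niche(
                    ax_t, ax_p, float(t_prev[cell]), float(p_prev[cell]),
                    cfg.C_adp, pool.adaptive[sid], world.std_T, world.std_P,
                )
                comm.nT[k] = params_array([new_t])[0]
                comm.nP[k] = params_array([new_p])[0]

    # (4) cascades (coextinction arm) over all of the year's primary losses
    if arm == COEXT:
        for cell in range(world.n_cells):
            comm = world.cells[cell]
            if comm.web is None:
                continue
            if not pending[cell]:
                continue
            new_web, coextinct, causes = cascade(comm.web, pending[cell])
            for sid, cause in causes.items():
                tallies[cell][cause] += 1
                events.append((year, cell, int(sid), cause))
            comm.web = new_web
            comm.restrict_to(new_web.idx)

    # (5) dispersal
    if cfg.dispersal == "yearly":
        _dispersal_round(world, arm, year, streams, tallies, gains, events)

    # (6) metrics
    records = []
    for cell in range(world.n_cells):
        comm = world.cells[cell]
        if arm == COEXT:
            rec = web_metrics(comm.web, pool)
        else:
            rec = _community_summary(comm, pool)
        rec.update(
            cell=cell,
            year=year,
            arm=arm,
            richness_nonbasal=int((~pool.basal[comm.idx]).sum()),
            immigrated=gains[cell],
            **{f"n_{c}": tallies[cell][c] for c in CAUSES},
        )
        records.append(rec)
    return records, events


def _community_summary(comm: Community, pool: SpeciesPool) -> dict:
    """Control-arm summary: no network, so structural metrics are undefined."""
    if comm.n == 0:
        return dict(
            richness=0, edges=np.nan, connectance=np.nan, diameter=np.nan,
            lwcc_fraction=np.nan, mean_tl=0.0, max_tl=0.0, mean_mass=0.0,
            max_mass=0.0, mean_log_mass=0.0,
        )
    tl = pool.tl[comm.idx]
    mass = pool.mass[comm.idx]
    return dict(
        richness=comm.n, edges=np.nan, connectance=np.nan, diameter=np.nan,
        lwcc_fraction=np.nan, mean_tl=float(tl.mean()), max_tl=float(tl.max()),
        mean_mass=float(mass.mean()), max_mass=float(mass.max()),
        mean_log_mass=float(np.log(mass).mean()),
    )


def run_arm(world: World, arm: str, years: int, streams: StreamSet):
    """Run one arm for ``years`` forcing years on (a clone of) a burned-in
    world.  The control arm drops all webs first."""
    if world.phase != "burned_in":
        raise RuntimeError("world must be burned in before forcing years")
    if arm == CONTROL:
        for comm in world.cells:
            comm.web = None
    all_records, all_events = [], []
    y0 = world.forcing_start_year
    for year in range(y0, y0 + years):
        records, events = step_year(world, arm, year, streams)
        all_records.extend(records)
        all_events.extend(events)
    world.phase = "done"
    return pd.DataFrame(all_records), pd.DataFrame(
        all_events, columns=["year", "cell", "species_id", "cause"]
    )


def coextinction_effect(loss_coext: float, loss_control: float) -> float:
    """Percentage increase in diversity loss caused by network effects;
    returns NaN (excluded from averages) when the control loss is zero."""
    if loss_coext < 0 or loss_control < 0:
        raise ValueError("losses must be non-negative")
    if loss_control == 0:
        return float("nan")
    return 100.0 * (loss_coext - loss_control) / loss_control


def web_edge_frame(world: World) -> pd.DataFrame:
    """All current webs as one tidy edge list (cell, resource_id,
    consumer_id, weight, weight_rescaled)."""
    rows = []
    for cell, comm in enumerate(world.cells):
        if comm.web is None or comm.web.n == 0:
            continue
        r_idx, c_idx = np.nonzero(comm.web.A)
        for i, j in zip(r_idx, c_idx):
            rows.append(
                (
                    cell,
                    int(comm.web.idx[i]),
                    int(comm.web.idx[j]),
                    float(comm.web.A[i, j]),
                    float(comm.web.A_prime[i, j]),
                )
            )
    return pd.DataFrame(
        rows, columns=["cell", "resource_id", "consumer_id", "weight", "weight_rescaled"]
    )


def run_experiment(
    tables: TraitTables,
    climate_T: GridSeries,
    climate_P: GridSeries,
    landuse: LandUseSeries,
    config: SimConfig,
    master_seed: int,
):
    """Full paired experiment: per replicate, an independently regenerated
    species pool and trait matrix, one shared burn-in, and both arms run from
    the same snapshot with identically seeded streams.

    Returns a dict with 'metrics' and 'events' DataFrames, a per-replicate
    'summary' DataFrame (losses per arm), the config and the seeds used.
    """
    arms = {"both": (COEXT, CONTROL), "coext": (COEXT,), "control": (CONTROL,)}[
        config.arms
    ]
    metrics, events, summary = [], [], []
    webs: dict[str, pd.DataFrame] = {}
    rep_seeds = []
    for rep in range(config.replicates):
        setup_rng = np.random.default_rng(np.random.SeedSequence((master_seed, rep, 0)))
        rep_seeds.append([master_seed, rep])
        world = build_world(tables, climate_T, climate_P, landuse, config, setup_rng)
        populate(world, setup_rng)
        burn_in(world, setup_rng)
        initial = sum(c.n for c in world.cells)
        initial_nb = sum(c.initial_nonbasal for c in world.cells)
        pooled0 = np.concatenate([c.idx for c in world.cells if c.n]) if initial else None
        lm0 = float(np.log(world.pool.mass[pooled0]).mean()) if initial else 0.0
        for arm in arms:
            arm_world = world.clone_for_arm()
            streams = StreamSet((master_seed, rep, 1))
            mdf, edf = run_arm(arm_world, arm, config.years, streams)
            if arm == COEXT:
                webs[f"rep{rep}_{arm}"] = web_edge_frame(arm_world)
            mdf.insert(0, "replicate", rep)
            edf.insert(0, "replicate", rep)
            edf.insert(1, "arm", arm)
            metrics.append(mdf)
            events.append(edf)
            final = sum(c.n for c in arm_world.cells)
            final_nb = sum(
                int((~world.pool.basal[c.idx]).sum()) for c in arm_world.cells
            )
            pooled1 = (
                np.concatenate([c.idx for c in arm_world.cells if c.n]) if final else None
            )
            lm1 = float(np.log(world.pool.mass[pooled1]).mean()) if final else 0.0
            summary.append(
                dict(
                    replicate=rep,
                    arm=arm,
                    initial_richness=initial,
                    final_richness=final,
                    loss=(initial - final) / initial if initial else 0.0,
                    initial_nonbasal=initial_nb,
                    final_nonbasal=final_nb,
                    loss_nonbasal=(initial_nb - final_nb) / initial_nb
                    if initial_nb
                    else 0.0,
                    mean_log_mass_initial=lm0,
                    mean_log_mass_final=lm1,
                )
            )
        log.info("replicate %d/%d done", rep + 1, config.replicates)
    return {
        "metrics": pd.concat(metrics, ignore_index=True) if metrics else pd.DataFrame(),
        "events": pd.concat(events, ignore_index=True) if events else pd.DataFrame(),
        "summary": pd.DataFrame(summary),
        "webs": webs,
        "config": config.to_dict(),
        "master_seed": master_seed,
        "replicate_seeds": rep_seeds,
    }


def draw_sensitivity_config(base: SimConfig, rng: np.random.Generator) -> SimConfig:
    """Parameter-randomization harness: uniform draws over the sensitivity
    ranges (burn-in steps 0-1000, c_f 0.45-0.65, p_adp 0-0.005, C_adp 0-0.05,
    S_LUC -1-1, V_LUC 0-1)."""
    d = base.to_dict()
    d.update(
        burn_in_steps=int(rng.integers(0, 1001)),
        c_f_thresh=float(rng.uniform(0.45, 0.65)),
        p_adp=float(rng.uniform(0.0, 0.005)),
        C_adp=float(rng.uniform(0.0, 0.05)),
        S_LUC=float(rng.uniform(-1.0, 1.0)),
        V_LUC=float(rng.uniform(0.0, 1.0)),
    )
    return SimConfig.from_dict(d)
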