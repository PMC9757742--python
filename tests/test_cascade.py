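"""Cascade propagation against an independent fixed-point oracle, and
colonizer adjudication."""

import numpy as np
import pytest

from coexsim.cascade import (
    ACCEPTED,
    ACCEPTED_WITH_CASCADE,
    REJECTED,
    cascade,
    try_colonize,
)
from coexsim.foodweb import FoodWeb, build_web, compute_thresholds, rescale_matrix
from coexsim.niche import fit_axis
from coexsim.species import RatioLimits, TraitMatrix, VirtualSpecies, pack_pool


def brute_force_cascade(A, basal, theta_c, theta_r, primary, eps=1e-9):
    """Pure-python fixed-point oracle recomputing every sum from scratch.

    ``eps`` mirrors the engine's numerical tie guard: a node exactly at a
    threshold (the node that defined it) is the equilibrium anchor, and
    summation-order noise must not count as a violation.
    """
    n = len(basal)
    alive = [i for i in range(n) if i not in primary]
    while True:
        # rescaled matrix from scratch
        Ap = [[0.0] * n for _ in range(n)]
        for i in alive:
            s = sum(A[i][j] for j in alive)
            if s > 0:
                for j in alive:
                    Ap[i][j] = A[i][j] * (A[i][j] / s)
        # reachability from basal along resource -> consumer links
        reach = {i for i in alive if basal[i]}
        changed = True
        while changed:
            changed = False
            for i in list(reach):
                for j in alive:
                    if A[i][j] > 0 and j not in reach:
                        reach.add(j)
                        changed = True
        marked = set()
        for j in alive:
            if not basal[j] and sum(Ap[i][j] for i in alive) < theta_c - eps:
                marked.add(j)
        for i in alive:
            if sum(Ap[i][j] for j in alive) > theta_r + eps:
                marked.add(i)
        for j in alive:
            if not basal[j] and j not in reach:
                marked.add(j)
        if not marked:
            return set(alive)
        alive = [i for i in alive if i not in marked]


def random_equilibrium_web(rng, n_max=10):
    """Random weighted web with thresholds computed at creation (equilibrium)."""
    n = int(rng.integers(2, n_max + 1))
    A = rng.uniform(0.05, 1.0, (n, n)) * (rng.random((n, n)) < 0.45)
    np.fill_diagonal(A, 0.0)
    basal = rng.random(n) < 0.4
    if not basal.any():
        basal[0] = True
    web = FoodWeb(idx=np.arange(n), basal=basal, A=A)
    web.A_prime = rescale_matrix(A)
    web.theta_consumer, web.theta_resource = compute_thresholds(web)
    web.frozen = True
    return web


class TestCascade:
    def test_no_primary_losses_no_coextinctions(self, small_pool, ratio_limits, trait_matrix):
        """A frozen equilibrium web is stable under the empty perturbation."""
        rng = np.random.default_rng(0)
        members = np.sort(rng.choice(len(small_pool), 90, replace=False))
        web = build_web(members, small_pool, ratio_limits, trait_matrix)
        web.frozen = True
        out, coextinct, _ = cascade(web, set())
        assert coextinct == set()
        assert np.array_equal(out.idx, web.idx)

    def test_specialist_loses_only_resource(self):
        """A consumer with one resource dies when that resource is removed."""
        A = np.zeros((2, 2))
        A[0, 1] = 0.8
        web = FoodWeb(idx=np.array([0, 1]), basal=np.array([True, False]), A=A)
        web.A_prime = rescale_matrix(A)
        web.theta_consumer, web.theta_resource = compute_thresholds(web)
        out, coextinct, causes = cascade(web, {0})
        assert coextinct == {1}
        assert causes[1] in {"bottom_up", "disconnected"}
        assert out.n == 0

    def test_matches_brute_force_oracle_on_random_webs(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            web = random_equilibrium_web(rng)
            k = int(rng.integers(0, web.n))
            primary = set(int(i) for i in rng.choice(web.n, size=k, replace=False))
            out, _, _ = cascade(web, primary)
            expect = brute_force_cascade(
                web.A.tolist(), web.basal.tolist(),
                web.theta_consumer, web.theta_resource, primary,
            )
            assert set(int(i) for i in out.idx) == expect

    def test_destruction_is_mostly_monotone(self):
        """Larger removal sets usually destroy supersets of what smaller ones
        do — but not always: removing a competitor lowers the total pressure
        on a shared resource, which *raises* the rescaled availability of the
        surviving consumers and can rescue one (competition release).  The
        assertion is therefore empirical: monotonicity holds for the large
        majority of random webs, and exceptions exist."""
        rng = np.random.default_rng(7)
        violations = 0
        n_trials = 300
        for _ in range(n_trials):
            web = random_equilibrium_web(rng)
            all_ids = list(range(web.n))
            s1 = set(int(i) for i in rng.choice(all_ids, size=1))
            s2 = set(int(i) for i in rng.choice(all_ids, size=1))
            surv_union = set(map(int, cascade(web, s1 | s2)[0].idx))
            surv_s1 = set(map(int, cascade(web, s1)[0].idx))
            if not surv_union <= surv_s1:
                violations += 1
        assert violations / n_trials < 0.15

    def test_terminates_within_n_sweeps(self):
        # a chain of specialists collapses one sweep per node at worst
        n = 8
        A = np.zeros((n, n))
        for i in range(n - 1):
            A[i, i + 1] = 0.9
        basal = np.zeros(n, dtype=bool)
        basal[0] = True
        web = FoodWeb(idx=np.arange(n), basal=basal, A=A)
        web.A_prime = rescale_matrix(A)
        web.theta_consumer, web.theta_resource = compute_thresholds(web)
        out, coextinct, _ = cascade(web, {0})
        assert coextinct == set(range(1, n))


def _mk(sid, mass, tl, floor, phenotype):
    ax = fit_axis([10.0, 20.0, 15.0])
    return VirtualSpecies(
        id=sid, taxon="mammal", body_mass=mass, trophic_level=tl,
        trophic_breadth_floor=floor, basal=floor <= 0, phenotype=phenotype,
        adaptive_capacity=0.5, niche_T=ax, niche_P=ax,
    )


@pytest.fixture()
def colonize_setup():
    tm = TraitMatrix(np.ones((26, 26)), 0.0, 100.0)  # compat = L1*L2/100
    limits = RatioLimits(np.full((4, 4), 1e-4), np.full((4, 4), 1e4), (1e-4, 1e4))
    species = [
        _mk(0, 10.0, 1.0, 0.0, "a" * 10),   # basal resource
        _mk(1, 100.0, 2.0, 0.5, "a" * 8),   # resident consumer, weight ~0.556
        _mk(2, 120.0, 2.0, 0.5, "a" * 10),  # stronger would-be consumer, weight 1
        _mk(3, 150.0, 2.0, 0.5, "a"),       # consumer with compat below threshold
        _mk(4, 12.0, 1.0, 0.0, "a" * 10),   # basal colonizer
    ]
    pool = pack_pool(species)
    web = build_web([0, 1], pool, limits, tm)
    web.frozen = True
    ext = {0: 0.01, 1: 0.01, 2: 0.02, 3: 0.02, 4: 0.9}  # colonizer 4 least suited
    ext_of = lambda ids: np.array([ext[int(i)] for i in ids])
    arrival_of = lambda ids: np.array([int(i) for i in ids])
    return tm, limits, pool, web, ext_of, arrival_of


class TestColonize:
    def test_consumer_without_resources_rejected(self, colonize_setup):
        tm, limits, pool, web, ext_of, arrival_of = colonize_setup
        outcome, new_web, causes = try_colonize(
            web, 3, pool, limits, tm, 0.55, 1, ext_of, arrival_of
        )
        assert outcome == REJECTED and causes == {}
        assert np.array_equal(new_web.idx, web.idx)

    def test_overloading_colonizer_triggers_cascade(self, colonize_setup):
        """A stronger consumer pushes the shared resource past the frozen
        pressure threshold; the resource and every dependent consumer die."""
        tm, limits, pool, web, ext_of, arrival_of = colonize_setup
        outcome, new_web, causes = try_colonize(
            web, 2, pool, limits, tm, 0.55, 1, ext_of, arrival_of
        )
        assert outcome == ACCEPTED_WITH_CASCADE
        assert causes[0] == "top_down"
        assert 1 in causes  # the resident consumer falls with its resource
        assert new_web.n == 0

    def test_basal_cap_displaces_least_suitable(self, colonize_setup):
        """A basal colonizer less suited than every resident is removed right
        back out: a net no-op reported as rejection."""
        tm, limits, pool, web, ext_of, arrival_of = colonize_setup
        outcome, new_web, causes = try_colonize(
            web, 4, pool, limits, tm, 0.55, 1, ext_of, arrival_of
        )
        assert outcome == REJECTED
        assert sorted(int(i) for i in new_web.idx) == [0, 1]

    def test_basal_admitted_under_cap(self, colonize_setup):
        tm, limits, pool, web, ext_of, arrival_of = colonize_setup
        outcome, new_web, _ = try_colonize(
            web, 4, pool, limits, tm, 0.55, 2, ext_of, arrival_of
        )
        assert outcome == ACCEPTED
        assert 4 in set(int(i) for i in new_web.idx)
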