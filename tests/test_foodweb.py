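"""Web assembly, competition rescaling, thresholds, metrics."""

import numpy as np
import pytest

from coexsim.foodweb import (
    FoodWeb,
    build_web,
    compute_thresholds,
    link_allowed,
    rescale_link_weight,
    rescale_matrix,
    web_metrics,
)
from coexsim.niche import fit_axis
from coexsim.species import RatioLimits, TraitMatrix, VirtualSpecies, pack_pool


def brute_force_rescale(A):
    """Independent double-loop oracle for the competition rescaling."""
    A = np.asarray(A, dtype=float)
    n, m = A.shape
    out = np.zeros_like(A)
    for i in range(n):
        s = sum(A[i][j] for j in range(m))
        if s > 0:
            for j in range(m):
                out[i][j] = A[i][j] * (A[i][j] / s)
    return out


class TestRescaleMatrix:
    def test_worked_three_consumer_example(self):
        """One resource, consumers 0.5/0.2/0.1 -> 0.3125/0.050/0.0125."""
        A = np.zeros((4, 4))
        A[0, 1:] = [0.5, 0.2, 0.1]
        out = rescale_matrix(A)
        assert out[0, 1] == pytest.approx(0.3125)
        assert out[0, 2] == pytest.approx(0.050)
        assert out[0, 3] == pytest.approx(0.0125)
        # rescaled pressure never exceeds the raw pressure
        assert out[0].sum() == pytest.approx(0.375)
        assert out[0].sum() <= A[0].sum()

    def test_single_consumer_is_identity(self):
        A = np.zeros((2, 2))
        A[0, 1] = 0.7
        assert rescale_matrix(A)[0, 1] == pytest.approx(0.7)

    def test_matches_brute_force_on_random_webs(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(1, 13))
            A = rng.uniform(0, 1, (n, n)) * (rng.random((n, n)) < 0.4)
            assert np.allclose(rescale_matrix(A), brute_force_rescale(A), atol=1e-12)

    def test_row_sums_never_increase(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            A = rng.uniform(0, 1, (8, 8)) * (rng.random((8, 8)) < 0.5)
            assert (rescale_matrix(A).sum(1) <= A.sum(1) + 1e-12).all()


class TestLinkWeight:
    def test_anchors(self):
        assert rescale_link_weight(0.55) == pytest.approx(0.0)
        assert rescale_link_weight(1.0) == pytest.approx(1.0)

    def test_linear_midpoint(self):
        assert rescale_link_weight(0.775) == pytest.approx(0.5)

    def test_below_threshold_rejected(self):
        with pytest.raises(ValueError):
            rescale_link_weight(0.5)


def _mk_species(sid, taxon, mass, tl, floor, phenotype):
    ax = fit_axis([10.0, 20.0, 15.0])
    return VirtualSpecies(
        id=sid, taxon=taxon, body_mass=mass, trophic_level=tl,
        trophic_breadth_floor=floor, basal=floor <= 0, phenotype=phenotype,
        adaptive_capacity=0.5, niche_T=ax, niche_P=ax,
    )


@pytest.fixture(scope="module")
def toy_setup():
    """Hand-built chain: basal -> mid -> top, fully compatible phenotypes."""
    tm = TraitMatrix(np.ones((26, 26)), 0.0, 100.0)  # compat = L1*L2/100
    ll = np.full((4, 4), 1e-4)
    lu = np.full((4, 4), 1e4)
    limits = RatioLimits(ll, lu, (1e-4, 1e4))
    basal = _mk_species(0, "mammal", 10.0, 1.0, 0.0, "aaaaaaaaaa")
    mid = _mk_species(1, "mammal", 100.0, 2.0, 0.5, "aaaaaaaaaa")
    top = _mk_species(2, "mammal", 1000.0, 3.0, 1.5, "aaaaaaaaaa")
    return tm, limits, [basal, mid, top]


class TestLinkRules:
    def test_equal_trophic_levels_forbidden(self, toy_setup):
        tm, limits, (basal, mid, top) = toy_setup
        ok, _ = link_allowed(mid, mid, limits, tm)
        assert not ok

    def test_mass_window_enforced(self, toy_setup):
        tm, _, (basal, mid, top) = toy_setup
        narrow = RatioLimits(np.full((4, 4), 0.5), np.full((4, 4), 0.9), (0.5, 0.9))
        ok, _ = link_allowed(basal, top, narrow, tm)  # ratio 0.01 outside window
        assert not ok

    def test_conjunction_passes_and_reports_compat(self, toy_setup):
        tm, limits, (basal, mid, top) = toy_setup
        ok, c = link_allowed(basal, mid, limits, tm)
        assert ok and c == pytest.approx(1.0)

    def test_breadth_floor_blocks_low_resources(self, toy_setup):
        tm, limits, (basal, mid, top) = toy_setup
        ok, _ = link_allowed(basal, top, limits, tm)  # basal TL 1 < top floor 1.5
        assert not ok


class TestBuildWeb:
    def test_chain_and_iterated_drop(self, toy_setup):
        tm, limits, species = toy_setup
        pool = pack_pool(species)
        web = build_web([0, 1, 2], pool, limits, tm)
        assert sorted(web.idx.tolist()) == [0, 1, 2]
        # deleting the basal species strands mid, which then strands top
        web2 = build_web([1, 2], pool, limits, tm)
        assert web2.n == 0

    def test_all_basal_community_retained(self, toy_setup):
        tm, limits, _ = toy_setup
        species = [_mk_species(i, "bird", 10.0 + i, 1.0, 0.0, "ab") for i in range(4)]
        pool = pack_pool(species)
        web = build_web([0, 1, 2, 3], pool, limits, tm)
        assert web.n == 4

    def test_idempotent_rebuild(self, small_pool, ratio_limits, trait_matrix):
        rng = np.random.default_rng(3)
        members = np.sort(rng.choice(len(small_pool), 80, replace=False))
        web = build_web(members, small_pool, ratio_limits, trait_matrix)
        web2 = build_web(web.idx, small_pool, ratio_limits, trait_matrix)
        assert np.array_equal(web.idx, web2.idx)
        assert np.allclose(web.A, web2.A)

    def test_empty_input_allowed(self, small_pool, ratio_limits, trait_matrix):
        web = build_web([], small_pool, ratio_limits, trait_matrix)
        assert web.n == 0


class TestThresholds:
    def test_resource_threshold_from_worked_example(self):
        A = np.zeros((4, 4))
        A[0, 1:] = [0.5, 0.2, 0.1]
        web = FoodWeb(
            idx=np.arange(4), basal=np.array([True, False, False, False]), A=A
        )
        web.A_prime = rescale_matrix(A)
        theta_c, theta_r = compute_thresholds(web)
        assert theta_r == pytest.approx(0.375)

    def test_single_link_consumer_threshold_closed_form(self):
        w = 0.6
        A = np.zeros((2, 2))
        A[0, 1] = w
        web = FoodWeb(idx=np.arange(2), basal=np.array([True, False]), A=A)
        web.A_prime = rescale_matrix(A)
        theta_c, _ = compute_thresholds(web)
        assert theta_c == pytest.approx(w)  # w^2 / w

    def test_fresh_web_is_at_equilibrium(self, small_pool, ratio_limits, trait_matrix):
        rng = np.random.default_rng(4)
        members = np.sort(rng.choice(len(small_pool), 90, replace=False))
        web = build_web(members, small_pool, ratio_limits, trait_matrix)
        if web.n == 0:
            pytest.skip("degenerate random draw produced an empty web")
        avail, press = web.availability(), web.pressure()
        nonbasal = ~web.basal
        assert not (avail[nonbasal] < web.theta_consumer).any()
        assert not (press > web.theta_resource).any()


class TestMetrics:
    def test_two_nodes_one_edge_connectance(self):
        A = np.zeros((2, 2))
        A[0, 1] = 0.5
        web = FoodWeb(idx=np.arange(2), basal=np.array([True, False]), A=A)
        web.A_prime = rescale_matrix(A)

        class PoolStub:
            tl = np.array([1.0, 2.0])
            mass = np.array([10.0, 100.0])

        m = web_metrics(web, PoolStub())
        assert m["connectance"] == pytest.approx(0.25)
        assert m["edges"] == 1 and m["diameter"] == 1
        assert m["lwcc_fraction"] == 1.0

    def test_empty_web_all_zero(self, small_pool):
        assert web_metrics(None, small_pool)["richness"] == 0
        assert web_metrics(None, small_pool)["connectance"] == 0.0

    def test_fully_connected_with_self_links(self):
        n = 3
        A = np.full((n, n), 0.5)
        web = FoodWeb(idx=np.arange(n), basal=np.ones(n, dtype=bool), A=A)
        web.A_prime = rescale_matrix(A)

        class PoolStub:
            tl = np.ones(n)
            mass = np.ones(n)

        assert web_metrics(web, PoolStub())["connectance"] == pytest.approx(1.0)
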