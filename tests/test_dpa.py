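import itertools

import numpy as np
import pytest

from midseg.boundary_dpa import (Centerline, DPAConfig, ProfileGraph,
                                 build_profile_graph, dpa_refine, dpa_solve,
                                 mean_abs_curvature, solve_graph, thin_mask)
from midseg.core_io import Contour, contour_to_mask, mask_to_contour
from midseg.errors import CollapseError, GeometryError, InfeasibleError
from midseg.phantoms import (PhantomSpec, enclosing_initial_contour,
                             make_shape_phantom)


# ---------------------------------------------------------------------------
# Independent Zhang-Suen reference (naive textbook implementation)
# ---------------------------------------------------------------------------

def zhang_suen_reference(mask):
    img = mask.astype(np.uint8).copy()

    def neighbours(x, y):
        return [img[x - 1, y], img[x - 1, y + 1], img[x, y + 1],
                img[x + 1, y + 1], img[x + 1, y], img[x + 1, y - 1],
                img[x, y - 1], img[x - 1, y - 1]]

    changed = True
    while changed:
        changed = False
        for step in (0, 1):
            to_del = []
            for x in range(1, img.shape[0] - 1):
                for y in range(1, img.shape[1] - 1):
                    if not img[x, y]:
                        continue
                    P = neighbours(x, y)
                    B = sum(P)
                    A = sum((P[i] == 0 and P[(i + 1) % 8] == 1)
                            for i in range(8))
                    if not (2 <= B <= 6 and A == 1):
                        continue
                    p2, p4, p6, p8 = P[0], P[2], P[4], P[6]
                    if step == 0:
                        if p2 * p4 * p6 == 0 and p4 * p6 * p8 == 0:
                            to_del.append((x, y))
                    else:
                        if p2 * p4 * p8 == 0 and p2 * p6 * p8 == 0:
                            to_del.append((x, y))
            for x, y in to_del:
                img[x, y] = 0
                changed = True
    return img.astype(bool)


class TestThinning:
    def test_bar_thins_to_single_chain(self):
        m = np.zeros((10, 26), bool)
        m[3:6, 3:23] = True
        cl = thin_mask(m)
        ref = zhang_suen_reference(m)
        np.testing.assert_array_equal(cl.mask, ref)
        # roughly bar-length single-pixel chain
        assert 16 <= cl.mask.sum() <= 22
        # no pixel thicker than 1: every row of the chain has <= 1 pixel
        assert (cl.mask.sum(axis=0) <= 1).all()

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_reference_on_random_blobs(self, seed):
        rng = np.random.default_rng(seed)
        from scipy import ndimage
        m = np.zeros((24, 24), bool)
        m[4:20, 4:20] = rng.random((16, 16)) > 0.4
        m = ndimage.binary_closing(m)
        m[0, :] = m[-1, :] = m[:, 0] = m[:, -1] = False
        if not m.any():
            pytest.skip("degenerate draw")
        np.testing.assert_array_equal(thin_mask(m).mask, zhang_suen_reference(m))

    def test_single_pixel_fixed_point(self):
        m = np.zeros((7, 7), bool)
        m[3, 3] = True
        np.testing.assert_array_equal(thin_mask(m).mask, m)

    def test_annulus_keeps_loop_topology(self):
        xs, ys = np.meshgrid(np.arange(40), np.arange(40), indexing="ij")
        r2 = (xs - 20) ** 2 + (ys - 20) ** 2
        ring = (r2 <= 14 ** 2) & (r2 >= 8 ** 2)
        cl = thin_mask(ring)
        from scipy import ndimage
        # still one 8-connected component, still one hole (Euler number 0)
        assert ndimage.label(cl.mask, structure=np.ones((3, 3)))[1] == 1
        filled = ndimage.binary_fill_holes(cl.mask)
        assert (filled & ~cl.mask).sum() > 0

    def test_idempotent(self):
        m = np.zeros((20, 20), bool)
        m[4:16, 6:13] = True
        once = thin_mask(m).mask
        np.testing.assert_array_equal(thin_mask(once).mask, once)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            thin_mask(np.zeros((5, 5), bool))


# ---------------------------------------------------------------------------
# Profile graph
# ---------------------------------------------------------------------------

def _circle_contour(center, radius, n=96):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Contour(0, np.stack([center[0] + radius * np.cos(t),
                                center[1] + radius * np.sin(t)], axis=1))


class TestProfileGraph:
    def test_constant_image_equal_node_costs(self):
        img = np.full((64, 64), 5.0)
        g = build_profile_graph(img, _circle_contour((32, 32), 15))
        # zero gradient everywhere: node costs equal per profile up to the
        # tiny intensity tie-break (constant image -> identical too)
        assert np.allclose(g.node_cost, g.node_cost[:, :1])

    def test_step_edge_minimum_at_zero_offset(self):
        xs, ys = np.meshgrid(np.arange(80), np.arange(80), indexing="ij")
        r = np.hypot(xs - 40, ys - 40)
        img = np.clip(25 - r, -1, 1)  # sharp ring edge at r = 25
        g = build_profile_graph(img, _circle_contour((40, 40), 25))
        assert (np.argmin(g.node_cost, axis=1)
                == np.argmin(np.abs(g.offsets))).mean() > 0.95

    def test_circle_edge_found_at_plus_three(self):
        xs, ys = np.meshgrid(np.arange(80), np.arange(80), indexing="ij")
        r = np.hypot(xs - 40, ys - 40)
        img = 1.0 / (1.0 + np.exp(r - 30.0))  # smooth edge at r = 30
        g = build_profile_graph(img, _circle_contour((40, 40), 27))
        chosen = g.offsets[np.argmin(g.node_cost, axis=1)]
        assert np.abs(chosen - 3).mean() < 0.5

    def test_contour_at_border_rejected(self):
        img = np.zeros((30, 30))
        with pytest.raises(GeometryError):
            build_profile_graph(img, _circle_contour((15, 15), 14.8))


# ---------------------------------------------------------------------------
# Cyclic DP solver
# ---------------------------------------------------------------------------

def brute_force_cycle(node, pair, tri):
    N, K = node.shape
    best = np.inf
    for path in itertools.product(range(K), repeat=N):
        c = 0.0
        for i in range(N):
            c += (node[i, path[i]] + pair[path[i], path[(i + 1) % N]]
                  + tri[i, path[i - 1], path[i], path[(i + 1) % N]])
        best = min(best, c)
    return best


def _graph_from_costs(node, pair, tri):
    N, K = node.shape
    return ProfileGraph(positions=np.zeros((N, K, 2)),
                        offsets=np.arange(K) - K // 2.0,
                        node_cost=node, pair_cost=pair, triple_cost=tri)


class TestSolver:
    def test_single_zero_cost_candidate_selected(self):
        N, K = 8, 5
        node = np.full((N, K), 10.0)
        want = [1, 2, 3, 2, 1, 0, 0, 1]
        for i, j in enumerate(want):
            node[i, j] = 0.0
        g = _graph_from_costs(node, np.zeros((K, K)), np.zeros((N, K, K, K)))
        cost, idx = solve_graph(g)
        assert list(idx) == want

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            N = int(rng.integers(3, 7))
            K = int(rng.integers(2, 5))
            node = rng.normal(size=(N, K))
            pair = rng.normal(size=(K, K))
            tri = rng.normal(size=(N, K, K, K))
            cost, idx = solve_graph(_graph_from_costs(node, pair, tri))
            assert np.isclose(cost, brute_force_cycle(node, pair, tri))

    def test_all_infinite_column_infeasible(self):
        node = np.zeros((5, 3))
        node[2, :] = np.inf
        g = _graph_from_costs(node, np.zeros((3, 3)), np.zeros((5, 3, 3, 3)))
        with pytest.raises(InfeasibleError):
            solve_graph(g)

    def test_noisy_circle_radius_recovered(self):
        rng = np.random.default_rng(3)
        xs, ys = np.meshgrid(np.arange(80), np.arange(80), indexing="ij")
        r = np.hypot(xs - 40, ys - 40)
        img = (r <= 30).astype(float) * 70 + 100 + rng.normal(0, 10, r.shape)
        g = build_profile_graph(img, _circle_contour((40, 40), 28))
        sol = dpa_solve(g, image=img)
        radii = np.hypot(sol.vertices[:, 0] - 40, sol.vertices[:, 1] - 40)
        assert abs(radii.mean() - 30) < 1.0

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        node = rng.normal(size=(6, 4))
        pair = rng.normal(size=(4, 4))
        tri = rng.normal(size=(6, 4, 4, 4))
        a = solve_graph(_graph_from_costs(node, pair, tri))
        b = solve_graph(_graph_from_costs(node, pair, tri))
        assert a[0] == b[0] and list(a[1]) == list(b[1])


# ---------------------------------------------------------------------------
# Iterated refinement
# ---------------------------------------------------------------------------

class TestRefine:
    def test_noise_free_rectangle_exact(self):
        spec = PhantomSpec(cnr=np.inf)
        img, truth, _ = make_shape_phantom(spec)
        out = dpa_refine(img, enclosing_initial_contour(spec, seed=0),
                         DPAConfig(adaptive_otsu=True))
        assert contour_to_mask(out, img.shape).sum() == truth.sum() == 1400

    def test_fixed_point_on_true_disk_edge(self):
        spec = PhantomSpec(shape="disk", cnr=np.inf)
        img, truth, _ = make_shape_phantom(spec)
        init = mask_to_contour(truth)[0]
        out = dpa_refine(img, init, DPAConfig(adaptive_otsu=True))
        assert (contour_to_mask(out, img.shape) ^ truth).sum() == 0

    def test_degenerate_contour_collapses(self):
        img = np.random.default_rng(0).normal(0, 1, (40, 40))
        tiny = Contour(0, [[20, 20], [21.2, 20], [20.6, 21]])
        with pytest.raises(CollapseError):
            dpa_refine(img, tiny, DPAConfig())

    def test_leakage_bound(self):
        """Output stays within search_radius * n_iterations of the start."""
        spec = PhantomSpec(shape="moon", cnr=7, seed=2)
        img, truth, _ = make_shape_phantom(spec)
        init = enclosing_initial_contour(spec, seed=7)
        cfg = DPAConfig(adaptive_otsu=True)
        out = dpa_refine(img, init, cfg)
        from shapely.geometry import Polygon
        d = Polygon(init.vertices).boundary
        bound = cfg.search_radius_px * cfg.n_iterations + 2.0  # + raster slack
        import shapely
        dists = [d.distance(shapely.points(x, y)) for x, y in out.vertices]
        assert max(dists) <= bound

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            DPAConfig(alpha=-0.1)
        with pytest.raises(ValueError):
            DPAConfig(n_iterations=0)
        with pytest.raises(ValueError):
            DPAConfig(n_profiles=8)
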