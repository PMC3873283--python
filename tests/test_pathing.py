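"""Graph construction, Dijkstra routing, constraints, endpoint anchoring."""

import itertools

import numpy as np
import pytest

from octseg.edges import LayerProfile, compute_candidates, smooth
from octseg.errors import (
    ConstraintConflictError,
    EndpointError,
    InfeasiblePathError,
)
from octseg.pathing import (
    ConstraintSet,
    CostParams,
    PathGraph,
    build_graph,
    segment_layer,
    select_endpoints,
    shortest_path,
)
from octseg.phantom import generate_bscan, random_phantom_spec

ILM = LayerProfile("ILM", "dark_to_bright", "vitreal", "top")
BM = LayerProfile("BM", "bright_to_dark", "vitreal", "bottom")


def make_graph(rng, n_cols=5, max_rows=3, rows=10, max_jump=9, waypoints=()):
    """Random small PathGraph with one to `max_rows` nodes per column."""
    nodes = {}
    for c in range(n_cols):
        k = rng.integers(1, max_rows + 1)
        nodes[c] = np.sort(rng.choice(rows, size=k, replace=False))
    weights = np.zeros((rows, n_cols))
    for c, rr in nodes.items():
        weights[rr, c] = rng.uniform(0.1, 5.0, size=len(rr))
    source = (int(nodes[0][0]), 0)
    dest = (int(nodes[n_cols - 1][-1]), n_cols - 1)
    return PathGraph(
        nodes_by_col=nodes,
        weights=weights,
        w_max=float(weights.max()),
        params=CostParams(beta=0.3, max_jump=max_jump),
        source=source,
        destination=dest,
        waypoints=list(waypoints),
        shape=(rows, n_cols),
    )


def enumerate_paths(graph):
    """All column-monotone source->destination paths through waypoints."""
    cols = range(graph.source[1], graph.destination[1] + 1)
    options = []
    fixed = {graph.source[1]: graph.source[0], graph.destination[1]: graph.destination[0]}
    for r, c in graph.waypoints:
        fixed[c] = r
    for c in cols:
        options.append([fixed[c]] if c in fixed else list(graph.nodes_by_col[c]))
    for rows_path in itertools.product(*options):
        ok = all(
            abs(b - a) <= graph.params.max_jump
            for a, b in zip(rows_path, rows_path[1:])
        )
        if ok:
            cost = sum(
                graph.arc_cost(a, b, c + graph.source[1] + 1)
                for c, (a, b) in enumerate(zip(rows_path, rows_path[1:]))
            )
            yield list(rows_path), cost


class TestShortestPath:
    def test_matches_bruteforce_on_random_graphs(self, rng):
        for _ in range(100):
            graph = make_graph(rng)
            best = min((c for _, c in enumerate_paths(graph)), default=None)
            assert best is not None
            result = shortest_path(graph)
            assert result.total_cost == pytest.approx(best, abs=1e-12)

    def test_single_feasible_path_cost_is_arc_sum(self, rng):
        graph = make_graph(rng, max_rows=1)
        result = shortest_path(graph)
        expected = sum(c for _, _, c in graph.arcs())
        assert result.total_cost == pytest.approx(expected)

    def test_waypoint_on_optimum_changes_nothing(self, rng):
        for _ in range(20):
            graph = make_graph(rng)
            free = shortest_path(graph)
            mid = graph.source[1] + 2
            r_mid = int(free.boundary.positions[mid])
            graph.waypoints = [(r_mid, mid)]
            pinned = shortest_path(graph)
            assert pinned.total_cost == pytest.approx(free.total_cost)
            assert np.array_equal(free.boundary.positions, pinned.boundary.positions)

    def test_constraint_monotonicity(self, rng):
        for _ in range(30):
            graph = make_graph(rng)
            free_cost = shortest_path(graph).total_cost
            mid = graph.source[1] + 2
            r = int(rng.choice(graph.nodes_by_col[mid]))
            graph.waypoints = [(r, mid)]
            assert shortest_path(graph).total_cost >= free_cost - 1e-12

    def test_waypoints_lie_on_path(self, rng):
        for _ in range(20):
            graph = make_graph(rng)
            wp_col = graph.source[1] + 1
            r = int(rng.choice(graph.nodes_by_col[wp_col]))
            graph.waypoints = [(r, wp_col)]
            result = shortest_path(graph)
            assert result.boundary.positions[wp_col] == r

    def test_deterministic(self, rng):
        graph = make_graph(rng)
        a = shortest_path(graph)
        b = shortest_path(graph)
        assert a.total_cost == b.total_cost
        assert np.array_equal(a.boundary.positions, b.boundary.positions)

    def test_infeasible_names_waypoint(self, rng):
        graph = make_graph(rng, max_jump=9)
        graph.params = CostParams(max_jump=1)
        nodes0 = graph.nodes_by_col[0]
        graph.nodes_by_col[1] = np.array([9 if nodes0[0] < 5 else 0])
        with pytest.raises(InfeasiblePathError):
            shortest_path(graph)


class TestBuildGraph:
    def _candidates(self, weights):
        from octseg.edges import EdgeCandidateMap
        from scipy import ndimage

        seg, _ = ndimage.label(weights > 0, structure=np.ones((3, 3)))
        cands = [tuple(np.nonzero(seg == k)) for k in range(1, seg.max() + 1)]
        return EdgeCandidateMap(
            weights=weights,
            candidates=cands,
            segment_ids=seg.astype(np.int32),
            source_image_shape=weights.shape,
        )

    def test_adjacent_same_row_arc_cost(self):
        w = np.zeros((6, 2))
        w[3, 0] = w[3, 1] = 4.0
        cand = self._candidates(w)
        graph = build_graph(cand, ILM, endpoints=((3, 0), (3, 1)))
        arcs = {(a, b): c for a, b, c in graph.arcs() if 3 in (a[0], b[0])}
        assert arcs[((3, 0), (3, 1))] == pytest.approx(1.0 * (1 - 4.0 / 4.0))

    def test_arc_set_matches_enumeration(self, rng):
        w = np.where(rng.random((8, 5)) < 0.5, rng.uniform(0.5, 3, (8, 5)), 0.0)
        w[2, 0] = 1.0
        w[2, 4] = 1.0
        cand = self._candidates(w)
        params = CostParams(max_jump=3)
        graph = build_graph(cand, ILM, endpoints=((2, 0), (2, 4)), params=params)
        got = {(a, b) for a, b, _ in graph.arcs()}
        expected = set()
        for c in range(4):
            for r1 in graph.nodes_by_col[c]:
                for r2 in graph.nodes_by_col[c + 1]:
                    if abs(int(r2) - int(r1)) <= 3:
                        expected.add(((int(r1), c), (int(r2), c + 1)))
        assert got == expected

    def test_far_rows_have_no_arc(self):
        w = np.zeros((40, 2))
        w[0, 0] = w[30, 1] = 1.0
        cand = self._candidates(w)
        graph = build_graph(cand, ILM, endpoints=((0, 0), (30, 1)))
        assert ((0, 0), (30, 1)) not in {(a, b) for a, b, _ in graph.arcs()}

    def test_excluded_segment_removed_and_conflicts_detected(self):
        w = np.zeros((6, 4))
        w[1, :] = 2.0
        w[4, :] = 3.0
        cand = self._candidates(w)
        excluded_id = int(cand.segment_ids[4, 0])
        constraints = ConstraintSet(excluded=[(0, excluded_id)])
        graph = build_graph(cand, ILM, constraints, endpoints=((1, 0), (1, 3)))
        assert graph.weights[4].max() == 0.0
        with pytest.raises(ConstraintConflictError):
            build_graph(
                cand,
                ILM,
                ConstraintSet(must_pass=[(0, 4, 1)], excluded=[(0, excluded_id)]),
                endpoints=((1, 0), (1, 3)),
            )

    def test_must_pass_off_candidates_rejected(self):
        w = np.zeros((6, 4))
        w[1, :] = 2.0
        cand = self._candidates(w)
        with pytest.raises(ConstraintConflictError):
            build_graph(
                cand, ILM, ConstraintSet(must_pass=[(0, 3, 2)]),
                endpoints=((1, 0), (1, 3)),
            )


class TestSelectEndpoints:
    def test_ilm_and_bm_anchors_on_phantom(self, noiseless_phantom, profiles):
        spec, image, _ = noiseless_phantom
        smoothed = smooth(image)
        for layer, truth_layer in (("ILM", "ILM"), ("BM", "BM")):
            cand = compute_candidates(image, profiles[layer])
            (r0, c0), (r1, c1) = select_endpoints(cand, profiles[layer], smoothed)
            assert c0 < 3 and c1 >= image.shape[1] - 3
            assert abs(r0 - spec.truth[truth_layer][c0]) <= 2
            assert abs(r1 - spec.truth[truth_layer][c1]) <= 2

    def test_empty_candidate_map_is_endpoint_error(self, profiles):
        from octseg.edges import link_candidates

        cand = link_candidates(np.zeros((20, 20)), ILM)
        with pytest.raises(EndpointError):
            select_endpoints(cand, ILM, np.random.default_rng(0).uniform(0, 1, (20, 20)))


class TestSegmentLayer:
    def test_noiseless_phantom_all_layers_subpixel(self, noiseless_phantom, profiles):
        spec, image, _ = noiseless_phantom
        for layer in ("ILM", "ISe", "RPE", "BM"):
            result = segment_layer(image, profiles[layer])
            pos = result.boundary.positions
            ok = np.isfinite(pos)
            rmse = np.sqrt(np.mean((pos[ok] - spec.truth[layer][ok]) ** 2))
            assert rmse < 1.0

    def test_layer_ordering_preserved(self, noiseless_phantom, profiles):
        _, image, _ = noiseless_phantom
        results = {
            layer: segment_layer(image, profiles[layer]).boundary.positions
            for layer in ("ILM", "ISe", "RPE", "BM")
        }
        common = np.logical_and.reduce([np.isfinite(p) for p in results.values()])
        assert np.all(results["ILM"][common] <= results["ISe"][common])
        assert np.all(results["ISe"][common] <= results["RPE"][common])
        assert np.all(results["RPE"][common] <= results["BM"][common])

    def test_bit_identical_reruns(self, profiles):
        spec = random_phantom_spec(11, shape=(224, 288), speckle_variance=1 / 9)
        image, _ = generate_bscan(spec)
        a = segment_layer(image, profiles["ILM"])
        b = segment_layer(image, profiles["ILM"])
        assert a.total_cost == b.total_cost
        assert np.array_equal(
            a.boundary.positions, b.boundary.positions, equal_nan=True
        )

    def test_session_counts_iterations(self, noiseless_phantom, profiles):
        from octseg.pathing import InteractiveSession

        _, image, _ = noiseless_phantom
        session = InteractiveSession(image, profiles["ILM"])
        first = session.segment()
        second = session.segment()
        assert (first.iterations, second.iterations) == (0, 1)
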