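"""Constrained shortest-path boundary tracing.

A weighted edge-candidate map is turned into a layer boundary by routing a
column-monotone path from an automatically chosen *source* pixel on the left
of the B-scan to a *destination* pixel on the right, using Dijkstra's
algorithm on a graph whose arcs advance exactly one column at a time.

Arc cost from ``(r1, c)`` to ``(r2, c+1)``::

    alpha * (1 - w(r2, c+1) / W)  +  beta * |r2 - r1|

where ``w`` is the candidate weight (0 on interpolation nodes) and ``W`` the
frame maximum. Strong edges are cheap; axial jumps are penalized. Columns
without any candidate receive zero-weight *interpolation nodes* at every row
so the path can bridge patchy or locally discontinuous layer signal.

Grader interaction is expressed as a :class:`ConstraintSet`: *must-pass*
picks are enforced exactly by decomposing the route into sequential Dijkstra
legs between waypoints, and *excluded* candidate segments are removed from
the graph before routing. Re-running with an augmented constraint set
re-routes the path deterministically — identical picks give bit-identical
boundaries, which is the mechanism behind the method's inter-grader
reproducibility.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from scipy import ndimage

from .edges import (
    EdgeCandidateMap,
    LayerProfile,
    compute_candidates,
    log_response,
    smooth,
)
from .errors import (
    ConstraintConflictError,
    EndpointError,
    InfeasiblePathError,
    ValidationError,
)
from .io import LayerBoundary

#: Width (columns) of the end bands searched for source/destination pixels.
END_BAND_COLS = 3

#: Normalized-intensity levels defining the anchor bands: the retinal bright
#: complex (seen from the vitreous) and the hyperreflective outer band.
BRIGHT_FRAC = 0.40
HYPER_FRAC = 0.75


@dataclass(frozen=True)
class CostParams:
    """Arc-cost parameters: weight attraction, jump penalty, jump limit."""

    alpha: float = 1.0
    beta: float = 0.3
    max_jump: int = 15

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0 or self.max_jump < 1:
            raise ValidationError("alpha, beta must be >= 0 and max_jump >= 1")


@dataclass
class ConstraintSet:
    """Grader-supplied picks driving re-routing.

    must_pass
        ``(frame_index, row, col)`` triples; each must be an existing,
        non-excluded candidate pixel, with strictly increasing columns per
        frame.
    excluded
        ``(frame_index, segment_id)`` pairs naming candidate segments
        (1-based labels from :class:`~octseg.edges.EdgeCandidateMap`) removed
        from the graph.
    """

    must_pass: list[tuple[int, int, int]] = field(default_factory=list)
    excluded: list[tuple[int, int]] = field(default_factory=list)

    def for_frame(self, frame_index: int) -> tuple[list[tuple[int, int]], set[int]]:
        """Return ((row, col) picks sorted by column, excluded segment ids)."""
        picks = sorted(
            [(r, c) for f, r, c in self.must_pass if f == frame_index],
            key=lambda rc: rc[1],
        )
        cols = [c for _, c in picks]
        if len(set(cols)) != len(cols):
            raise ValidationError("must_pass columns must be strictly increasing")
        return picks, {s for f, s in self.excluded if f == frame_index}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "must_pass": [
                {"frame_index": f, "row": r, "column": c} for f, r, c in self.must_pass
            ],
            "excluded": [
                {"frame_index": f, "segment": s} for f, s in self.excluded
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ConstraintSet":
        payload = json.loads(Path(path).read_text())
        return cls(
            must_pass=[
                (int(e["frame_index"]), int(e["row"]), int(e["column"]))
                for e in payload.get("must_pass", [])
            ],
            excluded=[
                (int(e["frame_index"]), int(e["segment"]))
                for e in payload.get("excluded", [])
            ],
        )


@dataclass
class PathGraph:
    """Column-monotone routing graph for one B-scan and one layer.

    ``nodes_by_col[c]`` holds the sorted candidate rows of column ``c``;
    candidate-free columns get interpolation nodes at every row (weight 0).
    Arcs are implicit: ``(r1, c) -> (r2, c+1)`` exists iff ``|r2 - r1| <=
    max_jump``; :meth:`arcs` enumerates them explicitly for small graphs.
    """

    nodes_by_col: dict[int, np.ndarray]
    weights: np.ndarray
    w_max: float
    params: CostParams
    source: tuple[int, int]  # (row, col)
    destination: tuple[int, int]
    waypoints: list[tuple[int, int]]  # (row, col), strictly increasing cols
    shape: tuple[int, int]
    layer: str = "ILM"
    frame_index: int = 0

    def arc_cost(self, r1: int, r2: int, c2: int) -> float:
        w = self.weights[r2, c2]
        rel = w / self.w_max if self.w_max > 0 else 0.0
        return self.params.alpha * (1.0 - rel) + self.params.beta * abs(r2 - r1)

    def arcs(self) -> Iterator[tuple[tuple[int, int], tuple[int, int], float]]:
        """Enumerate every arc as ((r1, c1), (r2, c2), cost)."""
        c0, c1 = self.source[1], self.destination[1]
        for c in range(c0, c1):
            if c not in self.nodes_by_col or (c + 1) not in self.nodes_by_col:
                continue
            for r1 in self.nodes_by_col[c]:
                for r2 in self.nodes_by_col[c + 1]:
                    if abs(int(r2) - int(r1)) <= self.params.max_jump:
                        yield (int(r1), c), (int(r2), c + 1), self.arc_cost(
                            int(r1), int(r2), c + 1
                        )

    @property
    def n_nodes(self) -> int:
        c0, c1 = self.source[1], self.destination[1]
        return sum(
            len(rows) for c, rows in self.nodes_by_col.items() if c0 <= c <= c1
        )


@dataclass
class SegmentationResult:
    """Boundary, constraints used, exact path cost, and re-route count."""

    boundary: LayerBoundary
    constraints_used: ConstraintSet
    total_cost: float
    iterations: int = 0


# ---------------------------------------------------------------------------
# endpoint selection


def _band_anchor(profile_column: np.ndarray, profile: LayerProfile) -> int:
    """Row anchoring source/destination selection for this layer.

    The mean end-band intensity profile is normalized to [0, 1]; the run of
    rows above BRIGHT_FRAC (band ``vitreal``: whole retinal complex) or
    HYPER_FRAC (band ``posterior``: hyperreflective outer band) containing
    the global maximum defines the band, whose top or bottom row is the
    anchor.
    """
    v = ndimage.uniform_filter1d(
        profile_column.astype(np.float64), size=9, mode="nearest"
    )
    lo, hi = np.percentile(v, 2.0), np.percentile(v, 98.0)
    if hi <= lo:
        raise EndpointError("flat intensity profile; cannot locate anchor band")
    norm = np.clip((v - lo) / (hi - lo), 0.0, 1.0)
    frac = BRIGHT_FRAC if profile.band == "vitreal" else HYPER_FRAC
    above = norm >= frac
    peak = int(np.argmax(norm))
    if not above[peak]:
        raise EndpointError("no high-reflectivity band found")
    top = peak
    while top > 0 and above[top - 1]:
        top -= 1
    bottom = peak
    while bottom < len(v) - 1 and above[bottom + 1]:
        bottom += 1
    return top if profile.anchor_edge == "top" else bottom


#: Candidates this close (rows) to the anchor compete on weight, so a strong
#: boundary edge beats a speckle candidate that happens to sit on the anchor.
_ANCHOR_WINDOW = 12


def _pick_endpoint(
    candidates: EdgeCandidateMap,
    cols: Sequence[int],
    anchor: int,
) -> tuple[int, int]:
    pixels = [
        (int(r), int(c))
        for c in cols
        for r in np.nonzero(candidates.weights[:, c] > 0)[0]
    ]
    if not pixels:
        raise EndpointError(
            "no edge candidates in the end band; supply endpoints via a "
            "ConstraintSet pick"
        )
    near = [p for p in pixels if abs(p[0] - anchor) <= _ANCHOR_WINDOW]
    if near:
        # strongest near-anchor candidate; ties to the smaller row/column
        return min(near, key=lambda p: (-candidates.weights[p[0], p[1]], p[0], p[1]))
    return min(
        pixels,
        key=lambda p: (abs(p[0] - anchor), -candidates.weights[p[0], p[1]], p[0], p[1]),
    )


def select_endpoints(
    candidates: EdgeCandidateMap,
    profile: LayerProfile,
    smoothed_image: np.ndarray,
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Choose source (left) and destination (right) candidate pixels.

    Within each end band (leftmost/rightmost END_BAND_COLS columns) the
    candidate pixel nearest the profile's anchor band is selected; ties are
    broken by larger weight, then smaller row, then smaller column.
    """
    rows, cols = candidates.source_image_shape
    left = range(0, min(END_BAND_COLS, cols))
    right = range(max(0, cols - END_BAND_COLS), cols)
    anchor_left = _band_anchor(smoothed_image[:, list(left)].mean(axis=1), profile)
    anchor_right = _band_anchor(smoothed_image[:, list(right)].mean(axis=1), profile)
    source = _pick_endpoint(candidates, list(left), anchor_left)
    dest = _pick_endpoint(candidates, list(right), anchor_right)
    return source, dest


# ---------------------------------------------------------------------------
# graph construction


def build_graph(
    candidates: EdgeCandidateMap,
    profile: LayerProfile,
    constraints: ConstraintSet | None = None,
    endpoints: tuple[tuple[int, int], tuple[int, int]] | None = None,
    params: CostParams = CostParams(),
    frame_index: int = 0,
) -> PathGraph:
    """Assemble the routing graph from candidates, constraints and endpoints.

    Excluded segments are removed before node collection; must-pass picks
    must refer to surviving candidate pixels and become ordered waypoints.
    If ``endpoints`` is None the first/last must-pass picks or the extreme
    candidate columns cannot substitute — callers normally obtain endpoints
    from :func:`select_endpoints`.
    """
    constraints = constraints or ConstraintSet()
    picks, excluded_ids = constraints.for_frame(frame_index)

    weights = candidates.weights.copy()
    if excluded_ids:
        missing = excluded_ids - set(range(1, candidates.n_candidates + 1))
        if missing:
            raise ConstraintConflictError(f"unknown excluded segments {sorted(missing)}")
        weights[np.isin(candidates.segment_ids, list(excluded_ids))] = 0.0

    for r, c in picks:
        seg = candidates.segment_ids[r, c]
        if seg == 0:
            raise ConstraintConflictError(
                f"must_pass pixel (row={r}, col={c}) is not an edge candidate"
            )
        if seg in excluded_ids:
            raise ConstraintConflictError(
                f"must_pass pixel (row={r}, col={c}) lies in excluded segment {seg}"
            )

    rows, cols = candidates.source_image_shape
    all_rows = np.arange(rows)
    # zero-weight bridge nodes on a coarse row grid keep the graph connected
    # across patchy signal (a column whose candidates all sit far from the
    # local track would otherwise strand the path); full-row interpolation
    # nodes fill candidate-free columns
    stride = max(1, params.max_jump // 2)
    grid = np.arange(0, rows, stride)
    nodes_by_col: dict[int, np.ndarray] = {}
    for c in range(cols):
        rr = np.nonzero(weights[:, c] > 0)[0]
        if rr.size:
            nodes_by_col[c] = np.union1d(rr, grid)
        else:
            nodes_by_col[c] = all_rows

    if endpoints is None:
        raise EndpointError(
            "endpoints are required; call select_endpoints or pass them explicitly"
        )
    source, dest = endpoints
    if source[1] > dest[1]:
        raise ValidationError("source column must not exceed destination column")
    for r, c in picks:
        if not (source[1] < c < dest[1]) and (r, c) not in (source, dest):
            raise ConstraintConflictError(
                f"must_pass pick at column {c} outside the source-destination span"
            )

    w_max = float(weights.max())
    return PathGraph(
        nodes_by_col=nodes_by_col,
        weights=weights,
        w_max=w_max,
        params=params,
        source=source,
        destination=dest,
        waypoints=picks,
        shape=(rows, cols),
        layer=profile.layer,
        frame_index=frame_index,
    )


# ---------------------------------------------------------------------------
# Dijkstra routing


def _dijkstra_leg(
    graph: PathGraph, start: tuple[int, int], goal: tuple[int, int]
) -> tuple[list[int], float]:
    """Shortest path between two pixels in strictly increasing columns.

    Returns (rows per column from start to goal inclusive, cost). Priority is
    lexicographic (cost, cumulative |row jump|, column, row), which fixes a
    deterministic optimum among cost ties.
    """
    r0, c0 = start
    r1, c1 = goal
    if c0 == c1:
        if r0 == r1:
            return [r0], 0.0
        raise InfeasiblePathError(
            f"waypoint (row={r1}, col={c1}) shares a column with the previous "
            "waypoint but a different row"
        )
    max_jump = graph.params.max_jump
    dist: dict[tuple[int, int], tuple[float, int]] = {(c0, r0): (0.0, 0)}
    prev: dict[tuple[int, int], int] = {}
    heap: list[tuple[float, int, int, int]] = [(0.0, 0, c0, r0)]
    settled: set[tuple[int, int]] = set()
    goal_key = (c1, r1)
    while heap:
        cost, jumps, c, r = heapq.heappop(heap)
        key = (c, r)
        if key in settled:
            continue
        settled.add(key)
        if key == goal_key:
            break
        if c == c1:
            continue
        nxt = graph.nodes_by_col.get(c + 1)
        if nxt is None:
            continue
        if c + 1 == c1:
            neighbours = [r1] if abs(r1 - r) <= max_jump else []
        else:
            lo = np.searchsorted(nxt, r - max_jump, side="left")
            hi = np.searchsorted(nxt, r + max_jump, side="right")
            neighbours = [int(x) for x in nxt[lo:hi]]
        for r2 in neighbours:
            ncost = cost + graph.arc_cost(r, r2, c + 1)
            njump = jumps + abs(r2 - r)
            old = dist.get((c + 1, r2))
            if old is None or (ncost, njump) < old:
                dist[(c + 1, r2)] = (ncost, njump)
                prev[(c + 1, r2)] = r
                heapq.heappush(heap, (ncost, njump, c + 1, r2))
    if goal_key not in settled:
        raise InfeasiblePathError(
            f"no feasible path to waypoint (row={r1}, col={c1}) "
            f"from (row={r0}, col={c0})"
        )
    rows_path = [r1]
    c, r = c1, r1
    while c > c0:
        r = prev[(c, r)]
        rows_path.append(r)
        c -= 1
    rows_path.reverse()
    return rows_path, dist[goal_key][0]


def shortest_path(graph: PathGraph) -> SegmentationResult:
    """Minimum-cost column-monotone path through all waypoints, in order.

    Computed as concatenated Dijkstra legs between consecutive waypoints.
    The boundary holds one valid (integer) row per column between the source
    and destination; columns outside that span are masked invalid. The
    result is deterministic for fixed inputs.
    """
    stations = [graph.source] + list(graph.waypoints) + [graph.destination]
    cols_order = [c for _, c in stations]
    if any(b < a for a, b in zip(cols_order, cols_order[1:])):
        raise ValidationError("waypoints must be ordered by column")

    rows_total: list[int] = []
    total_cost = 0.0
    for (ra, ca), (rb, cb) in zip(stations, stations[1:]):
        leg_rows, leg_cost = _dijkstra_leg(graph, (ra, ca), (rb, cb))
        if rows_total:
            leg_rows = leg_rows[1:]  # drop shared station column
        rows_total.extend(leg_rows)
        total_cost += leg_cost

    c0, c1 = graph.source[1], graph.destination[1]
    rows, cols = graph.shape
    positions = np.full(cols, np.nan)
    positions[c0 : c1 + 1] = rows_total
    boundary = LayerBoundary(
        layer=graph.layer,
        frame_index=graph.frame_index,
        positions=positions,
    )
    return SegmentationResult(
        boundary=boundary,
        constraints_used=ConstraintSet(
            must_pass=[(graph.frame_index, r, c) for r, c in graph.waypoints],
        ),
        total_cost=total_cost,
    )


# ---------------------------------------------------------------------------
# full per-frame pipeline with interactive re-routing


def _refine_subpixel(
    positions: np.ndarray, log_response: np.ndarray
) -> np.ndarray:
    """Shift integer path rows to the interpolated LoG zero location.

    For each valid column, if the LoG response changes sign between the path
    pixel and a vertical neighbour, the zero crossing is located by linear
    interpolation; corrections are bounded to one pixel.
    """
    out = positions.copy()
    n_rows = log_response.shape[0]
    for c in np.nonzero(np.isfinite(positions))[0]:
        r = int(positions[c])
        l0 = log_response[r, c]
        best = None
        if r + 1 < n_rows:
            l1 = log_response[r + 1, c]
            if l0 * l1 < 0:
                best = l0 / (l0 - l1)
        if r - 1 >= 0:
            lm = log_response[r - 1, c]
            if l0 * lm < 0:
                cand = -(l0 / (l0 - lm))
                if best is None or abs(cand) < abs(best):
                    best = cand
        if best is not None:
            out[c] = min(max(r + best, 0.0), n_rows - 1.0)
    return out


class InteractiveSession:
    """One layer on one B-scan, with cached edge maps for fast re-routing.

    Emulates the grader loop: call :meth:`segment` with a growing
    :class:`ConstraintSet`; only graph construction and routing are redone,
    and ``iterations`` counts the re-routes.
    """

    def __init__(
        self,
        image: np.ndarray,
        profile: LayerProfile,
        params: CostParams = CostParams(),
        frame_index: int = 0,
        subpixel: bool = True,
    ):
        self.profile = profile
        self.params = params
        self.frame_index = frame_index
        self.subpixel = subpixel
        self.smoothed = smooth(image)
        self.log_response = log_response(self.smoothed, profile.log_sigma)
        self.candidates = compute_candidates(image, profile)
        self.iterations = 0

    def segment(self, constraints: ConstraintSet | None = None) -> SegmentationResult:
        constraints = constraints or ConstraintSet()
        endpoints = select_endpoints(self.candidates, self.profile, self.smoothed)
        graph = build_graph(
            self.candidates,
            self.profile,
            constraints=constraints,
            endpoints=endpoints,
            params=self.params,
            frame_index=self.frame_index,
        )
        result = shortest_path(graph)
        if self.subpixel:
            refined = _refine_subpixel(result.boundary.positions, self.log_response)
            # grader picks are pinned: refinement never moves a waypoint
            for r, c in graph.waypoints:
                refined[c] = r
            result.boundary = LayerBoundary(
                layer=result.boundary.layer,
                frame_index=result.boundary.frame_index,
                positions=refined,
            )
        result.constraints_used = constraints
        result.iterations = self.iterations
        self.iterations += 1
        return result


def segment_layer(
    image: np.ndarray,
    profile: LayerProfile,
    constraints: ConstraintSet | None = None,
    params: CostParams = CostParams(),
    frame_index: int = 0,
    subpixel: bool = True,
) -> SegmentationResult:
    """Segment one layer on one B-scan: edge pipeline + constrained routing."""
    session = InteractiveSession(
        image, profile, params=params, frame_index=frame_index, subpixel=subpixel
    )
    return session.segment(constraints)
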