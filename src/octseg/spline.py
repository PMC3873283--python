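"""Manual segmentation baseline: seed points interpolated by a spline.

A grader places seed points on a layer; a natural cubic interpolating
spline through the seeds, evaluated at every integer column between the
first and last seed, is the boundary. No extrapolation happens beyond the
seeded span — those columns stay masked invalid. With exactly two seeds the
natural spline degenerates to the straight line between them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import SeedError, ValidationError
from .io import LayerBoundary


@dataclass(frozen=True)
class SeedPointSet:
    """Grader seed points for one layer on one frame.

    ``points`` are ``(column, row)`` pairs with strictly increasing columns;
    rows may be fractional.
    """

    layer: str
    frame_index: int
    points: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        pts = tuple((float(c), float(r)) for c, r in self.points)
        cols = [c for c, _ in pts]
        if any(b <= a for a, b in zip(cols, cols[1:])):
            raise ValidationError("seed columns must be strictly increasing")
        if any(r < 0 or not np.isfinite(r) or not np.isfinite(c) for c, r in pts):
            raise ValidationError("seed coordinates must be finite and rows >= 0")
        object.__setattr__(self, "points", pts)

    @property
    def columns(self) -> tuple[float, ...]:
        return tuple(c for c, _ in self.points)


def add_seed(seeds: SeedPointSet, point: tuple[float, float]) -> SeedPointSet:
    """Insert a seed; the column must not already be present."""
    col = float(point[0])
    if col in seeds.columns:
        raise ValidationError(f"duplicate seed column {col}")
    pts = sorted(seeds.points + ((col, float(point[1])),), key=lambda p: p[0])
    return replace(seeds, points=tuple(pts))


def remove_seed(seeds: SeedPointSet, point: tuple[float, float]) -> SeedPointSet:
    """Remove an existing seed point."""
    target = (float(point[0]), float(point[1]))
    if target not in seeds.points:
        raise ValidationError(f"seed {target} not present")
    pts = tuple(p for p in seeds.points if p != target)
    return replace(seeds, points=pts)


def fit_spline(seeds: SeedPointSet, image_width: int) -> LayerBoundary:
    """Natural cubic spline through all seeds, sampled at integer columns.

    The boundary passes exactly through every seed; columns outside the
    [first seed, last seed] span are invalid.
    """
    if len(seeds.points) < 2:
        raise SeedError(
            f"need at least 2 seed points to fit a boundary, got {len(seeds.points)}"
        )
    cols = np.array([c for c, _ in seeds.points])
    rows = np.array([r for _, r in seeds.points])
    if cols[0] < 0 or cols[-1] > image_width - 1:
        raise ValidationError("seed columns must lie within the image width")

    spline = CubicSpline(cols, rows, bc_type="natural")
    positions = np.full(image_width, np.nan)
    lo = int(np.ceil(cols[0]))
    hi = int(np.floor(cols[-1]))
    xs = np.arange(lo, hi + 1)
    vals = spline(xs)
    # exactness at knots to machine precision: overwrite integer-knot columns
    for c, r in seeds.points:
        if c == int(c) and lo <= int(c) <= hi:
            vals[int(c) - lo] = r
    positions[lo : hi + 1] = np.clip(vals, 0.0, None)
    return LayerBoundary(
        layer=seeds.layer, frame_index=seeds.frame_index, positions=positions
    )
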