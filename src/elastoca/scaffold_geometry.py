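"""Periodic collagen-scaffold line masks.

The collagen scaffold is idealized as straight cable lines rasterized onto the
simulation torus in one of three periodic tilings — ``square``, ``hexagon`` or
``triangle`` — all with the same enclosed area per periodic unit, so that the
shape of the scaffold (not the amount of it) is the varied quantity.

Coordinates follow numpy convention: axis 0 is x (rows), axis 1 is y
(columns); the domain wraps periodically on both axes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

SHAPES = ("square", "hexagon", "triangle")

__all__ = ["ScaffoldMask", "build_scaffold", "adjacency_map", "SHAPES"]


class ScaffoldConfigError(ValueError):
    """Raised for geometrically impossible scaffold requests."""


@dataclass
class ScaffoldMask:
    """Boolean cable-line mask on an N x N torus.

    Attributes
    ----------
    grid : (N, N) bool array, True on cable cells.
    shape_label : one of ``square``, ``hexagon``, ``triangle``.
    linewidth_px : rasterized cable width in pixels.
    tile_area_px : enclosed area of one periodic unit, in pixels.
    period : the (px, py) tiling period actually used (divisors of N).
    """

    grid: np.ndarray
    shape_label: str
    linewidth_px: int
    tile_area_px: float
    period: tuple[int, int]
    _dist_scaffold: np.ndarray | None = field(default=None, repr=False)
    _dist_adjacent: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.grid.shape[0]

    def distance_to_scaffold(self) -> np.ndarray:
        """Periodic Euclidean distance from each cell to the nearest cable cell."""
        if self._dist_scaffold is None:
            self._dist_scaffold = _periodic_edt(self.grid)
        return self._dist_scaffold

    def distance_to_adjacency(self) -> np.ndarray:
        """Periodic distance to the nearest cell of the cable adjacency map."""
        if self._dist_adjacent is None:
            self._dist_adjacent = _periodic_edt(adjacency_map(self))
        return self._dist_adjacent

    def to_text(self) -> str:
        """Plain-text 0/1 grid (row per line), usable as a small fixture."""
        return "\n".join("".join("1" if v else "0" for v in row) for row in self.grid)


def _periodic_edt(mask: np.ndarray) -> np.ndarray:
    """Euclidean distance to the nearest True cell, with wrap-around.

    Computed on a 3x3 tiling so that distances see the periodic images; valid
    as long as every cell is within one domain length of a True cell, which
    holds for any non-empty mask.
    """
    if not mask.any():
        return np.full(mask.shape, np.inf)
    tiled = np.tile(mask, (3, 3))
    dist = ndimage.distance_transform_edt(~tiled)
    n0, n1 = mask.shape
    return np.ascontiguousarray(dist[n0 : 2 * n0, n1 : 2 * n1])


def _divisor_near(n: int, ideal: float) -> int:
    divisors = [d for d in range(2, n + 1) if n % d == 0]
    return min(divisors, key=lambda d: (abs(d - ideal), d))


def _segments_square(px: int, py: int) -> list[tuple[float, float, float, float]]:
    # one vertical + one horizontal line per period
    return [(0.0, 0.0, 0.0, py), (0.0, 0.0, px, 0.0)]


def _segments_hexagon(px: int, py: int) -> list[tuple[float, float, float, float]]:
    # honeycomb: two hexagons per (px, py) period, centers (0,0) and (px/2, py/2);
    # vertex layout generalizes the regular case px = sqrt(3) a, py = 3 a.
    verts = [
        (0.0, py / 3),
        (px / 2, py / 6),
        (px / 2, -py / 6),
        (0.0, -py / 3),
        (-px / 2, -py / 6),
        (-px / 2, py / 6),
    ]
    segs = []
    for cx, cy in [(0.0, 0.0), (px / 2, py / 2)]:
        for (x1, y1), (x2, y2) in zip(verts, verts[1:] + verts[:1]):
            segs.append((cx + x1, cy + y1, cx + x2, cy + y2))
    return segs


def _segments_triangle(px: int, py: int) -> list[tuple[float, float, float, float]]:
    # row of alternating up/down triangles: baseline plus a zig-zag
    return [
        (0.0, 0.0, px, 0.0),
        (0.0, 0.0, px / 2, py),
        (px / 2, py, px, 0.0),
    ]


def _rasterize(
    segments: list[tuple[float, float, float, float]],
    period: tuple[int, int],
    n: int,
    linewidth: float,
) -> np.ndarray:
    """Rasterize period-tile segments onto an N x N torus.

    A pixel is cable iff the perpendicular distance from its center to some
    segment (or a periodic image thereof) is < linewidth / 2. Segment
    centerlines are shifted by (w - 1)/2 so an axis-aligned line of width w
    covers exactly w pixel columns/rows.
    """
    px, py = period
    shift = (linewidth - 1) / 2.0
    xs, ys = np.meshgrid(np.arange(px, dtype=float), np.arange(py, dtype=float), indexing="ij")
    tile = np.zeros((px, py), dtype=bool)
    for x1, y1, x2, y2 in segments:
        for ox in (-px, 0, px):
            for oy in (-py, 0, py):
                ax, ay = x1 + ox + shift, y1 + oy + shift
                bx, by = x2 + ox + shift, y2 + oy + shift
                dx, dy = bx - ax, by - ay
                L2 = dx * dx + dy * dy
                if L2 == 0:
                    d2 = (xs - ax) ** 2 + (ys - ay) ** 2
                else:
                    t = np.clip(((xs - ax) * dx + (ys - ay) * dy) / L2, 0.0, 1.0)
                    d2 = (xs - ax - t * dx) ** 2 + (ys - ay - t * dy) ** 2
                tile |= d2 < (linewidth / 2.0) ** 2
    reps = (n // px, n // py)
    return np.tile(tile, reps)


def build_scaffold(
    shape: str,
    domain_size_px: int,
    tile_area_px: float = 2500.0,
    linewidth_px: int = 4,
) -> ScaffoldMask:
    """Build a periodic cable-line scaffold mask.

    Parameters
    ----------
    shape : ``square``, ``hexagon`` or ``triangle``.
    domain_size_px : torus side length N (cells).
    tile_area_px : enclosed area of one periodic unit, in pixels. The default
        2500 gives 50-px units on the standard 200-px domain (50 um at the
        1 um/px length scale).
    linewidth_px : rasterized cable width (default 4 px).

    The tiling period is snapped to divisors of N on each axis so the mask is
    exactly periodic on the torus; the unit polygon is mildly sheared from
    regular when the ideal period is not a divisor, with its area preserved.
    """
    if shape not in SHAPES:
        raise ScaffoldConfigError(f"unknown scaffold shape {shape!r}; expected one of {SHAPES}")
    if linewidth_px < 1:
        raise ScaffoldConfigError("linewidth_px must be >= 1")
    if tile_area_px <= 0:
        raise ScaffoldConfigError("tile_area_px must be positive")
    if domain_size_px < 2 * math.sqrt(tile_area_px):
        raise ScaffoldConfigError(
            f"tile_area_px={tile_area_px} too large for domain_size_px={domain_size_px}: "
            f"need domain >= 2*sqrt(area) = {2 * math.sqrt(tile_area_px):.1f}"
        )

    n = int(domain_size_px)
    A = float(tile_area_px)
    if shape == "square":
        p = _divisor_near(n, math.sqrt(A))
        period = (p, p)
        segs = _segments_square(*period)
        unit_area = p * p
    elif shape == "hexagon":
        # regular: px = sqrt(3) a, py = 3 a, hexagon area = px*py/2
        a = math.sqrt(2 * A / (3 * math.sqrt(3)))
        px = _divisor_near(n, math.sqrt(3) * a)
        py = _divisor_near(n, 2 * A / px)
        period = (px, py)
        segs = _segments_hexagon(*period)
        unit_area = px * py / 2
    else:  # triangle
        # equilateral: side s, px = s, py = sqrt(3)/2 s, triangle area = px*py/2
        s = math.sqrt(4 * A / math.sqrt(3))
        px = _divisor_near(n, s)
        py = _divisor_near(n, 2 * A / px)
        period = (px, py)
        segs = _segments_triangle(*period)
        unit_area = px * py / 2

    grid = _rasterize(segs, period, n, float(linewidth_px))
    count = int(grid.sum())
    if not 0 < count < n * n / 2:
        raise ScaffoldConfigError(
            f"scaffold covers {count}/{n * n} cells; tiling degenerate for "
            f"shape={shape}, domain={n}, tile_area={tile_area_px}, linewidth={linewidth_px}"
        )
    return ScaffoldMask(
        grid=grid,
        shape_label=shape,
        linewidth_px=int(linewidth_px),
        tile_area_px=float(unit_area),
        period=period,
    )


def adjacency_map(mask: ScaffoldMask) -> np.ndarray:
    """Cells that are cable cells or 8-adjacent to one (periodic wrap).

    This precomputes the "adjacent to the cable line" predicate of the
    attachment rule as a single boolean dilation.
    """
    g = mask.grid
    out = g.copy()
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            if dx or dy:
                out |= np.roll(g, (dx, dy), axis=(0, 1))
    return out
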