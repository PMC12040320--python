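"""City-block maze geometry.

The apparatus is a walled rectangular platform with six square blocks
arranged in a 2x3 grid. The interstitial spaces between blocks and walls
define 17 alleys (9 vertical, 8 horizontal) and 12 intersections arranged
on a 3x4 lattice. Corridors are the straight concatenations of collinear
alleys spanning the platform (3 vertical + 4 horizontal = 7).

Coordinates are image-frame: x grows east (right), y grows south (down),
so "north" means decreasing y. All rectangles are half-open,
``[x0, x1) x [y0, y1)``, which gives every point a unique region.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, RegionLookupError

VERTICAL = "vertical"
HORIZONTAL = "horizontal"

#: Cardinal directions in image coordinates (north = decreasing y/row).
DIRECTIONS = ("N", "E", "S", "W")

#: Positive direction per orientation ("north and east taken as positive").
POSITIVE_DIRECTION = {VERTICAL: "N", HORIZONTAL: "E"}
DIRECTION_PAIRS = {VERTICAL: ("N", "S"), HORIZONTAL: ("E", "W")}


@dataclass(frozen=True)
class Rect:
    """Axis-aligned half-open rectangle in cm."""

    x0: float
    y0: float
    x1: float
    y1: float

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x0 + self.x1), 0.5 * (self.y0 + self.y1))

    def as_list(self) -> list[float]:
        return [self.x0, self.y0, self.x1, self.y1]


@dataclass(frozen=True)
class Alley:
    id: str
    rect: Rect
    orientation: str  # VERTICAL or HORIZONTAL


@dataclass(frozen=True)
class Intersection:
    id: str
    rect: Rect


@dataclass(frozen=True)
class Corridor:
    id: str
    orientation: str
    alley_ids: tuple[str, ...]  # ordered along the corridor axis


@dataclass
class MazeGeometry:
    """Full maze layout plus bin-resolution raster support."""

    platform: Rect
    blocks: list[Rect]
    alleys: list[Alley]
    intersections: list[Intersection]
    corridors: list[Corridor]
    px_per_cm: float
    bin_size_cm: float
    walkable_mask: np.ndarray = field(repr=False)  # bool, (rows, cols)
    region_grid: np.ndarray = field(repr=False)  # object ids, '' = off-track

    def __post_init__(self) -> None:
        self._alleys = {a.id: a for a in self.alleys}
        self._intersections = {i.id: i for i in self.intersections}
        self._corridor_of = {}
        for c in self.corridors:
            for aid in c.alley_ids:
                self._corridor_of[aid] = c.id

    # -- lookups ---------------------------------------------------------
    def alley(self, alley_id: str) -> Alley:
        try:
            return self._alleys[alley_id]
        except KeyError:
            raise RegionLookupError(f"unknown alley id: {alley_id!r}") from None

    def region_rect(self, region_id: str) -> Rect:
        if region_id in self._alleys:
            return self._alleys[region_id].rect
        if region_id in self._intersections:
            return self._intersections[region_id].rect
        raise RegionLookupError(f"unknown region id: {region_id!r}")

    def is_alley(self, region_id: str) -> bool:
        return region_id in self._alleys

    def orientation_of(self, region_id: str) -> str | None:
        """Orientation of an alley, or None for intersections."""
        a = self._alleys.get(region_id)
        return a.orientation if a is not None else None

    @property
    def region_ids(self) -> list[str]:
        return [a.id for a in self.alleys] + [i.id for i in self.intersections]

    def region_bins(self, region_id: str) -> np.ndarray:
        """(k, 2) array of [row, col] bins whose centers fall in the region."""
        self.region_rect(region_id)  # validate id
        rows, cols = np.nonzero(self.region_grid == region_id)
        return np.column_stack([rows, cols])

    @property
    def n_bins_walkable(self) -> int:
        return int(self.walkable_mask.sum())

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.walkable_mask.shape

    def bin_of(self, x: float, y: float) -> tuple[int, int]:
        """Bin (row, col) containing a point; may lie outside the grid."""
        return (int(np.floor(y / self.bin_size_cm)), int(np.floor(x / self.bin_size_cm)))

    # -- graph structure -------------------------------------------------
    def alley_adjacency(self) -> dict[str, set[str]]:
        """Alleys are adjacent when they touch a common intersection."""
        adj: dict[str, set[str]] = {a.id: set() for a in self.alleys}
        for inter in self.intersections:
            touching = [
                a.id
                for a in self.alleys
                if _rects_touch(a.rect, inter.rect)
            ]
            for i, aid in enumerate(touching):
                for bid in touching[i + 1 :]:
                    adj[aid].add(bid)
                    adj[bid].add(aid)
        return adj

    def alleys_at_intersection(self, intersection_id: str) -> list[str]:
        inter = self._intersections.get(intersection_id)
        if inter is None:
            raise RegionLookupError(f"unknown intersection id: {intersection_id!r}")
        return [a.id for a in self.alleys if _rects_touch(a.rect, inter.rect)]

    def intersections_of_alley(self, alley_id: str) -> list[str]:
        a = self.alley(alley_id)
        return [i.id for i in self.intersections if _rects_touch(a.rect, i.rect)]

    def alley_graph_distance(self, alley_a: str, alley_b: str) -> int:
        """Breadth-first shortest path length on the alley adjacency graph."""
        self.alley(alley_a)
        self.alley(alley_b)
        if alley_a == alley_b:
            return 0
        adj = self.alley_adjacency()
        frontier, seen, d = {alley_a}, {alley_a}, 0
        while frontier:
            d += 1
            frontier = {n for a in frontier for n in adj[a]} - seen
            if alley_b in frontier:
                return d
            seen |= frontier
        raise RegionLookupError(f"no path between {alley_a!r} and {alley_b!r}")

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "platform": self.platform.as_list(),
            "blocks": [b.as_list() for b in self.blocks],
            "alleys": [
                {"id": a.id, "rect": a.rect.as_list(), "orientation": a.orientation}
                for a in self.alleys
            ],
            "intersections": [
                {"id": i.id, "rect": i.rect.as_list()} for i in self.intersections
            ],
            "corridors": [
                {"id": c.id, "orientation": c.orientation, "alleys": list(c.alley_ids)}
                for c in self.corridors
            ],
            "px_per_cm": self.px_per_cm,
            "bin_size_cm": self.bin_size_cm,
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MazeGeometry":
        doc = json.loads(text)
        platform = Rect(*doc["platform"])
        blocks = [Rect(*b) for b in doc["blocks"]]
        alleys = [Alley(a["id"], Rect(*a["rect"]), a["orientation"]) for a in doc["alleys"]]
        intersections = [Intersection(i["id"], Rect(*i["rect"])) for i in doc["intersections"]]
        corridors = [
            Corridor(c["id"], c["orientation"], tuple(c["alleys"])) for c in doc["corridors"]
        ]
        walkable, grid = _rasterize(platform, alleys, intersections, doc["bin_size_cm"])
        return cls(
            platform=platform,
            blocks=blocks,
            alleys=alleys,
            intersections=intersections,
            corridors=corridors,
            px_per_cm=doc["px_per_cm"],
            bin_size_cm=doc["bin_size_cm"],
            walkable_mask=walkable,
            region_grid=grid,
        )

    def walkable_mask_text(self) -> str:
        """Walkable mask as a plain-text 0/1 grid (one row per line)."""
        return "\n".join("".join("1" if v else "0" for v in row) for row in self.walkable_mask)


def _rects_touch(a: Rect, b: Rect, tol: float = 1e-9) -> bool:
    """True when two closed rectangles share at least an edge segment."""
    return (
        a.x0 <= b.x1 + tol
        and b.x0 <= a.x1 + tol
        and a.y0 <= b.y1 + tol
        and b.y0 <= a.y1 + tol
    )


def _rasterize(platform, alleys, intersections, bin_size_cm):
    n_rows = int(np.ceil(platform.height / bin_size_cm))
    n_cols = int(np.ceil(platform.width / bin_size_cm))
    grid = np.full((n_rows, n_cols), "", dtype=object)
    yc = (np.arange(n_rows) + 0.5) * bin_size_cm
    xc = (np.arange(n_cols) + 0.5) * bin_size_cm
    for region in list(alleys) + list(intersections):
        r = region.rect
        rows = np.nonzero((yc >= r.y0) & (yc < r.y1))[0]
        cols = np.nonzero((xc >= r.x0) & (xc < r.x1))[0]
        for ri in rows:
            for ci in cols:
                grid[ri, ci] = region.id
    walkable = grid != ""
    return walkable, grid


def build_standard_maze(
    block_size_cm: float = 19.1,
    platform_cm: tuple[float, float] = (60.96, 91.44),
    px_per_cm: float = 10.0 / 2.1,
    bin_px: int = 10,
    n_block_cols: int = 2,
    n_block_rows: int = 3,
) -> MazeGeometry:
    """Build the standard city-block maze.

    Parameters
    ----------
    block_size_cm
        Side of the square obstacles. Defaults to 19.1 cm; the as-built
        value of 18.4 cm is also supported.
    platform_cm
        (width, height) of the walled platform in cm, width being the
        east-west extent.
    px_per_cm
        Camera pixels per cm (default 10 px / 2.1 cm).
    bin_px
        Ratemap bin size in camera pixels; with the default conversion a
        10 px bin is 2.1 cm.
    """
    width, height = platform_cm
    if block_size_cm <= 0 or width <= 0 or height <= 0:
        raise ConfigurationError("block and platform dimensions must be positive")
    gap_x = (width - n_block_cols * block_size_cm) / (n_block_cols + 1)
    gap_y = (height - n_block_rows * block_size_cm) / (n_block_rows + 1)
    if gap_x <= 0:
        raise ConfigurationError(
            f"blocks do not fit horizontally: {n_block_cols} x {block_size_cm} cm "
            f"inside {width} cm leaves gap {gap_x:.2f} cm"
        )
    if gap_y <= 0:
        raise ConfigurationError(
            f"blocks do not fit vertically: {n_block_rows} x {block_size_cm} cm "
            f"inside {height} cm leaves gap {gap_y:.2f} cm"
        )

    # x bands alternate gap/block starting and ending with a gap.
    x_edges = [0.0]
    for _ in range(n_block_cols):
        x_edges.append(x_edges[-1] + gap_x)
        x_edges.append(x_edges[-1] + block_size_cm)
    x_edges.append(x_edges[-1] + gap_x)
    y_edges = [0.0]
    for _ in range(n_block_rows):
        y_edges.append(y_edges[-1] + gap_y)
        y_edges.append(y_edges[-1] + block_size_cm)
    y_edges.append(y_edges[-1] + gap_y)

    def x_band(i):  # i-th band: even = gap, odd = block
        return x_edges[i], x_edges[i + 1]

    def y_band(j):
        return y_edges[j], y_edges[j + 1]

    blocks, alleys, intersections = [], [], []
    n_x_bands = 2 * n_block_cols + 1
    n_y_bands = 2 * n_block_rows + 1
    for j in range(n_y_bands):
        for i in range(n_x_bands):
            x0, x1 = x_band(i)
            y0, y1 = y_band(j)
            rect = Rect(x0, y0, x1, y1)
            x_gap, y_gap = i % 2 == 0, j % 2 == 0
            if x_gap and y_gap:
                intersections.append(Intersection(f"I{i // 2}{j // 2}", rect))
            elif x_gap and not y_gap:
                alleys.append(Alley(f"V{i // 2}{j // 2}", rect, VERTICAL))
            elif not x_gap and y_gap:
                alleys.append(Alley(f"H{i // 2}{j // 2}", rect, HORIZONTAL))
            else:
                blocks.append(rect)

    corridors = []
    for col in range(n_block_cols + 1):
        ids = tuple(f"V{col}{row}" for row in range(n_block_rows))
        corridors.append(Corridor(f"CV{col}", VERTICAL, ids))
    for row in range(n_block_rows + 1):
        ids = tuple(f"H{col}{row}" for col in range(n_block_cols))
        corridors.append(Corridor(f"CH{row}", HORIZONTAL, ids))

    bin_size_cm = bin_px / px_per_cm
    walkable, grid = _rasterize(Rect(0, 0, width, height), alleys, intersections, bin_size_cm)
    return MazeGeometry(
        platform=Rect(0, 0, width, height),
        blocks=blocks,
        alleys=alleys,
        intersections=intersections,
        corridors=corridors,
        px_per_cm=px_per_cm,
        bin_size_cm=bin_size_cm,
        walkable_mask=walkable,
        region_grid=grid,
    )


def region_lookup(geometry: MazeGeometry, x: float, y: float) -> str | None:
    """Region id containing (x, y), or None if off-track (block/outside).

    Membership follows the half-open convention ``[x0, x1) x [y0, y1)`` so
    every point maps to at most one region.
    """
    if not (np.isfinite(x) and np.isfinite(y)):
        return None
    for alley in geometry.alleys:
        if alley.rect.contains(x, y):
            return alley.id
    for inter in geometry.intersections:
        if inter.rect.contains(x, y):
            return inter.id
    return None


def region_lookup_array(geometry: MazeGeometry, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized region lookup; '' marks off-track samples.

    Each region is tested with half-open interval masks, so the result
    agrees with :func:`region_lookup` point-by-point.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    out = np.full(x.shape, "", dtype=object)
    for region in list(geometry.alleys) + list(geometry.intersections):
        r = region.rect
        mask = (x >= r.x0) & (x < r.x1) & (y >= r.y0) & (y < r.y1)
        out[mask] = region.id
    return out


def same_corridor(geometry: MazeGeometry, alley_a: str, alley_b: str) -> bool:
    """True iff both alleys lie on one corridor (equivalently: collinear)."""
    geometry.alley(alley_a)
    geometry.alley(alley_b)
    return geometry._corridor_of[alley_a] == geometry._corridor_of[alley_b]
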