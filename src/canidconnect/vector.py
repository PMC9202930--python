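"""Point, polyline, polygon and tabular domain types."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Polygon

__all__ = ["OccurrenceSet", "RoadNetwork", "ProtectedAreas", "RoadKillTable", "SEASONS"]

SEASONS = ("Spring", "Summer", "Autumn", "Winter")


@dataclass
class OccurrenceSet:
    """Species presence (or crossing) points in planar meters."""

    species: str
    points: np.ndarray  # (n, 2) x, y

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]


@dataclass
class RoadNetwork:
    """Polyline road network; lengths in meters are derived, never stored."""

    polylines: list[np.ndarray]  # each (k, 2) vertex sequence

    def __post_init__(self) -> None:
        self.polylines = [np.asarray(p, dtype=float).reshape(-1, 2) for p in self.polylines]
        for p in self.polylines:
            if len(p) < 2:
                raise ValueError("each polyline needs at least 2 vertices")

    @property
    def segment_lengths(self) -> list[np.ndarray]:
        return [np.hypot(*np.diff(p, axis=0).T) for p in self.polylines]

    @property
    def total_length(self) -> float:
        return float(sum(seg.sum() for seg in self.segment_lengths))

    def as_linestrings(self) -> list[LineString]:
        return [LineString(p) for p in self.polylines]


@dataclass
class ProtectedAreas:
    """Protected-area polygons with category labels (WR | CA | NHA)."""

    polygons: list[Polygon]
    categories: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.categories:
            self.categories = ["CA"] * len(self.polygons)
        if len(self.categories) != len(self.polygons):
            raise ValueError("one category per polygon required")
        for poly in self.polygons:
            if not poly.is_valid:
                raise ValueError("protected-area polygons must be valid (non-self-intersecting)")

    @property
    def total_area(self) -> float:
        return float(sum(p.area for p in self.polygons))


@dataclass
class RoadKillTable:
    """Season x year road-mortality counts for one species.

    Rows follow the fixed season order Spring, Summer, Autumn, Winter; totals
    are always derived from ``counts``, never stored.
    """

    species: str
    counts: np.ndarray  # (4, n_years) non-negative integers
    years: list[int] = field(default_factory=list)
    seasons: tuple[str, ...] = SEASONS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[0] != len(self.seasons):
            raise ValueError(f"counts must be ({len(self.seasons)}, n_years)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.years:
            self.years = list(range(self.counts.shape[1]))

    @property
    def n_years(self) -> int:
        return self.counts.shape[1]

    @property
    def season_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def year_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())
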