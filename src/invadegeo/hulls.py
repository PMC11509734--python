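"""Convex-hull range areas and subsampling-based fair comparison.

The extent of occurrence of a taxon is the area of the convex hull of
its occurrence points, measured in square degrees on the raw
(longitude, latitude) plane.  Hull area grows with sample size, so two
taxa with unequal numbers of points cannot be compared directly: the
larger sample is repeatedly subsampled down to the smaller sample's
size, and the smaller taxon's full-sample area is classified against a
percentile interval of the subsampled areas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import MultiPoint

from invadegeo.occurrences import TaxonPointSet

VERDICTS = ("reference_below_interval", "reference_within_interval",
            "reference_above_interval")


@dataclass
class ConvexHullResult:
    """Hull boundary vertices (latitude, longitude), counterclockwise in
    the (longitude, latitude) plane, and the planar shoelace area in
    square degrees.  Fewer than 3 non-collinear points give area 0."""

    vertices: list[tuple[float, float]]
    area_sq_deg: float

    def to_geojson(self) -> dict:
        ring = [(lon, lat) for lat, lon in self.vertices]
        if ring and ring[0] != ring[-1]:
            ring = ring + [ring[0]]
        return {
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [ring]},
            "properties": {"area_sq_deg": self.area_sq_deg},
        }


@dataclass
class SubsampleAreaDistribution:
    """Hull areas of ``replicates`` subsamples of size ``subsample_size``,
    with their mean and 2.5/97.5 percentile limits."""

    subsample_size: int
    replicates: int
    areas: list[float]
    mean_area: float
    ci_lower: float
    ci_upper: float
    seed: int

    def __post_init__(self) -> None:
        if len(self.areas) != self.replicates:
            raise ValueError("areas length must equal replicates")
        if self.ci_lower > self.ci_upper:
            raise ValueError("ci_lower must be <= ci_upper")


@dataclass
class AreaComparison:
    """Outcome of a sister-lineage area comparison: the larger-sample
    taxon subsampled to the smaller taxon's n, versus the smaller
    taxon's full hull area."""

    focal: SubsampleAreaDistribution
    reference_area: float
    verdict: str

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")


def _hull_from_array(xy: np.ndarray) -> tuple[list[tuple[float, float]], float]:
    """Hull vertices (lat, lon) and shoelace area from an (n, 2) array of
    (longitude, latitude) rows.  Degenerate inputs give area 0."""
    geom = MultiPoint(xy).convex_hull
    if geom.geom_type == "Polygon":
        ring = list(geom.exterior.coords)[:-1]
        # shapely orients exterior rings counterclockwise in newer versions;
        # enforce CCW for the contract
        if _signed_area(ring) < 0:
            ring = ring[::-1]
        return [(lat, lon) for lon, lat in ring], abs(_signed_area(ring))
    # Point or LineString: all points coincident or collinear
    coords = list(geom.coords)
    return [(lat, lon) for lon, lat in coords], 0.0


def _signed_area(ring: list[tuple[float, float]]) -> float:
    s = 0.0
    n = len(ring)
    for i in range(n):
        x1, y1 = ring[i]
        x2, y2 = ring[(i + 1) % n]
        s += x1 * y2 - x2 * y1
    return s / 2.0


def _as_xy(points: TaxonPointSet | list[tuple[float, float]]) -> np.ndarray:
    pts = points.points if isinstance(points, TaxonPointSet) else points
    if len(pts) == 0:
        raise ValueError("empty point set")
    arr = np.array([(lon, lat) for lat, lon in pts], dtype=float)
    lon = arr[:, 0]
    if lon.max() - lon.min() > 180.0:
        warnings.warn(
            "longitudes span more than a hemisphere; planar hull areas "
            "across the antimeridian are not meaningful"
        )
    return arr


def convex_hull(points: TaxonPointSet | list[tuple[float, float]]) -> ConvexHullResult:
    """Convex hull of the point set in the (longitude, latitude) plane.

    Duplicate points are ignored for the geometry; the area is the
    planar shoelace area in square degrees.
    """
    verts, area = _hull_from_array(_as_xy(points))
    return ConvexHullResult(vertices=verts, area_sq_deg=area)


def hull_area(points) -> float:
    """Convenience: just the hull area in square degrees."""
    return convex_hull(points).area_sq_deg


def subsample_areas(
    points: TaxonPointSet | list[tuple[float, float]],
    m: int,
    b: int,
    seed: int = 0,
    exhaustive: bool = False,
) -> SubsampleAreaDistribution:
    """Hull areas of ``b`` random subsamples of ``m`` points, without
    replacement, with percentile 95% limits (2.5th and 97.5th).

    With ``exhaustive=True`` every one of the C(n, m) subsets is
    evaluated instead (``b`` is ignored); feasible only for small sets.
    """
    xy = _as_xy(points)
    n = len(xy)
    if m < 3:
        raise ValueError("subsample size must be >= 3 (hull area undefined below)")
    if m > n:
        raise ValueError(f"subsample size {m} exceeds number of points {n}")
    if exhaustive:
        from itertools import combinations
        from math import comb
        if comb(n, m) > 200_000:
            raise ValueError(f"C({n},{m}) too large for exhaustive enumeration")
        areas = np.array([_hull_from_array(xy[list(idx)])[1]
                          for idx in combinations(range(n), m)])
        b = len(areas)
    else:
        if b < 1:
            raise ValueError("need at least one replicate")
        rng = np.random.default_rng(seed)
        areas = np.empty(b)
        for i in range(b):
            idx = rng.choice(n, size=m, replace=False)
            _, areas[i] = _hull_from_array(xy[idx])
    lo, hi = np.percentile(areas, [2.5, 97.5])
    return SubsampleAreaDistribution(
        subsample_size=m, replicates=b, areas=areas.tolist(),
        mean_area=float(areas.mean()), ci_lower=float(lo), ci_upper=float(hi),
        seed=seed,
    )


def rarefaction_curve(
    points: TaxonPointSet | list[tuple[float, float]],
    sizes: list[int],
    b: int,
    seed: int = 0,
) -> list[SubsampleAreaDistribution]:
    """One subsample-area distribution per requested size; suitable for
    plotting mean and 95% limits against sample size (each size gets an
    independent seeded stream)."""
    return [subsample_areas(points, m, b, seed=seed + i) for i, m in enumerate(sizes)]


def compare_sister_areas(
    focal_points: TaxonPointSet,
    reference_points: TaxonPointSet,
    b: int = 100,
    seed: int = 0,
) -> AreaComparison:
    """Fair sister-lineage range comparison under unequal sample sizes.

    The better-sampled (focal) taxon is subsampled to the reference
    taxon's sample size ``b`` times; the reference taxon's full hull
    area is then classified against the 95% percentile interval of the
    focal subsample areas.  A reference area below the lower limit means
    the focal range is wider than sampling effort alone explains.
    """
    if len(reference_points) > len(focal_points):
        warnings.warn(
            "reference has more points than focal; swapping roles "
            "(the comparison is symmetric)"
        )
        focal_points, reference_points = reference_points, focal_points
    m = len(reference_points)
    if m < 3:
        raise ValueError("reference needs at least 3 points")
    dist = subsample_areas(focal_points, m=m, b=b, seed=seed)
    ref_area = hull_area(reference_points)
    if ref_area < dist.ci_lower:
        verdict = "reference_below_interval"
    elif ref_area > dist.ci_upper:
        verdict = "reference_above_interval"
    else:
        verdict = "reference_within_interval"
    return AreaComparison(focal=dist, reference_area=ref_area, verdict=verdict)
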