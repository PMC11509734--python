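"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

Three generators cover the pipeline's inputs end to end: annual count
series whose expectation follows the logistic invasion curve scaled by a
constant observation rate c (optionally with Poisson sampling noise),
spatial point clouds with known support for convex-hull work, and random
trees whose tip coordinates arise from a Brownian dispersal walk along
the branches.  All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import dendropy
import numpy as np
from shapely.geometry import Point as _ShpPoint, Polygon as _ShpPolygon

from invadegeo.occurrences import AnnualCountSeries, TaxonPointSet
from invadegeo.logistic import LogisticParams, logistic_nt
from invadegeo.geophylo import GeoTree


@dataclass
class SeriesSimSpec:
    """Recipe for an annual count series: counts have expectation
    c * N(t) with N(t) the logistic curve; noise is 'none' (real-valued
    expectations, for exact oracle tests) or 'poisson'."""

    params: LogisticParams
    c: float = 1.0
    years: tuple[int, int] = (2003, 2011)
    noise: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("c must be > 0")
        if self.years[0] > self.years[1]:
            raise ValueError("empty year range")
        if self.noise not in ("none", "poisson"):
            raise ValueError("noise must be 'none' or 'poisson'")


@dataclass
class CloudSimSpec:
    """Recipe for a spatial point cloud: uniform points inside a convex
    polygon (given as (lat, lon) vertices), or a Gaussian mixture with
    the given centers and isotropic sd (degrees)."""

    n_points: int
    region: Optional[Sequence[tuple[float, float]]] = None
    centers: Optional[Sequence[tuple[float, float]]] = None
    sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("n_points must be >= 3")
        if (self.region is None) == (self.centers is None):
            raise ValueError("give exactly one of region or centers")


def simulate_series(spec: SeriesSimSpec) -> AnnualCountSeries:
    """Annual counts on integer years with expectation c * N(t)."""
    years = np.arange(spec.years[0], spec.years[1] + 1, dtype=float)
    mean = spec.c * np.asarray(logistic_nt(spec.params, years), dtype=float)
    if spec.noise == "none":
        counts = mean
    else:
        rng = np.random.default_rng(spec.seed)
        counts = rng.poisson(mean).astype(float)
    return AnnualCountSeries(spec.years[0], spec.years[1], counts.tolist())


def simulate_cloud(spec: CloudSimSpec, taxon: str = "synthetic") -> TaxonPointSet:
    """Point cloud by rejection sampling in a polygon or by drawing from
    a Gaussian mixture; reproducible by seed."""
    rng = np.random.default_rng(spec.seed)
    pts: list[tuple[float, float]] = []
    if spec.region is not None:
        poly = _ShpPolygon([(lon, lat) for lat, lon in spec.region])
        if poly.area <= 0:
            raise ValueError("degenerate region (zero area)")
        minx, miny, maxx, maxy = poly.bounds
        while len(pts) < spec.n_points:
            lon = rng.uniform(minx, maxx)
            lat = rng.uniform(miny, maxy)
            if poly.covers(_ShpPoint(lon, lat)):
                pts.append((lat, lon))
    else:
        if spec.sd < 0:
            raise ValueError("sd must be non-negative")
        centers = np.asarray(spec.centers, dtype=float)
        which = rng.integers(0, len(centers), size=spec.n_points)
        for i in range(spec.n_points):
            lat0, lon0 = centers[which[i]]
            lat = lat0 + rng.normal(0.0, spec.sd)
            lon = lon0 + rng.normal(0.0, spec.sd)
            pts.append((float(np.clip(lat, -90, 90)), float(np.clip(lon, -180, 180))))
    return TaxonPointSet(taxon=taxon, points=pts,
                         provenance=f"simulated (seed={spec.seed})")


def simulate_geo_tree(
    n_tips: int,
    dispersal_sd: float = 1.0,
    seed: int = 0,
    root_coord: tuple[float, float] = (0.0, 0.0),
    mean_branch_length: float = 1.0,
) -> GeoTree:
    """Random bifurcating tree with tip coordinates from a dispersal walk.

    Topology grows by uniformly random pairwise joins (coalescent-style);
    every branch gets an exponential length with the given mean.
    Coordinates evolve root-to-tip as a Brownian walk: each node is
    displaced from its parent by independent N(0, dispersal_sd^2 * L)
    in latitude and longitude, L the connecting branch length — so tip
    scatter grows with root-to-tip distance.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes = []
    for i in range(n_tips):
        node = dendropy.Node()
        node.taxon = tns.new_taxon(label=f"T{i + 1}")
        node.edge.length = float(rng.exponential(mean_branch_length))
        nodes.append(node)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = float(rng.exponential(mean_branch_length))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = nodes[0]
    root.edge.length = None
    tree.seed_node = root

    coords: dict[dendropy.Node, tuple[float, float]] = {root: root_coord}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        plat, plon = coords[node.parent_node]
        L = node.edge.length or 0.0
        step_sd = dispersal_sd * np.sqrt(L)
        coords[node] = (plat + float(rng.normal(0.0, step_sd)),
                        plon + float(rng.normal(0.0, step_sd)))
    tip_coordinates = {leaf.taxon.label: coords[leaf] for leaf in tree.leaf_node_iter()}
    return GeoTree(tree=tree, tip_coordinates=tip_coordinates)


def france_scenario() -> SeriesSimSpec:
    """France-like invasion series: fast growth (r = 1.3667 / yr) from a
    late-May 2002 founding, observed 2003-2011.  The population proxies
    (n0 = 0.4, k = 400 observation units, the canonical founding
    fraction of 1e-3) give expected counts near one in 2003 saturating
    near 400 by 2011."""
    return SeriesSimSpec(
        params=LogisticParams(n0=0.4, k=400.0, r=1.3667, t0=2002.40),
        c=1.0, years=(2003, 2011), noise="none", seed=0,
    )


def korea_scenario() -> SeriesSimSpec:
    """South-Korea-like invasion series: slow growth (r = 0.2812 / yr)
    from an early-October 2002 founding, observed 2003-2015.  Proxies
    (n0 = 1, k = 1000) keep expected counts near one for several years —
    the sparse-series regime where the fit is hardest."""
    return SeriesSimSpec(
        params=LogisticParams(n0=1.0, k=1000.0, r=0.2812, t0=2002.77),
        c=1.0, years=(2003, 2015), noise="none", seed=0,
    )
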