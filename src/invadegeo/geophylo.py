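"""Geophylogeny construction and export.

A geophylogeny draws a phylogenetic tree in geographic space: each tip
is anchored at its specimen's collection coordinates, branch lengths are
rendered as vertical bars proportional to their length, and connector
segments trace the topology between bar tops and parent anchors.  Tips
with identical coordinates are deterministically jittered apart; clades
can be collapsed to a single marker at their coordinate centroid.
Layouts export to GeoJSON (RFC 7946) and KML.
"""

from __future__ import annotations

import json
import math
import warnings
import xml.sax.saxutils as _sax
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import dendropy


class NewickParseError(ValueError):
    pass


class AnchoringError(ValueError):
    """Tips that a layout needs are missing coordinates."""


class MonophylyError(ValueError):
    """The requested tip set is not a clade in the tree."""


@dataclass
class GeoTree:
    """A rooted tree plus tip coordinates and optional tip metadata.

    tip_coordinates maps tip label -> (latitude, longitude); tips absent
    from the mapping are unanchored.  collapsed_members holds the
    anchors of tips that were absorbed into a collapsed-clade marker
    (retained as unlinked map markers).
    """

    tree: dendropy.Tree
    tip_coordinates: dict[str, tuple[float, float]] = field(default_factory=dict)
    tip_metadata: dict[str, dict] = field(default_factory=dict)
    collapsed_members: list[tuple[str, tuple[float, float], str]] = field(default_factory=list)

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def branch_lengths(self) -> dict[str, float]:
        return {leaf.taxon.label: (leaf.edge.length or 0.0)
                for leaf in self.tree.leaf_node_iter()}

    def is_fully_anchored(self) -> bool:
        return all(lbl in self.tip_coordinates for lbl in self.tip_labels)

    def write_newick(self, path) -> None:
        self.tree.write(path=str(path), schema="newick",
                        suppress_rooting=True, real_value_format_specifier=".10g")


@dataclass
class GeoPhyloLayout:
    """Renderable geophylogeny: per-node anchors, north-pointing bars
    whose length is a single global scale times the branch length, and
    connector segments joining each bar top to its parent anchor."""

    anchors: dict[str, tuple[float, float]]          # node id -> (lat, lon)
    bar_lengths: dict[str, float]                    # node id -> map units
    bars: list[tuple[str, tuple[float, float], tuple[float, float]]]       # (node, base, top)
    connectors: list[tuple[str, str, tuple[float, float], tuple[float, float]]]  # (child, parent, from, to)
    tip_ids: list[str]
    collapsed_markers: list[tuple[str, tuple[float, float], str]]
    bar_scale: float
    tip_metadata: dict[str, dict] = field(default_factory=dict)


def _validate_tips(tree: dendropy.Tree) -> None:
    unlabeled = [repr(leaf) for leaf in tree.leaf_node_iter()
                 if leaf.taxon is None or not (leaf.taxon.label or "").strip()]
    if unlabeled:
        raise NewickParseError(f"tree has unlabeled tips: {unlabeled}")
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise NewickParseError(f"duplicate tip labels: {sorted(dupes)}")


def read_newick(source: Union[str, "object"]) -> GeoTree:
    """Read a newick tree (file path or newick string) into a GeoTree.

    Branch lengths that are missing become 0 with a warning; malformed
    newick raises :class:`NewickParseError` carrying the parser's
    position message.
    """
    src = str(source)
    try:
        if src.lstrip().startswith("("):
            tree = dendropy.Tree.get(data=src, schema="newick",
                                     suppress_internal_node_taxa=True,
                                     preserve_underscores=True)
        else:
            tree = dendropy.Tree.get(path=src, schema="newick",
                                     suppress_internal_node_taxa=True,
                                     preserve_underscores=True)
    except Exception as err:  # dendropy errors carry line/column info
        raise NewickParseError(f"malformed newick: {err}") from err
    tree.is_rooted = True  # geophylogenies are drawn from a rooted tree
    _validate_tips(tree)
    n_missing = 0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            edge.length = 0.0
            n_missing += 1
    if n_missing:
        warnings.warn(f"{n_missing} branch length(s) missing; set to 0")
    return GeoTree(tree=tree)


def attach_coordinates(
    geotree: GeoTree,
    table: Union[dict[str, tuple[float, float]], Sequence[tuple]],
    metadata: Optional[dict[str, dict]] = None,
) -> GeoTree:
    """Anchor tips at specimen coordinates.

    ``table`` is either a mapping label -> (lat, lon) or rows of
    ``(id, latitude, longitude, ...)`` as produced by the specimen-table
    reader.  Labels match tips exactly after whitespace normalization.
    Extra table rows are reported with a warning; tips left without
    coordinates raise :class:`AnchoringError` naming them.
    """
    if isinstance(table, dict):
        coords = {" ".join(k.split()): (float(v[0]), float(v[1])) for k, v in table.items()}
    else:
        coords = {" ".join(str(row[0]).split()): (float(row[1]), float(row[2])) for row in table}
    tips = {" ".join(lbl.split()): lbl for lbl in geotree.tip_labels}
    orphans = sorted(set(coords) - set(tips))
    if orphans:
        warnings.warn(f"coordinate rows without matching tips: {orphans}")
    missing = sorted(set(tips) - set(coords))
    if missing:
        raise AnchoringError(f"tips without coordinates: {missing}")
    geotree.tip_coordinates = {tips[k]: coords[k] for k in tips}
    if metadata:
        geotree.tip_metadata.update(metadata)
    return geotree


def jitter_coincident(geotree: GeoTree, offset_deg: float = 0.05) -> GeoTree:
    """Displace tips sharing identical coordinates onto a small circle.

    Each group of k >= 2 coincident tips is placed on a regular k-gon of
    radius ``offset_deg`` centred on the shared point, assigned in tip-
    label sort order, so output is deterministic and the group centroid
    is preserved.  Non-coincident tips are untouched.
    """
    if offset_deg <= 0:
        raise ValueError("offset_deg must be > 0")
    groups: dict[tuple[float, float], list[str]] = {}
    for lbl, xy in geotree.tip_coordinates.items():
        groups.setdefault(xy, []).append(lbl)
    new_coords = dict(geotree.tip_coordinates)
    for (lat0, lon0), labels in groups.items():
        k = len(labels)
        if k < 2:
            continue
        for i, lbl in enumerate(sorted(labels)):
            theta = 2.0 * math.pi * i / k
            new_coords[lbl] = (lat0 + offset_deg * math.cos(theta),
                               lon0 + offset_deg * math.sin(theta))
    geotree.tip_coordinates = new_coords
    return geotree


def _resolve_clade(tree: dendropy.Tree, clade_spec) -> dendropy.Node:
    """Resolve a tip-label set or a node to a monophyletic ancestor node."""
    if isinstance(clade_spec, dendropy.Node):
        return clade_spec
    labels = set(clade_spec)
    taxa = [t for t in tree.taxon_namespace if t.label in labels]
    if len(taxa) != len(labels):
        known = {t.label for t in taxa}
        raise ValueError(f"unknown tip labels: {sorted(labels - known)}")
    mrca = tree.mrca(taxa=taxa)
    mrca_leaves = {leaf.taxon.label for leaf in mrca.leaf_iter()}
    intruders = mrca_leaves - labels
    if intruders:
        raise MonophylyError(
            f"tip set is not monophyletic; intruding tips: {sorted(intruders)}"
        )
    return mrca


def collapse_clade(geotree: GeoTree, clade_spec, marker: str = "star") -> GeoTree:
    """Collapse a monophyletic group to a single pseudo-tip.

    The pseudo-tip is anchored at the centroid of the member
    coordinates, carries the clade's stem branch length, and is labelled
    after the marker.  Member anchors are retained as unlinked markers
    so the collapsed clade's geographic spread stays visible.
    """
    tree = geotree.tree
    node = _resolve_clade(tree, clade_spec)
    members = [leaf.taxon.label for leaf in node.leaf_iter()]
    anchored = [geotree.tip_coordinates[m] for m in members if m in geotree.tip_coordinates]
    if anchored:
        centroid = (sum(a[0] for a in anchored) / len(anchored),
                    sum(a[1] for a in anchored) / len(anchored))
    else:
        centroid = None
    stem = node.edge.length or 0.0
    pseudo_label = f"collapsed_{marker}_{len(geotree.collapsed_members) + 1}"

    for m in members:
        if m in geotree.tip_coordinates:
            geotree.collapsed_members.append((m, geotree.tip_coordinates.pop(m), marker))
        geotree.tip_metadata.pop(m, None)

    taxon = tree.taxon_namespace.new_taxon(label=pseudo_label)
    if node is tree.seed_node:
        # full collapse: the whole tree becomes one pseudo-tip
        new_tree = dendropy.Tree(taxon_namespace=tree.taxon_namespace)
        new_tree.seed_node.taxon = taxon
        new_tree.seed_node.edge.length = stem
        geotree.tree = new_tree
    else:
        parent = node.parent_node
        parent.remove_child(node)
        leaf = parent.new_child(taxon=taxon, edge_length=stem)
        assert leaf.is_leaf()
    if centroid is not None:
        geotree.tip_coordinates[pseudo_label] = centroid
    geotree.tip_metadata[pseudo_label] = {"collapsed": True, "marker": marker,
                                          "members": members}
    return geotree


def layout_geophylogeny(
    geotree: GeoTree,
    bar_scale: float = 1.0,
    internal_placement: str = "centroid",
) -> GeoPhyloLayout:
    """Compute the geographic layout of an anchored tree.

    Tip anchors are their (possibly jittered) coordinates; each internal
    node is placed at the centroid of its children's anchors.  Every
    node carries a north-pointing bar of length ``bar_scale`` times its
    branch length; a connector joins each node's bar top to its parent's
    anchor.  Zero-length branches draw connectors only.
    """
    if internal_placement != "centroid":
        raise ValueError("only centroid internal placement is supported")
    if not geotree.is_fully_anchored():
        missing = sorted(set(geotree.tip_labels) - set(geotree.tip_coordinates))
        raise AnchoringError(f"unanchored tips: {missing}")

    tree = geotree.tree
    leaves = [n for n in tree.leaf_node_iter()]
    if len(leaves) == 1:
        # degenerate single-tip tree: one anchor, its own bar, no connectors
        lbl = leaves[0].taxon.label
        lat, lon = geotree.tip_coordinates[lbl]
        blen = bar_scale * (leaves[0].edge.length or 0.0)
        bars = [(lbl, (lat, lon), (lat + blen, lon))] if blen > 0 else []
        return GeoPhyloLayout(
            anchors={lbl: (lat, lon)}, bar_lengths={lbl: blen}, bars=bars,
            connectors=[], tip_ids=[lbl],
            collapsed_markers=list(geotree.collapsed_members),
            bar_scale=bar_scale, tip_metadata=dict(geotree.tip_metadata),
        )
    node_ids: dict[dendropy.Node, str] = {}
    anchors: dict[str, tuple[float, float]] = {}
    bar_lengths: dict[str, float] = {}
    tip_ids: list[str] = []
    i_internal = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            nid = node.taxon.label
            anchors[nid] = geotree.tip_coordinates[nid]
            tip_ids.append(nid)
        else:
            nid = f"node_{i_internal}"
            i_internal += 1
            child_xy = [anchors[node_ids[c]] for c in node.child_nodes()]
            anchors[nid] = (sum(p[0] for p in child_xy) / len(child_xy),
                            sum(p[1] for p in child_xy) / len(child_xy))
        node_ids[node] = nid
        bl = 0.0 if node is tree.seed_node else (node.edge.length or 0.0)
        bar_lengths[nid] = bar_scale * bl

    bars = []
    connectors = []
    for node in tree.postorder_node_iter():
        nid = node_ids[node]
        lat, lon = anchors[nid]
        top = (lat + bar_lengths[nid], lon)
        if bar_lengths[nid] > 0:
            bars.append((nid, (lat, lon), top))
        if node.parent_node is not None:
            pid = node_ids[node.parent_node]
            connectors.append((nid, pid, top, anchors[pid]))
    return GeoPhyloLayout(
        anchors=anchors, bar_lengths=bar_lengths, bars=bars,
        connectors=connectors, tip_ids=tip_ids,
        collapsed_markers=list(geotree.collapsed_members),
        bar_scale=bar_scale, tip_metadata=dict(geotree.tip_metadata),
    )


def layout_to_geojson(layout: GeoPhyloLayout) -> dict:
    """GeoJSON FeatureCollection: points for tips and unlinked markers,
    line strings for bars and connectors.  Coordinates are emitted
    (longitude, latitude) per the GeoJSON standard."""
    feats = []
    for nid in layout.tip_ids:
        lat, lon = layout.anchors[nid]
        props = {"label": nid, "kind": "tip"}
        props.update(layout.tip_metadata.get(nid, {}))
        feats.append({"type": "Feature",
                      "geometry": {"type": "Point", "coordinates": [lon, lat]},
                      "properties": props})
    for label, (lat, lon), marker in layout.collapsed_markers:
        feats.append({"type": "Feature",
                      "geometry": {"type": "Point", "coordinates": [lon, lat]},
                      "properties": {"label": label, "kind": "collapsed_member",
                                     "marker": marker}})
    for nid, base, top in layout.bars:
        feats.append({"type": "Feature",
                      "geometry": {"type": "LineString",
                                   "coordinates": [[base[1], base[0]], [top[1], top[0]]]},
                      "properties": {"label": nid, "kind": "bar",
                                     "bar_length": layout.bar_lengths[nid]}})
    for child, parent, frm, to in layout.connectors:
        feats.append({"type": "Feature",
                      "geometry": {"type": "LineString",
                                   "coordinates": [[frm[1], frm[0]], [to[1], to[0]]]},
                      "properties": {"child": child, "parent": parent,
                                     "kind": "connector"}})
    return {"type": "FeatureCollection", "features": feats}


def layout_to_kml(layout: GeoPhyloLayout) -> str:
    """Minimal KML mirror of the GeoJSON export (Placemarks with Point
    or LineString geometry; KML is also longitude,latitude ordered)."""
    def esc(s: str) -> str:
        return _sax.escape(str(s))

    parts = ['<?xml version="1.0" encoding="UTF-8"?>',
             '<kml xmlns="http://www.opengis.net/kml/2.2">', "<Document>"]
    for nid in layout.tip_ids:
        lat, lon = layout.anchors[nid]
        parts.append(
            f"<Placemark><name>{esc(nid)}</name>"
            f"<Point><coordinates>{lon},{lat},0</coordinates></Point></Placemark>"
        )
    for label, (lat, lon), marker in layout.collapsed_markers:
        parts.append(
            f"<Placemark><name>{esc(label)}</name>"
            f"<description>collapsed member ({esc(marker)})</description>"
            f"<Point><coordinates>{lon},{lat},0</coordinates></Point></Placemark>"
        )
    for nid, base, top in layout.bars:
        parts.append(
            f"<Placemark><name>bar {esc(nid)}</name><LineString><coordinates>"
            f"{base[1]},{base[0]},0 {top[1]},{top[0]},0"
            "</coordinates></LineString></Placemark>"
        )
    for child, parent, frm, to in layout.connectors:
        parts.append(
            f"<Placemark><name>connector {esc(child)}-{esc(parent)}</name>"
            f"<LineString><coordinates>{frm[1]},{frm[0]},0 {to[1]},{to[0]},0"
            "</coordinates></LineString></Placemark>"
        )
    parts.extend(["</Document>", "</kml>"])
    return "\n".join(parts)


def export_layout(layout: GeoPhyloLayout, path, format: str = "geojson") -> None:
    """Write the layout to ``path`` as GeoJSON or KML."""
    if format == "geojson":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(layout_to_geojson(layout), fh, indent=1)
    elif format == "kml":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(layout_to_kml(layout))
    else:
        raise ValueError("format must be 'geojson' or 'kml'")
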