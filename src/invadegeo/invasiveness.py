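"""Index of invasiveness.

A taxon's invasive potential is summarized as distribution area per unit
divergence time, I_inv = A / T.  Absolute divergence times are rarely
available, so for sister lineages — which by definition have diverged
for the same amount of time — T can be replaced by root-to-tip branch
lengths, and with equal T the contrast reduces to a ratio of
(bias-corrected) areas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

from invadegeo.hulls import AreaComparison

DIVERGENCE_KINDS = ("absolute_time", "branch_length_proxy")


@dataclass
class InvasivenessIndex:
    area: float            # A, square degrees
    divergence: float      # T, time units or substitutions/site
    index: float           # A / T
    divergence_kind: str

    def __post_init__(self) -> None:
        if self.divergence_kind not in DIVERGENCE_KINDS:
            raise ValueError(f"unknown divergence kind {self.divergence_kind!r}")


def invasiveness_index(
    area: float, divergence: float, kind: str = "absolute_time"
) -> InvasivenessIndex:
    """I_inv = area / divergence; divergence must be positive."""
    if divergence <= 0:
        raise ValueError("divergence must be > 0 (index undefined)")
    if area < 0:
        raise ValueError("area must be non-negative")
    return InvasivenessIndex(
        area=area, divergence=divergence, index=area / divergence,
        divergence_kind=kind,
    )


@dataclass
class SisterContrast:
    focal: InvasivenessIndex
    reference: InvasivenessIndex
    ratio: float  # focal.index / reference.index


def sister_invasiveness(
    comparison: AreaComparison,
    divergence_focal: float,
    divergence_reference: float,
    kind: str = "branch_length_proxy",
    raw_focal_area: Optional[float] = None,
) -> SisterContrast:
    """Invasiveness indices for a sister pair and their contrast ratio.

    The focal area defaults to the subsample-corrected mean (the fair,
    equal-n estimate from the comparison); passing ``raw_focal_area``
    substitutes the full-sample hull area with a warning, since raw
    areas are biased by sample size.  With equal divergence the ratio
    reduces to the area ratio.
    """
    if raw_focal_area is None:
        focal_area = comparison.focal.mean_area
    else:
        warnings.warn("using raw (sample-size-biased) focal area")
        focal_area = raw_focal_area
    focal = invasiveness_index(focal_area, divergence_focal, kind)
    reference = invasiveness_index(comparison.reference_area, divergence_reference, kind)
    if reference.index == 0:
        raise ValueError("reference index is zero; ratio undefined")
    return SisterContrast(focal=focal, reference=reference,
                          ratio=focal.index / reference.index)


def mean_root_to_tip(tree, clade_tips: Optional[set[str]] = None) -> float:
    """Mean root-to-tip branch-length sum over (a clade's) tips.

    Under a roughly constant substitution rate the two sister clades'
    sums are nearly equal; averaging within each clade symmetrizes the
    remaining noise.  Accepts a GeoTree or a dendropy Tree.
    """
    dtree = getattr(tree, "tree", tree)
    total, n = 0.0, 0
    for leaf in dtree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon else None
        if clade_tips is not None and label not in clade_tips:
            continue
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        total += d
        n += 1
    if n == 0:
        raise ValueError("no matching tips in tree")
    return total / n
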