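"""Family-clade extraction and subfamily partition from dual supports.

Internal branches carry an (SH-aLRT, UFBoot) support pair.  A branch is
*strong* when UFBoot >= 95 and SH-aLRT >= 85, *medium* when (not
strong and) UFBoot >= 75 and SH-aLRT >= 65, else *weak*; a missing
value fails its comparison.  The UFBoot-only medium variant (no SH-aLRT
clause) is available via ``medium_ufboot_only`` because both
formulations are in circulation.

The family is the largest clade, at or above a minimum support class,
that contains all designated reference leaves (the PfuPif / MgaBMSP
stand-ins).  Subfamilies are the maximal supported proper sub-clades of
the family, taken top-down so a supported clade nested inside a chosen
one is absorbed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

import dendropy

from .io_formats import SupportTree


class SupportClass(enum.IntEnum):
    """Ordered nodal support classes (weak < medium < strong)."""

    weak = 0
    medium = 1
    strong = 2


STRONG_UFBOOT = 95.0
STRONG_ALRT = 85.0
MEDIUM_UFBOOT = 75.0
MEDIUM_ALRT = 65.0


def classify_support(alrt: Optional[float], ufboot: Optional[float],
                     medium_ufboot_only: bool = False) -> SupportClass:
    """Classify an (SH-aLRT, UFBoot) pair; missing values fail comparisons."""
    for v, name in ((alrt, "alrt"), (ufboot, "ufboot")):
        if v is not None and not (0.0 <= v <= 100.0):
            raise ValueError(f"{name} support {v} outside [0, 100]")

    def ge(value: Optional[float], cut: float) -> bool:
        return value is not None and value >= cut

    if ge(ufboot, STRONG_UFBOOT) and ge(alrt, STRONG_ALRT):
        return SupportClass.strong
    if ge(ufboot, MEDIUM_UFBOOT) and (medium_ufboot_only
                                      or ge(alrt, MEDIUM_ALRT)):
        return SupportClass.medium
    return SupportClass.weak


@dataclass
class Clade:
    """A clade: its subtending node, leaf set, and branch support class."""

    node: dendropy.Node
    leaf_names: frozenset[str]
    support_class: SupportClass
    supported: bool = True  # False when only the unsupported MRCA remains


@dataclass
class SubfamilyPartition:
    """Supported subfamilies of the family clade plus unassigned leaves."""

    family_leaves: frozenset[str]
    subfamilies: list[tuple[str, frozenset[str], SupportClass]]
    unassigned: frozenset[str]


def _node_class(node: dendropy.Node,
                medium_ufboot_only: bool = False) -> SupportClass:
    if node.parent_node is None:
        # The root has no subtending branch, hence no branch support:
        # every threshold comparison fails (conservative).
        return SupportClass.weak
    return classify_support(node.alrt, node.ufboot, medium_ufboot_only)


def _leaf_names(node: dendropy.Node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def find_family_clade(st: SupportTree, references: set[str],
                      min_class: SupportClass = SupportClass.strong,
                      medium_ufboot_only: bool = False) -> Clade:
    """Largest supported clade containing every reference leaf.

    Among clades whose branch class is at least ``min_class`` and whose
    leaves include all references, the one with most leaves wins; among
    equally large ones the one closest to the root.  If none qualifies,
    the references' MRCA is returned flagged unsupported.
    """
    refs = set(references)
    if not refs:
        raise ValueError("need at least one reference leaf")
    all_leaves = set(lf.taxon.label for lf in st.tree.leaf_node_iter())
    missing = refs - all_leaves
    if missing:
        raise ValueError(f"reference leaves absent from tree: "
                         f"{sorted(missing)}")

    best: Optional[tuple[int, int, dendropy.Node, frozenset[str],
                         SupportClass]] = None
    for depth, node in _nodes_with_depth(st.tree):
        if node.is_leaf():
            continue
        leaves = _leaf_names(node)
        if not refs <= leaves:
            continue
        cls = _node_class(node, medium_ufboot_only)
        if cls < min_class:
            continue
        key = (len(leaves), -depth)  # larger, then closer to root
        if best is None or key > (best[0], -best[1]):
            best = (len(leaves), depth, node, leaves, cls)
    if best is not None:
        _, _, node, leaves, cls = best
        return Clade(node=node, leaf_names=leaves, support_class=cls,
                     supported=True)

    mrca = st.tree.mrca(taxon_labels=sorted(refs))
    return Clade(node=mrca, leaf_names=_leaf_names(mrca),
                 support_class=_node_class(mrca, medium_ufboot_only),
                 supported=False)


def _nodes_with_depth(tree: dendropy.Tree):
    stack = [(0, tree.seed_node)]
    while stack:
        depth, node = stack.pop()
        yield depth, node
        for ch in node.child_nodes():
            stack.append((depth + 1, ch))


def partition_subfamilies(st: SupportTree, family: Clade,
                          min_class: SupportClass = SupportClass.medium,
                          medium_ufboot_only: bool = False,
                          ) -> SubfamilyPartition:
    """Top-down maximal supported sub-clades of the family clade.

    Descending from the family node, the first proper sub-clade on each
    path whose branch class is at least ``min_class`` and which has at
    least two leaves becomes a subfamily; everything nested inside it is
    absorbed.  Leaves on no such clade are unassigned.  Subfamilies are
    ordered (and named sf1, sf2, ...) by their smallest leaf name.
    """
    fam_leaves = family.leaf_names
    if len(fam_leaves) < 2:
        raise ValueError("family clade has fewer than 2 leaves")

    chosen: list[tuple[frozenset[str], SupportClass]] = []

    def descend(node: dendropy.Node, is_family_root: bool) -> None:
        if not is_family_root and not node.is_leaf():
            cls = _node_class(node, medium_ufboot_only)
            leaves = _leaf_names(node)
            if cls >= min_class and len(leaves) >= 2:
                chosen.append((leaves, cls))
                return
        for ch in node.child_nodes():
            if not ch.is_leaf():
                descend(ch, False)

    descend(family.node, True)
    chosen.sort(key=lambda t: min(t[0]))
    subfamilies = [(f"sf{i + 1}", leaves, cls)
                   for i, (leaves, cls) in enumerate(chosen)]
    assigned = frozenset().union(*(l for _, l, _ in subfamilies)) \
        if subfamilies else frozenset()
    return SubfamilyPartition(family_leaves=fam_leaves,
                              subfamilies=subfamilies,
                              unassigned=fam_leaves - assigned)
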