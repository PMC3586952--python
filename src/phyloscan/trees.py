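"""Shared tree utilities on top of dendropy: Newick I/O, clade queries,
rooting, surgery (detach/attach) and topology comparison.

Conventions used throughout the package:

* leaf taxon labels carry gene ids (gene trees) or species ids (species trees);
* internal ``node.label`` strings carry branch supports in [0, 1];
* species ids never contain ``_`` so that gene ids of the form
  ``<species>_<n>`` can be mapped back to species unambiguously.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import dendropy


# ----------------------------------------------------------------------- I/O

def parse_newick(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = True
    return tree


def read_newick(path: str | Path) -> dendropy.Tree:
    return parse_newick(Path(path).read_text())


def to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True).strip()


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(to_newick(tree) + "\n")


# ------------------------------------------------------------- leaf queries

def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def node_leafset(node: dendropy.Node) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in node.leaf_iter())


def find_leaf(tree: dendropy.Tree, label: str) -> dendropy.Node:
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label == label:
            return leaf
    raise KeyError(f"leaf {label!r} not in tree")


def find_clade(tree: dendropy.Tree, labels: Iterable[str]) -> dendropy.Node | None:
    """Node whose leaf set equals ``labels`` exactly, or None."""
    want = frozenset(labels)
    for node in tree.preorder_node_iter():
        if node_leafset(node) == want:
            return node
    return None


def is_monophyletic(tree: dendropy.Tree, labels: Iterable[str]) -> bool:
    return find_clade(tree, labels) is not None


def species_of(gene_id: str) -> str:
    """Species id from a ``<species>_<n>`` gene id."""
    return gene_id.split("_", 1)[0]


# ----------------------------------------------------------------- supports

def node_support(node: dendropy.Node) -> float | None:
    if node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


def set_all_supports(tree: dendropy.Tree, value: float) -> None:
    for node in tree.preorder_internal_node_iter():
        node.label = f"{value:g}"


# ------------------------------------------------------------------ rooting

def reroot_on_leaf_edge(tree: dendropy.Tree, leaf_label: str,
                        fraction: float = 0.5) -> dendropy.Tree:
    """Re-root ``tree`` in place on the terminal branch of ``leaf_label``."""
    leaf = find_leaf(tree, leaf_label)
    edge = leaf.edge
    if edge.tail_node is None:  # already the root's edge
        return tree
    length = edge.length if edge.length is not None else 0.0
    tree.reroot_at_edge(edge, length1=length * (1 - fraction),
                        length2=length * fraction)
    tree.is_rooted = True
    return tree


# ------------------------------------------------------------------ surgery

def detach_clade(tree: dendropy.Tree, node: dendropy.Node) -> dendropy.Node:
    """Remove ``node``'s subtree from ``tree``, suppressing the unifurcation
    left behind; returns the detached subtree root (its edge length is kept)."""
    parent = node.parent_node
    if parent is None:
        raise ValueError("cannot detach the root")
    parent.remove_child(node)
    _suppress_unifurcation(tree, parent)
    return node


def _suppress_unifurcation(tree: dendropy.Tree, node: dendropy.Node) -> None:
    if len(node.child_nodes()) != 1:
        return
    child = node.child_nodes()[0]
    grand = node.parent_node
    if grand is None:
        # node is root with single child: make the child the new root
        node.remove_child(child)
        child.parent_node = None
        tree.seed_node = child
        child.edge.length = None
    else:
        extra = node.edge.length or 0.0
        grand.remove_child(node)
        grand.add_child(child)
        child.edge.length = (child.edge.length or 0.0) + extra


def attach_sister(tree: dendropy.Tree, target: dendropy.Node,
                  subtree: dendropy.Node, stem_length: float = 0.1,
                  split: float = 0.5) -> None:
    """Graft ``subtree`` as the sister of ``target`` by splitting the edge
    above ``target``; ``subtree`` keeps its own edge length plus ``stem_length``
    if it has none."""
    parent = target.parent_node
    if parent is None:
        # attach at the root: new root with children (old root, subtree)
        new_root = dendropy.Node()
        old = tree.seed_node
        new_root.add_child(old)
        old.edge.length = stem_length
        new_root.add_child(subtree)
        tree.seed_node = new_root
    else:
        length = target.edge.length if target.edge.length is not None else 0.0
        joint = dendropy.Node()
        parent.remove_child(target)
        parent.add_child(joint)
        joint.edge.length = length * (1 - split)
        joint.add_child(target)
        target.edge.length = length * split
        joint.add_child(subtree)
    if subtree.edge.length is None:
        subtree.edge.length = stem_length
    tree.update_taxon_namespace()


# ------------------------------------------------------------- comparisons

def topology_key(tree: dendropy.Tree) -> str:
    """Canonical rooted-topology string (child order independent, no lengths)."""

    def render(node: dendropy.Node) -> str:
        if node.is_leaf():
            return node.taxon.label
        return "(" + ",".join(sorted(render(c) for c in node.child_nodes())) + ")"

    return render(tree.seed_node)


def unrooted_splits(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial splits of the unrooted topology, each normalized to the
    side not containing the alphabetically first leaf."""
    all_leaves = frozenset(leaf_labels(tree))
    anchor = min(all_leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_internal_node_iter():
        side = node_leafset(node)
        if anchor in side:
            side = all_leaves - side
        if 1 < len(side) < len(all_leaves) - 1:
            splits.add(side)
    return splits


def rf_distance_unrooted(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson-Foulds distance on unrooted topologies (shared leaf set)."""
    if frozenset(leaf_labels(t1)) != frozenset(leaf_labels(t2)):
        raise ValueError("trees must share an identical leaf set")
    s1, s2 = unrooted_splits(t1), unrooted_splits(t2)
    return len(s1 ^ s2)


def leaf_path_lengths(tree: dendropy.Tree) -> dict[str, dict[str, float]]:
    """All pairwise leaf-to-leaf path lengths (sum of branch lengths)."""
    dist: dict[dendropy.Node, dict[str, float]] = {}
    out: dict[str, dict[str, float]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            dist[node] = {node.taxon.label: 0.0}
            out.setdefault(node.taxon.label, {})
        else:
            children = node.child_nodes()
            merged: dict[str, float] = {}
            for i, ci in enumerate(children):
                di = dist[ci]
                li = ci.edge.length or 0.0
                for cj in children[i + 1:]:
                    dj = dist[cj]
                    lj = cj.edge.length or 0.0
                    for a, da in di.items():
                        for b, db in dj.items():
                            d = da + li + db + lj
                            out[a][b] = d
                            out[b][a] = d
            for ci in children:
                li = ci.edge.length or 0.0
                for a, da in dist[ci].items():
                    merged[a] = da + li
                del dist[ci]
            dist[node] = merged
    return out
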