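"""Birth-death gene-family evolution inside a known species tree.

One gene lineage enters the species-tree root; along every species-tree branch
each lineage experiences duplications and losses as a Poisson process with
per-branch rates (branches are unit time for event counts; physical event
positions scale with the branch length so gene-tree branch lengths remain in
expected-substitution units).  Every internal node of the resulting gene tree
carries the planted ground-truth label ``node.planted_event`` ("duplication"
or "speciation"); the tree carries ``tree.planted_duplications``.
"""

from __future__ import annotations

import dendropy
import numpy as np

from ..trees import set_all_supports


def simulate_gene_trees(species_tree: dendropy.Tree, n_trees: int,
                        dup_rate: float, loss_rate: float, seed: int = 0,
                        ) -> list[dendropy.Tree]:
    """Simulate ``n_trees`` gene trees; leaf names are ``<species>_<k>``.

    Trees are conditioned on having at least two surviving genes (extinct or
    single-gene outcomes are redrawn).  All internal support labels are set to
    1.0; downstream metadata samplers may overwrite them.
    """
    if dup_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    trees = []
    for _ in range(n_trees):
        while True:
            tree = _simulate_one(species_tree, dup_rate, loss_rate, rng)
            if tree is not None and len(tree.leaf_nodes()) >= 2:
                break
        set_all_supports(tree, 1.0)
        trees.append(tree)
    return trees


def _simulate_one(species_tree: dendropy.Tree, dup_rate: float,
                  loss_rate: float, rng: np.random.Generator,
                  ) -> dendropy.Tree | None:
    counters: dict[str, int] = {}
    root = _speciate(species_tree.seed_node, dup_rate, loss_rate, rng, counters)
    if root is None:
        return None
    root.edge.length = None
    tree = dendropy.Tree(seed_node=root)
    tree.is_rooted = True
    ns = tree.taxon_namespace
    n_dup = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.taxon = ns.new_taxon(label=node.label)
            node.label = None
        elif getattr(node, "planted_event", None) == "duplication":
            n_dup += 1
    tree.planted_duplications = n_dup
    return tree


def _speciate(sp_node: dendropy.Node, dup: float, loss: float,
              rng: np.random.Generator, counters: dict[str, int],
              ) -> dendropy.Node | None:
    """Gene lineage sitting exactly at ``sp_node``; returns subtree or None.

    The returned node's ``edge.length`` is 0 and is extended by the caller."""
    if sp_node.is_leaf():
        species = sp_node.taxon.label
        counters[species] = counters.get(species, 0) + 1
        leaf = dendropy.Node()
        leaf.label = f"{species}_{counters[species]}"
        leaf.edge.length = 0.0
        return leaf
    children = [_descend(child, 0.0, dup, loss, rng, counters)
                for child in sp_node.child_nodes()]
    alive = [c for c in children if c is not None]
    if not alive:
        return None
    if len(alive) == 1:
        return alive[0]
    node = dendropy.Node()
    node.planted_event = "speciation"
    node.edge.length = 0.0
    for c in alive:
        node.add_child(c)
    return node


def _descend(sp_node: dendropy.Node, frac: float, dup: float, loss: float,
             rng: np.random.Generator, counters: dict[str, int],
             ) -> dendropy.Node | None:
    """Gene lineage entering the branch above ``sp_node`` at fractional
    position ``frac`` (0 = top).  Returns the surviving subtree whose edge
    length covers the distance from the entry point, or None if extinct."""
    branch_len = sp_node.edge.length or 0.0
    total = dup + loss
    if total > 0:
        wait = rng.exponential(1.0 / total)
        if wait < 1.0 - frac:
            if rng.random() < loss / total:
                return None
            pos = frac + wait
            left = _descend(sp_node, pos, dup, loss, rng, counters)
            right = _descend(sp_node, pos, dup, loss, rng, counters)
            step = wait * branch_len
            if left is None and right is None:
                return None
            if left is None or right is None:
                survivor = left if right is None else right
                survivor.edge.length += step
                return survivor
            node = dendropy.Node()
            node.planted_event = "duplication"
            node.edge.length = step
            node.add_child(left)
            node.add_child(right)
            return node
    sub = _speciate(sp_node, dup, loss, rng, counters)
    if sub is not None:
        sub.edge.length += (1.0 - frac) * branch_len
    return sub
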