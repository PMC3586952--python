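"""Gene-tree / species-tree reconciliation by LCA mapping and search for the
species tree minimizing the total number of implied duplications.

Each gene-tree leaf maps to its species; each internal node maps to the last
common ancestor (in the species tree) of its children's mappings; a node is a
duplication iff it maps to the same species-tree node as at least one of its
children.  The supertree objective is the sum of duplication counts over all
gene trees; losses are not counted.

The search enumerates all rooted topologies exhaustively (practical up to 8
species) or hill-climbs with nearest-neighbor interchanges from random starts.
Scoring is vectorized: gene trees are encoded once as per-node species
bitmasks, and each candidate species topology reduces to a lookup table from
bitmask to LCA node id.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np

from .trees import parse_newick, species_of

TupleTree = tuple | int  # nested tuples of species indices


@dataclass
class Reconciliation:
    """LCA mapping of one gene tree into one species tree."""
    node_map: dict[dendropy.Node, dendropy.Node]
    duplication_count: int
    duplication_nodes: list[dendropy.Node]


# ------------------------------------------------------------- LCA mapping

def count_duplications(gene_tree: dendropy.Tree, species_tree: dendropy.Tree,
                       species_map: dict[str, str] | None = None,
                       ) -> Reconciliation:
    """Standard LCA reconciliation of a rooted gene tree.

    ``species_map`` maps gene ids to species; by default species are parsed
    from ``<species>_<n>`` leaf names.  Unknown species raise KeyError.
    """
    sp_nodes: dict[str, dendropy.Node] = {}
    depth: dict[dendropy.Node, int] = {}
    parent: dict[dendropy.Node, dendropy.Node | None] = {}
    for node in species_tree.preorder_node_iter():
        parent[node] = node.parent_node
        depth[node] = 0 if node.parent_node is None else depth[node.parent_node] + 1
        if node.is_leaf():
            sp_nodes[node.taxon.label] = node

    def lca(a: dendropy.Node, b: dendropy.Node) -> dendropy.Node:
        while a is not b:
            if depth[a] < depth[b]:
                b = parent[b]
            else:
                a = parent[a]
        return a

    node_map: dict[dendropy.Node, dendropy.Node] = {}
    dup_nodes: list[dendropy.Node] = []
    for node in gene_tree.postorder_node_iter():
        if node.is_leaf():
            gene = node.taxon.label
            species = species_map[gene] if species_map else species_of(gene)
            if species not in sp_nodes:
                raise KeyError(f"species {species!r} not in species tree")
            node_map[node] = sp_nodes[species]
        else:
            children = node.child_nodes()
            mapping = node_map[children[0]]
            for child in children[1:]:
                mapping = lca(mapping, node_map[child])
            node_map[node] = mapping
            if any(node_map[c] is mapping for c in children):
                dup_nodes.append(node)
    return Reconciliation(node_map, len(dup_nodes), dup_nodes)


def total_duplications(gene_trees: Sequence[dendropy.Tree],
                       species_tree: dendropy.Tree,
                       species_map: dict[str, str] | None = None) -> int:
    return sum(count_duplications(t, species_tree, species_map)
               .duplication_count for t in gene_trees)


# -------------------------------------------------- vectorized encoding

def _encode_gene_trees(gene_trees: Sequence[dendropy.Tree],
                       species_index: dict[str, int],
                       species_map: dict[str, str] | None) -> np.ndarray:
    """(n_internal_nodes, 3) array of (node, child1, child2) species bitmasks
    over all gene trees; polytomy children beyond two are folded in pairwise
    (LCA mapping and the duplication test only need mask containment)."""
    rows: list[tuple[int, int, int]] = []
    for tree in gene_trees:
        masks: dict[dendropy.Node, int] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                gene = node.taxon.label
                sp = species_map[gene] if species_map else species_of(gene)
                masks[node] = 1 << species_index[sp]
            else:
                children = node.child_nodes()
                mask = 0
                for c in children:
                    mask |= masks[c]
                masks[node] = mask
                acc = masks[children[0]]
                for c in children[1:]:
                    rows.append((acc | masks[c], acc, masks[c]))
                    acc |= masks[c]
    return np.array(rows, dtype=np.int64)


def _topology_masks(tree: TupleTree) -> list[tuple[int, int]]:
    """Postorder list of (node mask, popcount) for a tuple topology."""
    out: list[tuple[int, int]] = []

    def walk(node: TupleTree) -> int:
        if isinstance(node, int):
            mask = 1 << node
        else:
            mask = walk(node[0]) | walk(node[1])
        out.append((mask, bin(mask).count("1")))
        return mask

    walk(tree)
    return out


def _lca_table(tree: TupleTree, n_species: int) -> np.ndarray:
    """table[mask] = id of the smallest species-tree node containing mask."""
    nodes = _topology_masks(tree)
    node_masks = np.array([m for m, _ in nodes], dtype=np.int64)
    sizes = np.array([s for _, s in nodes])
    masks = np.arange(1, 2 ** n_species, dtype=np.int64)
    contains = (node_masks[:, None] & masks[None, :]) == masks[None, :]
    penalized = np.where(contains, sizes[:, None], 2 ** 30)
    table = np.empty(2 ** n_species, dtype=np.int32)
    table[1:] = np.argmin(penalized, axis=0)
    table[0] = 0
    return table


def _score(table: np.ndarray, enc: np.ndarray) -> int:
    node, c1, c2 = table[enc[:, 0]], table[enc[:, 1]], table[enc[:, 2]]
    return int(np.sum((node == c1) | (node == c2)))


# --------------------------------------------------- topology generation

def all_rooted_topologies(n_leaves: int):
    """Yield every rooted binary topology on leaves 0..n-1 as nested tuples
    ((2n-3)!! of them)."""
    def extend(tree: TupleTree, leaf: int):
        yield (tree, leaf)
        if isinstance(tree, tuple):
            for i in (0, 1):
                for sub in extend(tree[i], leaf):
                    yield (sub, tree[1 - i]) if i == 0 else (tree[0], sub)

    def build(k: int):
        if k == 1:
            yield 0
            return
        for tree in build(k - 1):
            yield from extend(tree, k - 1)

    yield from build(n_leaves)


def random_rooted_topology(n_leaves: int, rng: np.random.Generator) -> TupleTree:
    tips: list[TupleTree] = list(rng.permutation(n_leaves))
    tips = [int(t) for t in tips]
    while len(tips) > 1:
        i, j = sorted(rng.choice(len(tips), size=2, replace=False))
        merged = (tips[i], tips[j])
        tips = [t for k, t in enumerate(tips) if k not in (i, j)] + [merged]
    return tips[0]


def nni_neighbors(tree: TupleTree):
    """Distinct rooted-NNI rearrangements: for every internal edge, swap one
    grandchild with the sibling subtree."""
    seen = set()
    for cand in _nni_all(tree):
        key = _canonical(cand)
        if key != _canonical(tree) and key not in seen:
            seen.add(key)
            yield cand


def _nni_all(node: TupleTree):
    if isinstance(node, int):
        return
    left, right = node
    if isinstance(left, tuple):
        yield ((left[0], right), left[1])
        yield ((left[1], right), left[0])
    if isinstance(right, tuple):
        yield ((right[0], left), right[1])
        yield ((right[1], left), right[0])
    for sub in _nni_all(left):
        yield (sub, right)
    for sub in _nni_all(right):
        yield (left, sub)


def _canonical(tree: TupleTree) -> str:
    if isinstance(tree, int):
        return str(tree)
    a, b = _canonical(tree[0]), _canonical(tree[1])
    return f"({min(a, b)},{max(a, b)})"


def tuple_to_newick(tree: TupleTree, labels: Sequence[str]) -> str:
    def render(node: TupleTree) -> str:
        if isinstance(node, int):
            return labels[node]
        return f"({render(node[0])},{render(node[1])})"

    return render(tree) + ";"


# ----------------------------------------------------------------- search

def search_min_dup_supertree(gene_trees: Sequence[dendropy.Tree],
                             strategy: str = "exhaustive",
                             seed: int = 0, restarts: int = 50,
                             species_map: dict[str, str] | None = None,
                             ) -> tuple[dendropy.Tree, int]:
    """Species tree minimizing total duplications over ``gene_trees``.

    ``exhaustive`` guarantees the global optimum (ties broken by the
    lexicographically smallest canonical Newick) and refuses > 8 species;
    ``nni_hillclimb`` restarts ``restarts`` times from random topologies.
    """
    if not gene_trees:
        raise ValueError("no gene trees supplied")
    species = sorted({
        (species_map[leaf.taxon.label] if species_map
         else species_of(leaf.taxon.label))
        for tree in gene_trees for leaf in tree.leaf_node_iter()})
    n = len(species)
    index = {s: i for i, s in enumerate(species)}
    enc = _encode_gene_trees(gene_trees, index, species_map)

    def score(tree: TupleTree) -> int:
        return _score(_lca_table(tree, n), enc)

    if strategy == "exhaustive":
        if n > 8:
            raise ValueError("exhaustive search supports at most 8 species")
        best_tree, best_score, best_key = None, None, None
        for cand in all_rooted_topologies(n):
            s = score(cand)
            key = _canonical(cand)
            if best_score is None or s < best_score or (
                    s == best_score and key < best_key):
                best_tree, best_score, best_key = cand, s, key
    elif strategy == "nni_hillclimb":
        rng = np.random.default_rng(seed)
        best_tree, best_score, best_key = None, None, None
        for _ in range(restarts):
            current = random_rooted_topology(n, rng)
            current_score = score(current)
            improved = True
            while improved:
                improved = False
                for cand in nni_neighbors(current):
                    s = score(cand)
                    if s < current_score:
                        current, current_score = cand, s
                        improved = True
                        break
            key = _canonical(current)
            if best_score is None or current_score < best_score or (
                    current_score == best_score and key < best_key):
                best_tree, best_score, best_key = current, current_score, key
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    tree = parse_newick(tuple_to_newick(best_tree, species))
    return tree, int(best_score)
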