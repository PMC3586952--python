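"""Random and canonical species trees.

Random trees follow a Yule (successive random tip splitting) process with
exponentially distributed branch lengths.  :func:`fungal_species_tree` builds
the fixed deep-fungal study tree used throughout the examples: four outgroup
species, six fast-evolving microsporidia sister to all other fungi, and the
six classical fungal groups nested as chytrids -> zygos -> (basidios, (taphrino,
(saccharo, pezizo))), i.e. ascomycota and dikarya are clades.
"""

from __future__ import annotations

import dendropy
import numpy as np

from ..trees import parse_newick

#: Group labels in basal-to-derived order.
FUNGAL_GROUPS = ["Outgroup", "Microsporidia", "Chytridiomycotina",
                 "Zygomycotina", "Basidiomycotina", "Taphrinomycotina",
                 "Saccharomycotina", "Pezizomycotina"]

#: Single-letter scenario codes of the six non-focal fungal groups.
GROUP_LETTERS = {
    "Chytridiomycotina": "C",
    "Zygomycotina": "Z",
    "Basidiomycotina": "B",
    "Taphrinomycotina": "T",
    "Saccharomycotina": "S",
    "Pezizomycotina": "P",
}


def _yule_topology(labels: list[str], rng: np.random.Generator) -> dendropy.Node:
    """Rooted binary topology by successive random tip splitting."""
    tips = [dendropy.Node()]
    while len(tips) < len(labels):
        tip = tips[rng.integers(len(tips))]
        left, right = dendropy.Node(), dendropy.Node()
        tip.add_child(left)
        tip.add_child(right)
        tips.remove(tip)
        tips.extend([left, right])
    order = rng.permutation(len(labels))
    for tip, k in zip(tips, order):
        tip.label = labels[k]  # resolved to taxa by the caller
    return _root_of(tips[0])


def _root_of(node: dendropy.Node) -> dendropy.Node:
    while node.parent_node is not None:
        node = node.parent_node
    return node


def _finalize(root: dendropy.Node, rng: np.random.Generator,
              mean_branch_length: float) -> dendropy.Tree:
    tree = dendropy.Tree(seed_node=root)
    tree.is_rooted = True
    ns = tree.taxon_namespace
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = float(rng.exponential(mean_branch_length))
        if node.is_leaf():
            node.taxon = ns.new_taxon(label=node.label)
            node.label = None
    return tree


def generate_species_tree(n_species: int,
                          group_sizes: dict[str, int] | None = None,
                          seed: int = 0,
                          mean_branch_length: float = 0.1,
                          ) -> tuple[dendropy.Tree, dict[str, str]]:
    """Random rooted binary species tree plus a species -> group map.

    Without ``group_sizes`` all species are labelled ``s1..sN`` and assigned to
    a single group ``"Ingroup"``.  With ``group_sizes`` the backbone joining
    the groups is itself a Yule tree over group placeholders and each group
    expands into a Yule subtree, so every group is monophyletic by
    construction (as the downstream hypothesis machinery requires).
    """
    if n_species < 2:
        raise ValueError("need at least two species")
    rng = np.random.default_rng(seed)
    if group_sizes is None:
        labels = [f"s{i + 1}" for i in range(n_species)]
        root = _yule_topology(labels, rng)
        tree = _finalize(root, rng, mean_branch_length)
        return tree, {lab: "Ingroup" for lab in labels}

    if sum(group_sizes.values()) != n_species:
        raise ValueError("group sizes must sum to n_species")
    if any(v < 1 for v in group_sizes.values()):
        raise ValueError("every group needs at least one species")
    group_map: dict[str, str] = {}
    groups = list(group_sizes)
    backbone = (_yule_topology(groups, rng) if len(groups) > 1
                else dendropy.Node())
    if len(groups) == 1:
        backbone.label = groups[0]
    for tip in list(_iter_labelled_tips(backbone)):
        group = tip.label
        size = group_sizes[group]
        labels = [f"{group[:3].lower()}{i + 1}" for i in range(size)]
        for lab in labels:
            group_map[lab] = group
        if size == 1:
            tip.label = labels[0]
        else:
            sub = _yule_topology(labels, rng)
            tip.label = None
            for child in sub.child_nodes():
                tip.add_child(child)
    tree = _finalize(backbone, rng, mean_branch_length)
    return tree, group_map


def _iter_labelled_tips(root: dendropy.Node):
    for node in root.preorder_iter():
        if node.is_leaf():
            yield node


def fungal_species_tree(micro_stem: float = 0.6,
                        micro_terminal: float = 0.5,
                        outgroup_stem: float = 0.5,
                        outgroup_terminal: float = 0.6,
                        internal: float = 0.08,
                        terminal: float = 0.2,
                        ) -> tuple[dendropy.Tree, dict[str, str]]:
    """Fixed 22-species deep-fungal tree (4 outgroups, 6 microsporidia, 12
    fungi covering the six groups), with microsporidia sister to all other
    fungi.  Microsporidian and outgroup branches are longer than the rest to
    emulate their elevated divergence.
    """
    i, t = internal, terminal
    mt, ms = micro_terminal, micro_stem
    ot, os_ = outgroup_terminal, outgroup_stem
    mic = (f"(((mic1:{mt},mic2:{mt}):{i},(mic3:{mt},mic4:{mt}):{i}):{i},"
           f"(mic5:{mt},mic6:{mt}):{i}):{ms}")
    out = (f"((out1:{ot},out2:{ot}):{i},(out3:{ot},out4:{ot}):{i}):{os_}")
    asco = (f"(tap1:{t},((sac1:{t},sac2:{t}):{i},(pez1:{t},pez2:{t}):{i}):{i}):{i}"
            )
    dikarya = f"((bas1:{t},bas2:{t}):{i},{asco}):{i}"
    fungi = (f"((chy1:{t},chy2:{t}):{i},((zyg1:{t},(zyg2:{t},zyg3:{t}):{i}):{i},"
             f"{dikarya}):{i}):{i}")
    newick = f"({out},({mic},{fungi}):{i});"
    tree = parse_newick(newick)
    group_map = {}
    prefixes = {"out": "Outgroup", "mic": "Microsporidia",
                "chy": "Chytridiomycotina", "zyg": "Zygomycotina",
                "bas": "Basidiomycotina", "tap": "Taphrinomycotina",
                "sac": "Saccharomycotina", "pez": "Pezizomycotina"}
    for leaf in tree.leaf_node_iter():
        group_map[leaf.taxon.label] = prefixes[leaf.taxon.label[:3]]
    return tree, group_map
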