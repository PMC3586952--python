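"""Phylome scanning: rooting, duplication/speciation labelling by species
overlap, sister-group classification of a focal clade, quality filters and the
genome-wide scenario census.

Scenario vocabulary (sister-group content of the focal clade):

====================  =====================================================
label                 sister partition
====================  =====================================================
``C Z B T S P``       exactly one fungal group
``S+P``               saccharo + pezizo (their common ancestor)
``T+S+P``             base of ascomycota
``B+T+S+P``           base of dikarya
``B+T+S+P+Z``         everything after the chytrids
``A``                 all six groups (focal clade basal to all fungi)
``A-C+Z``             basal, but chytrids and zygos grouped together — also
                      reported when the sister partition is exactly C+Z
``other``             any other species content
====================  =====================================================

Records whose focal clade or outgroup is not monophyletic are tallied under
``non_monophyletic_focal`` / ``non_monophyletic_outgroup`` rather than forced
into a scenario.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import dendropy
import pandas as pd

from .trees import (find_clade, leaf_labels, node_leafset, node_support,
                    leaf_path_lengths, reroot_on_leaf_edge, species_of)

SIX_GROUPS = ("Chytridiomycotina", "Zygomycotina", "Basidiomycotina",
              "Taphrinomycotina", "Saccharomycotina", "Pezizomycotina")
_LETTER = {"Chytridiomycotina": "C", "Zygomycotina": "Z",
           "Basidiomycotina": "B", "Taphrinomycotina": "T",
           "Saccharomycotina": "S", "Pezizomycotina": "P"}
_COMPOSITE = {
    frozenset("SP"): "S+P",
    frozenset("TSP"): "T+S+P",
    frozenset("BTSP"): "B+T+S+P",
    frozenset("ZBTSP"): "B+T+S+P+Z",
    frozenset("CZ"): "A-C+Z",
}

SCENARIO_LABELS = ("A", "C", "Z", "B", "T", "S", "P", "S+P", "T+S+P",
                   "B+T+S+P", "B+T+S+P+Z", "A-C+Z", "other",
                   "non_monophyletic_outgroup", "non_monophyletic_focal")

FILTER_NAMES = ("all", "support", "consistency", "length", "all_filters")


@dataclass
class PhylomeRecord:
    """One gene tree plus the per-tree metadata the quality filters consume."""
    tree: dendropy.Tree
    alignment_length: int
    consistency_score: float
    seed_gene: str | None = None
    tree_id: str | None = None

    def __post_init__(self) -> None:
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be >= 1")


# ---------------------------------------------------------------- rooting

def root_by_most_distant_outgroup(tree: dendropy.Tree,
                                  outgroup_species: set[str],
                                  species_map: dict[str, str] | None = None,
                                  ) -> dendropy.Tree:
    """Root (in place) on the terminal branch of the outgroup leaf with the
    greatest mean branch-length distance to the in-group leaves; ties break on
    leaf name."""
    labels = leaf_labels(tree)
    sp = {lab: (species_map[lab] if species_map else species_of(lab))
          for lab in labels}
    og = [lab for lab in labels if sp[lab] in outgroup_species]
    ing = [lab for lab in labels if sp[lab] not in outgroup_species]
    if not og:
        raise ValueError("no outgroup leaf present")
    if not ing:
        raise ValueError("tree has only outgroup leaves")
    dist = leaf_path_lengths(tree)
    best = min(og, key=lambda lab: (-sum(dist[lab][i] for i in ing) / len(ing),
                                    lab))
    return reroot_on_leaf_edge(tree, best)


def check_outgroup_monophyly(tree: dendropy.Tree, outgroup_species: set[str],
                             species_map: dict[str, str] | None = None,
                             ) -> bool:
    """True iff the outgroup leaves form one clade of the rooted tree (either
    side of the root qualifies)."""
    labels = leaf_labels(tree)
    sp = {lab: (species_map[lab] if species_map else species_of(lab))
          for lab in labels}
    og = frozenset(lab for lab in labels if sp[lab] in outgroup_species)
    if not og:
        return False
    rest = frozenset(labels) - og
    if not rest:
        return True
    return (find_clade(tree, og) is not None
            or find_clade(tree, rest) is not None)


# ------------------------------------------------- species-overlap events

def resolve_polytomies(tree: dendropy.Tree) -> bool:
    """Arbitrarily bifurcate polytomies with zero-length branches; returns
    True when the tree had any."""
    had = False
    for node in list(tree.preorder_internal_node_iter()):
        while len(node.child_nodes()) > 2:
            had = True
            a, b = node.child_nodes()[:2]
            node.remove_child(a)
            node.remove_child(b)
            joint = dendropy.Node()
            joint.edge.length = 0.0
            joint.add_child(a)
            joint.add_child(b)
            node.insert_child(0, joint)
    return had


def label_events_species_overlap(tree: dendropy.Tree,
                                 species_map: dict[str, str] | None = None,
                                 threshold: float = 0.0,
                                 ) -> dict[dendropy.Node, str]:
    """Label every internal node duplication/speciation by species overlap.

    A node whose two child partitions share species (Jaccard overlap of the
    child species sets strictly above ``threshold``) is a duplication.  Labels
    are stored on ``node.event`` and returned as a dict."""
    resolve_polytomies(tree)
    events: dict[dendropy.Node, str] = {}
    species_below: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            lab = node.taxon.label
            species_below[node] = frozenset(
                {species_map[lab] if species_map else species_of(lab)})
        else:
            children = node.child_nodes()
            sets = [species_below[c] for c in children]
            merged = frozenset().union(*sets)
            species_below[node] = merged
            inter = sets[0]
            for s in sets[1:]:
                inter = inter & s
            score = len(inter) / len(merged)
            events[node] = "duplication" if score > threshold else "speciation"
            node.event = events[node]
    return events


# ------------------------------------------------------- classification

def classify_sister_group(tree: dendropy.Tree, focal_group: str,
                          group_map: dict[str, str],
                          species_map: dict[str, str] | None = None) -> str:
    """Scenario label for the sister partition of the focal clade.

    The tree must be rooted and contain at least one leaf from each of the six
    non-focal fungal groups (callers pre-filter; a missing group raises)."""
    labels = leaf_labels(tree)
    sp = {lab: (species_map[lab] if species_map else species_of(lab))
          for lab in labels}
    groups_present = {group_map[s] for s in sp.values()}
    missing = set(SIX_GROUPS) - groups_present
    if missing:
        raise ValueError(f"groups absent from tree: {sorted(missing)}")
    focal_leaves = frozenset(lab for lab in labels
                             if group_map[sp[lab]] == focal_group)
    if not focal_leaves:
        raise ValueError(f"no {focal_group} leaf in tree")
    focal_node = find_clade(tree, focal_leaves)
    if focal_node is None:
        return "non_monophyletic_focal"
    parent = focal_node.parent_node
    if parent is None:
        return "other"
    sisters = [c for c in parent.child_nodes() if c is not focal_node]
    sister_leaves = frozenset().union(*(node_leafset(s) for s in sisters))
    sister_groups = {group_map[sp[lab]] for lab in sister_leaves}
    if any(g not in _LETTER for g in sister_groups):
        return "other"
    letters = frozenset(_LETTER[g] for g in sister_groups)
    if len(letters) == 1:
        return next(iter(letters))
    if letters == frozenset("CZBTSP"):
        cz = frozenset(lab for lab in sister_leaves
                       if group_map[sp[lab]] in
                       ("Chytridiomycotina", "Zygomycotina"))
        if len(sisters) == 1 and find_clade2(sisters[0], cz):
            return "A-C+Z"
        return "A"
    return _COMPOSITE.get(letters, "other")


def find_clade2(node: dendropy.Node, labels: frozenset[str]) -> bool:
    """True when ``labels`` form a clade within the subtree of ``node``."""
    for nd in node.preorder_iter():
        if node_leafset(nd) == labels:
            return True
    return False


# ------------------------------------------------------------- filters

def apply_filters(record: PhylomeRecord, focal_group: str,
                  group_map: dict[str, str],
                  species_map: dict[str, str] | None = None,
                  support_min: float = 0.8, consistency_min: float = 0.75,
                  length_min: int = 500) -> dict[str, bool]:
    """Evaluate the three per-tree quality filters and their conjunction.

    All thresholds are strict: support *higher than* 0.8, consistency *over*
    0.75, alignment length *larger than* 500 columns.  The support examined is
    the one on the parent node joining the focal clade and its sister."""
    support_ok = False
    labels = leaf_labels(record.tree)
    sp = {lab: (species_map[lab] if species_map else species_of(lab))
          for lab in labels}
    focal_leaves = frozenset(lab for lab in labels
                             if group_map.get(sp[lab]) == focal_group)
    node = find_clade(record.tree, focal_leaves) if focal_leaves else None
    if node is not None and node.parent_node is not None:
        support = node_support(node.parent_node)
        if support is None and node.parent_node.parent_node is None:
            # root support is conventionally carried by its children
            support = node_support(node)
        support_ok = support is not None and support > support_min
    out = {
        "support": support_ok,
        "consistency": record.consistency_score > consistency_min,
        "length": record.alignment_length > length_min,
    }
    out["all_filters"] = all(out.values())
    return out


# --------------------------------------------------------------- census

@dataclass
class ScenarioTally:
    """Scenario counts overall and under each filter setting."""
    counts: dict[str, Counter] = field(
        default_factory=lambda: {f: Counter() for f in FILTER_NAMES})
    n_records: int = 0
    n_eligible: int = 0

    def fractions(self, filter_name: str = "all") -> dict[str, float]:
        counter = self.counts[filter_name]
        total = sum(counter.values())
        if total == 0:
            return {}
        return {lab: counter[lab] / total for lab in counter}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for filt in FILTER_NAMES:
            fracs = self.fractions(filt)
            for lab in SCENARIO_LABELS:
                if self.counts[filt][lab] or lab in fracs:
                    rows.append((lab, filt, self.counts[filt][lab],
                                 fracs.get(lab, 0.0)))
        return pd.DataFrame(rows, columns=["scenario", "filter", "count",
                                           "fraction"])


def census(records: list[PhylomeRecord], focal_group: str,
           group_map: dict[str, str],
           species_map: dict[str, str] | None = None,
           outgroup_group: str = "Outgroup",
           support_min: float = 0.8, consistency_min: float = 0.75,
           length_min: int = 500) -> ScenarioTally:
    """Classify every eligible record and tally scenario support, overall and
    under each quality filter.

    Eligible records contain at least one leaf of each of the six fungal
    groups plus the focal group and an outgroup leaf.  Records are rooted on
    the most distant outgroup leaf; those without a monophyletic outgroup or
    focal clade are tallied in their own categories.
    """
    if not records:
        raise ValueError("no records supplied")
    outgroup_species = {s for s, g in group_map.items() if g == outgroup_group}
    tally = ScenarioTally()
    tally.n_records = len(records)
    for record in records:
        labels = leaf_labels(record.tree)
        sp = {lab: (species_map[lab] if species_map else species_of(lab))
              for lab in labels}
        groups_present = {group_map[s] for s in sp.values() if s in group_map}
        needed = set(SIX_GROUPS) | {focal_group, outgroup_group}
        if not needed <= groups_present:
            continue
        tally.n_eligible += 1
        root_by_most_distant_outgroup(record.tree, outgroup_species,
                                      species_map)
        if not check_outgroup_monophyly(record.tree, outgroup_species,
                                        species_map):
            label = "non_monophyletic_outgroup"
        else:
            label_events_species_overlap(record.tree, species_map)
            label = classify_sister_group(record.tree, focal_group, group_map,
                                          species_map)
        flags = apply_filters(record, focal_group, group_map, species_map,
                              support_min, consistency_min, length_min)
        tally.counts["all"][label] += 1
        for name in ("support", "consistency", "length", "all_filters"):
            if flags[name]:
                tally.counts[name][label] += 1
    return tally
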