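"""Long-branch-attraction diagnostics.

Two tests probe whether a fast-evolving focal clade sits at its position for
signal or for artifact:

* **random replacement** — the focal rows of a concatenated alignment are
  replaced by random sequences many times; if the inference method places
  such signal-free sequences at the focal clade's position, that position is
  LBA-suspect.  The expected artifactual behaviour is attraction into the
  divergent outgroups instead.
* **parametric simulation** — sequences are simulated on a known tree with
  the focal clade planted at a rival position; if inference on the simulated
  data recovers the planted position rather than pulling the clade basal,
  the observed basal placement on real data is unlikely to be an LBA artifact.

A neighbor-joining builder on p or Poisson-corrected distances is bundled;
any callable mapping an alignment to a tree can be substituted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import dendropy
import numpy as np

from .alignment import AlignmentMatrix
from .alignops import concatenate
from .model import GAP
from .simgen.sequences import evolve_alignment, randomize_clade_sequences
from .treescan import classify_sister_group, root_by_most_distant_outgroup
from .trees import node_leafset

logger = logging.getLogger(__name__)

TreeBuilder = Callable[[AlignmentMatrix], dendropy.Tree]


# ------------------------------------------------------------ distances

def distance_matrix(alignment: AlignmentMatrix,
                    distance: str = "p_distance") -> np.ndarray:
    """Pairwise distances over columns where both rows are ungapped.

    ``p_distance`` is the mismatch proportion; ``poisson_corrected`` is
    -ln(1 - p); ``jc20`` is the 20-state equal-rates correction
    -(19/20) ln(1 - 20 p / 19), the transform under which distances are
    additive for the bundled substitution model.  Saturated proportions are
    capped just below the divergence ceiling to stay finite.  A pair with no
    comparable column raises."""
    if distance not in ("p_distance", "poisson_corrected", "jc20"):
        raise ValueError(f"unknown distance {distance!r}")
    data = alignment.data
    n = alignment.n_rows
    ungapped = data != GAP
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ungapped[i] & ungapped[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns between {alignment.names[i]} "
                    f"and {alignment.names[j]}")
            p = float((data[i, both] != data[j, both]).sum()) / m
            if distance == "poisson_corrected":
                p = min(p, 1.0 - 1e-6)
                d = -np.log(1.0 - p)
            elif distance == "jc20":
                p = min(p, 0.95 - 1e-6)
                d = -(19.0 / 20.0) * np.log(1.0 - 20.0 * p / 19.0)
            else:
                d = p
            out[i, j] = out[j, i] = d
    return out


# ------------------------------------------------------------------- NJ

def build_nj_tree(alignment: AlignmentMatrix,
                  distance: str = "p_distance") -> dendropy.Tree:
    """Neighbor joining on alignment distances; see
    :func:`nj_from_distance_matrix` for the agglomeration conventions."""
    if alignment.n_rows < 3:
        raise ValueError("need at least three sequences")
    D = distance_matrix(alignment, distance)
    return nj_from_distance_matrix(alignment.names, D)


def nj_from_distance_matrix(names: list[str],
                            D: np.ndarray) -> dendropy.Tree:
    """Classic neighbor joining; deterministic label-order tie-break;
    negative branch lengths are clamped to zero with the deficit moved to the
    sibling branch.  Returns the unrooted tree (trifurcating root node)."""
    if len(names) < 3:
        raise ValueError("need at least three sequences")
    nodes: dict[str, dendropy.Node] = {}
    for name in names:
        leaf = dendropy.Node()
        leaf.label = name
        nodes[name] = leaf
    dist: dict[frozenset[str], float] = {}
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            dist[frozenset((a, names[j]))] = D[i, j]
    active = sorted(nodes)  # cluster keys; key = min member label

    def d(a: str, b: str) -> float:
        return dist[frozenset((a, b))]

    while len(active) > 3:
        n = len(active)
        r = {a: sum(d(a, b) for b in active if b != a) for a in active}
        best = min(((a, b) for i, a in enumerate(active)
                    for b in active[i + 1:]),
                   key=lambda ab: ((n - 2) * d(*ab) - r[ab[0]] - r[ab[1]],
                                   ab))
        a, b = best
        va = 0.5 * d(a, b) + (r[a] - r[b]) / (2 * (n - 2))
        vb = d(a, b) - va
        va, vb = _clamp_pair(va, vb)
        joint = dendropy.Node()
        nodes[a].edge.length = va
        nodes[b].edge.length = vb
        joint.add_child(nodes[a])
        joint.add_child(nodes[b])
        key = min(a, b)
        for c in active:
            if c in (a, b):
                continue
            dist[frozenset((key, c))] = 0.5 * (d(a, c) + d(b, c) - d(a, b))
        active = sorted([c for c in active if c not in (a, b)] + [key])
        nodes[key] = joint

    root = dendropy.Node()
    if len(active) == 3:
        a, b, c = active
        va = 0.5 * (d(a, b) + d(a, c) - d(b, c))
        vb = 0.5 * (d(a, b) + d(b, c) - d(a, c))
        vc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
        for key, v in zip((a, b, c), (va, vb, vc)):
            nodes[key].edge.length = max(v, 0.0)
            root.add_child(nodes[key])
    else:  # exactly two clusters remain (n_rows == 3 never reaches here)
        a, b = active
        nodes[a].edge.length = nodes[b].edge.length = 0.5 * d(a, b)
        root.add_child(nodes[a])
        root.add_child(nodes[b])

    tree = dendropy.Tree(seed_node=root)
    tree.is_rooted = False
    ns = tree.taxon_namespace
    for node in tree.leaf_node_iter():
        node.taxon = ns.new_taxon(label=node.label)
        node.label = None
    return tree


def _clamp_pair(va: float, vb: float) -> tuple[float, float]:
    if va < 0:
        vb += va
        va = 0.0
    if vb < 0:
        va += vb
        vb = 0.0
    return max(va, 0.0), max(vb, 0.0)


# ------------------------------------------------- placement classification

@dataclass
class PlacementTally:
    """Counts of focal-clade attachment sites across replicas."""
    within_outgroups: int = 0
    at_focal_position: int = 0
    elsewhere: int = 0
    n_replicas: int = 0
    n_failed: int = 0
    labels: list[str] = field(default_factory=list)

    def fraction(self, category: str) -> float:
        if self.n_replicas == 0:
            return 0.0
        return getattr(self, category) / self.n_replicas


def classify_attachment(tree: dendropy.Tree, focal: frozenset[str],
                        outgroups: frozenset[str],
                        focal_position: frozenset[str]) -> str:
    """Locate the focal clade's attachment edge in the tree pruned of the
    focal leaves, and classify it.

    ``focal_position`` is one side of the planted attachment bipartition of
    the pruned tree.  Precedence: exact match of the planted edge, then any
    attachment whose one side consists solely of outgroup leaves (inside the
    outgroup subtree or on its stem), else ``elsewhere``; a non-monophyletic
    focal set is ``elsewhere``."""
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    pruned = leaves - focal
    sides = _attachment_sides(tree, focal, leaves)
    if sides is None:
        return "elsewhere"
    comp = pruned - focal_position
    if any(s == focal_position or s == comp for s in sides):
        return "at_focal_position"
    if any(s <= outgroups for s in sides):
        return "within_outgroups"
    return "elsewhere"


def _attachment_sides(tree, focal, leaves):
    """The two leaf-sets flanking the focal attachment point in the pruned
    tree, or None when the focal set is not a cluster of the unrooted tree."""
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = node_leafset(node)
        if below == focal:
            parent = node.parent_node
            rest = [c for c in parent.child_nodes() if c is not node]
            side1 = frozenset().union(*(node_leafset(c) for c in rest))
            side2 = leaves - focal - side1
            if side2:
                return (side1, side2)
            return tuple(node_leafset(c) for c in rest)
        if below == leaves - focal:
            return tuple(node_leafset(c) for c in node.child_nodes())
    return None


# ------------------------------------------------------ replacement test

def random_replacement_test(alignment: AlignmentMatrix,
                            focal_clade: set[str],
                            outgroup_species: set[str],
                            focal_position_spec: set[str],
                            n_replicas: int = 100,
                            tree_builder: TreeBuilder | None = None,
                            seed: int = 0,
                            mode: str = "composition_matched",
                            ) -> PlacementTally:
    """Replace focal rows by random sequences ``n_replicas`` times, rebuild
    the tree each time and tally where the random clade attaches."""
    focal = frozenset(focal_clade)
    outgroups = frozenset(outgroup_species)
    if focal & outgroups:
        raise ValueError("focal and outgroup sets overlap")
    if not focal or not outgroups:
        raise ValueError("focal and outgroup sets must be non-empty")
    if tree_builder is None:
        tree_builder = build_nj_tree
    rng = np.random.default_rng(seed)
    tally = PlacementTally()
    position = frozenset(focal_position_spec)
    for _ in range(n_replicas):
        rep_seed = int(rng.integers(2 ** 31))
        randomized = randomize_clade_sequences(alignment, focal, mode,
                                               rep_seed)
        try:
            tree = tree_builder(randomized)
        except Exception as exc:  # builder failures excluded from denominator
            tally.n_failed += 1
            logger.warning("replica failed: %s", exc)
            continue
        label = classify_attachment(tree, focal, outgroups, position)
        tally.labels.append(label)
        setattr(tally, label, getattr(tally, label) + 1)
        tally.n_replicas += 1
    return tally


# ------------------------------------------------------- parametric test

def parametric_lba_test(known_tree: dendropy.Tree,
                        focal_group: str,
                        group_map: dict[str, str],
                        n_families: int = 53,
                        family_length: int = 300,
                        gamma_shape: float = 1.0,
                        n_categories: int = 4,
                        tree_builder: TreeBuilder | None = None,
                        seed: int = 0,
                        outgroup_group: str = "Outgroup",
                        ) -> tuple[dendropy.Tree, str]:
    """Simulate ``n_families`` alignments on ``known_tree`` (the focal clade
    planted at a stated rival position), concatenate, re-infer the tree and
    report the focal clade's sister-group scenario label."""
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if tree_builder is None:
        tree_builder = build_nj_tree
    rng = np.random.default_rng(seed)
    species = [l.taxon.label for l in known_tree.leaf_node_iter()]
    families = {}
    for k in range(n_families):
        aln, _ = evolve_alignment(known_tree, family_length, gamma_shape,
                                  n_categories,
                                  seed=int(rng.integers(2 ** 31)))
        families[f"fam{k + 1:03d}"] = aln
    concat = concatenate(families, species)
    inferred = tree_builder(concat)
    inferred = inferred.clone(depth=1)
    outgroup_species = {s for s, g in group_map.items()
                       if g == outgroup_group}
    root_by_most_distant_outgroup(inferred, outgroup_species)
    label = classify_sister_group(inferred, focal_group, group_map)
    return inferred, label
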