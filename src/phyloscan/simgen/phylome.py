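"""Bundle simulated gene trees with sampled per-tree metadata (branch support,
alignment length, alignment consistency score) into phylome records."""

from __future__ import annotations

from typing import Callable, Sequence

import dendropy
import numpy as np

from ..treescan import PhylomeRecord
from ..trees import set_all_supports

Dist = float | int | Callable[[np.random.Generator], float]


def _draw(dist: Dist, rng: np.random.Generator) -> float:
    return float(dist(rng)) if callable(dist) else float(dist)


def make_phylome_records(gene_trees: Sequence[dendropy.Tree],
                         support_dist: Dist, consistency_dist: Dist,
                         length_dist: Dist, seed: int = 0,
                         ) -> list[PhylomeRecord]:
    """One record per tree; metadata drawn per tree from the given
    distributions (constants or callables taking the generator).

    The sampled support value is written onto every internal node of the tree,
    which makes it the support of the focal clade's parent node that the
    census filters read.
    """
    if not gene_trees:
        raise ValueError("no gene trees supplied")
    rng = np.random.default_rng(seed)
    records = []
    for k, tree in enumerate(gene_trees):
        support = _draw(support_dist, rng)
        consistency = _draw(consistency_dist, rng)
        length = int(round(_draw(length_dist, rng)))
        if not 0.0 <= support <= 1.0:
            raise ValueError("support must be in [0, 1]")
        if not 0.0 <= consistency <= 1.0:
            raise ValueError("consistency must be in [0, 1]")
        if length < 1:
            raise ValueError("alignment length must be >= 1")
        set_all_supports(tree, support)
        records.append(PhylomeRecord(tree=tree, alignment_length=length,
                                     consistency_score=consistency,
                                     tree_id=f"t{k + 1:05d}"))
    return records
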