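"""Sequence evolution along a tree under a reversible amino-acid CTMC with
discrete-gamma among-site rate variation, plus the random-sequence replacement
used by the long-branch-attraction diagnostics.  Simulated alignments are
gap-free; gaps only enter via explicit injection by callers.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from ..alignment import AlignmentMatrix
from ..model import AMINO_ACIDS, GAP, N_STATES, SubstitutionModel, \
    discrete_gamma_rates

_AA_ARRAY = np.array(list(AMINO_ACIDS))


@dataclass
class SiteRateTruth:
    """Planted per-column rates; categories are 1-based, 1 = slowest."""
    rates: np.ndarray
    categories: np.ndarray
    category_rates: np.ndarray


def evolve_alignment(tree: dendropy.Tree, n_columns: int,
                     gamma_shape: float = 1.0, n_categories: int = 16,
                     seed: int = 0, model: SubstitutionModel | None = None,
                     ) -> tuple[AlignmentMatrix, SiteRateTruth]:
    """Simulate an alignment of ``n_columns`` on ``tree`` (leaf-label rows)."""
    if n_columns < 1:
        raise ValueError("n_columns must be >= 1")
    if gamma_shape <= 0:
        raise ValueError("gamma shape must be positive")
    if model is None:
        model = SubstitutionModel.equal_exchange()
    rng = np.random.default_rng(seed)
    cat_rates = discrete_gamma_rates(gamma_shape, n_categories)
    categories = rng.integers(0, n_categories, size=n_columns)
    rates = cat_rates[categories]

    states: dict[int, np.ndarray] = {}
    root = tree.seed_node
    states[id(root)] = rng.choice(N_STATES, size=n_columns, p=model.freqs)
    names: list[str] = []
    rows: list[np.ndarray] = []
    for node in tree.preorder_node_iter():
        if node is root:
            pass
        else:
            parent_states = states[id(node.parent_node)]
            t = node.edge.length or 0.0
            child = parent_states.copy()
            if t > 0:
                for k in range(n_categories):
                    cols = np.nonzero(categories == k)[0]
                    if cols.size == 0:
                        continue
                    P = model.transition_matrix(t * cat_rates[k])
                    cum = np.cumsum(P, axis=1)
                    u = rng.random(cols.size)
                    child[cols] = (u[:, None] > cum[parent_states[cols]]
                                   ).sum(axis=1)
            states[id(node)] = child
        if node.is_leaf():
            names.append(node.taxon.label)
            rows.append(_AA_ARRAY[states[id(node)]])
    aln = AlignmentMatrix(names, np.array(rows))
    return aln, SiteRateTruth(rates, categories + 1, cat_rates)


def randomize_clade_sequences(alignment: AlignmentMatrix,
                              focal_species: set[str] | list[str],
                              mode: str = "composition_matched",
                              seed: int = 0) -> AlignmentMatrix:
    """Replace every focal row, column by column, with i.i.d. residues.

    ``composition_matched`` draws each replacement from that row's original
    non-gap residue frequencies; ``uniform`` draws uniformly over the 20 amino
    acids.  Gap positions are preserved; non-focal rows are untouched.
    """
    focal = set(focal_species)
    if not focal:
        raise ValueError("focal species set is empty")
    missing = focal - set(alignment.names)
    if missing:
        raise KeyError(f"focal species not in alignment: {sorted(missing)}")
    if mode not in ("composition_matched", "uniform"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    out = alignment.copy()
    for i, name in enumerate(out.names):
        if name not in focal:
            continue
        row = out.data[i]
        keep = row != GAP
        n = int(keep.sum())
        if n == 0:
            continue
        if mode == "uniform":
            probs = np.full(N_STATES, 1.0 / N_STATES)
        else:
            residues, counts = np.unique(row[keep], return_counts=True)
            probs = np.zeros(N_STATES)
            for res, cnt in zip(residues, counts):
                probs[AMINO_ACIDS.index(res)] = cnt
            probs /= probs.sum()
        row[keep] = _AA_ARRAY[rng.choice(N_STATES, size=n, p=probs)]
    return out
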