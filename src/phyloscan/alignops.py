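"""Concatenated-alignment construction and signal stratification.

Covers the concatenation workflow: choosing widespread single-copy families,
concatenating their alignments with gap fill, trimming uninformative columns,
computing per-site log-likelihoods under a discrete-gamma model (Felsenstein
pruning), assigning every column to one of 16 rate categories, removing the
fastest categories, partitioning columns by residue variability within a focal
clade, and recoding into a reduced amino-acid alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
from scipy.special import logsumexp

from .alignment import AlignmentMatrix
from .model import (AMINO_ACIDS, GAP, N_STATES, SubstitutionModel,
                    discrete_gamma_rates)

#: Default four-letter recoding (SR4-style groups by physicochemistry):
#: A/G/N/P/S/T -> a, C/H/W/Y -> c, D/E/K/Q/R -> d, F/I/L/M/V -> f.
DEFAULT_RECODING = {}
for _res, _sym in [("AGNPST", "a"), ("CHWY", "c"), ("DEKQR", "d"),
                   ("FILMV", "f")]:
    for _r in _res:
        DEFAULT_RECODING[_r] = _sym
DEFAULT_RECODING[GAP] = GAP


# ------------------------------------------------------ family selection

def select_single_copy_families(families: dict[str, dict[str, int]],
                                min_species: int) -> list[str]:
    """Families with at most one gene per species, present in at least
    ``min_species`` species; order of the input mapping is preserved."""
    out = []
    for family, counts in families.items():
        present = [s for s, c in counts.items() if c > 0]
        if all(counts[s] <= 1 for s in present) and len(present) >= min_species:
            out.append(family)
    return out


# --------------------------------------------------------- concatenation

def concatenate(alignments: dict[str, AlignmentMatrix],
                species_universe: list[str]) -> AlignmentMatrix:
    """Concatenate per-family alignments over ``species_universe`` rows.

    Species absent from a family get gap runs; every output column is labelled
    with its source family in ``partitions``."""
    if not alignments:
        raise ValueError("no alignments supplied")
    blocks, labels = [], []
    for family, aln in alignments.items():
        if len(set(aln.names)) != len(aln.names):
            raise ValueError(f"duplicate species rows in family {family}")
        block = np.full((len(species_universe), aln.n_sites), GAP, dtype="<U1")
        for i, name in enumerate(aln.names):
            if name in species_universe:
                block[species_universe.index(name)] = aln.data[i]
        blocks.append(block)
        labels.extend([family] * aln.n_sites)
    return AlignmentMatrix(list(species_universe), np.hstack(blocks),
                           np.array(labels, dtype=object))


def extract_partition(alignment: AlignmentMatrix, family: str,
                      drop_gap_only_rows: bool = False) -> AlignmentMatrix:
    """Columns of one source family (inverse of :func:`concatenate`)."""
    if alignment.partitions is None:
        raise ValueError("alignment has no partition annotations")
    sub = alignment.select_columns(alignment.partitions == family)
    if drop_gap_only_rows:
        keep = ~(sub.data == GAP).all(axis=1)
        sub = AlignmentMatrix([n for n, k in zip(sub.names, keep) if k],
                              sub.data[keep], sub.partitions)
    return sub


def partition_table(alignment: AlignmentMatrix) -> list[tuple[str, int, int]]:
    """(family, start, end) blocks, 1-based inclusive column coordinates."""
    if alignment.partitions is None:
        raise ValueError("alignment has no partition annotations")
    out: list[tuple[str, int, int]] = []
    for i, fam in enumerate(alignment.partitions, start=1):
        if out and out[-1][0] == fam and out[-1][2] == i - 1:
            out[-1] = (fam, out[-1][1], i)
        else:
            out.append((fam, i, i))
    return out


# ---------------------------------------------------------------- trimming

def trim_uninformative(alignment: AlignmentMatrix,
                       focal_clade: set[str] | list[str]) -> AlignmentMatrix:
    """Drop invariant columns (all non-gap residues identical) and columns
    gapped in every focal-clade row; survivor order is preserved."""
    focal_idx = [alignment.names.index(s) for s in focal_clade]
    if not focal_idx:
        raise ValueError("focal clade is empty")
    data = alignment.data
    gaps = data == GAP
    keep = np.ones(alignment.n_sites, dtype=bool)
    for j in range(alignment.n_sites):
        residues = set(data[~gaps[:, j], j])
        if len(residues) <= 1:
            keep[j] = False
        elif gaps[focal_idx, j].all():
            keep[j] = False
    return alignment.select_columns(keep)


# ------------------------------------------------------- site likelihoods

@dataclass
class SiteLikelihoods:
    """Per-site per-rate-category log-likelihoods on a fixed tree."""
    loglik: np.ndarray           # (n_sites, n_categories)
    category_rates: np.ndarray   # ascending, mean 1
    gamma_shape: float

    @property
    def site_loglik(self) -> np.ndarray:
        """Per-site log-likelihood with equal category priors."""
        n_cat = self.loglik.shape[1]
        return logsumexp(self.loglik, axis=1) - np.log(n_cat)


def compute_site_loglik(alignment: AlignmentMatrix, tree: dendropy.Tree,
                        model: SubstitutionModel | None = None,
                        gamma_shape: float = 1.0, n_categories: int = 16,
                        ) -> SiteLikelihoods:
    """Felsenstein pruning per column and rate category; gaps are missing
    data (conditional likelihood 1 over all states)."""
    if alignment.n_sites < 1:
        raise ValueError("alignment has no columns")
    if model is None:
        model = SubstitutionModel.equal_exchange()
    rates = discrete_gamma_rates(gamma_shape, n_categories)
    n_sites = alignment.n_sites

    # integer-encoded rows, -1 for gap/unknown
    codes = {}
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    for name, row in zip(alignment.names, alignment.data):
        codes[name] = np.array([aa_index.get(r, -1) for r in row])

    loglik = np.empty((n_sites, n_categories))
    for k, rate in enumerate(rates):
        partials: dict[int, np.ndarray] = {}
        scale = np.zeros(n_sites)
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                label = node.taxon.label
                if label not in codes:
                    raise KeyError(f"leaf {label!r} not in alignment")
                part = np.zeros((N_STATES, n_sites))
                code = codes[label]
                part[:, code < 0] = 1.0
                ok = code >= 0
                part[code[ok], np.nonzero(ok)[0]] = 1.0
            else:
                part = np.ones((N_STATES, n_sites))
                for child in node.child_nodes():
                    t = (child.edge.length or 0.0) * rate
                    P = model.transition_matrix(t)
                    part *= P @ partials.pop(id(child))
                top = part.max(axis=0)
                top[top == 0.0] = 1.0
                part /= top
                scale += np.log(top)
            partials[id(node)] = part
        root_part = partials[id(tree.seed_node)]
        loglik[:, k] = np.log(model.freqs @ root_part) + scale
    return SiteLikelihoods(loglik, rates, gamma_shape)


def estimate_gamma_shape(alignment: AlignmentMatrix, tree: dendropy.Tree,
                         model: SubstitutionModel | None = None,
                         n_categories: int = 16,
                         grid: np.ndarray | None = None) -> float:
    """Maximum-likelihood gamma shape over a 1-D grid (default 0.1..5)."""
    if grid is None:
        grid = np.geomspace(0.1, 5.0, 25)
    best_shape, best_ll = None, -np.inf
    for shape in grid:
        sl = compute_site_loglik(alignment, tree, model, shape, n_categories)
        ll = sl.site_loglik.sum()
        if ll > best_ll:
            best_shape, best_ll = float(shape), ll
    return best_shape


# ------------------------------------------------------ rate assignment

@dataclass
class SiteRateAssignment:
    """Per-column discrete-gamma category (1-based, 1 slowest) and posterior
    category probabilities under equal priors."""
    categories: np.ndarray       # (n_sites,) int, 1-based
    posteriors: np.ndarray       # (n_sites, n_categories)
    gamma_shape: float

    @property
    def n_categories(self) -> int:
        return self.posteriors.shape[1]


def assign_rate_categories(site_logliks: SiteLikelihoods) -> SiteRateAssignment:
    """Posterior category per column; ties resolve to the slower category."""
    lnl = site_logliks.loglik
    post = np.exp(lnl - logsumexp(lnl, axis=1, keepdims=True))
    categories = np.argmax(post, axis=1) + 1  # argmax takes first = slowest
    return SiteRateAssignment(categories, post, site_logliks.gamma_shape)


def remove_fastest_sites(alignment: AlignmentMatrix,
                         assignment: SiteRateAssignment,
                         k: int) -> AlignmentMatrix:
    """Drop columns assigned to the ``k`` fastest of the rate categories."""
    n_cat = assignment.n_categories
    if k >= n_cat:
        raise ValueError("k must be smaller than the number of categories")
    keep = assignment.categories <= n_cat - k
    return alignment.select_columns(keep)


# ------------------------------------------------- variability partition

def partition_by_clade_variability(alignment: AlignmentMatrix,
                                   focal_clade: set[str] | list[str],
                                   ) -> dict[int, AlignmentMatrix]:
    """Partition columns by the number of distinct non-gap residues among the
    focal-clade rows: 1 (<= 2 residues), 2 (= 3), 3 (= 4), 4 (>= 5); columns
    whose focal rows are all gaps are excluded."""
    focal_idx = [alignment.names.index(s) for s in focal_clade]
    if not focal_idx:
        raise ValueError("focal clade is empty")
    sub = alignment.data[focal_idx]
    buckets = {1: [], 2: [], 3: [], 4: []}
    for j in range(alignment.n_sites):
        residues = set(sub[:, j]) - {GAP}
        if not residues:
            continue
        n = len(residues)
        bucket = 1 if n <= 2 else 2 if n == 3 else 3 if n == 4 else 4
        buckets[bucket].append(j)
    return {b: alignment.select_columns(np.array(cols, dtype=int))
            for b, cols in buckets.items()}


# ---------------------------------------------------------------- recoding

def recode_alphabet(alignment: AlignmentMatrix,
                    mapping: dict[str, str] | None = None) -> AlignmentMatrix:
    """Symbol-wise recoding into a reduced alphabet; dimensions preserved.

    ``mapping`` must cover all 20 amino acids; the gap maps to itself unless
    remapped explicitly.  Unmapped residues in the data raise KeyError."""
    if mapping is None:
        mapping = DEFAULT_RECODING
    missing = set(AMINO_ACIDS) - set(mapping)
    if missing:
        raise ValueError(f"mapping misses residues: {sorted(missing)}")
    table = dict(mapping)
    table.setdefault(GAP, GAP)
    out = alignment.copy()
    symbols = np.unique(out.data)
    for sym in symbols:
        if sym not in table:
            raise KeyError(f"unmapped residue {sym!r}")
        out.data[alignment.data == sym] = table[sym]
    return out


def read_recoding_map(path: str | Path) -> dict[str, str]:
    """residue<TAB>symbol file -> mapping dict."""
    mapping = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        residue, symbol = line.split("\t")
        mapping[residue] = symbol
    return mapping
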