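"""Constrained alternative topologies and RELL-based topology tests.

Twelve alternative placements of a focal clade (each single fungal group, four
ancestral positions, basal, and basal-with-chytrids+zygos-grouped) are built
by pruning the focal clade and regrafting it; the clade's internal structure
is preserved across hypotheses.

Tests operate on a trees x sites matrix of per-site log-likelihoods and use
resampling of estimated log-likelihoods (RELL): AU (multiscale bootstrap with
probit regression), NP (smoothed bootstrap probability at scale 1), BP (raw
replicate-win fraction), PP (BIC-approximation posterior weights), KH and WKH
(signed one-sided comparison of each tree against the best of the others,
plain and standardized), SH and WSH (worst-case centering over all trees).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy.stats import norm

from .trees import (detach_clade, attach_sister, find_clade, leaf_labels,
                    to_newick, unrooted_splits)

HYPOTHESIS_LABELS = ("A", "C", "Z", "B", "T", "S", "P", "S+P", "T+S+P",
                     "B+T+S+P", "B+T+S+P+Z", "A-C+Z")

_GROUP_OF_LETTER = {"C": "Chytridiomycotina", "Z": "Zygomycotina",
                    "B": "Basidiomycotina", "T": "Taphrinomycotina",
                    "S": "Saccharomycotina", "P": "Pezizomycotina"}

TEST_NAMES = ("au", "np", "bp", "pp", "kh", "sh", "wkh", "wsh")

DEFAULT_AU_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 2))


# ----------------------------------------------------------- hypotheses

def _species_of_groups(group_map: dict[str, str], groups) -> frozenset[str]:
    wanted = set(groups)
    return frozenset(s for s, g in group_map.items() if g in wanted)


def generate_alternative_topologies(species_tree: dendropy.Tree,
                                    focal_group: str,
                                    group_map: dict[str, str],
                                    ) -> dict[str, dendropy.Tree]:
    """The 12 alternative placements of the focal clade, keyed by label.

    Requires every group, and each ancestral set the hypotheses name (S+P,
    ascomycota, dikarya, dikarya+zygos, all six), to be a clade in the input.
    """
    present = frozenset(leaf_labels(species_tree))
    targets: dict[str, frozenset[str]] = {}
    for letter, group in _GROUP_OF_LETTER.items():
        targets[letter] = _species_of_groups(group_map, [group]) & present
    targets["S+P"] = targets["S"] | targets["P"]
    targets["T+S+P"] = targets["T"] | targets["S+P"]
    targets["B+T+S+P"] = targets["B"] | targets["T+S+P"]
    targets["B+T+S+P+Z"] = targets["Z"] | targets["B+T+S+P"]
    targets["A"] = targets["C"] | targets["B+T+S+P+Z"]

    focal_species = _species_of_groups(group_map, [focal_group]) & present
    if not focal_species:
        raise ValueError(f"no {focal_group} species in tree")

    out: dict[str, dendropy.Tree] = {}
    for label in HYPOTHESIS_LABELS:
        tree = species_tree.clone(depth=1)
        focal_node = find_clade(tree, focal_species)
        if focal_node is None:
            raise ValueError(f"{focal_group} is not monophyletic")
        focal_sub = detach_clade(tree, focal_node)
        if label == "A-C+Z":
            c_node = find_clade(tree, targets["C"])
            if c_node is None:
                raise ValueError("Chytridiomycotina is not monophyletic")
            c_sub = detach_clade(tree, c_node)
            z_node = find_clade(tree, targets["Z"])
            if z_node is None:
                raise ValueError("Zygomycotina is not monophyletic")
            attach_sister(tree, z_node, c_sub)
            target = find_clade(tree, targets["A"])
        else:
            target = find_clade(tree, targets[label])
        if target is None:
            raise ValueError(f"hypothesis {label}: target set is not a clade")
        attach_sister(tree, target, focal_sub)
        out[label] = tree

    keys = {lab: frozenset(unrooted_splits(t)) for lab, t in out.items()}
    if len(set(keys.values())) != len(out):
        raise AssertionError("generated hypotheses are not all distinct")
    return out


# ------------------------------------------------------ site-lnL matrix

@dataclass
class SiteLnLMatrix:
    """Per-site log-likelihoods, one row per candidate tree."""
    tree_ids: list[str]
    lnl: np.ndarray  # (n_trees, n_sites)

    def __post_init__(self) -> None:
        self.lnl = np.asarray(self.lnl, dtype=float)
        if self.lnl.ndim != 2 or self.lnl.shape[0] != len(self.tree_ids):
            raise ValueError("one lnL row per tree required")
        if not np.all(np.isfinite(self.lnl)):
            raise ValueError("non-finite log-likelihoods")

    @property
    def n_sites(self) -> int:
        return self.lnl.shape[1]

    @property
    def n_trees(self) -> int:
        return self.lnl.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for tree_id, row in zip(self.tree_ids, self.lnl):
                fh.write(tree_id + "\t" + " ".join(f"{v:.10g}" for v in row)
                         + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SiteLnLMatrix":
        ids, rows = [], []
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            head, rest = line.split("\t", 1)
            ids.append(head)
            rows.append([float(x) for x in rest.split()])
        return cls(ids, np.array(rows))


def hypothesis_site_loglik(alignment, hypotheses: dict[str, dendropy.Tree],
                           model=None, gamma_shape: float = 1.0,
                           n_categories: int = 4) -> SiteLnLMatrix:
    """Convenience: per-site lnL of an alignment under each hypothesis tree
    using the bundled pruning engine (fixed branch lengths)."""
    from .alignops import compute_site_loglik
    rows, ids = [], []
    for label, tree in hypotheses.items():
        sl = compute_site_loglik(alignment, tree, model, gamma_shape,
                                 n_categories)
        ids.append(label)
        rows.append(sl.site_loglik)
    return SiteLnLMatrix(ids, np.vstack(rows))


# -------------------------------------------------------------- RELL core

def rell_resample(matrix: SiteLnLMatrix, n_reps: int, scale: float = 1.0,
                  seed: int = 0, rng: np.random.Generator | None = None,
                  ) -> np.ndarray:
    """RELL bootstrap: (n_reps, n_trees) totals of ceil(scale*n) sites drawn
    with replacement (implemented as multinomial column weights)."""
    if matrix.n_sites < 1:
        raise ValueError("empty matrix")
    if n_reps < 1 or scale <= 0:
        raise ValueError("n_reps must be >= 1 and scale > 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = matrix.n_sites
    m = int(np.ceil(scale * n))
    out = np.empty((n_reps, matrix.n_trees))
    chunk = max(1, int(2e7) // max(n, 1))
    probs = np.full(n, 1.0 / n)
    for start in range(0, n_reps, chunk):
        stop = min(start + chunk, n_reps)
        counts = rng.multinomial(m, probs, size=stop - start)
        out[start:stop] = counts @ matrix.lnl.T
    return out


# ------------------------------------------------------------- the tests

@dataclass
class TestReport:
    tree_ids: list[str]
    observed: np.ndarray                 # total lnL per tree
    best: str
    pvalues: dict[str, np.ndarray]       # test name -> per-tree p

    def frame(self, alpha: float = 0.05) -> pd.DataFrame:
        data = {"tree": self.tree_ids, "lnL": self.observed,
                "delta": self.observed.max() - self.observed}
        for test in TEST_NAMES:
            data[test] = self.pvalues[test]
        df = pd.DataFrame(data)
        df["best"] = [t == self.best for t in self.tree_ids]
        return df


def _multiscale_bp(matrix: SiteLnLMatrix, n_reps: int, scales,
                   rng: np.random.Generator) -> np.ndarray:
    """(n_scales, n_trees) replicate-win fractions."""
    bp = np.empty((len(scales), matrix.n_trees))
    for k, scale in enumerate(scales):
        totals = rell_resample(matrix, n_reps, scale, rng=rng)
        winners = np.argmax(totals, axis=1)
        bp[k] = np.bincount(winners, minlength=matrix.n_trees) / n_reps
    return bp


def _au_np_fit(bp: np.ndarray, scales, n_reps: int) -> tuple[float, float]:
    """Weighted probit regression of multiscale bootstrap probabilities;
    returns (p_au, p_np) for one tree."""
    scales = np.asarray(scales, dtype=float)
    if np.all(bp <= 0):
        return 0.0, 0.0
    if np.all(bp >= 1):
        return 1.0, 1.0
    eps = 1.0 / (2.0 * n_reps)
    bpc = np.clip(bp, eps, 1 - eps)
    # with sigma^2 = n/n' (scale r = n'/n): z(sigma) = d/sigma + c*sigma,
    # i.e. z = d*sqrt(r) + c/sqrt(r); p_AU = 1 - Phi(d - c), p_NP at sigma=1.
    z = norm.ppf(1.0 - bpc)
    srt = np.sqrt(scales)
    X = np.column_stack([srt, 1.0 / srt])
    w = n_reps * norm.pdf(z) ** 2 / (bpc * (1 - bpc))
    WX = X * w[:, None]
    beta, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ z, rcond=None)
    d, c = beta
    p_au = float(1.0 - norm.cdf(d - c))
    p_np = float(1.0 - norm.cdf(d + c))
    return p_au, p_np


def run_tests(matrix: SiteLnLMatrix, n_reps: int = 1000, seed: int = 0,
              scales=DEFAULT_AU_SCALES) -> TestReport:
    """All eight tests on a site-lnL matrix.

    KH/WKH compare each tree against the best of the remaining trees with a
    signed one-sided statistic, so the best tree's p exceeds 0.5 and a
    designated tree's p is uniform under the no-difference null; SH/WSH use
    worst-case centering and are never less conservative than KH/WKH on the
    shared replicates.  With a single tree all p-values are 1.
    """
    n_trees = matrix.n_trees
    observed = matrix.lnl.sum(axis=1)
    best_idx = int(np.argmax(observed))
    if n_trees == 1:
        pvalues = {t: np.ones(1) for t in TEST_NAMES}
        return TestReport(list(matrix.tree_ids), observed,
                          matrix.tree_ids[0], pvalues)

    rng = np.random.default_rng(seed)
    totals = rell_resample(matrix, n_reps, 1.0, rng=rng)   # (B, T)
    centered = totals - totals.mean(axis=0)

    # BP: raw replicate-win fractions at scale 1
    winners = np.argmax(totals, axis=1)
    bp = np.bincount(winners, minlength=n_trees) / n_reps

    # PP: BIC-approximation posterior weights (equal dimensionality)
    shifted = observed - observed.max()
    pp = np.exp(shifted) / np.exp(shifted).sum()

    kh = np.empty(n_trees)
    wkh = np.empty(n_trees)
    sh = np.empty(n_trees)
    wsh = np.empty(n_trees)
    sd_pair = np.empty((n_trees, n_trees))
    for i in range(n_trees):
        diff = centered - centered[:, [i]]
        sd = diff.std(axis=0, ddof=1)
        sd[sd == 0] = np.inf
        sd_pair[i] = sd

    for i in range(n_trees):
        others = [j for j in range(n_trees) if j != i]
        rival = others[int(np.argmax(observed[others]))]
        stat = observed[rival] - observed[i]
        null = centered[:, rival] - centered[:, i]
        kh[i] = np.mean(null >= stat)
        sd = sd_pair[i, rival]
        if np.isinf(sd):
            wkh[i] = kh[i]
        else:
            wkh[i] = np.mean(null / sd >= stat / sd)
        # SH: max over all candidates, unstandardized
        sh_stat = observed.max() - observed[i]
        sh_null = (centered - centered[:, [i]]).max(axis=1)
        sh[i] = np.mean(sh_null >= sh_stat)
        # WSH: max over rivals, standardized per pair
        w = 1.0 / sd_pair[i, others]
        wsh_stat = ((observed[others] - observed[i]) * w).max()
        wsh_null = ((centered[:, others] - centered[:, [i]]) * w).max(axis=1)
        wsh[i] = np.mean(wsh_null >= wsh_stat)

    # AU / NP from multiscale bootstrap
    ms_bp = _multiscale_bp(matrix, n_reps, scales, rng)
    au = np.empty(n_trees)
    np_ = np.empty(n_trees)
    for i in range(n_trees):
        au[i], np_[i] = _au_np_fit(ms_bp[:, i], scales, n_reps)

    pvalues = {"au": au, "np": np_, "bp": bp, "pp": pp,
               "kh": kh, "sh": sh, "wkh": wkh, "wsh": wsh}
    return TestReport(list(matrix.tree_ids), observed,
                      matrix.tree_ids[best_idx], pvalues)


def confidence_set(report: TestReport, test: str,
                   alpha: float = 0.05) -> set[str]:
    """Trees that cannot be rejected: p >= alpha; the best tree is always
    retained."""
    if test not in report.pvalues:
        raise KeyError(f"unknown test {test!r}; choose from {TEST_NAMES}")
    keep = {tid for tid, p in zip(report.tree_ids, report.pvalues[test])
            if p >= alpha}
    keep.add(report.best)
    return keep


def report_frame(report: TestReport, alpha: float = 0.05) -> pd.DataFrame:
    """Hypotheses x tests table with per-test retained/rejected flags."""
    df = report.frame(alpha)
    for test in TEST_NAMES:
        kept = confidence_set(report, test, alpha)
        df[f"{test}_retained"] = [t in kept for t in df["tree"]]
    return df
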