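"""Conserved gene-neighborhood detection between two genomes.

Two detection strategies are implemented:

* **relaxed** — two query genes with at most three intervening genes are
  syntenic when homologs (same family) of both co-occur in the target genome
  separated by at most four genes; an intervening query gene that has target
  homologs must have one within a window of fewer than 15 genes around the
  target locus (here: within 7 genes of either member of the target pair).
* **strict** — two query genes in the same orientation with at most three
  intervening genes are syntenic when their 1:1 *orthologs* lie at most three
  intervening genes apart in the target and share an orientation with each
  other.  An intervening query gene that has a target ortholog discards the
  pair (``literal`` mode, implying a rearrangement) or discards it only when
  that ortholog falls outside the target interval spanned by the pair's
  orthologs (``interval_consistent`` mode).

Recent tandem segmental duplications inflate relaxed counts because one query
pair detects several paralogous target loci; :func:`collapse_paralogous_pairs`
counts each (query pair, family pair) combination once.  Counts are normalized
per 1000 shared homologs (relaxed) or shared 1:1 orthologs (strict); counts
are direction dependent and both directions should be reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .geneorder import Gene, GeneOrderGenome


@dataclass(frozen=True)
class SyntenicPair:
    query_pair: tuple[str, str]
    target_pair: tuple[str, str]
    mode: str
    family_pair: tuple[str, str]  # sorted, unordered semantics


@dataclass
class SyntenyResult:
    raw_count: int
    corrected_count: int
    shared_homologs: int
    shared_orthologs: int
    normalized_raw: float
    normalized_corrected: float


# ------------------------------------------------------------- detectors

def _families(genome: GeneOrderGenome,
              homology: dict[str, str] | None) -> dict[str, str]:
    """gene_id -> family, honouring an explicit homology map when given."""
    out = {}
    for _, gene in genome.genes():
        if homology is not None:
            if gene.gene_id not in homology:
                raise KeyError(f"no family for gene {gene.gene_id}")
            out[gene.gene_id] = homology[gene.gene_id]
        else:
            out[gene.gene_id] = gene.family_id
    return out


def find_relaxed_pairs(query: GeneOrderGenome, target: GeneOrderGenome,
                       homology: dict[str, str] | None = None,
                       max_query_gap: int = 3, max_target_gap: int = 4,
                       window: int = 7) -> list[SyntenicPair]:
    """All relaxed syntenic pairs, one per (query pair, target locus pair)."""
    qfam = _families(query, homology)
    tfam = _families(target, homology)
    tpos: dict[str, list[tuple[str, int]]] = {}
    for contig_id, gene in target.genes():
        tpos.setdefault(tfam[gene.gene_id], []).append((contig_id, gene.index))
    tgene: dict[tuple[str, int], Gene] = {
        (c, g.index): g for c, g in target.genes()}

    pairs: list[SyntenicPair] = []
    for contig_id, genes in query.contigs.items():
        for i, ga in enumerate(genes):
            for gb in genes[i + 1:i + 2 + max_query_gap]:
                if gb.index - ga.index - 1 > max_query_gap:
                    break
                fa, fb = qfam[ga.gene_id], qfam[gb.gene_id]
                between = genes[ga.index + 1:gb.index]
                seen: set[tuple[str, int, str, int]] = set()
                for ca, xa in tpos.get(fa, ()):
                    for cb, xb in tpos.get(fb, ()):
                        if ca != cb or (xa, ca) == (xb, cb):
                            continue
                        if abs(xa - xb) - 1 > max_target_gap:
                            continue
                        locus = (ca, min(xa, xb), cb, max(xa, xb))
                        if locus in seen:
                            continue
                        if not _window_ok(between, qfam, tpos, ca, xa, xb,
                                          window):
                            continue
                        seen.add(locus)
                        ta = tgene[(ca, min(xa, xb))]
                        tb = tgene[(cb, max(xa, xb))]
                        pairs.append(SyntenicPair(
                            (ga.gene_id, gb.gene_id),
                            (ta.gene_id, tb.gene_id), "relaxed",
                            tuple(sorted((fa, fb)))))
    return pairs


def _window_ok(between, qfam, tpos, contig, xa, xb, window) -> bool:
    for g in between:
        hits = tpos.get(qfam[g.gene_id])
        if not hits:
            continue
        if not any(c == contig and (abs(x - xa) <= window
                                    or abs(x - xb) <= window)
                   for c, x in hits):
            return False
    return True


def _one_to_one(query: GeneOrderGenome, target: GeneOrderGenome,
                orthology: dict[str, str] | None,
                ) -> dict[str, tuple[str, int, str]]:
    """query gene_id -> (target contig, index, strand) for 1:1 orthologs."""
    if orthology is not None:
        tloc = {g.gene_id: (c, g.index, g.strand) for c, g in target.genes()}
        targets = list(orthology.values())
        if len(set(targets)) != len(targets):
            raise ValueError("orthology map is not one-to-one")
        return {q: tloc[t] for q, t in orthology.items() if t in tloc}
    qtok = query.ortholog_tokens()
    out = {}
    ttok: dict[str, tuple[str, int, str]] = {}
    for c, g in target.genes():
        if g.ortholog_id is not None:
            ttok[g.ortholog_id] = (c, g.index, g.strand)
    by_token_q: dict[str, str] = {}
    for c, g in query.genes():
        if g.ortholog_id is not None:
            by_token_q[g.ortholog_id] = g.gene_id
    for token, gid in by_token_q.items():
        if token in ttok:
            out[gid] = ttok[token]
    return out


def find_strict_pairs(query: GeneOrderGenome, target: GeneOrderGenome,
                      orthology: dict[str, str] | None = None,
                      intervening_mode: str = "literal",
                      max_gap: int = 3) -> list[SyntenicPair]:
    """All strict syntenic pairs under the chosen intervening-gene reading."""
    if intervening_mode not in ("literal", "interval_consistent"):
        raise ValueError(f"unknown intervening_mode {intervening_mode!r}")
    omap = _one_to_one(query, target, orthology)
    tgene: dict[tuple[str, int], Gene] = {
        (c, g.index): g for c, g in target.genes()}

    pairs: list[SyntenicPair] = []
    for contig_id, genes in query.contigs.items():
        for i, ga in enumerate(genes):
            for gb in genes[i + 1:i + 2 + max_gap]:
                if gb.index - ga.index - 1 > max_gap:
                    break
                if ga.strand != gb.strand:
                    continue
                la, lb = omap.get(ga.gene_id), omap.get(gb.gene_id)
                if la is None or lb is None or la[0] != lb[0]:
                    continue
                if abs(la[1] - lb[1]) - 1 > max_gap:
                    continue
                if la[2] != lb[2]:
                    continue
                lo, hi = sorted((la[1], lb[1]))
                ok = True
                for g in genes[ga.index + 1:gb.index]:
                    loc = omap.get(g.gene_id)
                    if loc is None:
                        continue
                    if intervening_mode == "literal":
                        ok = False
                    elif loc[0] != la[0] or not lo < loc[1] < hi:
                        ok = False
                    if not ok:
                        break
                if not ok:
                    continue
                ta = tgene[(la[0], lo)]
                tb = tgene[(lb[0], hi)]
                pairs.append(SyntenicPair(
                    (ga.gene_id, gb.gene_id), (ta.gene_id, tb.gene_id),
                    "strict",
                    tuple(sorted((ga.family_id, gb.family_id)))))
    return pairs


# ------------------------------------------------------------ correction

def collapse_paralogous_pairs(pairs: list[SyntenicPair]) -> list[SyntenicPair]:
    """Count each (query pair, family pair) once: paralogous target loci that
    arise from lineage-specific duplications collapse to a single pair."""
    seen: set[tuple] = set()
    out: list[SyntenicPair] = []
    for pair in pairs:
        key = (tuple(sorted(pair.query_pair)), pair.family_pair)
        if key not in seen:
            seen.add(key)
            out.append(pair)
    return out


# --------------------------------------------------------- normalization

def shared_homolog_count(query: GeneOrderGenome, target: GeneOrderGenome,
                         homology: dict[str, str] | None = None) -> int:
    """Number of query genes whose family has a member in the target."""
    qfam = _families(query, homology)
    tfams = set(_families(target, homology).values())
    return sum(1 for fam in qfam.values() if fam in tfams)


def shared_ortholog_count(query: GeneOrderGenome, target: GeneOrderGenome,
                          orthology: dict[str, str] | None = None) -> int:
    """Number of 1:1 ortholog pairs between the two genomes."""
    return len(_one_to_one(query, target, orthology))


def normalize_pair_count(count: int, shared: int) -> float:
    """Syntenic pairs per 1000 shared (homologous or orthologous) genes."""
    if shared <= 0:
        raise ValueError("shared gene count must be positive")
    return 1000.0 * count / shared


def compare_genomes(query: GeneOrderGenome, target: GeneOrderGenome,
                    mode: str = "relaxed",
                    intervening_mode: str = "literal") -> SyntenyResult:
    """Full one-direction comparison: detect, correct, normalize."""
    if mode == "relaxed":
        pairs = find_relaxed_pairs(query, target)
        shared = shared_homolog_count(query, target)
    elif mode == "strict":
        pairs = find_strict_pairs(query, target,
                                  intervening_mode=intervening_mode)
        shared = shared_ortholog_count(query, target)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    corrected = collapse_paralogous_pairs(pairs)
    return SyntenyResult(
        raw_count=len(pairs), corrected_count=len(corrected),
        shared_homologs=shared_homolog_count(query, target),
        shared_orthologs=shared_ortholog_count(query, target),
        normalized_raw=normalize_pair_count(len(pairs), shared),
        normalized_corrected=normalize_pair_count(len(corrected), shared))


def comparison_frame(results: dict[tuple[str, str], SyntenyResult],
                     ) -> pd.DataFrame:
    rows = [(q, t, r.shared_homologs, r.shared_orthologs, r.raw_count,
             r.normalized_raw, r.corrected_count, r.normalized_corrected)
            for (q, t), r in results.items()]
    return pd.DataFrame(rows, columns=[
        "query", "target", "shared_homologs", "shared_orthologs", "raw",
        "normalized_raw", "corrected", "normalized_corrected"])


# ------------------------------------------------------------ statistics

def compare_groups_kw(rates_by_group: dict[str, list[float]],
                      ) -> tuple[float, float]:
    """Kruskal-Wallis H (midrank tie correction) across >= 2 groups of
    normalized synteny scores; p from chi-square with k-1 df."""
    if len(rates_by_group) < 2:
        raise ValueError("need at least two groups")
    samples = list(rates_by_group.values())
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be non-empty")
    flat = [x for s in samples for x in s]
    if len(set(flat)) == 1:
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)
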