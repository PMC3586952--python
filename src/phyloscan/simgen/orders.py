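"""Evolution of gene order along a species tree.

The ancestral genome is a single contig of single-copy families.  Along every
species-tree branch three event types occur, each with Poisson counts per
branch: inversions (reverse a contiguous block and flip strands), tandem
segmental duplications (copy a contiguous block next to itself; copies keep
the family id but receive fresh ortholog tokens), and gene gain/loss (gains
insert a novel family; losses remove a gene, never the last copy of its family
in the genome).  True orthology is descent without duplication: genes sharing
an ortholog token are 1:1 orthologs wherever both survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from ..geneorder import Gene, GeneOrderGenome

# internal working representation of one gene: [family, token, strand]


@dataclass
class GeneOrderEvolution:
    """Planted ground truth for one gene-order simulation."""
    events: list[dict] = field(default_factory=list)
    genomes: dict[str, GeneOrderGenome] = field(default_factory=dict)

    def ortholog_sets(self) -> dict[str, list[tuple[str, str]]]:
        """token -> [(genome_id, gene_id), ...] — partitions all genes."""
        out: dict[str, list[tuple[str, str]]] = {}
        for genome in self.genomes.values():
            for _, gene in genome.genes():
                out.setdefault(gene.ortholog_id, []).append(
                    (genome.genome_id, gene.gene_id))
        return out


def evolve_gene_orders(species_tree: dendropy.Tree, n_genes: int,
                       inv_rate: float, segdup_rate: float,
                       gainloss_rate: float, seed: int = 0,
                       max_block: int = 4,
                       ) -> tuple[dict[str, GeneOrderGenome], GeneOrderEvolution]:
    """One :class:`GeneOrderGenome` per species-tree leaf, plus ground truth."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if min(inv_rate, segdup_rate, gainloss_rate) < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    truth = GeneOrderEvolution()
    counter = {"token": n_genes, "family": n_genes}
    ancestor = [[f"F{i:05d}", f"L{i:05d}", "+" if rng.random() < 0.5 else "-"]
                for i in range(n_genes)]

    def visit(sp_node: dendropy.Node, genome: list[list[str]]) -> None:
        if sp_node.parent_node is not None:
            genome = _evolve_branch(genome, sp_node, inv_rate, segdup_rate,
                                    gainloss_rate, max_block, rng, counter,
                                    truth.events)
        if sp_node.is_leaf():
            species = sp_node.taxon.label
            truth.genomes[species] = _freeze(species, genome)
        else:
            for child in sp_node.child_nodes():
                visit(child, [g[:] for g in genome])

    visit(species_tree.seed_node, ancestor)
    return truth.genomes, truth


def _evolve_branch(genome, sp_node, inv_rate, segdup_rate, gainloss_rate,
                   max_block, rng, counter, log):
    species = (sp_node.taxon.label if sp_node.is_leaf()
               else f"node{id(sp_node) % 10 ** 6}")
    events = (["inv"] * rng.poisson(inv_rate)
              + ["dup"] * rng.poisson(segdup_rate)
              + ["gl"] * rng.poisson(gainloss_rate))
    rng.shuffle(events)
    for kind in events:
        if not genome:
            break
        n = len(genome)
        if kind == "inv":
            i, j = sorted(rng.integers(0, n, size=2))
            block = genome[i:j + 1][::-1]
            for g in block:
                g[2] = "+" if g[2] == "-" else "-"
            genome[i:j + 1] = block
            log.append({"branch": species, "type": "inversion",
                        "start": int(i), "end": int(j)})
        elif kind == "dup":
            length = int(rng.integers(1, max_block + 1))
            start = int(rng.integers(0, n))
            block = genome[start:start + length]
            copies = []
            for fam, _tok, strand in block:
                copies.append([fam, f"L{counter['token']:05d}", strand])
                counter["token"] += 1
            at = start + len(block)
            genome[at:at] = copies
            log.append({"branch": species, "type": "segmental_duplication",
                        "start": start, "length": len(block)})
        else:  # gain or loss, equal odds
            if rng.random() < 0.5:
                fam = f"F{counter['family']:05d}"
                tok = f"L{counter['token']:05d}"
                counter["family"] += 1
                counter["token"] += 1
                at = int(rng.integers(0, n + 1))
                genome.insert(at, [fam, tok, "+" if rng.random() < 0.5 else "-"])
                log.append({"branch": species, "type": "gain", "at": at})
            else:
                fam_counts: dict[str, int] = {}
                for fam, _t, _s in genome:
                    fam_counts[fam] = fam_counts.get(fam, 0) + 1
                for _ in range(20):  # keep the family alive in this genome
                    at = int(rng.integers(0, n))
                    if fam_counts[genome[at][0]] > 1:
                        genome.pop(at)
                        log.append({"branch": species, "type": "loss", "at": at})
                        break
    return genome


def _freeze(species: str, genome: list[list[str]]) -> GeneOrderGenome:
    genes = [Gene(f"{species}_g{i + 1:04d}", i, strand, fam, tok)
             for i, (fam, tok, strand) in enumerate(genome)]
    return GeneOrderGenome(species, {"c1": genes})


def tandem_duplicate(genome: GeneOrderGenome, contig_id: str, start: int,
                     length: int, token_prefix: str = "DUP",
                     ) -> GeneOrderGenome:
    """Plant one tandem segmental duplication of ``length`` genes at ``start``.

    Copies share their source family ids but get fresh ortholog tokens, so the
    duplication inflates homology-based pair counts without creating new 1:1
    orthologs — the confound the correction step removes.
    """
    old = genome.contigs[contig_id]
    if not (0 <= start and start + length <= len(old)):
        raise ValueError("block out of range")
    block = old[start:start + length]
    copies = [Gene(f"{g.gene_id}_{token_prefix.lower()}{k}", 0, g.strand,
                   g.family_id, f"{token_prefix}{k}")
              for k, g in enumerate(block)]
    merged = old[:start + length] + copies + old[start + length:]
    reindexed = [Gene(g.gene_id, i, g.strand, g.family_id, g.ortholog_id)
                 for i, g in enumerate(merged)]
    contigs = dict(genome.contigs)
    contigs[contig_id] = reindexed
    return GeneOrderGenome(genome.genome_id, contigs)
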