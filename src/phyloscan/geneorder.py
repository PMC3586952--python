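"""Gene-order containers: stranded, ordered genes on contigs with family and
ortholog labels, plus the TSV dialect shared by the simulator and the synteny
detectors.

``family_id`` groups all homologs (any descent); ``ortholog_id`` is a lineage
token shared only by genes related by speciation (descent without duplication);
genes created by duplication or gain carry fresh tokens.  A missing ortholog id
is written as ``.`` in TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple

import pandas as pd

TSV_COLUMNS = ["genome_id", "contig_id", "index", "gene_id", "strand",
               "family_id", "ortholog_id"]


class Gene(NamedTuple):
    gene_id: str
    index: int
    strand: str  # '+' or '-'
    family_id: str
    ortholog_id: str | None


@dataclass
class GeneOrderGenome:
    genome_id: str
    contigs: dict[str, list[Gene]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for contig_id, genes in self.contigs.items():
            for pos, gene in enumerate(genes):
                if gene.index != pos:
                    raise ValueError(
                        f"{self.genome_id}/{contig_id}: gene indices must be "
                        f"consecutive from 0 (got {gene.index} at {pos})")
                if gene.strand not in "+-":
                    raise ValueError(f"bad strand {gene.strand!r}")
                if gene.gene_id in seen:
                    raise ValueError(f"duplicate gene id {gene.gene_id}")
                seen.add(gene.gene_id)

    def genes(self) -> Iterator[tuple[str, Gene]]:
        for contig_id, genes in self.contigs.items():
            for gene in genes:
                yield contig_id, gene

    @property
    def n_genes(self) -> int:
        return sum(len(g) for g in self.contigs.values())

    def families(self) -> set[str]:
        return {g.family_id for _, g in self.genes()}

    def family_positions(self) -> dict[str, list[tuple[str, int]]]:
        """family_id -> [(contig_id, index), ...]"""
        out: dict[str, list[tuple[str, int]]] = {}
        for contig_id, gene in self.genes():
            out.setdefault(gene.family_id, []).append((contig_id, gene.index))
        return out

    def ortholog_tokens(self) -> dict[str, tuple[str, int]]:
        """ortholog_id -> (contig_id, index); tokens are unique per genome."""
        out: dict[str, tuple[str, int]] = {}
        for contig_id, gene in self.genes():
            if gene.ortholog_id is not None:
                if gene.ortholog_id in out:
                    raise ValueError(
                        f"ortholog token {gene.ortholog_id} not unique in "
                        f"{self.genome_id}")
                out[gene.ortholog_id] = (contig_id, gene.index)
        return out

    # ------------------------------------------------------------------ I/O

    def to_frame(self) -> pd.DataFrame:
        rows = [(self.genome_id, contig_id, g.index, g.gene_id, g.strand,
                 g.family_id, g.ortholog_id if g.ortholog_id is not None else ".")
                for contig_id, g in self.genes()]
        return pd.DataFrame(rows, columns=TSV_COLUMNS)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GeneOrderGenome":
        genome_ids = frame["genome_id"].unique()
        if len(genome_ids) != 1:
            raise ValueError("frame must describe exactly one genome")
        frame = frame.assign(index=frame["index"].astype(int))
        contigs: dict[str, list[Gene]] = {}
        for contig_id, sub in frame.groupby("contig_id", sort=True):
            sub = sub.sort_values("index")
            contigs[str(contig_id)] = [
                Gene(str(r["gene_id"]), int(r["index"]), str(r["strand"]),
                     str(r["family_id"]),
                     None if str(r["ortholog_id"]) == "."
                     else str(r["ortholog_id"]))
                for _, r in sub.iterrows()]
        return cls(str(genome_ids[0]), contigs)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneOrderGenome":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype=str))
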