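"""In-memory container for protein alignments with per-column partition labels."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import GAP


@dataclass
class AlignmentMatrix:
    """Species x columns residue matrix.

    ``data`` is a (n_rows, n_sites) array of single characters (amino acids or
    the gap character '-').  ``partitions`` optionally labels every column with
    the identifier of the source gene family after concatenation.
    """

    names: list[str]
    data: np.ndarray
    partitions: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype="<U1")
        if self.data.ndim != 2:
            raise ValueError("alignment data must be 2-D")
        if len(self.names) != self.data.shape[0]:
            raise ValueError("one name per row required")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate row names")
        if self.partitions is not None:
            self.partitions = np.asarray(self.partitions, dtype=object)
            if self.partitions.shape != (self.data.shape[1],):
                raise ValueError("one partition label per column required")

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def row(self, name: str) -> np.ndarray:
        return self.data[self.names.index(name)]

    def select_columns(self, keep: np.ndarray) -> "AlignmentMatrix":
        """Subset columns by boolean mask or integer index array."""
        parts = self.partitions[keep] if self.partitions is not None else None
        return AlignmentMatrix(list(self.names), self.data[:, keep], parts)

    def copy(self) -> "AlignmentMatrix":
        parts = self.partitions.copy() if self.partitions is not None else None
        return AlignmentMatrix(list(self.names), self.data.copy(), parts)

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_fasta(cls, path: str | Path) -> "AlignmentMatrix":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        lengths = {len(r.seq) for r in records}
        if len(lengths) != 1:
            raise ValueError("sequences are not aligned (unequal lengths)")
        names = [r.id for r in records]
        data = np.array([list(str(r.seq)) for r in records], dtype="<U1")
        return cls(names, data)

    def write_fasta(self, path: str | Path) -> None:
        records = [SeqRecord(Seq("".join(row)), id=name, description="")
                   for name, row in zip(self.names, self.data)]
        SeqIO.write(records, str(path), "fasta-2line")

    def gap_mask(self) -> np.ndarray:
        """Boolean (n_rows, n_sites) array, True where gapped."""
        return self.data == GAP
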