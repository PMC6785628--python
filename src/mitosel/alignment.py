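"""Alignment matrices with reference-coordinate bookkeeping.

The container is a character matrix plus taxon names, an alphabet tag
(``nt``/``aa``/``codon``) and, optionally, a per-column map to 1-based
coordinates on a reference sequence (``-1`` marks columns that are insertions
relative to the reference).  File I/O goes through Biopython.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class AlignmentError(ValueError):
    pass


INSERTION = -1


@dataclass
class Alignment:
    names: list[str]
    data: np.ndarray                     # (n_taxa, n_columns) of single chars
    alphabet: str = "nt"                 # nt | aa | codon
    gene: str | None = None
    reference_map: np.ndarray | None = None   # per column: 1-based ref coord

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype="U1")
        if self.data.ndim != 2:
            raise AlignmentError("alignment matrix must be 2-D")
        if len(self.names) != self.data.shape[0]:
            raise AlignmentError("row count does not match taxon names")
        if len(set(self.names)) != len(self.names):
            dupes = {n for n in self.names if self.names.count(n) > 1}
            raise AlignmentError(f"duplicate taxon names: {sorted(dupes)}")
        if self.reference_map is not None:
            self.reference_map = np.asarray(self.reference_map, dtype=np.intp)
            if len(self.reference_map) != self.n_columns:
                raise AlignmentError("reference_map length mismatch")

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_columns(self) -> int:
        return self.data.shape[1]

    def row(self, name: str) -> np.ndarray:
        try:
            return self.data[self.names.index(name)]
        except ValueError:
            raise AlignmentError(f"taxon {name!r} not in alignment") from None

    def sequence(self, name: str) -> str:
        return "".join(self.row(name))

    def take_columns(self, cols, gene: str | None = None) -> "Alignment":
        cols = np.asarray(cols, dtype=np.intp)
        ref = None if self.reference_map is None else self.reference_map[cols]
        return Alignment(list(self.names), self.data[:, cols], self.alphabet,
                         gene or self.gene, ref)

    def reorder(self, names: list[str]) -> "Alignment":
        idx = [self.names.index(n) for n in names]
        return Alignment(list(names), self.data[idx], self.alphabet, self.gene,
                         None if self.reference_map is None
                         else self.reference_map.copy())

    def __eq__(self, other) -> bool:
        return (isinstance(other, Alignment)
                and self.names == other.names
                and self.alphabet == other.alphabet
                and np.array_equal(self.data, other.data))

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_records(cls, records, alphabet="nt", gene=None) -> "Alignment":
        names, rows = [], []
        for name, seq in records:
            names.append(name)
            rows.append(list(str(seq).upper()))
        if not rows:
            raise AlignmentError("empty alignment")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment rows, lengths {sorted(lengths)}")
        return cls(names, np.array(rows, dtype="U1"), alphabet, gene)

    @classmethod
    def read(cls, path, alphabet: str = "nt", fmt: str | None = None) -> "Alignment":
        """Read FASTA (default) or relaxed PHYLIP; taxon order preserved."""
        if fmt is None:
            with open(path) as fh:
                first = fh.readline()
            fmt = "fasta" if first.startswith(">") else "phylip-relaxed"
        if fmt == "fasta":
            records = [(r.id, r.seq) for r in SeqIO.parse(str(path), "fasta")]
        else:
            aln = AlignIO.read(str(path), fmt)
            records = [(r.id, r.seq) for r in aln]
        return cls.from_records(records, alphabet=alphabet)

    def write(self, path, fmt: str = "fasta") -> None:
        records = [SeqRecord(Seq(self.sequence(n)), id=n, description="")
                   for n in self.names]
        SeqIO.write(records, str(path), fmt)
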