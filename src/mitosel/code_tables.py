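"""Genetic-code and alphabet tables.

Everything downstream (translation, codon rate matrices, synonymy
classification) is driven by an NCBI translation table; the package default is
transl_table 2, the vertebrate mitochondrial code (TGA=Trp, ATA=Met, AGA/AGG
are stops), which leaves 60 sense codons.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
#: one-letter amino acids in the order used by PAML-style empirical matrices
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
NT_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}

#: state used for gaps/ambiguities; likelihood code marginalises over it
MISSING_AA = "X"
MISSING_NT = "N"

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def is_transition(n1: str, n2: str) -> bool:
    """True if the nucleotide change n1->n2 is a transition (A<->G, C<->T)."""
    return (n1 in _PURINES and n2 in _PURINES) or (
        n1 in _PYRIMIDINES and n2 in _PYRIMIDINES
    )


@dataclass(frozen=True, eq=False)  # identity hash: allows caching on methods
class GeneticCode:
    """A sense-codon state space derived from an NCBI translation table."""

    table_id: int
    codons: tuple[str, ...]          # sense codons, lexicographic in ACGT
    stop_codons: frozenset[str]
    aa_of_codon: tuple[str, ...]     # one-letter aa per sense codon
    codon_index: dict[str, int] = field(repr=False)

    @property
    def n_codons(self) -> int:
        return len(self.codons)

    def translate_codon(self, codon: str) -> str:
        """Translate one codon; gaps/ambiguity -> missing, stops -> '*'."""
        codon = codon.upper().replace("U", "T")
        if codon in self.stop_codons:
            return "*"
        idx = self.codon_index.get(codon)
        return MISSING_AA if idx is None else self.aa_of_codon[idx]

    @lru_cache(maxsize=None)
    def single_change_pairs(self):
        """Index arrays for codon pairs differing at exactly one position.

        Returns (i, j, transition, nonsynonymous) as numpy arrays over ordered
        pairs; the backbone of any GY94-style rate matrix.
        """
        ii, jj, ts, nonsyn = [], [], [], []
        for i, ci in enumerate(self.codons):
            for j, cj in enumerate(self.codons):
                if i == j:
                    continue
                diffs = [k for k in range(3) if ci[k] != cj[k]]
                if len(diffs) != 1:
                    continue
                k = diffs[0]
                ii.append(i)
                jj.append(j)
                ts.append(is_transition(ci[k], cj[k]))
                nonsyn.append(self.aa_of_codon[i] != self.aa_of_codon[j])
        return (
            np.asarray(ii, dtype=np.intp),
            np.asarray(jj, dtype=np.intp),
            np.asarray(ts, dtype=bool),
            np.asarray(nonsyn, dtype=bool),
        )

    def aa_indices(self) -> np.ndarray:
        """Per sense codon, the index of its amino acid in AMINO_ACIDS."""
        return np.array([AA_INDEX[a] for a in self.aa_of_codon], dtype=np.intp)


@lru_cache(maxsize=None)
def genetic_code(table_id: int = 2) -> GeneticCode:
    """Build the sense-codon table for an NCBI translation table id."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    stops = frozenset(table.stop_codons)
    codons = tuple(
        a + b + c
        for a in NUCLEOTIDES
        for b in NUCLEOTIDES
        for c in NUCLEOTIDES
        if a + b + c not in stops
    )
    aa = tuple(table.forward_table[c] for c in codons)
    return GeneticCode(
        table_id=table_id,
        codons=codons,
        stop_codons=stops,
        aa_of_codon=aa,
        codon_index={c: i for i, c in enumerate(codons)},
    )


VERTEBRATE_MT = 2
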