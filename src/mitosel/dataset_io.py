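"""Reading the study's tabular inputs and slicing mitogenome alignments.

Covers: species depth tables and the deep/shallow classification (deep-sea =
maximum recorded depth at or beyond 1,000 m, threshold configurable),
reference-anchored partitioning of a whole-mitogenome alignment into the 13
protein-coding genes, and translation under the vertebrate mitochondrial code.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import INSERTION, Alignment, AlignmentError
from .code_tables import MISSING_AA, VERTEBRATE_MT, genetic_code
from .trees import PhyloTree

log = logging.getLogger(__name__)

MT_GENES = ("ATP6", "ATP8", "COX1", "COX2", "COX3", "CytB",
            "ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6")

DEEP_SEA_THRESHOLD_M = 1000.0

_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")


class InternalStopError(ValueError):
    pass


@dataclass(frozen=True)
class SpeciesRecord:
    taxon_id: str
    depth_min: float
    depth_max: float
    group_label: str = "none"

    def __post_init__(self):
        dmin, dmax = self.depth_min, self.depth_max
        if np.isfinite(dmin) and np.isfinite(dmax) and dmin > dmax:
            raise ValueError(f"{self.taxon_id}: depth_min > depth_max")


@dataclass(frozen=True)
class GeneCoordinate:
    gene: str
    start: int          # 1-based inclusive on the reference
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene}: start > end")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene}: bad strand {self.strand!r}")


# -- depth tables ----------------------------------------------------------

def read_depth_table(path) -> list[SpeciesRecord]:
    """TSV with columns taxon_id, depth_min, depth_max[, group]."""
    df = pd.read_csv(path, sep="\t", dtype={"taxon_id": str})
    if df["taxon_id"].duplicated().any():
        raise ValueError("duplicate taxon_id in depth table")
    records = []
    for row in df.itertuples(index=False):
        records.append(SpeciesRecord(
            taxon_id=row.taxon_id,
            depth_min=float(row.depth_min),
            depth_max=float(row.depth_max),
            group_label=str(getattr(row, "group", "none")),
        ))
    return records


def classify_deep_sea(records, threshold_m: float = DEEP_SEA_THRESHOLD_M
                      ) -> dict[str, str]:
    """Map taxon -> 'deep' / 'shallow'; taxa with missing depths are dropped.

    The boundary is inclusive: a maximum recorded depth of exactly the
    threshold counts as deep.
    """
    out: dict[str, str] = {}
    for rec in records:
        if not np.isfinite(rec.depth_max):
            log.warning("taxon %s has no usable depth; excluded", rec.taxon_id)
            continue
        out[rec.taxon_id] = "deep" if rec.depth_max >= threshold_m else "shallow"
    return out


# -- gene coordinates and partitioning -------------------------------------

def read_gene_coordinates(path) -> list[GeneCoordinate]:
    """TSV with columns gene, start, end, strand."""
    df = pd.read_csv(path, sep="\t")
    return [GeneCoordinate(str(r.gene), int(r.start), int(r.end), str(r.strand))
            for r in df.itertuples(index=False)]


def partition_genes(alignment: Alignment, coords, reference_taxon: str,
                    trim_to_codon: bool = True) -> dict[str, Alignment]:
    """Slice a reference-anchored alignment into per-gene alignments.

    Alignment columns are numbered by the ungapped positions of the reference
    row; insertion columns (reference gap) belong to no gene.  Minus-strand
    genes (ND6 in vertebrate mitogenomes) are reverse-complemented so every
    output reads in coding orientation.  ``trim_to_codon`` drops trailing
    columns of genes whose annotated span is not a whole number of codons
    (incomplete stop codons in real mitogenomes).
    """
    ref_row = alignment.row(reference_taxon)
    ref_coord = np.full(alignment.n_columns, INSERTION, dtype=np.intp)
    pos = 0
    for col, ch in enumerate(ref_row):
        if ch != "-":
            pos += 1
            ref_coord[col] = pos
    ref_len = pos

    out: dict[str, Alignment] = {}
    for gc in coords:
        if gc.end > ref_len:
            raise ValueError(
                f"{gc.gene}: interval {gc.start}..{gc.end} exceeds reference "
                f"length {ref_len}")
        cols = np.flatnonzero((ref_coord >= gc.start) & (ref_coord <= gc.end))
        sub = alignment.take_columns(cols, gene=gc.gene)
        sub.reference_map = ref_coord[cols]
        if gc.strand == "-":
            rows = ["".join(r)[::-1].translate(_COMPLEMENT) for r in sub.data]
            sub = Alignment(list(sub.names),
                            np.array([list(r) for r in rows], dtype="U1"),
                            sub.alphabet, gc.gene, sub.reference_map[::-1].copy())
        if trim_to_codon and sub.n_columns % 3:
            keep = sub.n_columns - sub.n_columns % 3
            sub = sub.take_columns(np.arange(keep))
        out[gc.gene] = sub
    return out


# -- translation -----------------------------------------------------------

def translate_mt(codon_alignment: Alignment, table_id: int = VERTEBRATE_MT,
                 on_internal_stop: str = "warn") -> Alignment:
    """Translate an in-frame nucleotide alignment (vertebrate mito code).

    Codons containing gaps or ambiguity codes become the missing state.
    Internal stop codons warn and become missing; ``on_internal_stop='error'``
    raises instead.  A stop in the final codon column (the natural terminator)
    is treated as missing without complaint.
    """
    if codon_alignment.n_columns % 3:
        raise AlignmentError("codon alignment length not divisible by 3")
    code = genetic_code(table_id)
    n_codons = codon_alignment.n_columns // 3
    rows = []
    for taxon in codon_alignment.names:
        seq = codon_alignment.sequence(taxon)
        aa = []
        for i in range(n_codons):
            codon = seq[3 * i: 3 * i + 3]
            res = code.translate_codon(codon)
            if res == "*":
                if i == n_codons - 1:
                    res = MISSING_AA
                elif on_internal_stop == "error":
                    raise InternalStopError(
                        f"internal stop codon {codon} at codon {i + 1} "
                        f"in {taxon}")
                else:
                    warnings.warn(
                        f"internal stop codon {codon} at codon {i + 1} in "
                        f"{taxon}; treated as missing", stacklevel=2)
                    res = MISSING_AA
            aa.append(res)
        rows.append(aa)
    ref = codon_alignment.reference_map
    aa_ref = None if ref is None else ref[::3].copy()
    return Alignment(list(codon_alignment.names), np.array(rows, dtype="U1"),
                     "aa", codon_alignment.gene, aa_ref)


# -- trees (thin wrappers so all dataset I/O lives here) --------------------

def read_tree(path) -> PhyloTree:
    return PhyloTree.read(path)


def write_tree(tree: PhyloTree, path) -> None:
    tree.write(path)
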