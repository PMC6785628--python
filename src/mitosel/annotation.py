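"""Membrane-topology domain assignment and amino-acid polarity classes.

Topology comes in as TMHMM-style long-format text (one interval per line:
protein, method, label, start, end) or an equivalent TSV; labels collapse to
{TM, inside, outside}.  Polarity uses the standard four-class scheme
(nonpolar, polar-neutral, positively-charged, negatively-charged).
"""
from __future__ import annotations

from dataclasses import dataclass

from .code_tables import AMINO_ACIDS

TM, INSIDE, OUTSIDE = "TM", "inside", "outside"

_LABEL_MAP = {
    "tmhelix": TM, "tm": TM,
    "inside": INSIDE, "intracellular": INSIDE,
    "outside": OUTSIDE, "extracellular": OUTSIDE,
}


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class DomainInterval:
    start: int          # 1-based inclusive
    end: int
    label: str

    def __post_init__(self):
        if self.start > self.end or self.start < 1:
            raise AnnotationError(f"bad interval {self.start}..{self.end}")
        if self.label not in (TM, INSIDE, OUTSIDE):
            raise AnnotationError(f"bad domain label {self.label!r}")


@dataclass
class TopologyAnnotation:
    protein: str
    intervals: list[DomainInterval]

    def __post_init__(self):
        ivs = sorted(self.intervals, key=lambda iv: iv.start)
        if not ivs or ivs[0].start != 1:
            raise AnnotationError(f"{self.protein}: intervals must start at 1")
        for a, b in zip(ivs, ivs[1:]):
            if b.start != a.end + 1:
                raise AnnotationError(
                    f"{self.protein}: gap or overlap between {a.end} and "
                    f"{b.start}")
        self.intervals = ivs

    @property
    def length(self) -> int:
        return self.intervals[-1].end

    def assign_domain(self, site: int) -> str:
        """Domain label covering a 1-based residue position."""
        if not 1 <= site <= self.length:
            raise AnnotationError(
                f"site {site} outside 1..{self.length} of {self.protein}")
        for iv in self.intervals:
            if iv.start <= site <= iv.end:
                return iv.label
        raise AssertionError("coverage invariant violated")  # pragma: no cover


def assign_domain(site: int, annotation: TopologyAnnotation) -> str:
    return annotation.assign_domain(site)


def read_topology(path) -> dict[str, TopologyAnnotation]:
    """Parse TMHMM-style long-format lines into per-protein annotations."""
    rows: dict[str, list[DomainInterval]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) == 5:
                protein, _method, label, start, end = parts
            elif len(parts) == 4:
                protein, label, start, end = parts
            else:
                raise AnnotationError(f"unparseable topology line: {line!r}")
            key = _LABEL_MAP.get(label.lower())
            if key is None:
                raise AnnotationError(f"unknown topology label {label!r}")
            rows.setdefault(protein, []).append(
                DomainInterval(int(start), int(end), key))
    return {p: TopologyAnnotation(p, ivs) for p, ivs in rows.items()}


def write_topology(annotations: dict[str, TopologyAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("# protein\tlabel\tstart\tend\n")
        for protein in sorted(annotations):
            for iv in annotations[protein].intervals:
                label = "TMhelix" if iv.label == TM else iv.label
                fh.write(f"{protein}\t{label}\t{iv.start}\t{iv.end}\n")


# -- polarity --------------------------------------------------------------

NONPOLAR = "nonpolar"
POLAR_NEUTRAL = "polar-neutral"
POSITIVE = "positively-charged"
NEGATIVE = "negatively-charged"

#: standard 4-class assignment (S/T polar-neutral; A/I/L/F/V etc. nonpolar)
DEFAULT_POLARITY: dict[str, str] = {
    **{aa: NONPOLAR for aa in "GAVLIMFWP"},
    **{aa: POLAR_NEUTRAL for aa in "STCYNQ"},
    **{aa: POSITIVE for aa in "KRH"},
    **{aa: NEGATIVE for aa in "DE"},
}
assert set(DEFAULT_POLARITY) == set(AMINO_ACIDS)


def polarity_change(aa_from: str, aa_to: str,
                    table: dict[str, str] | None = None):
    """None if the two residues share a polarity class, else the class pair."""
    table = table or DEFAULT_POLARITY
    for aa in (aa_from, aa_to):
        if aa not in table:
            raise AnnotationError(f"unknown residue code {aa!r}")
    c1, c2 = table[aa_from], table[aa_to]
    return None if c1 == c2 else (c1, c2)
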