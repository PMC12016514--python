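"""Degenerate consensus motif scanning on promoter sequences.

Consensus elements like the Yap Response Element (YRE,
5'-T(T/G)A(C/G)T(C/A)A-3', IUPAC ``TKASTMA``) are matched positionally:
each pattern position is a set of allowed bases.  ``N`` in a sequence
never matches a non-``N`` pattern position.  Scanning can cover both
strands; the YRE's position classes happen to be reverse-complement
symmetric, so each of its forward hits has a mirror hit on the other
strand at the same offset — gene-level statistics deduplicate.

The Pdr1/Pdr3 response element (PDRE) has no single agreed consensus;
``PDRE_DEFAULT`` ships the common literature core ``TCCGCGGA`` as a
configurable default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import AbstractSet, Mapping

from Bio.Seq import reverse_complement

__all__ = [
    "MotifPattern",
    "MotifHit",
    "parse_slash_consensus",
    "scan_sequence",
    "promoter_motif_fraction",
    "YRE",
    "PDRE_DEFAULT",
]

IUPAC_CLASSES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}
_CLASS_TO_CODE = {bases: code for code, bases in IUPAC_CLASSES.items()}


@dataclass(frozen=True)
class MotifPattern:
    """A named IUPAC consensus of length >= 4."""

    name: str
    iupac: str

    def __post_init__(self) -> None:
        if len(self.iupac) < 4:
            raise ValueError("motif must be at least 4 bp")
        bad = set(self.iupac) - set(IUPAC_CLASSES)
        if bad:
            raise ValueError(f"non-IUPAC symbols in pattern: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.iupac)

    def classes(self) -> list[frozenset[str]]:
        """Allowed concrete bases per position (used e.g. to instantiate)."""
        return [IUPAC_CLASSES[c] for c in self.iupac]

    def match_classes(self) -> list[frozenset[str]]:
        """Classes for matching: N accepts anything, including sequence N."""
        return [
            frozenset("ACGTN") if c == "N" else IUPAC_CLASSES[c] for c in self.iupac
        ]


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence in a gene's promoter.

    ``offset`` is relative to the TSS (negative = upstream) and refers to
    the 5'-most base of the matched window on the gene's forward strand.
    """

    gene_id: str
    offset: int
    strand_of_hit: str
    matched: str


def parse_slash_consensus(text: str, name: str = "consensus") -> MotifPattern:
    """Parse slash notation like ``TT/GAC/GTC/AA`` into an IUPAC pattern.

    Each position is a base optionally followed by ``/alternative``; the
    two allowed bases collapse to their IUPAC two-base code (the YRE above
    becomes ``TKASTMA``).
    """
    text = text.strip().upper()
    codes: list[str] = []
    i = 0
    while i < len(text):
        base = text[i]
        if base not in "ACGT":
            raise ValueError(f"malformed consensus at position {i}: {text!r}")
        i += 1
        if i < len(text) and text[i] == "/":
            i += 1
            if i >= len(text) or text[i] not in "ACGT":
                raise ValueError(f"malformed consensus near '/' in {text!r}")
            codes.append(_CLASS_TO_CODE[frozenset({base, text[i]})])
            i += 1
        else:
            codes.append(base)
    return MotifPattern(name=name, iupac="".join(codes))


YRE = parse_slash_consensus("TT/GAC/GTC/AA", name="YRE")
# Not derived from this study; standard PDRE core from the pleiotropic
# drug resistance literature, override via configuration.
PDRE_DEFAULT = MotifPattern(name="PDRE", iupac="TCCGCGGA")


def _window_matches(window: str, classes: list[frozenset[str]]) -> bool:
    return all(b in cls for b, cls in zip(window, classes))


def scan_sequence(
    seq: str, pattern: MotifPattern, both_strands: bool = True
) -> list[tuple[int, str, str]]:
    """Scan one sequence; return ``(offset, strand, matched)`` tuples.

    Offsets index the forward sequence (0-based window start).  A reverse
    hit means the reverse complement of the window matches the pattern;
    its ``matched`` string is that reverse complement.
    """
    seq = seq.upper()
    classes = pattern.match_classes()
    m = len(pattern)
    hits: list[tuple[int, str, str]] = []
    for i in range(len(seq) - m + 1):
        window = seq[i : i + m]
        if _window_matches(window, classes):
            hits.append((i, "+", window))
        if both_strands:
            rc = reverse_complement(window)
            if _window_matches(rc, classes):
                hits.append((i, "-", rc))
    return hits


def scan_promoter(
    gene_id: str, promoter: str, pattern: MotifPattern, both_strands: bool = True
) -> list[MotifHit]:
    """Scan a promoter given 5'->3' ending just before the TSS (-len..-1)."""
    length = len(promoter)
    return [
        MotifHit(gene_id=gene_id, offset=i - length, strand_of_hit=strand, matched=matched)
        for i, strand, matched in scan_sequence(promoter, pattern, both_strands)
    ]


def promoter_motif_fraction(
    targets: AbstractSet[str],
    promoters: Mapping[str, str],
    pattern: MotifPattern,
    both_strands: bool = True,
) -> tuple[int, float]:
    """Fraction of target genes whose promoter contains >= 1 motif hit.

    A gene counts once regardless of hit multiplicity.  Raises ``KeyError``
    if a target lacks a promoter sequence.
    """
    missing = set(targets) - set(promoters)
    if missing:
        raise KeyError(f"targets without promoter sequence: {sorted(missing)[:5]}")
    n_with = sum(
        1 for g in targets if scan_sequence(promoters[g], pattern, both_strands)
    )
    fraction = n_with / len(targets) if targets else 0.0
    return n_with, fraction
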