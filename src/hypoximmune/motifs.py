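"""IUPAC motif scanning over TSS-relative promoter windows.

Coordinate convention
---------------------
Promoter sequences are oriented 5'->3' on the gene strand and end at the base
immediately upstream of the transcription start site (TSS), which is position
-1. A hit's ``position`` is the TSS-relative offset of its 5'-most base on the
gene strand (always negative for upstream windows), so a pattern of length m at
position p occupies [p, p+m) with p + m <= 0. Minus-strand hits are reported at
the same gene-strand window with ``matched`` given as read on the minus strand.

Built-in motif library
----------------------
* HRE canonical core RCGTG (HIF dimers favour A over G at the R position) and
  the non-canonical variant CCGTG, optionally annotated with a nearby CAC
  trimer.
* AP-1 canonical core TGASTCA plus the non-canonical variants TGCATCA and
  TGCGTCA.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

__all__ = [
    "IUPAC_SETS",
    "MOTIF_CLASSES",
    "MotifPattern",
    "PromoterSequence",
    "MotifHit",
    "HRE_CANONICAL",
    "HRE_NONCANONICAL",
    "AP1_CANONICAL",
    "AP1_NONCANONICAL",
    "reverse_complement",
    "iupac_match",
    "scan",
    "find_hre",
    "find_ap1",
    "count_literal",
    "extract_upstream",
]

# Degenerate-base expansion. A sequence N matches only the pattern symbol N.
IUPAC_SETS: Dict[str, frozenset] = {
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
    "N": frozenset("ACGTN"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

MOTIF_CLASSES = (
    "HRE_canonical",
    "HRE_noncanonical",
    "AP1_canonical",
    "AP1_noncanonical",
    "literal",
)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA/IUPAC string (case-insensitive, upper out)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifPattern:
    """An IUPAC pattern with a motif-class label."""

    name: str
    iupac: str
    motif_class: str = "literal"

    def __post_init__(self):
        pattern = self.iupac.upper()
        if not pattern:
            raise ValueError("empty IUPAC pattern")
        bad = set(pattern) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"invalid IUPAC symbols {sorted(bad)} in {self.iupac!r}")
        if self.motif_class not in MOTIF_CLASSES:
            raise ValueError(f"unknown motif class {self.motif_class!r}")
        object.__setattr__(self, "iupac", pattern)

    def __len__(self) -> int:
        return len(self.iupac)

    @property
    def is_literal(self) -> bool:
        return set(self.iupac) <= set("ACGT")

    def regex(self) -> "re.Pattern[str]":
        parts = []
        for sym in self.iupac:
            bases = "".join(sorted(IUPAC_SETS[sym]))
            parts.append(bases if len(bases) == 1 else f"[{bases}]")
        return re.compile("".join(parts))


HRE_CANONICAL = MotifPattern("HRE_RCGTG", "RCGTG", "HRE_canonical")
HRE_NONCANONICAL = MotifPattern("HRE_CCGTG", "CCGTG", "HRE_noncanonical")
AP1_CANONICAL = MotifPattern("AP1_TGASTCA", "TGASTCA", "AP1_canonical")
AP1_NONCANONICAL = (
    MotifPattern("AP1_TGCATCA", "TGCATCA", "AP1_noncanonical"),
    MotifPattern("AP1_TGCGTCA", "TGCGTCA", "AP1_noncanonical"),
)


@dataclass(frozen=True)
class PromoterSequence:
    """A gene-strand promoter sequence whose final base is TSS position -1."""

    sequence: str
    source_id: Optional[str] = None
    mask_lowercase_as_n: bool = False

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty promoter sequence")
        seq = self.sequence
        seq = "".join("N" if c.islower() else c for c in seq) if self.mask_lowercase_as_n else seq.upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"non-DNA characters in promoter: {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifHit:
    """A strand-aware match at a TSS-relative position.

    ``position`` is the gene-strand 5'-most base of the match; ``matched`` is
    the sequence as read on ``strand`` (reverse complement of the gene-strand
    window for minus-strand hits).
    """

    pattern_name: str
    position: int
    strand: str
    matched: str
    motif_class: str = "literal"
    nearby_cac: Optional[bool] = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid hit strand {self.strand!r}")
        if self.position + len(self.matched) > 0:
            raise ValueError(
                f"hit at {self.position} of length {len(self.matched)} extends past the TSS"
            )


def iupac_match(pattern: MotifPattern, window: str) -> bool:
    """True iff every base of ``window`` is in the IUPAC set of the pattern
    symbol at that position. ``window`` must have the pattern's length."""
    window = window.upper()
    if len(window) != len(pattern):
        raise ValueError(
            f"window length {len(window)} != pattern length {len(pattern)}"
        )
    return all(base in IUPAC_SETS[sym] for sym, base in zip(pattern.iupac, window))


def _scan_indices(sequence: str, pattern: MotifPattern) -> List[int]:
    """0-based start indices of (possibly overlapping) matches on the given strand."""
    rx = pattern.regex()
    hits = []
    pos = 0
    while True:
        m = rx.search(sequence, pos)
        if m is None:
            break
        hits.append(m.start())
        pos = m.start() + 1
    return hits


def scan(
    promoter: PromoterSequence,
    pattern: MotifPattern,
    strand_mode: str = "gene_strand_only",
) -> List[MotifHit]:
    """All matches of ``pattern`` in the promoter, ordered by increasing
    (more negative -> less negative) position; overlapping matches all reported.

    With ``strand_mode="both"`` the reverse complement of the pattern is also
    scanned and its hits reported with strand '-' at the gene-strand position
    of the window's leftmost base.
    """
    if strand_mode not in ("gene_strand_only", "both"):
        raise ValueError(f"invalid strand_mode {strand_mode!r}")
    seq = promoter.sequence
    L = len(seq)
    m = len(pattern)
    hits: List[MotifHit] = []
    for i in _scan_indices(seq, pattern):
        hits.append(
            MotifHit(pattern.name, i - L, "+", seq[i : i + m], pattern.motif_class)
        )
    if strand_mode == "both":
        rc_pattern = MotifPattern(pattern.name, reverse_complement(pattern.iupac), pattern.motif_class)
        for i in _scan_indices(seq, rc_pattern):
            hits.append(
                MotifHit(
                    pattern.name,
                    i - L,
                    "-",
                    reverse_complement(seq[i : i + m]),
                    pattern.motif_class,
                )
            )
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def _has_nearby_cac(seq: str, start: int, end: int, cac_window: int) -> bool:
    """CAC entirely outside [start, end) with its 5' base within
    ``cac_window`` bp of either end of the match."""
    upstream = seq[max(0, start - cac_window) : start]
    if "CAC" in upstream:
        return True
    downstream = seq[end : end + cac_window + 2]
    j = downstream.find("CAC")
    return 0 <= j < cac_window


def find_hre(
    promoter: PromoterSequence,
    include_noncanonical: bool = True,
    cac_window: int = 20,
    strand_mode: str = "gene_strand_only",
) -> List[MotifHit]:
    """Scan the canonical HRE core RCGTG and (optionally) the non-canonical
    CCGTG variant, annotating each hit with whether a CAC trimer lies within
    ``cac_window`` bp of either end of the match (bases inside the match are
    excluded)."""
    if cac_window < 0:
        raise ValueError("cac_window must be >= 0")
    patterns = [HRE_CANONICAL]
    if include_noncanonical:
        patterns.append(HRE_NONCANONICAL)
    seq = promoter.sequence
    L = len(seq)
    hits: List[MotifHit] = []
    for pattern in patterns:
        for hit in scan(promoter, pattern, strand_mode):
            i = hit.position + L
            hits.append(
                MotifHit(
                    hit.pattern_name,
                    hit.position,
                    hit.strand,
                    hit.matched,
                    hit.motif_class,
                    nearby_cac=_has_nearby_cac(seq, i, i + len(pattern), cac_window),
                )
            )
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def find_ap1(
    promoter: PromoterSequence,
    strand_mode: str = "gene_strand_only",
) -> List[MotifHit]:
    """Scan the canonical AP-1 core TGASTCA and the non-canonical variants
    TGCATCA and TGCGTCA; hits carry their motif-class label."""
    hits: List[MotifHit] = []
    for pattern in (AP1_CANONICAL, *AP1_NONCANONICAL):
        hits.extend(scan(promoter, pattern, strand_mode))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def count_literal(
    seq: str,
    patterns: Sequence[str],
    strand_mode: str = "gene_strand_only",
) -> Dict[str, int]:
    """Per-pattern count of (possibly overlapping) literal occurrences under
    the chosen strand mode. Patterns must be literal ACGT strings."""
    if strand_mode not in ("gene_strand_only", "both"):
        raise ValueError(f"invalid strand_mode {strand_mode!r}")
    seq = seq.upper()
    counts: Dict[str, int] = {}
    for raw in patterns:
        pat = raw.upper()
        if not pat or set(pat) - set("ACGT"):
            raise ValueError(f"pattern {raw!r} is not a literal ACGT string")
        n = len(_scan_indices(seq, MotifPattern(pat, pat)))
        if strand_mode == "both":
            rc = reverse_complement(pat)
            n += len(_scan_indices(seq, MotifPattern(rc, rc)))
        counts[raw] = n
    return counts


def extract_upstream(
    chrom_sequence: str,
    tss: int,
    gene_strand: str,
    length: int,
    source_id: Optional[str] = None,
) -> PromoterSequence:
    """Extract the ``length`` bp immediately upstream of a TSS.

    ``tss`` is the 0-based position of the first transcribed base. For +-strand
    genes this is ``[tss-length, tss)``; for --strand genes the reverse
    complement of ``(tss, tss+length]``, i.e. ``[tss+1, tss+1+length)``. The
    returned string's final base is promoter position -1.
    """
    if gene_strand not in ("+", "-"):
        raise ValueError(f"invalid gene strand {gene_strand!r}")
    if length <= 0:
        raise ValueError("length must be positive")
    n = len(chrom_sequence)
    if gene_strand == "+":
        lo, hi = tss - length, tss
        if lo < 0 or hi > n:
            raise ValueError(f"upstream window [{lo}, {hi}) out of bounds for length-{n} sequence")
        window = chrom_sequence[lo:hi].upper()
    else:
        lo, hi = tss + 1, tss + 1 + length
        if lo < 0 or hi > n:
            raise ValueError(f"upstream window [{lo}, {hi}) out of bounds for length-{n} sequence")
        window = reverse_complement(chrom_sequence[lo:hi])
    return PromoterSequence(window, source_id=source_id)
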