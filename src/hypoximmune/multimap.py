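"""Homology-aware multi-mapping audit.

Multi-mapping reads over a target locus (e.g. the highly homologous
FCGR2B/FCGR2C pair) are checked against a declared set of homologous partner
regions: a read is *on-target* when at least one of its reported alignments
overlaps the target region, and *confined* when every one of its alignments
overlaps some allowed region. Escaping reads — on-target reads with an
alignment outside the allowed set — are listed by id.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

from .intervals import GenomicInterval, IntervalCollection

__all__ = [
    "ReadAlignments",
    "HomologySpec",
    "AuditReport",
    "AlignmentParseError",
    "audit",
    "read_alignment_table",
]

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_REF_CONSUMING = set("MDN=X")


class AlignmentParseError(ValueError):
    """An alignment line could not be parsed; the message names the line number."""


@dataclass(frozen=True)
class ReadAlignments:
    """One read's full set of reported alignment positions."""

    read_id: str
    alignments: Sequence[GenomicInterval]

    def __post_init__(self):
        if not self.alignments:
            raise ValueError(f"read {self.read_id!r} has no alignments")
        object.__setattr__(self, "alignments", tuple(self.alignments))


@dataclass(frozen=True)
class HomologySpec:
    """The region of interest and its allowed homologous partner regions
    (which include the target itself)."""

    target: GenomicInterval
    allowed: IntervalCollection

    def __post_init__(self):
        if not any(self.target.overlaps(iv) for iv in self.allowed):
            raise ValueError("target region overlaps no allowed interval")


@dataclass
class AuditReport:
    n_reads_on_target: int
    n_confined: int
    n_escaping: int
    escaping_ids: List[str]

    @property
    def confined(self) -> bool:
        return self.n_escaping == 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_reads_on_target": self.n_reads_on_target,
                "n_confined": self.n_confined,
                "n_escaping": self.n_escaping,
                "confined": self.confined,
                "escaping_ids": self.escaping_ids,
            },
            indent=2,
        )

    def summary(self) -> str:
        verdict = (
            "all multi-mapping confined to the declared homologous regions"
            if self.confined
            else f"{self.n_escaping} read(s) align outside the declared homologous regions"
        )
        return (
            f"reads on target: {self.n_reads_on_target}\n"
            f"confined: {self.n_confined}\n"
            f"escaping: {self.n_escaping}\n"
            f"verdict: {verdict}"
        )


def audit(reads: Sequence[ReadAlignments], spec: HomologySpec) -> AuditReport:
    """Tally on-target reads into confined vs escaping.

    Independent of the order of reads and of alignments within a read;
    escaping ids are reported sorted.
    """
    allowed = list(spec.allowed)
    n_on_target = 0
    escaping: List[str] = []
    for read in reads:
        if not any(a.overlaps(spec.target) for a in read.alignments):
            continue
        n_on_target += 1
        confined = all(
            any(a.overlaps(h) for h in allowed) for a in read.alignments
        )
        if not confined:
            escaping.append(read.read_id)
    escaping.sort()
    return AuditReport(
        n_reads_on_target=n_on_target,
        n_confined=n_on_target - len(escaping),
        n_escaping=len(escaping),
        escaping_ids=escaping,
    )


def _cigar_reference_span(cigar: str, lineno: int) -> int:
    total = 0
    consumed = 0
    for m in _CIGAR_RE.finditer(cigar):
        n, op = int(m.group(1)), m.group(2)
        consumed += len(m.group(0))
        if op in _REF_CONSUMING:
            total += n
    if consumed != len(cigar) or total == 0:
        raise AlignmentParseError(f"line {lineno}: unparseable CIGAR {cigar!r}")
    return total


def read_alignment_table(path) -> List[ReadAlignments]:
    """Read alignments from a plain-text SAM subset or a 4-column TSV.

    SAM subset: header lines starting with '@' are skipped; each record needs
    QNAME, FLAG, RNAME, 1-based POS and a CIGAR (M/I/D/N/S/=/X); records with
    the unmapped bit (0x4) or RNAME '*' are skipped, and the reference span is
    the sum of reference-consuming CIGAR operations (M, D, N, =, X).
    TSV dialect: read_id, chrom, start (0-based), end (exclusive).
    Alignments are grouped by read name in first-seen order.
    """
    grouped: Dict[str, List[GenomicInterval]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("@") or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 4:
                read_id, chrom, s, e = fields
                try:
                    start, end = int(s), int(e)
                except ValueError as exc:
                    raise AlignmentParseError(
                        f"{path}: line {lineno}: non-integer coordinates"
                    ) from exc
                if not (0 <= start < end):
                    raise AlignmentParseError(
                        f"{path}: line {lineno}: invalid interval {start}-{end}"
                    )
                grouped.setdefault(read_id, []).append(GenomicInterval(chrom, start, end))
            elif len(fields) >= 6:
                read_id, flag_s, rname, pos_s, _mapq, cigar = fields[:6]
                try:
                    flag = int(flag_s)
                    pos = int(pos_s)
                except ValueError as exc:
                    raise AlignmentParseError(
                        f"{path}: line {lineno}: non-integer FLAG/POS"
                    ) from exc
                if flag & 0x4 or rname == "*":
                    continue
                span = _cigar_reference_span(cigar, lineno)
                start = pos - 1
                grouped.setdefault(read_id, []).append(
                    GenomicInterval(rname, start, start + span)
                )
            else:
                raise AlignmentParseError(
                    f"{path}: line {lineno}: expected 4 (TSV) or >=6 (SAM) fields, got {len(fields)}"
                )
    return [ReadAlignments(rid, ivs) for rid, ivs in grouped.items()]
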