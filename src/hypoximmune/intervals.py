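"""Genome model, genomic intervals, BED I/O and uniform random interval sampling.

All coordinates are 0-based, half-open (BED convention). Overlap throughout the
package means >= 1 bp intersection and is strand-blind.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "GenomeModel",
    "GenomicInterval",
    "IntervalCollection",
    "BedParseError",
    "ValidationError",
    "SamplingError",
    "read_bed",
    "write_bed",
    "count_overlapping_sites",
    "sample_random_intervals",
    "derive_replicate_seed",
]


class BedParseError(ValueError):
    """A BED line could not be parsed; the message names the line number."""


class ValidationError(ValueError):
    """An interval violates the attached genome model."""


class SamplingError(RuntimeError):
    """Random interval placement is impossible or exceeded the rejection cap."""


class GenomeModel:
    """Named chromosomes with their lengths in bp.

    Parameters
    ----------
    entries
        Mapping of chromosome name to length. Every length must be positive.
    """

    def __init__(self, entries: Mapping[str, int]):
        entries = dict(entries)
        for name, length in entries.items():
            if int(length) <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        self.entries: Dict[str, int] = {name: int(length) for name, length in entries.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.entries

    def __getitem__(self, chrom: str) -> int:
        return self.entries[chrom]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GenomeModel) and self.entries == other.entries

    def __repr__(self) -> str:
        return f"GenomeModel({self.entries!r})"

    @property
    def total_length(self) -> int:
        return sum(self.entries.values())

    @classmethod
    def from_file(cls, path) -> "GenomeModel":
        """Read a two-column chrom-sizes text file (name, length)."""
        entries: Dict[str, int] = {}
        for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"chrom-sizes line {i}: expected 2 columns, got {len(parts)}")
            entries[parts[0]] = int(parts[1])
        return cls(entries)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in self.entries.items():
                fh.write(f"{name}\t{length}\n")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "requires 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """>=1 bp intersection, strand-blind."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class IntervalCollection:
    """An ordered sequence of :class:`GenomicInterval` with an optional genome.

    On construction every interval is validated against the genome (when one is
    attached). ``normalize()`` sorts by (chrom, start, end).
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        genome: Optional[GenomeModel] = None,
    ):
        self.intervals: List[GenomicInterval] = list(intervals)
        self.genome = genome
        if genome is not None:
            self.validate()
        self._arrays_cache: Optional[Dict[str, Tuple[np.ndarray, np.ndarray]]] = None

    def validate(self) -> None:
        if self.genome is None:
            return
        for iv in self.intervals:
            if iv.chrom not in self.genome:
                raise ValidationError(f"chromosome {iv.chrom!r} absent from genome model")
            if iv.end > self.genome[iv.chrom]:
                raise ValidationError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} extends past "
                    f"chromosome end {self.genome[iv.chrom]}"
                )

    def normalize(self) -> "IntervalCollection":
        """Return a copy sorted by (chrom, start, end)."""
        ordered = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        return IntervalCollection(ordered, genome=self.genome)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __getitem__(self, idx):
        return self.intervals[idx]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, IntervalCollection) and self.intervals == other.intervals
        )

    def __repr__(self) -> str:
        return f"IntervalCollection(n={len(self.intervals)}, genome={self.genome is not None})"

    @property
    def lengths(self) -> List[int]:
        return [iv.length for iv in self.intervals]

    def chrom_arrays(self) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) arrays sorted by start (cached)."""
        if self._arrays_cache is None:
            by_chrom: Dict[str, List[Tuple[int, int]]] = {}
            for iv in self.intervals:
                by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
            out: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
            for chrom, pairs in by_chrom.items():
                pairs.sort()
                arr = np.asarray(pairs, dtype=np.int64)
                out[chrom] = (arr[:, 0].copy(), arr[:, 1].copy())
            self._arrays_cache = out
        return self._arrays_cache

    def merged_arrays(self) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome merged (union) interval arrays, sorted and disjoint."""
        out: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends) in self.chrom_arrays().items():
            m_starts: List[int] = []
            m_ends: List[int] = []
            for s, e in zip(starts.tolist(), ends.tolist()):
                if m_ends and s <= m_ends[-1]:
                    if e > m_ends[-1]:
                        m_ends[-1] = e
                else:
                    m_starts.append(s)
                    m_ends.append(e)
            out[chrom] = (
                np.asarray(m_starts, dtype=np.int64),
                np.asarray(m_ends, dtype=np.int64),
            )
        return out


def read_bed(path, genome: Optional[GenomeModel] = None) -> IntervalCollection:
    """Parse BED3+ into an :class:`IntervalCollection`.

    Columns 4-6 map to name/score/strand when present; ``track``, ``browser``
    and ``#`` comment lines are skipped. Coordinates are kept 0-based half-open.
    """
    intervals: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields"
                )
            chrom = fields[0]
            try:
                start = int(fields[1])
                end = int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if not (0 <= start < end):
                raise BedParseError(
                    f"{path}: line {lineno}: invalid coordinates start={start} end={end}"
                )
            name = None
            score = None
            strand = "."
            if len(fields) >= 4 and fields[3] != ".":
                name = fields[3]
            if len(fields) >= 5 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(
                        f"{path}: line {lineno}: non-numeric score {fields[4]!r}"
                    ) from exc
            if len(fields) >= 6:
                if fields[5] not in ("+", "-", "."):
                    raise BedParseError(
                        f"{path}: line {lineno}: invalid strand {fields[5]!r}"
                    )
                strand = fields[5]
            intervals.append(
                GenomicInterval(chrom, start, end, strand=strand, name=name, score=score)
            )
    return IntervalCollection(intervals, genome=genome)


def write_bed(coll: IntervalCollection, path) -> None:
    """Write BED6 when any name/score/strand is present, else BED3.

    ``read_bed(write_bed(x))`` reproduces ``x``'s intervals exactly.
    """
    bed6 = any(
        iv.name is not None or iv.score is not None or iv.strand != "."
        for iv in coll
    )
    with open(path, "w") as fh:
        for iv in coll:
            if bed6:
                name = iv.name if iv.name is not None else "."
                score = "." if iv.score is None else format(iv.score, "g")
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def _count_overlaps_arrays(
    site_starts: np.ndarray,
    site_ends: np.ndarray,
    merged_starts: np.ndarray,
    merged_ends: np.ndarray,
) -> np.ndarray:
    """Boolean vector: does each site overlap the merged (disjoint) interval set."""
    if len(merged_starts) == 0 or len(site_starts) == 0:
        return np.zeros(len(site_starts), dtype=bool)
    # rightmost merged interval starting strictly before the site end
    idx = np.searchsorted(merged_starts, site_ends, side="left") - 1
    hit = idx >= 0
    hit[hit] = merged_ends[idx[hit]] > site_starts[hit]
    return hit


def count_overlapping_sites(
    sites: IntervalCollection,
    peaks: IntervalCollection,
    count_pairs: bool = False,
) -> int:
    """Number of site records with >= 1 bp intersection with at least one peak.

    Each site counts at most once regardless of how many peaks it touches;
    with ``count_pairs=True`` every overlapping site x peak pair counts instead.
    Strand is ignored. Empty inputs give 0.
    """
    if len(sites) == 0 or len(peaks) == 0:
        return 0
    if not count_pairs:
        merged = peaks.merged_arrays()
        total = 0
        for chrom, (s_starts, s_ends) in sites.chrom_arrays().items():
            if chrom not in merged:
                continue
            m_starts, m_ends = merged[chrom]
            total += int(_count_overlaps_arrays(s_starts, s_ends, m_starts, m_ends).sum())
        return total
    # pair counting: per site, #peaks - #(peaks entirely left) - #(peaks entirely right)
    peak_arrays = peaks.chrom_arrays()
    total = 0
    for chrom, (s_starts, s_ends) in sites.chrom_arrays().items():
        if chrom not in peak_arrays:
            continue
        p_starts, p_ends = peak_arrays[chrom]
        p_ends_sorted = np.sort(p_ends)
        n = len(p_starts)
        right = n - np.searchsorted(p_starts, s_ends, side="left")  # p_start >= s_end
        left = np.searchsorted(p_ends_sorted, s_starts, side="right")  # p_end <= s_start
        total += int((n - right - left).sum())
    return total


def derive_replicate_seed(seed: int, replicate: int) -> np.random.SeedSequence:
    """Per-replicate seed so permutation replicates are independent and
    individually reproducible: replicate r uses SeedSequence(seed, spawn_key=(r,))."""
    return np.random.SeedSequence(seed, spawn_key=(replicate,))


def _sample_starts(
    genome: GenomeModel,
    lengths: Sequence[int],
    rng: np.random.Generator,
    mask_merged: Optional[Dict[str, Tuple[np.ndarray, np.ndarray]]] = None,
    max_attempts: int = 1000,
) -> List[Tuple[str, int, int]]:
    """Draw one (chrom, start, end) per requested length, uniform over all
    valid start positions across chromosomes."""
    chroms = list(genome.entries)
    chrom_lengths = np.asarray([genome.entries[c] for c in chroms], dtype=np.int64)
    placements: List[Tuple[str, int, int]] = []
    for length in lengths:
        length = int(length)
        if length <= 0:
            raise SamplingError(f"requested interval length {length} must be positive")
        valid = np.maximum(chrom_lengths - length + 1, 0)
        total = int(valid.sum())
        if total == 0:
            raise SamplingError(
                f"no chromosome can hold an interval of length {length}"
            )
        probs = valid / total
        for attempt in range(max_attempts):
            ci = int(rng.choice(len(chroms), p=probs))
            start = int(rng.integers(0, valid[ci]))
            chrom, end = chroms[ci], start + length
            if mask_merged is not None and chrom in mask_merged:
                m_starts, m_ends = mask_merged[chrom]
                hit = _count_overlaps_arrays(
                    np.asarray([start]), np.asarray([end]), m_starts, m_ends
                )[0]
                if hit:
                    continue
            placements.append((chrom, start, end))
            break
        else:
            raise SamplingError(
                f"could not place an interval of length {length} disjoint from the "
                f"mask within {max_attempts} attempts"
            )
    return placements


def sample_random_intervals(
    genome: GenomeModel,
    lengths: Sequence[int],
    seed,
    mask: Optional[IntervalCollection] = None,
) -> IntervalCollection:
    """Uniform random placement of one interval per requested length.

    The chromosome is chosen with probability proportional to its number of
    valid start positions for that length, then the start uniformly among them;
    intervals never extend past a chromosome end and may overlap one another.
    With ``mask`` given, placements overlapping the mask are rejected and
    redrawn (cap: 1000 attempts per interval). Same seed + inputs => identical
    output. ``seed`` may be an int or a ``numpy.random.SeedSequence``.
    """
    if isinstance(seed, np.random.SeedSequence):
        rng = np.random.default_rng(seed)
    else:
        rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    mask_merged = mask.merged_arrays() if mask is not None else None
    placements = _sample_starts(genome, lengths, rng, mask_merged)
    intervals = [GenomicInterval(c, s, e) for c, s, e in placements]
    return IntervalCollection(intervals, genome=genome)
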