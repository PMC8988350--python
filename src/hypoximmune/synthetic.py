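"""Synthetic-data generators with recorded ground truth.

Every generator is a pure function of (parameters, seed): repeated calls are
bit-identical, and the returned :class:`SimulationTruth` is sufficient to score
the corresponding pipeline stage. The defaults emulate the study conditions
the package's analyses target: a 1 Mb toy genome with ~20 accessible-chromatin
peaks of ~500 bp, TF binding sites at a background density of 500 per Mb with
an in-peak density ratio rho, 1-15 kb promoters with motifs planted at known
TSS-relative offsets, paired flow panels with a tenfold A:I ratio difference,
and reads multi-mapping between two homologous segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .enrichment import TFSiteAnnotation
from .immuno import (
    ACTIVATING_MARKERS,
    INHIBITORY_MARKER,
    FcgrPanel,
    MarkerMeasurement,
)
from .intervals import GenomeModel, GenomicInterval, IntervalCollection
from .motifs import PromoterSequence, reverse_complement
from .multimap import HomologySpec, ReadAlignments

__all__ = [
    "SimulationTruth",
    "SimulationError",
    "DEFAULT_GC",
    "DEFAULT_SITE_LEN",
    "DEFAULT_BACKGROUND_DENSITY_PER_MB",
    "simulate_genome",
    "simulate_peaks",
    "plant_tf_sites",
    "simulate_promoter",
    "simulate_homolog_reads",
    "simulate_flow_panels",
]

DEFAULT_GC = 0.41  # human-like background base composition
DEFAULT_SITE_LEN = 10
DEFAULT_BACKGROUND_DENSITY_PER_MB = 500.0

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationError(RuntimeError):
    """A generator could not satisfy its constraints."""


@dataclass
class SimulationTruth:
    """Ground truth recorded by a generator, sufficient to score the stage."""

    seed: int
    planted_motifs: List[Tuple[str, int]] = field(default_factory=list)
    tf_enrichment: Dict[str, float] = field(default_factory=dict)
    decoy_read_ids: List[str] = field(default_factory=list)
    panel_ratios: List[Tuple[float, float]] = field(default_factory=list)


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(int(seed)))


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def simulate_genome(
    chrom_lengths: Mapping[str, int],
    gc: float = DEFAULT_GC,
    seed: int = 0,
) -> Tuple[Dict[str, str], GenomeModel]:
    """i.i.d. random chromosome sequences with P(G)+P(C)=gc split evenly and
    P(A)=P(T). Returns (sequences, GenomeModel)."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc={gc} must lie in [0, 1]")
    model = GenomeModel(chrom_lengths)  # validates positive lengths
    rng = _rng(seed)
    seqs = {
        name: _random_bases(rng, length, gc).tobytes().decode("ascii")
        for name, length in model.entries.items()
    }
    return seqs, model


def simulate_peaks(
    genome: GenomeModel,
    n: int,
    length_mean: int = 500,
    length_sd: float = 50.0,
    seed: int = 0,
    max_attempts_per_peak: int = 1000,
) -> IntervalCollection:
    """``n`` pairwise-disjoint intervals; lengths ~ Normal(mean, sd) truncated
    at [50, inf) and rounded; placement uniform with rejection of overlaps."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    lengths = np.maximum(np.rint(rng.normal(length_mean, length_sd, size=n)), 50).astype(int)
    chroms = list(genome.entries)
    chrom_lengths = np.asarray([genome.entries[c] for c in chroms], dtype=np.int64)
    placed: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}
    out: List[GenomicInterval] = []
    for k, length in enumerate(lengths.tolist()):
        valid = np.maximum(chrom_lengths - length + 1, 0)
        total = int(valid.sum())
        if total == 0:
            raise SimulationError(f"no chromosome can hold a peak of length {length}")
        probs = valid / total
        for _ in range(max_attempts_per_peak):
            ci = int(rng.choice(len(chroms), p=probs))
            start = int(rng.integers(0, valid[ci]))
            end = start + length
            if any(start < e and s < end for s, e in placed[chroms[ci]]):
                continue
            placed[chroms[ci]].append((start, end))
            out.append(GenomicInterval(chroms[ci], start, end, name=f"peak_{k}"))
            break
        else:
            raise SimulationError(
                f"could not place {n} disjoint peaks (failed at peak {k})"
            )
    return IntervalCollection(out, genome=genome).normalize()


def _segment_complement(
    genome: GenomeModel, peaks: IntervalCollection
) -> Dict[str, List[Tuple[int, int]]]:
    """Non-peak segments per chromosome (whole chromosomes when peak-free)."""
    merged = peaks.merged_arrays()
    segments: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, clen in genome.entries.items():
        segs: List[Tuple[int, int]] = []
        pos = 0
        if chrom in merged:
            for s, e in zip(*[a.tolist() for a in merged[chrom]]):
                if s > pos:
                    segs.append((pos, s))
                pos = e
        if pos < clen:
            segs.append((pos, clen))
        segments[chrom] = segs
    return segments


def _place_in_segments(
    rng: np.random.Generator,
    segments: Sequence[Tuple[str, int, int]],
    count: int,
    site_len: int,
) -> List[Tuple[str, int]]:
    """Uniformly place ``count`` sites fully inside the given segments."""
    valid = np.asarray([max(0, e - s - site_len + 1) for _, s, e in segments], dtype=np.int64)
    total = int(valid.sum())
    if total == 0:
        if count > 0:
            raise SimulationError("no room to place sites in the given segments")
        return []
    probs = valid / total
    seg_idx = rng.choice(len(segments), size=count, p=probs)
    out = []
    for i in seg_idx.tolist():
        chrom, s, _ = segments[i]
        out.append((chrom, s + int(rng.integers(0, valid[i]))))
    return out


def plant_tf_sites(
    genome: GenomeModel,
    peaks: IntervalCollection,
    tf_specs: Mapping[str, Tuple[int, float, float]],
    seed: int = 0,
) -> Tuple[TFSiteAnnotation, SimulationTruth]:
    """Plant per-TF binding sites at background density outside peaks and at
    ``rho`` times that density inside peaks.

    ``tf_specs`` maps TF name -> (site_len bp, background density per Mb, rho).
    Counts are Poisson with mean density x space (in Mb); placement is uniform
    over the corresponding space, so rho=1 is a homogeneous Poisson placement
    genome-wide in distribution. Truth records rho per TF.
    """
    rng = _rng(seed)
    complement = _segment_complement(genome, peaks)
    bg_segments = [(c, s, e) for c, segs in complement.items() for s, e in segs]
    peak_segments = [(iv.chrom, iv.start, iv.end) for iv in peaks]
    bg_bp = sum(e - s for _, s, e in bg_segments)
    peak_bp = sum(e - s for _, s, e in peak_segments)
    per_tf: Dict[str, IntervalCollection] = {}
    truth = SimulationTruth(seed=seed)
    for tf, (site_len, density_per_mb, rho) in tf_specs.items():
        if rho < 0:
            raise ValueError(f"{tf}: rho must be >= 0, got {rho}")
        n_bg = int(rng.poisson(density_per_mb * bg_bp / 1e6))
        n_peak = int(rng.poisson(density_per_mb * rho * peak_bp / 1e6)) if peak_bp else 0
        placements = _place_in_segments(rng, bg_segments, n_bg, site_len)
        placements += _place_in_segments(rng, peak_segments, n_peak, site_len)
        intervals = [
            GenomicInterval(c, s, s + site_len, name=f"{tf}_site_{i}")
            for i, (c, s) in enumerate(placements)
        ]
        per_tf[tf] = IntervalCollection(intervals, genome=genome).normalize()
        truth.tf_enrichment[tf] = float(rho)
    return TFSiteAnnotation(per_tf), truth


def _find_any(seq: str, patterns: Sequence[str], skip_starts: frozenset) -> Optional[Tuple[int, str]]:
    """First occurrence of any pattern whose start is not an exempt (planted)
    position of that same pattern."""
    best: Optional[Tuple[int, str]] = None
    for pat in patterns:
        pos = seq.find(pat)
        while pos >= 0:
            if (pos, pat) not in skip_starts:
                if best is None or pos < best[0]:
                    best = (pos, pat)
                break
            pos = seq.find(pat, pos + 1)
    return best


def simulate_promoter(
    length: int,
    plants: Sequence[Tuple[str, int]] = (),
    seed: int = 0,
    forbid_spurious: Sequence[str] = (),
    gc: float = DEFAULT_GC,
    max_redraws: int = 1_000_000,
) -> Tuple[PromoterSequence, SimulationTruth]:
    """A random promoter with literal motifs planted at exact TSS-relative
    positions and no accidental gene-strand occurrence of any planted or
    forbidden pattern elsewhere.

    ``plants`` is a sequence of (literal motif, TSS-relative position of the
    motif's 5' base); positions lie in [-length, -len(motif)] and plants must
    not overlap. Accidental occurrences in the background are redrawn until
    absent (cap ``max_redraws`` single-base redraws).
    """
    if length <= 0:
        raise ValueError("length must be positive")
    plant_list: List[Tuple[str, int]] = []
    occupied: List[Tuple[int, int]] = []
    for motif, pos in plants:
        motif = motif.upper()
        if set(motif) - set("ACGT"):
            raise ValueError(f"planted motif {motif!r} must be a literal ACGT string")
        if not (-length <= pos <= -len(motif)):
            raise ValueError(
                f"plant position {pos} out of range [{-length}, {-len(motif)}] "
                f"for motif of length {len(motif)}"
            )
        start = length + pos
        for s, e in occupied:
            if start < e and s < start + len(motif):
                raise ValueError("planted motifs overlap")
        occupied.append((start, start + len(motif)))
        plant_list.append((motif, pos))

    avoid = sorted({m for m, _ in plant_list} | {p.upper() for p in forbid_spurious})
    for pat in avoid:
        if set(pat) - set("ACGT"):
            raise ValueError(f"forbidden pattern {pat!r} must be a literal ACGT string")

    rng = _rng(seed)
    arr = _random_bases(rng, length, gc)
    planted_index = set()
    skip_starts = set()
    for motif, pos in plant_list:
        start = length + pos
        arr[start : start + len(motif)] = np.frombuffer(motif.encode(), dtype=np.uint8)
        planted_index.update(range(start, start + len(motif)))
        skip_starts.add((start, motif))
    seq = arr.tobytes().decode("ascii")

    redraws = 0
    skip = frozenset(skip_starts)
    while True:
        found = _find_any(seq, avoid, skip)
        if found is None:
            break
        pos, pat = found
        mutable = [i for i in range(pos, pos + len(pat)) if i not in planted_index]
        if not mutable:
            raise SimulationError(
                f"pattern {pat!r} unavoidable: spurious occurrence at {pos - length} "
                "lies entirely within planted bases"
            )
        i = mutable[int(rng.integers(0, len(mutable)))]
        arr[i] = _random_bases(rng, 1, gc)[0]
        seq = arr.tobytes().decode("ascii")
        redraws += 1
        if redraws > max_redraws:
            raise SimulationError(
                f"could not exclude patterns {avoid} within {max_redraws} redraws"
            )

    truth = SimulationTruth(seed=seed, planted_motifs=list(plant_list))
    return PromoterSequence(seq), truth


def simulate_homolog_reads(
    segment_len: int = 2000,
    identity: float = 0.95,
    n_reads: int = 50,
    read_len: int = 50,
    n_decoys: int = 5,
    seed: int = 0,
    background_len: int = 10_000,
) -> Tuple[List[ReadAlignments], HomologySpec, SimulationTruth]:
    """Reads from a target segment that multi-map to a homologous copy.

    A toy genome holds two segments on "chrH" (the second a per-base mutated
    copy of the first at the given identity) separated by background, plus an
    unrelated background chromosome "chrBG". Reads are sampled uniformly from
    segment 1 and reported at their true position; when the read's window has
    no mutated base the homologous position in segment 2 is reported too.
    ``n_decoys`` reads additionally receive an off-homolog background
    alignment; truth records their ids.
    """
    if not 0.0 < identity <= 1.0:
        raise ValueError(f"identity={identity} must lie in (0, 1]")
    if read_len >= segment_len:
        raise ValueError("read_len must be smaller than segment_len")
    if n_decoys > n_reads:
        raise ValueError("n_decoys cannot exceed n_reads")
    rng = _rng(seed)
    gap = background_len
    seg1_start = gap
    seg2_start = gap + segment_len + gap
    chrom_len = seg2_start + segment_len + gap
    mutated = rng.random(segment_len) < (1.0 - identity)
    # cumulative mutated-base count for O(1) window-identity queries
    cum = np.concatenate([[0], np.cumsum(mutated)])
    reads: List[ReadAlignments] = []
    decoy_ids = sorted(
        f"read_{i}" for i in rng.choice(n_reads, size=n_decoys, replace=False).tolist()
    )
    decoy_set = set(decoy_ids)
    for i in range(n_reads):
        rid = f"read_{i}"
        p = int(rng.integers(0, segment_len - read_len + 1))
        alns = [GenomicInterval("chrH", seg1_start + p, seg1_start + p + read_len)]
        if cum[p + read_len] - cum[p] == 0:  # window identical in the copy
            alns.append(
                GenomicInterval("chrH", seg2_start + p, seg2_start + p + read_len)
            )
        if rid in decoy_set:
            bg_pos = int(rng.integers(0, 50_000 - read_len))
            alns.append(GenomicInterval("chrBG", bg_pos, bg_pos + read_len))
        reads.append(ReadAlignments(rid, alns))
    spec = HomologySpec(
        target=GenomicInterval("chrH", seg1_start, seg1_start + segment_len, name="segment1"),
        allowed=IntervalCollection(
            [
                GenomicInterval("chrH", seg1_start, seg1_start + segment_len, name="segment1"),
                GenomicInterval("chrH", seg2_start, seg2_start + segment_len, name="segment2"),
            ]
        ),
    )
    truth = SimulationTruth(seed=seed, decoy_read_ids=decoy_ids)
    return reads, spec, truth


_MARKER_BASELINES = {"FcgRI": 5000.0, "FcgRIIa": 8000.0, "FcgRIIIa": 3000.0}
_ISOTYPE_MFI = 50.0


def simulate_flow_panels(
    n_subjects: int = 11,
    ratio_lo: float = 1.0,
    ratio_hi: float = 10.0,
    noise_cv: float = 0.2,
    seed: int = 0,
) -> Tuple[List[Tuple[FcgrPanel, FcgrPanel]], SimulationTruth]:
    """Paired FcgR panels per subject with planted A:I ratios.

    Both panels of a pair share the same activating draws (log-normal around
    marker baselines with coefficient of variation ``noise_cv``); the
    inhibitory FcgRIIb is set so that the isotype-corrected A:I ratio equals
    ``ratio_hi`` (condition 1) and ``ratio_lo`` (condition 2) exactly in the
    noise-free construction. Defaults mirror an 11-donor panel with a tenfold
    ratio difference between conditions.
    """
    if ratio_lo <= 0 or ratio_hi <= 0:
        raise ValueError("planted ratios must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = _rng(seed)
    sigma = float(np.sqrt(np.log1p(noise_cv**2)))
    pairs: List[Tuple[FcgrPanel, FcgrPanel]] = []
    truth = SimulationTruth(seed=seed)
    for s in range(n_subjects):
        activating = []
        for marker in ACTIVATING_MARKERS:
            base = _MARKER_BASELINES[marker]
            noisy = base * float(np.exp(rng.normal(-sigma**2 / 2, sigma))) if sigma else base
            activating.append(
                MarkerMeasurement(marker, noisy + _ISOTYPE_MFI, _ISOTYPE_MFI)
            )
        # inhibitory set from the noise-free activating baselines, so the
        # planted ratio is exact at noise_cv=0 and a target otherwise
        total = sum(_MARKER_BASELINES.values())
        panels = []
        for ratio in (ratio_hi, ratio_lo):
            inhib = MarkerMeasurement(
                INHIBITORY_MARKER, total / ratio + _ISOTYPE_MFI, _ISOTYPE_MFI
            )
            panels.append(
                FcgrPanel(activating=activating, inhibitory=inhib, subject_id=f"subject_{s}")
            )
        pairs.append((panels[0], panels[1]))
        truth.panel_ratios.append((float(ratio_hi), float(ratio_lo)))
    return pairs, truth
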