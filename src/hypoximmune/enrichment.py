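"""Per-TF binding-site frequency in a peak set against a random-interval
permutation null, summarised as z-scores.

The procedure: count the TF binding-site records overlapping the observed peak
set; then, for each of ``n_perm`` replicates, draw the same number of random
intervals (length multiset preserved) uniformly from the genome and count
again; report z = (observed - null mean) / null sd per TF, with the population
(n) denominator for the sd. When the null is degenerate (sd = 0), the z-score
is flagged rather than returned as +/-infinity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np

from .intervals import (
    GenomeModel,
    IntervalCollection,
    _count_overlaps_arrays,
    _sample_starts,
    count_overlapping_sites,
    derive_replicate_seed,
)

__all__ = [
    "TFSiteAnnotation",
    "EnrichmentResult",
    "observed_frequency",
    "permutation_null",
    "enrichment_zscores",
    "rank_report",
]

DEGENERATE_EQUAL = "degenerate_equal"
DEGENERATE_EXTREME = "degenerate_extreme"


class TFSiteAnnotation:
    """Per-TF interval collections of binding-site records sharing one genome."""

    def __init__(self, per_tf: Mapping[str, IntervalCollection]):
        self.per_tf: Dict[str, IntervalCollection] = dict(per_tf)
        genomes = {id(c.genome) for c in self.per_tf.values() if c.genome is not None}
        if len(genomes) > 1:
            models = [c.genome for c in self.per_tf.values() if c.genome is not None]
            if any(m != models[0] for m in models[1:]):
                raise ValueError("TF site collections attached to different genome models")

    def __iter__(self):
        return iter(self.per_tf)

    def __len__(self) -> int:
        return len(self.per_tf)

    def __getitem__(self, tf: str) -> IntervalCollection:
        return self.per_tf[tf]

    def items(self):
        return self.per_tf.items()

    @classmethod
    def from_bed(cls, path, genome: Optional[GenomeModel] = None) -> "TFSiteAnnotation":
        """One BED file with the TF name in column 4; records grouped by TF."""
        from .intervals import read_bed

        coll = read_bed(path, genome=genome)
        per_tf: Dict[str, List] = {}
        for iv in coll:
            if iv.name is None:
                raise ValueError(f"{path}: site record {iv.chrom}:{iv.start}-{iv.end} lacks a TF name (column 4)")
            per_tf.setdefault(iv.name, []).append(iv)
        return cls({tf: IntervalCollection(ivs, genome=genome) for tf, ivs in per_tf.items()})


@dataclass
class EnrichmentResult:
    """Observed count, permutation-null summary and z-score for one TF."""

    tf: str
    observed: int
    null_mean: float
    null_sd: float
    zscore: float  # NaN when flagged
    n_perm: int
    flag: Optional[str] = None  # None | degenerate_equal | degenerate_extreme
    empirical_p: Optional[float] = None
    null_counts: Optional[np.ndarray] = None

    @property
    def defined(self) -> bool:
        return self.flag is None


def observed_frequency(
    peaks: IntervalCollection,
    annotation: TFSiteAnnotation,
    count_pairs: bool = False,
) -> Dict[str, int]:
    """Per TF, the number of its site records overlapping the peak set."""
    return {
        tf: count_overlapping_sites(sites, peaks, count_pairs=count_pairs)
        for tf, sites in annotation.items()
    }


def permutation_null(
    peaks: IntervalCollection,
    annotation: TFSiteAnnotation,
    genome: GenomeModel,
    n_perm: int,
    seed: int,
    mask: Optional[IntervalCollection] = None,
    count_pairs: bool = False,
) -> Dict[str, np.ndarray]:
    """Per-TF count vectors of length ``n_perm`` against random interval sets.

    Replicate r draws the same number of intervals as peaks, with the peaks'
    length multiset, uniformly from the genome (seeded with a per-replicate
    seed derived from ``seed`` so the vectors are reproducible replicate by
    replicate), and records each TF's overlapping-site count.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    lengths = peaks.lengths
    mask_merged = mask.merged_arrays() if mask is not None else None
    tf_names = list(annotation)
    site_arrays = {tf: annotation[tf].chrom_arrays() for tf in tf_names}
    counts = {tf: np.zeros(n_perm, dtype=np.int64) for tf in tf_names}
    for r in range(n_perm):
        rng = np.random.default_rng(derive_replicate_seed(seed, r))
        placements = _sample_starts(genome, lengths, rng, mask_merged)
        # merge the replicate's intervals per chromosome
        by_chrom: Dict[str, List] = {}
        for chrom, s, e in placements:
            by_chrom.setdefault(chrom, []).append((s, e))
        merged: Dict[str, tuple] = {}
        for chrom, pairs in by_chrom.items():
            pairs.sort()
            m_starts, m_ends = [], []
            for s, e in pairs:
                if m_ends and s <= m_ends[-1]:
                    m_ends[-1] = max(m_ends[-1], e)
                else:
                    m_starts.append(s)
                    m_ends.append(e)
            merged[chrom] = (
                np.asarray(m_starts, dtype=np.int64),
                np.asarray(m_ends, dtype=np.int64),
            )
        for tf in tf_names:
            total = 0
            for chrom, (s_starts, s_ends) in site_arrays[tf].items():
                if chrom not in merged:
                    continue
                m_starts, m_ends = merged[chrom]
                if count_pairs:
                    # pair counting needs the unmerged replicate intervals
                    p = sorted(by_chrom[chrom])
                    p_starts = np.asarray([x[0] for x in p], dtype=np.int64)
                    p_ends_sorted = np.sort(np.asarray([x[1] for x in p], dtype=np.int64))
                    n = len(p_starts)
                    right = n - np.searchsorted(p_starts, s_ends, side="left")
                    left = np.searchsorted(p_ends_sorted, s_starts, side="right")
                    total += int((n - right - left).sum())
                else:
                    total += int(
                        _count_overlaps_arrays(s_starts, s_ends, m_starts, m_ends).sum()
                    )
            counts[tf][r] = total
    return counts


def enrichment_zscores(
    peaks: IntervalCollection,
    annotation: TFSiteAnnotation,
    genome: GenomeModel,
    n_perm: int = 1000,
    seed: int = 0,
    mask: Optional[IntervalCollection] = None,
    sd_ddof: int = 0,
    keep_null: bool = False,
    count_pairs: bool = False,
) -> List[EnrichmentResult]:
    """Per-TF z-scores of the observed site frequency against the permutation
    null. The null sd uses the population (n) denominator by default
    (``sd_ddof=0``). The supplementary empirical p-value uses the add-one
    estimator (1 + #{null >= observed}) / (n_perm + 1)."""
    observed = observed_frequency(peaks, annotation, count_pairs=count_pairs)
    null = permutation_null(
        peaks, annotation, genome, n_perm, seed, mask=mask, count_pairs=count_pairs
    )
    results: List[EnrichmentResult] = []
    for tf in annotation:
        counts = null[tf]
        mean = float(counts.mean())
        sd = float(counts.std(ddof=sd_ddof))
        obs = observed[tf]
        if sd > 0:
            z, flag = (obs - mean) / sd, None
        elif obs == mean:
            z, flag = float("nan"), DEGENERATE_EQUAL
        else:
            z, flag = float("nan"), DEGENERATE_EXTREME
        emp_p = (1 + int((counts >= obs).sum())) / (n_perm + 1)
        results.append(
            EnrichmentResult(
                tf=tf,
                observed=obs,
                null_mean=mean,
                null_sd=sd,
                zscore=z,
                n_perm=n_perm,
                flag=flag,
                empirical_p=emp_p,
                null_counts=counts if keep_null else None,
            )
        )
    return results


def rank_report(
    results: Sequence[EnrichmentResult], top_n: Optional[int] = None
) -> List[EnrichmentResult]:
    """Results sorted by descending z-score (flagged/undefined last), ties
    broken by descending observed count then TF name, truncated to ``top_n``."""
    if not results:
        raise ValueError("empty result sequence")
    ordered = sorted(
        results,
        key=lambda r: (
            r.flag is not None,
            -(r.zscore if r.flag is None else 0.0),
            -r.observed,
            r.tf,
        ),
    )
    return ordered[:top_n] if top_n is not None else ordered
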