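# Methods

## Coordinates and overlap semantics

All intervals are 0-based, half-open on named chromosomes (BED convention);
public I/O is BED3/BED6 plus a two-column chrom-sizes file for the genome
model. "Overlap" everywhere means at least 1 bp of intersection and is
strand-blind — the weakest, and therefore safest, criterion for both site
counting and the multi-mapping audit. Overlap counting is backed by sorted
numpy arrays and binary search (merged peak unions for counted-once
semantics); the pure-Python all-pairs double loop serves as the independent
oracle in the tests, never as the implementation.

By default a TF site touching several adjacent peaks counts **once**
(distinct-record counting), because double-counting one record across peaks
would inflate the observed statistic asymmetrically against a null whose
random intervals rarely abut; `count_pairs=True` switches to site × peak pair
counting for users who want occurrence semantics.

## Permutation enrichment model

For a peak set *P* (n intervals with lengths ℓ₁…ℓₙ) and per-TF site records,
the observed frequency *f* is the number of records overlapping *P*. Each null
replicate places n intervals with exactly the lengths ℓ₁…ℓₙ uniformly over the
genome: a chromosome is chosen with probability proportional to its number of
valid start positions for that length, then the start uniformly among them, so
placement is uniform over all valid positions genome-wide. Intervals may
overlap one another; nothing is GC- or gap-matched (an optional exclusion mask
with a 1000-attempt rejection cap is available but off by default). Replicate
*r* uses the derived seed `SeedSequence(seed, spawn_key=(r,))`, making every
replicate independently reproducible.

Summary per TF: z = (f − μ)/σ with σ the **population** (ddof = 0) standard
deviation of the replicate counts (a sample-sd flag exists; the tests pin the
default). When σ = 0 the z-score is *flagged* (`degenerate_equal` when f = μ,
`degenerate_extreme` otherwise) rather than returned as ±∞, keeping ranking
total and serialization clean. The supplementary empirical p-value uses the
add-one estimator (1 + #{null ≥ f}) / (n_perm + 1), which cannot return zero
at finite n_perm. Ranking sorts by descending z with flagged results last,
ties broken by descending observed count then TF name.

Default n_perm is 1000; the calibration and recovery analyses in the tests and
the acceptance script use n_perm = 200 per dataset across 100–200 simulated
datasets, a problem size chosen so a full run completes in tens of seconds on
one CPU while keeping Monte-Carlo error on the z mean/variance well inside the
asserted bands.

## Motif scanning conventions

Promoters are 5′→3′ on the gene strand, ending at the base immediately
upstream of the TSS; that base is position −1, and a hit's position is the
TSS-relative offset of its 5′-most base on the gene strand (so a length-m hit
at p occupies [p, p+m), p + m ≤ 0). This is the most common promoter
convention; published per-study coordinates can differ by a few bp when they
anchor on match ends or count 1-based, which is why the convention is stated
explicitly and validated end to end by planting-and-recovery tests. Matching
is case-insensitive; soft-masked lowercase bases are uppercased by default,
with an option to read them as N. A sequence N matches only the pattern symbol
N. Minus-strand scanning matches the reverse-complement pattern and reports
the hit at the same gene-strand window, with `matched` given as read on the
minus strand. Scanning uses compiled regular expressions over IUPAC character
classes with overlap-permitting stepping; the naive O(n·m) sliding window is
the test oracle.

Preset library: HRE canonical RCGTG, HRE non-canonical CCGTG, AP-1 canonical
TGASTCA, AP-1 non-canonical TGCATCA and TGCGTCA. Presets are plain
`MotifPattern` objects; any user-supplied IUPAC string can replace them. HRE
hits carry a `nearby_cac` flag: true when a CAC trimer lies entirely outside
the match with its 5′ base within `cac_window` bp (default 20, configurable —
"close proximity" has no standard width) of either match end. Default strand
mode is gene-strand-only; both-strand scanning is a flag. Pentamer counting
(`count_literal`) counts possibly-overlapping literal occurrences and equals
the scan hit count by construction.

`extract_upstream` returns [tss−L, tss) for + genes and the reverse complement
of [tss+1, tss+1+L) for − genes, so the returned string's last base is always
position −1 regardless of strand.

## Immunophenotyping arithmetic

Isotype correction subtracts the isotype-control geometric MFI; a negative
difference is clamped to 0 and flagged, since negative expression is not
meaningful and 0 preserves the monotonicity of the A:I ratio. A clamped
inhibitory value makes the ratio undefined — surfaced as an explicit
`UndefinedRatioError`, never infinity. Whether the ratio should use corrected
or raw geomeans is a genuine choice; the default is corrected with a
`corrected=False` path, and the tests pin both. The A:I ratio is invariant
under a common positive scale, strictly increasing in each activating value
and strictly decreasing in the inhibitory value; Western fold changes satisfy
exact reciprocity. MFIs are abstract positive reals — no FCS parsing, gating
or hypothesis testing is attempted here.

## Multi-mapping audit

A read is *on-target* when ≥ 1 of its reported alignments overlaps the target
region and *confined* when all of its alignments overlap some allowed region;
escaping ids are reported sorted, and the verdict is order-independent in both
reads and alignments. All mapped records of a read name count as its alignment
set — secondary/supplementary flags are not distinguished, mirroring
`-k`-style multi-alignment reporting. Input is a plain-text SAM subset (QNAME,
FLAG, RNAME, POS, CIGAR; unmapped records skipped; reference span = sum of
M/D/N/=/X operations) or a 4-column TSV (read_id, chrom, start0, end); BAM is
out of scope.

## Synthetic-data generators

Every generator is a pure function of (parameters, seed) built on numpy's
`SeedSequence`/`default_rng`, so outputs are bit-identical across runs, and
each returns a `SimulationTruth` sufficient to score the downstream stage.

* **Genome**: i.i.d. bases, GC fraction 0.41 (human-like) split evenly between
  G and C; nothing downstream depends on composition.
* **Peaks**: n disjoint intervals, lengths ~ Normal(500, 50) truncated at
  50 bp and rounded, uniform placement with overlap rejection. The default
  study scale is 20 peaks on a 1 Mb single-chromosome genome.
* **TF sites**: background count ~ Poisson(density × non-peak Mb) placed
  uniformly in non-peak space; in-peak count ~ Poisson(density × ρ × peak Mb)
  uniformly within peaks, so ρ = 1 is homogeneous Poisson placement in
  distribution and ρ is the planted effect size. Defaults: 10 bp sites at
  500/Mb — a few hundred records, typical of a well-annotated TF, giving an
  expected null count of ~5 per 20-peak set and an expected in-peak count of
  ~25 at ρ = 5, i.e. a cleanly separable planted effect while ρ = 1 stays
  calibrated. Sites are placed entirely within their stratum; the ~(site
  length − 1) bp edge effect this induces at stratum boundaries biases the
  null z mean by only a few hundredths at the default scale.
* **Promoters**: i.i.d. background with literal motifs written at exact
  TSS-relative offsets; any accidental gene-strand occurrence of a planted or
  forbidden pattern is removed by redrawing a uniformly chosen non-planted
  base of the offending window (cap 10⁶ redraws) — simpler than constructive
  avoidance and ample at desk scale. A forbidden pattern lying entirely inside
  planted bases is reported as unavoidable.
* **Homolog reads**: two same-length segments on one chromosome, the second a
  per-base mutated copy at the requested identity, plus unrelated background;
  reads sample uniformly from segment 1, gain the homologous alignment when
  their window contains no mutated base, and a chosen subset additionally gets
  an off-homolog background alignment (the decoys, recorded in truth).
* **Flow panels**: per subject, one activating draw set (log-normal around
  fixed marker baselines, coefficient of variation `noise_cv`, mean-corrected)
  shared by both conditions; the inhibitory MFI is set from the *noise-free*
  baselines so the planted A:I ratios (defaults 10 vs 1, n = 11 subjects,
  noise_cv = 0.2 — a tenfold ratio difference across a typical donor panel)
  are exact at noise_cv = 0 and targets otherwise. A constant isotype MFI of
  50 is added to every channel so the correction path is exercised.

What the generators deliberately do **not** emulate: read-level sequence data,
fragment-size or Tn5-insertion structure, GC- or mappability-biased peak
placement, correlated site clustering, instrument-specific MFI scaling, or
gating noise. Passing tests therefore demonstrate correctness of the
*procedures* under their stated sampling models, not robustness to every
artefact of real ATAC/ChIP or cytometry data.

## Numerical and degenerate-input choices

Seeds are plain integers (replicate seeds derived via spawn keys stay within
numpy's SeedSequence arithmetic); z-identity is kept to 1e-12 of the direct
formula; empty site/peak sets count 0 overlaps; an empty result list is a
contract error for ranking; BED and alignment parse errors always name the
offending line; sampling errors (no valid placement, mask-rejection cap, peak
packing) raise dedicated exception types rather than looping forever.

## Known limitations

The permutation null is uniform over the genome — no blacklist, gap, GC or
chromatin matching — matching the procedure it reimplements; enrichment
z-scores are reported raw, with no cross-TF multiple-testing correction. The
motif layer is pattern-matching only: no position-weight matrices, motif
discovery or database clients. The audit consumes alignment output; it never
performs alignment itself.
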