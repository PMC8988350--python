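"""Observed TF-site frequency, permutation null and z-score reporting."""

import numpy as np
import pytest

import hypoximmune as hx
from hypoximmune.enrichment import DEGENERATE_EQUAL, DEGENERATE_EXTREME

from conftest import brute_force_overlap_count, random_interval_collection


def make_annotation(genome, **colls):
    return hx.TFSiteAnnotation(
        {tf: hx.IntervalCollection(ivs, genome=genome) for tf, ivs in colls.items()}
    )


class TestObservedFrequency:
    def test_sites_inside_peaks_all_counted(self, toy_genome):
        peaks = hx.IntervalCollection(
            [hx.GenomicInterval("chrA", 100, 600)], genome=toy_genome
        )
        ann = make_annotation(
            toy_genome,
            TF=[
                hx.GenomicInterval("chrA", 110, 120),
                hx.GenomicInterval("chrA", 300, 310),
                hx.GenomicInterval("chrA", 590, 600),
            ],
        )
        assert hx.observed_frequency(peaks, ann) == {"TF": 3}

    def test_tf_with_no_sites_reports_zero(self, toy_genome):
        peaks = hx.IntervalCollection(
            [hx.GenomicInterval("chrA", 0, 100)], genome=toy_genome
        )
        ann = hx.TFSiteAnnotation({"TF": hx.IntervalCollection([], genome=toy_genome)})
        assert hx.observed_frequency(peaks, ann) == {"TF": 0}

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_per_tf(self, trial, toy_genome):
        rng = np.random.default_rng(400 + trial)
        peaks = random_interval_collection(rng, toy_genome, 8, max_len=600)
        ann = hx.TFSiteAnnotation(
            {
                f"TF{k}": random_interval_collection(rng, toy_genome, 40, max_len=30)
                for k in range(3)
            }
        )
        got = hx.observed_frequency(peaks, ann)
        for tf, sites in ann.items():
            assert got[tf] == brute_force_overlap_count(sites, peaks)


class TestPermutationNull:
    def test_saturating_annotation_gives_constant_counts(self):
        """Site records spanning the whole (single) chromosome overlap any
        random interval set: every replicate equals the number of site records."""
        genome = hx.GenomeModel({"chrA": 10_000})
        peaks = hx.IntervalCollection(
            [hx.GenomicInterval("chrA", 0, 500)], genome=genome
        )
        ann = make_annotation(
            genome,
            TF=[hx.GenomicInterval("chrA", 0, 10_000), hx.GenomicInterval("chrA", 0, 10_000)],
        )
        null = hx.permutation_null(peaks, ann, genome, n_perm=20, seed=1)
        assert np.all(null["TF"] == 2)
        assert hx.observed_frequency(peaks, ann) == {"TF": 2}

    def test_single_replicate_vector_length(self, toy_genome):
        peaks = hx.IntervalCollection(
            [hx.GenomicInterval("chrA", 0, 500)], genome=toy_genome
        )
        ann = make_annotation(toy_genome, TF=[hx.GenomicInterval("chrA", 50, 60)])
        null = hx.permutation_null(peaks, ann, toy_genome, n_perm=1, seed=1)
        assert null["TF"].shape == (1,)

    def test_same_seed_identical_vectors(self, toy_genome):
        rng = np.random.default_rng(0)
        peaks = random_interval_collection(rng, toy_genome, 10, max_len=400)
        ann = hx.TFSiteAnnotation(
            {"TF": random_interval_collection(rng, toy_genome, 50, max_len=20)}
        )
        a = hx.permutation_null(peaks, ann, toy_genome, n_perm=50, seed=9)
        b = hx.permutation_null(peaks, ann, toy_genome, n_perm=50, seed=9)
        assert np.array_equal(a["TF"], b["TF"])

    @pytest.mark.parametrize("trial", range(5))
    def test_replicates_match_brute_force_on_reconstructed_draws(self, trial, toy_genome):
        """Each replicate's count equals the all-pairs brute force over the
        interval set reconstructed from the replicate's derived seed."""
        rng = np.random.default_rng(500 + trial)
        peaks = random_interval_collection(rng, toy_genome, 6, max_len=500)
        ann = hx.TFSiteAnnotation(
            {"TF": random_interval_collection(rng, toy_genome, 30, max_len=25)}
        )
        seed = 700 + trial
        null = hx.permutation_null(peaks, ann, toy_genome, n_perm=10, seed=seed)
        for r in range(10):
            draw = hx.sample_random_intervals(
                toy_genome, peaks.lengths, hx.derive_replicate_seed(seed, r)
            )
            assert null["TF"][r] == brute_force_overlap_count(ann["TF"], draw)

    def test_null_mean_matches_analytic_coverage_probability(self):
        """Toy uniform model: the empirical null mean matches the closed-form
        inclusion probability that a random interval set covers a given site."""
        genome = hx.GenomeModel({"chrA": 100_000})
        rng = np.random.default_rng(21)
        starts = rng.integers(0, 100_000 - 10, size=200)
        ann = make_annotation(
            genome, TF=[hx.GenomicInterval("chrA", int(s), int(s) + 10) for s in starts]
        )
        peak_starts = np.arange(20) * 5000
        peaks = hx.IntervalCollection(
            [hx.GenomicInterval("chrA", int(s), int(s) + 500) for s in peak_starts],
            genome=genome,
        )
        null = hx.permutation_null(peaks, ann, genome, n_perm=500, seed=22)
        counts = null["TF"]
        # P(one random 500 bp interval overlaps site [s, e)):
        # valid starts V = C - L + 1, overlapping starts t in [s-L+1, e-1] ∩ [0, V-1]
        C, L = 100_000, 500
        V = C - L + 1
        expected = 0.0
        for s in starts.tolist():
            e = s + 10
            lo, hi = max(0, s - L + 1), min(V - 1, e - 1)
            p = (hi - lo + 1) / V if hi >= lo else 0.0
            expected += 1 - (1 - p) ** 20
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - expected) < 4 * se + 1e-9


class TestEnrichmentZscores:
    def test_degenerate_equal_flag_not_division_by_zero(self, toy_genome):
        peaks = hx.IntervalCollection(
            [hx.GenomicInterval("chrA", 0, 500)], genome=toy_genome
        )
        ann = make_annotation(
            toy_genome,
            TF=[hx.GenomicInterval(c, 0, l) for c, l in toy_genome.entries.items()],
        )
        (res,) = hx.enrichment_zscores(peaks, ann, toy_genome, n_perm=10, seed=1)
        assert res.flag == DEGENERATE_EQUAL
        assert np.isnan(res.zscore)

    def test_degenerate_extreme_flag(self, toy_genome):
        # sites on chrB only; peaks and every replicate confined to chrA by mask
        mask = hx.IntervalCollection([hx.GenomicInterval("chrB", 0, 5000)])
        peaks = hx.IntervalCollection(
            [hx.GenomicInterval("chrB", 10, 30)], genome=toy_genome
        )
        ann = make_annotation(toy_genome, TF=[hx.GenomicInterval("chrB", 0, 5000)])
        (res,) = hx.enrichment_zscores(
            peaks, ann, toy_genome, n_perm=10, seed=1, mask=mask
        )
        assert res.flag == DEGENERATE_EXTREME
        assert res.observed == 1 and res.null_mean == 0.0

    def test_zscore_identity_and_population_sd(self, toy_genome):
        rng = np.random.default_rng(2)
        peaks = random_interval_collection(rng, toy_genome, 10, max_len=400)
        ann = hx.TFSiteAnnotation(
            {"TF": random_interval_collection(rng, toy_genome, 60, max_len=20)}
        )
        (res,) = hx.enrichment_zscores(
            peaks, ann, toy_genome, n_perm=100, seed=3, keep_null=True
        )
        counts = res.null_counts
        assert res.null_sd == pytest.approx(counts.std(ddof=0), abs=1e-12)
        assert res.zscore == pytest.approx(
            (res.observed - counts.mean()) / counts.std(ddof=0), abs=1e-12
        )
        assert res.empirical_p == pytest.approx(
            (1 + (counts >= res.observed).sum()) / 101
        )

    def test_masked_decoy_sites_change_nothing(self, toy_genome):
        """Sites in a masked region can never overlap peaks or null draws, so
        adding them shifts neither observed nor null counts."""
        mask = hx.IntervalCollection([hx.GenomicInterval("chrB", 0, 5000)])
        rngA = np.random.default_rng(31)
        peaks = hx.IntervalCollection(
            [
                hx.GenomicInterval("chrA", int(s), int(s) + 100)
                for s in rngA.integers(0, 9900, size=8)
            ],
            genome=toy_genome,
        )
        base_sites = [
            hx.GenomicInterval("chrA", int(s), int(s) + 10)
            for s in rngA.integers(0, 9990, size=40)
        ]
        decoys = [hx.GenomicInterval("chrB", i * 100, i * 100 + 10) for i in range(20)]
        ann_plain = make_annotation(toy_genome, TF=base_sites)
        ann_decoy = make_annotation(toy_genome, TF=base_sites + decoys)
        kw = dict(n_perm=50, seed=8, mask=mask, keep_null=True)
        (a,) = hx.enrichment_zscores(peaks, ann_plain, toy_genome, **kw)
        (b,) = hx.enrichment_zscores(peaks, ann_decoy, toy_genome, **kw)
        assert a.observed == b.observed
        assert np.array_equal(a.null_counts, b.null_counts)

    def test_monotone_in_planted_density(self, mb_genome):
        """Median z never decreases as the in-peak density ratio rho grows."""
        medians = []
        for rho in (1.0, 2.0, 5.0):
            zs = []
            for d in range(10):
                peaks = hx.simulate_peaks(mb_genome, 20, 500, 50, seed=9000 + d)
                ann, _ = hx.plant_tf_sites(
                    mb_genome, peaks, {"TF": (10, 500.0, rho)}, seed=9100 + d
                )
                (res,) = hx.enrichment_zscores(
                    peaks, ann, mb_genome, n_perm=100, seed=9200 + d
                )
                zs.append(res.zscore)
            medians.append(float(np.median(zs)))
        assert medians[0] <= medians[1] <= medians[2]


class TestRankReport:
    def test_highest_z_first(self):
        a = hx.EnrichmentResult("A", 5, 1.0, 1.0, 2.0, 10)
        b = hx.EnrichmentResult("B", 5, 1.0, 1.0, 5.0, 10)
        assert [r.tf for r in hx.rank_report([a, b], top_n=1)] == ["B"]

    def test_tie_broken_by_observed_then_name(self):
        a = hx.EnrichmentResult("A", 7, 1.0, 1.0, 2.0, 10)
        b = hx.EnrichmentResult("B", 10, 1.0, 1.0, 2.0, 10)
        c = hx.EnrichmentResult("C", 10, 1.0, 1.0, 2.0, 10)
        assert [r.tf for r in hx.rank_report([c, a, b])] == ["B", "C", "A"]

    def test_undefined_ranked_last(self):
        a = hx.EnrichmentResult("A", 5, 5.0, 0.0, float("nan"), 10, flag=DEGENERATE_EQUAL)
        b = hx.EnrichmentResult("B", 5, 1.0, 1.0, -3.0, 10)
        assert [r.tf for r in hx.rank_report([a, b])] == ["B", "A"]

    def test_random_order_matches_oracle_sort(self):
        rng = np.random.default_rng(55)
        results = [
            hx.EnrichmentResult(
                f"TF{i}", int(rng.integers(0, 20)), 1.0, 1.0, float(rng.integers(-3, 4)), 10
            )
            for i in range(50)
        ]
        got = [r.tf for r in hx.rank_report(results)]
        oracle = [
            r.tf
            for r in sorted(results, key=lambda r: (-r.zscore, -r.observed, r.tf))
        ]
        assert got == oracle

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hx.rank_report([])


class TestAnnotationIO:
    def test_from_bed_groups_by_column4(self, tmp_path, toy_genome):
        path = tmp_path / "sites.bed"
        path.write_text(
            "chrA\t10\t20\tHIF1A\t.\t+\nchrA\t50\t60\tGATA2\t.\t-\nchrB\t5\t15\tHIF1A\t.\t+\n"
        )
        ann = hx.TFSiteAnnotation.from_bed(path, genome=toy_genome)
        assert sorted(ann) == ["GATA2", "HIF1A"]
        assert len(ann["HIF1A"]) == 2 and len(ann["GATA2"]) == 1

    def test_from_bed_requires_name_column(self, tmp_path):
        path = tmp_path / "sites.bed"
        path.write_text("chrA\t10\t20\n")
        with pytest.raises(ValueError):
            hx.TFSiteAnnotation.from_bed(path)
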