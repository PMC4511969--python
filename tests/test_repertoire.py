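"""GC-binned coverage baseline, correction factors, gene classification."""

import numpy as np
import pytest

from kiwigenomics.repertoire import (
    CoverageBaseline,
    RegionProfile,
    classify_gene,
    correction_factor,
    estimate_copy_number,
    gc_binned_baseline,
    intact_fraction,
)
from kiwigenomics.simulate import simulate_coverage_track


class TestBaseline:
    def test_uniform_depth_fills_bins_uniformly(self):
        gcs = np.linspace(0.3, 0.6, 500)
        base = gc_binned_baseline(np.full(500, 35.0), gcs, bin_width=0.01)
        occupied = base.bin_means[base.bin_counts > 0]
        assert np.allclose(occupied, 35.0)
        assert base.genome_wide_mean == pytest.approx(35.0)

    def test_two_bin_fixture(self):
        depths = np.array([10.0, 10.0, 30.0, 30.0])
        gcs = np.array([0.30, 0.305, 0.50, 0.505])
        base = gc_binned_baseline(depths, gcs, bin_width=0.01)
        assert base.mean_for_gc(0.30) == pytest.approx(10.0)
        assert base.mean_for_gc(0.50) == pytest.approx(30.0)
        assert base.genome_wide_mean == pytest.approx(20.0)

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError):
            gc_binned_baseline([], [], 0.01)

    def test_empty_bin_is_an_error_without_fallback(self):
        base = gc_binned_baseline([35.0], [0.50], bin_width=0.01)
        with pytest.raises(ValueError, match=r"GC bin \[0\.70"):
            base.mean_for_gc(0.70)
        # explicit fallback picks the nearest occupied bin
        assert base.mean_for_gc(0.70, fallback_nearest=True) == 35.0


class TestCorrectionFactor:
    def test_worked_coverage_example(self):
        """105-fold region over a 35-fold GC bin gives a factor of 3."""
        base = gc_binned_baseline([35.0, 35.0], [0.50, 0.505], bin_width=0.01)
        region = RegionProfile("OR1", mean_depth=105.0, gc=0.50)
        assert correction_factor(region, base) == pytest.approx(3.0)

    def test_region_at_baseline_gives_one(self):
        base = gc_binned_baseline([35.0], [0.42], bin_width=0.01)
        assert correction_factor(RegionProfile("x", 35.0, 0.42), base) == pytest.approx(1.0)

    def test_scale_invariance(self):
        """Multiplying all depths by a constant leaves the factor alone."""
        for scale in (1.0, 2.5, 10.0):
            base = gc_binned_baseline([35.0 * scale], [0.42], bin_width=0.01)
            region = RegionProfile("x", 70.0 * scale, 0.42)
            assert correction_factor(region, base) == pytest.approx(2.0)


class TestCopyNumber:
    def test_all_factors_one_keeps_annotated_count(self):
        base = gc_binned_baseline([35.0], [0.42], bin_width=0.01)
        regions = [RegionProfile(f"g{i}", 35.0, 0.42) for i in range(5)]
        est = estimate_copy_number(regions, base)
        assert est.estimated_total == est.annotated_count == 5

    def test_sum_of_integer_factors(self):
        base = gc_binned_baseline([35.0], [0.42], bin_width=0.01)
        regions = [
            RegionProfile("a", 35.0, 0.42),
            RegionProfile("b", 70.0, 0.42),
            RegionProfile("c", 105.0, 0.42),
        ]
        est = estimate_copy_number(regions, base)
        assert est.estimated_total == 6
        assert est.estimated_total_unrounded == pytest.approx(6.0)

    def test_factors_below_one_floor_at_one(self):
        base = gc_binned_baseline([35.0], [0.42], bin_width=0.01)
        est = estimate_copy_number([RegionProfile("a", 20.0, 0.42)], base)
        assert est.estimated_total == 1

    def test_recovery_on_simulated_collapsed_duplications(self):
        """82 annotated genes carrying planted copy numbers (true total
        141) recovered within 10 % from a Poisson coverage track."""
        rng = np.random.default_rng(42)
        n_genes, true_total = 82, 141
        copies = np.ones(n_genes, dtype=int)
        extra = true_total - n_genes
        copies[rng.choice(n_genes, size=30, replace=False)] += rng.multinomial(
            extra, np.ones(30) / 30
        )
        gene_len = 1000
        copy_map = {
            f"or{i}": (2_000_000 + i * 3000, 2_000_000 + i * 3000 + gene_len, int(c))
            for i, c in enumerate(copies)
        }
        track, _ = simulate_coverage_track(
            4_000_000, mean_depth=35, copy_map=copy_map, seed=7
        )
        base = gc_binned_baseline(track["depth"], track["gc"], bin_width=0.01)
        regions = []
        for rid, (start, end, _) in copy_map.items():
            sl = slice(start // 200, end // 200)
            regions.append(
                RegionProfile(rid, track["depth"][sl].mean(), track["gc"][sl].mean())
            )
        est = estimate_copy_number(regions, base)
        assert est.estimated_total == pytest.approx(true_total, rel=0.10)


class TestClassification:
    def test_clean_full_length_orf_is_intact(self):
        orf = "ATG" + "GCT" * 99 + "TAA"
        assert classify_gene(orf, family_reference_length=100).status == "intact"

    def test_premature_stop(self):
        orf = "ATG" + "GCT" * 48 + "TAA" + "GCT" * 49 + "TAA"
        res = classify_gene(orf, family_reference_length=100)
        assert res.status == "pseudogene" and res.reason == "premature_stop"

    def test_frameshift(self):
        res = classify_gene("ATGGC", family_reference_length=100)
        assert res.status == "pseudogene" and res.reason == "frameshift"

    def test_truncation_at_70_percent_with_threshold_80(self):
        orf = "ATG" + "GCT" * 69  # 70 codons vs reference 100
        res = classify_gene(orf, family_reference_length=100, truncation_threshold=0.8)
        assert res.status == "pseudogene" and res.reason == "truncation"

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            classify_gene("", 100)


class TestIntactFraction:
    def test_86_of_141_is_61_percent(self):
        res = intact_fraction(86, 141)
        assert res.percent_rounded == 61
        assert res.percent == pytest.approx(60.9929, abs=1e-3)

    def test_bounds(self):
        assert intact_fraction(0, 10).percent == 0.0
        assert intact_fraction(10, 10).percent == 100.0
        with pytest.raises(ValueError):
            intact_fraction(5, 0)
        with pytest.raises(ValueError):
            intact_fraction(11, 10)
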