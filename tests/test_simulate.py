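"""Determinism and statistical shape of the synthetic-data generators."""

import numpy as np
import pytest

from kiwigenomics import CodonModelParams
from kiwigenomics.simulate import (
    demo_bird_tree,
    simulate_category_data,
    simulate_codon_alignment,
    simulate_coverage_track,
    simulate_or_family,
    simulate_reads,
    simulate_ucne_orthologs,
)
from kiwigenomics.ucne import UCNERecord


@pytest.fixture(scope="module")
def tree():
    return demo_bird_tree()


@pytest.fixture(scope="module")
def params():
    return CodonModelParams(kappa=2.0, omega_background=0.3)


class TestCodonSimulator:
    def test_same_seed_bit_identical(self, tree, params):
        a1, _ = simulate_codon_alignment(tree, params, 50, seed=9)
        a2, _ = simulate_codon_alignment(tree, params, 50, seed=9)
        assert a1.sequences == a2.sequences
        a3, _ = simulate_codon_alignment(tree, params, 50, seed=10)
        assert a1.sequences != a3.sequences

    def test_zero_codons_valid_structure(self, tree, params):
        aln, _ = simulate_codon_alignment(tree, params, 0, seed=1)
        assert aln.n_codons == 0 and aln.n_taxa == 8

    def test_shift_validation(self, tree, params):
        with pytest.raises(ValueError, match="not a taxon"):
            simulate_codon_alignment(tree, params, 10, seed=1, shift=("moa", 0.5))
        with pytest.raises(ValueError, match="fraction"):
            simulate_codon_alignment(tree, params, 10, seed=1, shift=("kiwi", 1.5))

    def test_shift_truth_records_branch_average(self, tree, params):
        _, truth = simulate_codon_alignment(
            tree, params, 10, seed=1, shift=("kiwi", 0.4)
        )
        assert truth["expected_branch_average_omega"] == pytest.approx(
            0.3 * 0.6 + 1.0 * 0.4
        )

    def test_no_internal_stops(self, tree, params):
        aln, _ = simulate_codon_alignment(tree, params, 200, seed=13)
        for seq in aln.sequences:
            for i in range(0, len(seq) - 3, 3):
                assert seq[i : i + 3] not in {"TAA", "TAG", "TGA"}


class TestCoverageSimulator:
    def test_flat_track_mean_near_target(self):
        track, _ = simulate_coverage_track(400_000, mean_depth=35, seed=1)
        mean = track["depth"].mean()
        se = np.sqrt(35 / len(track["depth"]))
        assert mean == pytest.approx(35, abs=3 * se + 0.2)

    def test_deterministic_mode_is_exact(self):
        track, _ = simulate_coverage_track(
            10_000, mean_depth=20, noise="none", copy_map={"r": (0, 2000, 3)}, seed=1
        )
        assert np.all(track["depth"][:10] == 60.0)
        assert np.all(track["depth"][10:] == 20.0)

    def test_copy_number_scales_depth(self):
        track, _ = simulate_coverage_track(
            200_000, mean_depth=35, copy_map={"r": (50_000, 60_000, 3)}, seed=2
        )
        sl = slice(250, 300)
        assert track["depth"][sl].mean() == pytest.approx(105, rel=0.05)

    def test_copy_numbers_must_be_integers(self):
        with pytest.raises(ValueError, match="integer"):
            simulate_coverage_track(10_000, copy_map={"r": (0, 100, 1.5)}, seed=1)


class TestFamilySimulator:
    def test_zero_divergence_identical(self):
        fams, truth = simulate_or_family(
            per_species_divergence={"a": 0.0}, genes_per_species=5, seed=3
        )
        assert len(set(fams["a"])) == 1
        assert fams["a"][0] == truth["consensus"]

    def test_same_seed_identical(self):
        f1, _ = simulate_or_family(per_species_divergence={"a": 0.1}, seed=5)
        f2, _ = simulate_or_family(per_species_divergence={"a": 0.1}, seed=5)
        assert f1 == f2


class TestReadSimulator:
    def test_zero_coverage_empty(self):
        reads, _ = simulate_reads(10_000, 0, seed=1)
        assert reads == []

    def test_read_length_guard(self):
        with pytest.raises(ValueError, match="read length"):
            simulate_reads(50, 10, read_length=100, seed=1)

    def test_determinism_and_error_rate(self):
        r1, t1 = simulate_reads(5_000, 5, error_rate=0.01, seed=7)
        r2, _ = simulate_reads(5_000, 5, error_rate=0.01, seed=7)
        assert r1 == r2
        # at 1 % per-base error most 100-bp reads carry at least one
        # substitution, so exact genome matches are the minority
        genome = t1["genome"]
        exact = sum(genome.find(r) >= 0 for r in r1[:50])
        assert exact < 25


class TestCategorySimulator:
    def test_determinism(self):
        d1, s1, _ = simulate_category_data(seed=1)
        d2, s2, _ = simulate_category_data(seed=1)
        assert s1 == s2 and d1["categories"] == d2["categories"]

    def test_sig_fraction_near_target(self):
        _, sig, _ = simulate_category_data(n_genes=5000, sig_fraction=0.05, seed=2)
        assert len(sig) / 5000 == pytest.approx(0.05, abs=0.01)


class TestUcneSimulator:
    def test_zero_divergence_identity(self):
        rec = UCNERecord("e", "ACGT" * 100)
        out, _ = simulate_ucne_orthologs([rec], {"e": 0.0}, seed=1)
        assert out["e"] == rec.sequence

    def test_divergence_above_one_rejected(self):
        rec = UCNERecord("e", "ACGT" * 100)
        with pytest.raises(ValueError, match="exceeds 1"):
            simulate_ucne_orthologs([rec], {"e": 1.5}, seed=1)

    def test_rate_reflected_in_hamming_distance(self):
        rec = UCNERecord("e", "ACGT" * 250)
        out, _ = simulate_ucne_orthologs([rec], {"e": 0.08}, seed=2)
        ham = sum(a != b for a, b in zip(rec.sequence, out["e"]))
        assert ham / 1000 == pytest.approx(0.08, abs=0.025)
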