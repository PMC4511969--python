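"""Branch-model fitting, the LRT, and pairwise Ka/Ks."""

import numpy as np
import pytest

from kiwigenomics import CodonAlignment, CodonModelParams, FitConfig, PhyloTree, branch_lrt, fit_model
from kiwigenomics.selection import ONE_RATIO, TWO_RATIO, pairwise_kaks
from kiwigenomics.simulate import demo_bird_tree, simulate_codon_alignment

FAST = FitConfig(n_starts=1)


def test_one_ratio_recovery(bird_tree, default_params):
    """omega-hat lands within +/-0.05 of the simulated omega = 0.3 on a
    500-codon, 8-taxon alignment."""
    aln, _ = simulate_codon_alignment(bird_tree, default_params, 500, seed=21)
    fit = fit_model(aln, bird_tree, ONE_RATIO, FAST)
    assert fit.converged
    assert fit.params.omega_background == pytest.approx(0.3, abs=0.05)
    assert fit.params.omega_foreground == fit.params.omega_background


def test_identical_sequences_drive_branch_lengths_to_zero(bird_tree):
    seq = "ATGGCTAAA" * 30
    aln = CodonAlignment(list(bird_tree.taxa), [seq] * 8)
    fit = fit_model(aln, bird_tree, ONE_RATIO, FAST)
    lengths = [fit.tree.lengths[e] for e in fit.tree.edges()]
    # squeezed against the lower bound: the whole tree expects far less
    # than one substitution across the alignment
    assert max(lengths) < 1e-4


def test_two_ratio_nests_one_ratio(bird_alignment, bird_tree):
    aln, _ = bird_alignment
    fit0 = fit_model(aln, bird_tree, ONE_RATIO, FAST)
    fit1 = fit_model(aln, bird_tree, TWO_RATIO, FAST, init_fit=fit0)
    assert fit1.lnL >= fit0.lnL - 1e-6


def test_two_ratio_requires_foreground():
    tree = PhyloTree.from_newick("(A:0.1,B:0.1,C:0.1);")
    aln = CodonAlignment(["A", "B", "C"], ["ATGGCT"] * 3)
    with pytest.raises(ValueError, match="foreground"):
        fit_model(aln, tree, TWO_RATIO)


def test_two_ratio_recovers_foreground_omega(bird_tree):
    """A neutral focal branch over a purifying background separates the
    two omegas."""
    params = CodonModelParams(kappa=2.0, omega_background=0.2, omega_foreground=1.0)
    aln, _ = simulate_codon_alignment(bird_tree, params, 800, seed=33)
    fit0 = fit_model(aln, bird_tree, ONE_RATIO, FAST)
    fit1 = fit_model(aln, bird_tree, TWO_RATIO, FAST, init_fit=fit0)
    assert fit1.params.omega_background == pytest.approx(0.2, abs=0.07)
    assert fit1.params.omega_foreground == pytest.approx(1.0, rel=0.45)
    assert branch_lrt(fit0, fit1).significant


def test_recovery_sharpens_with_alignment_length(bird_tree, default_params):
    """|omega-hat - omega| shrinks, on average over replicates, as the
    alignment grows."""
    def mean_abs_err(n_codons, n_rep=20):
        errs = []
        for r in range(n_rep):
            aln, _ = simulate_codon_alignment(
                bird_tree, default_params, n_codons, seed=1000 * n_codons + r
            )
            fit = fit_model(aln, bird_tree, ONE_RATIO, FAST)
            errs.append(abs(fit.params.omega_background - 0.3))
        return np.mean(errs)

    assert mean_abs_err(100) > mean_abs_err(900)


def test_lrt_zero_when_likelihoods_equal(bird_alignment, bird_tree):
    aln, _ = bird_alignment
    fit0 = fit_model(aln, bird_tree, ONE_RATIO, FAST)
    fit1 = fit_model(aln, bird_tree, TWO_RATIO, FAST, init_fit=fit0)
    forced = branch_lrt(fit0, fit0.__class__(**{**fit0.__dict__, "model_id": TWO_RATIO}))
    assert forced.statistic == 0.0
    assert forced.pvalue == pytest.approx(1.0)
    assert not forced.significant
    # and the real pair orders correctly
    assert branch_lrt(fit0, fit1).statistic >= 0.0


def test_lrt_critical_value_and_checks(bird_alignment, bird_tree, default_params):
    aln, _ = bird_alignment
    fit0 = fit_model(aln, bird_tree, ONE_RATIO, FAST)
    fit1 = fit_model(aln, bird_tree, TWO_RATIO, FAST, init_fit=fit0)
    res = branch_lrt(fit0, fit1, alpha=0.05)
    assert res.critical_value == pytest.approx(3.84, abs=0.005)
    assert res.df == 1
    with pytest.raises(ValueError, match="one-ratio"):
        branch_lrt(fit1, fit0)
    other, _ = simulate_codon_alignment(bird_tree, default_params, 300, seed=99)
    fit_other = fit_model(other, bird_tree, TWO_RATIO, FAST)
    with pytest.raises(ValueError, match="different alignments"):
        branch_lrt(fit0, fit_other)


def test_pairwise_kaks_identical_sequences():
    res = pairwise_kaks("ATGGCTAAA" * 20, "ATGGCTAAA" * 20)
    assert res.ka == 0.0 and res.ks == 0.0
    assert res.undefined and np.isnan(res.omega)


def test_pairwise_kaks_recovery():
    """omega-hat within +/-0.1 for a pair at total divergence 0.4,
    omega = 0.5."""
    tree = PhyloTree.from_newick("(A:0.2,B:0.2);")
    params = CodonModelParams(kappa=2.0, omega_background=0.5)
    aln, _ = simulate_codon_alignment(tree, params, 2000, seed=5)
    res = pairwise_kaks(aln.sequences[0], aln.sequences[1])
    assert not res.undefined
    assert res.omega == pytest.approx(0.5, abs=0.1)
    assert res.ka / res.ks == pytest.approx(res.omega, rel=1e-6)


def test_pairwise_kaks_consistent_with_fit_model():
    """The pairwise estimator is the two-taxon special case of the full
    branch-model fit."""
    tree = PhyloTree.from_newick("(A:0.15,B:0.15);")
    params = CodonModelParams(kappa=2.0, omega_background=0.4)
    aln, _ = simulate_codon_alignment(tree, params, 300, seed=8)
    res = pairwise_kaks(aln.sequences[0], aln.sequences[1], names=("A", "B"))
    fit = fit_model(aln, tree, ONE_RATIO, FitConfig(n_starts=2))
    assert res.omega == pytest.approx(fit.params.omega_background, rel=1e-3)
    assert res.t == pytest.approx(
        sum(fit.tree.lengths[e] for e in fit.tree.edges()), rel=1e-3
    )


def test_pairwise_kaks_frame_violation():
    with pytest.raises(ValueError):
        pairwise_kaks("ATGGC", "ATGGC")
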