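"""Hypergeometric enrichment, FWER correction, and the relaxed filter."""

import itertools
import math

import pytest
from hypothesis import given, settings, strategies as st

from kiwigenomics.enrichment import (
    BONFERRONI,
    HOLM,
    CategoryAnnotation,
    EnrichmentRow,
    apply_relaxed_filter,
    fwer_correct,
    hypergeometric_enrichment,
    relaxed_filter,
    species_specific_categories,
)
from kiwigenomics.simulate import simulate_category_data


def make_annotation(n_universe, category_sizes):
    universe = {f"g{i}" for i in range(n_universe)}
    ordered = sorted(universe)
    cats, start = {}, 0
    for name, size in category_sizes.items():
        cats[name] = set(ordered[start : start + size])
        start += size
    return CategoryAnnotation(categories=cats, universe=universe)


def brute_force_uppertail(N, K, n, k):
    """P(X >= k) by direct enumeration of drawn subsets."""
    hits = sum(
        1
        for draw in itertools.combinations(range(N), n)
        if sum(1 for g in draw if g < K) >= k
    )
    return hits / math.comb(N, n)


class TestHypergeometric:
    def test_worked_example_n10_k5(self):
        """N=10, K=5, n=4, k=3: p = (C(5,3)C(5,1)+C(5,4)C(5,0))/C(10,4)."""
        annot = make_annotation(10, {"cat": 5})
        sig = sorted(annot.categories["cat"])[:3] + [sorted(annot.universe - annot.categories["cat"])[0]]
        rows = hypergeometric_enrichment(annot, sig)
        assert rows[0].pvalue == pytest.approx(55 / 210)

    def test_empty_significant_list(self):
        annot = make_annotation(10, {"cat": 5})
        rows = hypergeometric_enrichment(annot, [])
        assert rows[0].pvalue == 1.0
        assert rows[0].n_significant_in_category == 0

    def test_category_equal_to_universe(self):
        annot = make_annotation(6, {"all": 6})
        rows = hypergeometric_enrichment(annot, ["g0", "g1"])
        assert rows[0].pvalue == pytest.approx(1.0)

    def test_genes_outside_universe_rejected(self):
        annot = make_annotation(6, {"cat": 3})
        with pytest.raises(ValueError, match="outside"):
            hypergeometric_enrichment(annot, ["nope"])

    @pytest.mark.parametrize(
        "N,K,n", [(8, 3, 4), (10, 5, 4), (12, 6, 5), (9, 4, 3)]
    )
    def test_matches_enumeration_for_small_universes(self, N, K, n):
        annot = make_annotation(N, {"cat": K})
        in_cat = sorted(annot.categories["cat"])
        out_cat = sorted(annot.universe - annot.categories["cat"])
        for k in range(0, min(K, n) + 1):
            sig = in_cat[:k] + out_cat[: n - k]
            row = hypergeometric_enrichment(annot, sig)[0]
            assert row.pvalue == pytest.approx(
                brute_force_uppertail(N, K, n, k), abs=1e-12
            ), (N, K, n, k)


class TestFWER:
    def _rows(self, pvals):
        return [
            EnrichmentRow(f"c{i}", 100, 10, 5, 2, p) for i, p in enumerate(pvals)
        ]

    def test_single_test_unchanged(self):
        out = fwer_correct(self._rows([0.03]))
        assert out[0].fwer_adjusted == pytest.approx(0.03)

    def test_bonferroni_multiplies(self):
        out = fwer_correct(self._rows([0.01] * 20), method=BONFERRONI)
        assert all(r.fwer_adjusted == pytest.approx(0.20) for r in out)

    def test_holm_dominates_bonferroni(self):
        pvals = [0.001, 0.01, 0.02, 0.04, 0.2, 0.5]
        bonf = fwer_correct(self._rows(pvals), method=BONFERRONI)
        holm = fwer_correct(self._rows(pvals), method=HOLM)
        for b, h in zip(bonf, holm):
            assert h.fwer_adjusted <= b.fwer_adjusted + 1e-15
            assert h.fwer_adjusted >= h.pvalue

    def test_adjusted_capped_at_one(self):
        out = fwer_correct(self._rows([0.3, 0.4, 0.9]))
        assert all(r.fwer_adjusted <= 1.0 for r in out)


class TestRelaxedFilter:
    def _row(self, p, k, K):
        return EnrichmentRow("c", 1000, K, 50, k, p)

    def test_boundary_pass(self):
        assert relaxed_filter(self._row(0.04, 3, 60))  # exactly 5 %

    def test_two_genes_always_fail(self):
        assert not relaxed_filter(self._row(1e-9, 2, 10))

    def test_below_five_percent_fails(self):
        assert not relaxed_filter(self._row(0.04, 3, 100))

    def test_p_at_alpha_fails(self):
        assert not relaxed_filter(self._row(0.05, 10, 50))

    @given(
        p=st.floats(1e-6, 0.2),
        k=st.integers(0, 30),
        K=st.integers(30, 200),
    )
    @settings(deadline=None)
    def test_monotone_in_p_and_k(self, p, k, K):
        """Decreasing p or increasing k (K fixed) never flips pass->fail."""
        base = relaxed_filter(self._row(p, k, K))
        if base:
            assert relaxed_filter(self._row(p / 2, k, K))
            assert relaxed_filter(self._row(p, min(k + 1, K), K))


class TestSpeciesSpecific:
    def test_partition(self):
        passing = {
            "kiwi": {"vision", "immune", "circadian"},
            "ostrich": {"vision"},
            "owl": {"metabolism"},
        }
        out = species_specific_categories(passing, focal="kiwi")
        assert out["specific"] == {"immune", "circadian"}
        assert out["shared"] == {"vision": ["ostrich"]}

    def test_empty_focal(self):
        out = species_specific_categories({"kiwi": set(), "ostrich": {"x"}}, "kiwi")
        assert out["specific"] == set() and out["shared"] == {}

    def test_missing_focal_rejected(self):
        with pytest.raises(ValueError, match="focal"):
            species_specific_categories({"ostrich": set()}, "kiwi")


class TestPlantedEnrichment:
    def test_planted_category_passes_relaxed_filter(self):
        """A 10-fold odds category is detected in nearly every seed."""
        hits = 0
        for seed in range(10):
            data, sig, truth = simulate_category_data(
                n_genes=2000, n_categories=20, sig_fraction=0.05,
                planted=(3, 10.0), seed=seed,
            )
            annot = CategoryAnnotation(**data)
            rows = apply_relaxed_filter(hypergeometric_enrichment(annot, sig))
            passing = {r.category for r in rows if r.passes_relaxed}
            hits += truth["planted_category"] in passing
        assert hits >= 9

    def test_null_odds_rarely_pass(self):
        """Without planted signal the three criteria seldom fire."""
        n_pass = 0
        for seed in range(5):
            data, sig, _ = simulate_category_data(
                n_genes=2000, n_categories=20, sig_fraction=0.05, seed=100 + seed
            )
            annot = CategoryAnnotation(**data)
            rows = apply_relaxed_filter(hypergeometric_enrichment(annot, sig))
            n_pass += sum(r.passes_relaxed for r in rows)
        assert n_pass <= 10  # ~5 % of 100 category-tests, with slack
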