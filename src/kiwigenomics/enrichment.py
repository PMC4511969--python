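"""Category enrichment over selection-screen gene lists.

Per-species gene lists (genes with significantly different omega on the
focal branch) are tested category-by-category with the one-sided
upper-tail hypergeometric probability, corrected for family-wise error,
then filtered by three relaxed criteria: nominal p < 0.05, at least three
significant genes in the category, and significant genes making up at
least 5 % of the category. Categories passing only in the focal species
are flagged species-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd
from scipy.stats import hypergeom

BONFERRONI = "bonferroni"
HOLM = "holm"


@dataclass
class CategoryAnnotation:
    """gene -> category membership over a fixed gene universe.

    ``categories`` maps category id to its member gene set; ``universe``
    is every annotated gene. If the input annotation has ancestral terms
    propagated, they are used as-is — no ontology graph traversal happens
    here.
    """

    categories: dict
    universe: set

    def __post_init__(self):
        self.universe = set(self.universe)
        for cat, members in self.categories.items():
            members = set(members)
            if not members:
                raise ValueError(f"category {cat!r} is empty")
            extra = members - self.universe
            if extra:
                raise ValueError(f"category {cat!r} has genes outside the universe: {sorted(extra)[:5]}")
            self.categories[cat] = members

    @classmethod
    def from_tsv(cls, path, universe=None) -> "CategoryAnnotation":
        """Read `gene<TAB>category` pairs, one per line."""
        df = pd.read_csv(path, sep="\t", header=None, names=["gene", "category"], dtype=str)
        cats = {}
        for cat, grp in df.groupby("category"):
            cats[cat] = set(grp["gene"])
        return cls(categories=cats, universe=universe or set(df["gene"]))


@dataclass
class EnrichmentRow:
    category: str
    n_universe: int
    n_category: int
    n_significant_total: int
    n_significant_in_category: int
    pvalue: float
    fwer_adjusted: float = None
    passes_relaxed: bool = None


def hypergeometric_enrichment(annotation: CategoryAnnotation, significant_genes) -> list:
    """Upper-tail hypergeometric P(X >= k) per category.

    With N universe genes, K in the category, n significant overall and k
    significant inside the category, the p-value is the probability of
    drawing at least k category members in n draws without replacement.
    """
    sig = set(significant_genes)
    outside = sig - annotation.universe
    if outside:
        raise ValueError(f"significant genes outside the universe: {sorted(outside)}")
    N, n = len(annotation.universe), len(sig)
    rows = []
    for cat in sorted(annotation.categories):
        members = annotation.categories[cat]
        K = len(members)
        k = len(sig & members)
        p = float(hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append(
            EnrichmentRow(
                category=cat, n_universe=N, n_category=K,
                n_significant_total=n, n_significant_in_category=k,
                pvalue=min(p, 1.0),
            )
        )
    return rows


def fwer_correct(rows, method: str = BONFERRONI) -> list:
    """Family-wise error-rate adjustment (Bonferroni default, Holm available)."""
    m = len(rows)
    if m == 0:
        return []
    if method == BONFERRONI:
        adj = {id(r): min(1.0, r.pvalue * m) for r in rows}
    elif method == HOLM:
        order = sorted(rows, key=lambda r: r.pvalue)
        adj, running = {}, 0.0
        for i, r in enumerate(order):
            running = max(running, min(1.0, (m - i) * r.pvalue))
            adj[id(r)] = running
    else:
        raise ValueError(f"unknown FWER method {method!r}")
    return [replace(r, fwer_adjusted=adj[id(r)]) for r in rows]


def relaxed_filter(row: EnrichmentRow, alpha: float = 0.05, min_genes: int = 3,
                   min_fraction: float = 0.05) -> bool:
    """Three-criterion relaxed filter on an enrichment row.

    Passes iff nominal p < alpha AND at least ``min_genes`` significant
    genes fall in the category AND they are at least ``min_fraction`` of
    the category's genes. The p threshold is strict (< alpha); the count
    and fraction thresholds are inclusive (>=).
    """
    k, K = row.n_significant_in_category, row.n_category
    return row.pvalue < alpha and k >= min_genes and k / K >= min_fraction


def apply_relaxed_filter(rows, **kwargs) -> list:
    return [replace(r, passes_relaxed=relaxed_filter(r, **kwargs)) for r in rows]


def species_specific_categories(per_species_passing: dict, focal: str) -> dict:
    """Split the focal species' passing categories into specific vs shared.

    A category is species-specific when it passes in the focal species but
    in none of the others; otherwise it is shared and annotated with the
    co-occurring species.
    """
    if focal not in per_species_passing:
        raise ValueError(f"focal species {focal!r} missing from the map")
    focal_set = set(per_species_passing[focal])
    shared = {}
    for cat in focal_set:
        others = sorted(
            sp for sp, cats in per_species_passing.items()
            if sp != focal and cat in set(cats)
        )
        if others:
            shared[cat] = others
    return {
        "specific": focal_set - set(shared),
        "shared": shared,
    }


def rows_to_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "category": [r.category for r in rows],
            "n_universe": [r.n_universe for r in rows],
            "n_category": [r.n_category for r in rows],
            "n_significant_total": [r.n_significant_total for r in rows],
            "n_significant_in_category": [r.n_significant_in_category for r in rows],
            "pvalue": [r.pvalue for r in rows],
            "fwer_adjusted": [r.fwer_adjusted for r in rows],
            "passes_relaxed": [r.passes_relaxed for r in rows],
        }
    )
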