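"""End-to-end orchestration of the analysis stages.

``run_selection_screen`` is the two-stage screen: per-gene branch-model
LRTs (uncorrected at alpha, matching a screen whose multiple-testing
control lives at the category level), then hypergeometric category
enrichment with FWER adjustment and the three-criterion relaxed filter.
``run_nocturnality_report`` collates the stage outputs into one JSON-able
report; a missing stage is marked absent rather than aborting.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import pandas as pd

from . import enrichment as enr
from .codon_alignment import CodonAlignment, filter_set1, longest_clean_block
from .phylo import PhyloTree
from .selection import (
    ONE_RATIO,
    TWO_RATIO,
    FitConfig,
    branch_lrt,
    fit_model,
)

log = logging.getLogger("kiwigenomics")


@dataclass
class SelectionScreenResult:
    gene_table: pd.DataFrame
    enrichment_faster: list
    enrichment_slower: list
    n_filtered: int          # alignments failing both pre-filters
    n_failed: int            # per-gene fit failures (isolated, not fatal)


def screen_gene(
    aln: CodonAlignment,
    tree: PhyloTree,
    alpha: float = 0.05,
    config: FitConfig = None,
) -> dict:
    """Fit both branch models on one gene and run the LRT.

    The two-ratio fit warm-starts from the one-ratio optimum, which also
    guarantees the nested likelihood ordering.
    """
    fit0 = fit_model(aln, tree, ONE_RATIO, config)
    fit1 = fit_model(aln, tree, TWO_RATIO, config, init_fit=fit0)
    lrt = branch_lrt(fit0, fit1, alpha=alpha)
    return {
        "lnL0": fit0.lnL,
        "lnL1": fit1.lnL,
        "kappa": fit1.params.kappa,
        "omega_background": fit1.params.omega_background,
        "omega_foreground": fit1.params.omega_foreground,
        "lrt": lrt.statistic,
        "pvalue": lrt.pvalue,
        "significant": lrt.significant,
        "direction": (
            "faster" if fit1.params.omega_foreground > fit1.params.omega_background else "slower"
        ),
        "converged": fit0.converged and fit1.converged,
    }


def prefilter_alignment(aln: CodonAlignment, min_block: int = 200):
    """Apply the strict no-frameshift filter, falling back to the longest
    clean block of at least ``min_block`` aligned bases.

    Returns (usable alignment or None, filter label).
    """
    if filter_set1(aln):
        return aln, "set1"
    block = longest_clean_block(aln, min_len=min_block)
    if block is None:
        return None, "rejected"
    start, end = block
    return aln.subset_columns(start // 3, end // 3), "clean-block"


def run_selection_screen(
    alignments: dict,
    tree: PhyloTree,
    foreground: str,
    annotation: "enr.CategoryAnnotation" = None,
    alpha: float = 0.05,
    config: FitConfig = None,
    fwer_method: str = enr.BONFERRONI,
) -> SelectionScreenResult:
    """Per-gene branch LRT screen plus category enrichment.

    ``alignments`` maps gene id -> CodonAlignment over the tree's taxa.
    One bad gene never aborts the screen: failures are logged and tallied.
    """
    if not alignments:
        raise ValueError("no alignments supplied")
    fg_tree = tree.with_foreground_taxon(foreground)
    rows, n_filtered, n_failed = [], 0, 0
    for gene, aln in sorted(alignments.items()):
        usable, label = prefilter_alignment(aln)
        if usable is None:
            n_filtered += 1
            log.info("gene %s rejected by alignment pre-filters", gene)
            continue
        try:
            rec = screen_gene(usable, fg_tree, alpha=alpha, config=config)
        except Exception as exc:  # isolate per-gene failures
            n_failed += 1
            log.warning("gene %s failed: %s", gene, exc)
            continue
        rec.update(gene=gene, filter=label)
        rows.append(rec)
    gene_table = pd.DataFrame(rows)

    enr_faster, enr_slower = [], []
    if annotation is not None and not gene_table.empty:
        sig = gene_table[gene_table["significant"]]
        for direction, out in (("faster", enr_faster), ("slower", enr_slower)):
            genes = set(sig[sig["direction"] == direction]["gene"]) & annotation.universe
            rows_e = enr.hypergeometric_enrichment(annotation, genes)
            rows_e = enr.fwer_correct(rows_e, method=fwer_method)
            out.extend(enr.apply_relaxed_filter(rows_e))
    return SelectionScreenResult(
        gene_table=gene_table,
        enrichment_faster=enr_faster,
        enrichment_slower=enr_slower,
        n_filtered=n_filtered,
        n_failed=n_failed,
    )


def run_nocturnality_report(sections: dict, path=None) -> dict:
    """Collate stage outputs into a single report.

    ``sections`` maps section name (selection, dating, repertoire,
    entropy, genome_size, ucne) to a JSON-able payload or None; absent or
    None sections are marked, never fatal.
    """
    known = ["selection", "dating", "repertoire", "entropy", "genome_size", "ucne"]
    report = {}
    for name in known:
        payload = sections.get(name)
        report[name] = {"present": payload is not None, "data": payload}
    for extra in sorted(set(sections) - set(known)):
        report[extra] = {"present": sections[extra] is not None, "data": sections[extra]}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(report, fh, indent=2, default=str)
    return report
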