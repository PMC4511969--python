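"""Divergence screen of ultra-conserved non-coding elements (UCNEs).

UCNEs are non-coding regions of at least 95 % human-chicken identity over
more than 200 bp; in a lineage where one is evolving freely, its ortholog
accumulates more than the ~5 % variation the definition tolerates. Each
candidate ortholog is globally aligned to the reference element and
flagged when (mismatches + gap columns) / reference length exceeds the
threshold (strictly). Ortholog retrieval is the caller's job; missing
orthologs are counted, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import Align, SeqIO

DEFAULT_THRESHOLD = 0.05


@dataclass
class UCNERecord:
    element_id: str
    sequence: str
    gene_label: str = ""

    def __post_init__(self):
        self.sequence = self.sequence.upper()

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class VariationResult:
    element_id: str
    aligned_length: int
    mismatches: int
    gap_columns: int
    variation: float
    flagged: bool


@dataclass
class ScreenSummary:
    n_screened: int
    n_flagged: int
    n_missing: int
    results: pd.DataFrame


def load_catalog(fasta_path) -> list:
    """Read a UCNE catalog from FASTA (record id = element id; the rest of
    the header, if any, is kept as the associated gene label)."""
    out = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        out.append(UCNERecord(rec.id, str(rec.seq), rec.description.partition(" ")[2]))
    return out


def validate_catalog(records, min_length: int = 200):
    """Split records into accepted elements and rejects with reasons.

    The length bound is strict (elements must be longer than
    ``min_length``); sequences must be pure ACGT. Rejection is data, not
    failure.
    """
    accepted, rejects = [], []
    for rec in records:
        if rec.length <= min_length:
            rejects.append((rec, f"length {rec.length} <= {min_length}"))
        elif set(rec.sequence) - set("ACGT"):
            bad = sorted(set(rec.sequence) - set("ACGT"))
            rejects.append((rec, f"non-ACGT symbols {bad}"))
        else:
            accepted.append(rec)
    return accepted, rejects


def _make_aligner(match=1.0, mismatch=-1.0, gap_open=-5.0, gap_extend=-1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def variation_fraction(
    reference: str,
    ortholog: str,
    threshold: float = DEFAULT_THRESHOLD,
    aligner: Align.PairwiseAligner = None,
    element_id: str = "",
) -> VariationResult:
    """Fraction of the reference diverged in the ortholog.

    Globally aligns the ortholog to the reference (affine gaps) and counts
    substitutions plus gap columns over the reference length; gaps count
    as differences (the conservative reading of 'mismatches'). Flagged
    when variation strictly exceeds the threshold.
    """
    if not reference or not ortholog:
        raise ValueError("empty sequence")
    aligner = aligner or _make_aligner()
    alignment = aligner.align(reference.upper(), ortholog.upper())[0]
    counts = alignment.counts()
    variation = (counts.mismatches + counts.gaps) / len(reference)
    return VariationResult(
        element_id=element_id,
        aligned_length=alignment.length,
        mismatches=int(counts.mismatches),
        gap_columns=int(counts.gaps),
        variation=float(variation),
        flagged=variation > threshold,
    )


def screen_catalog(
    records,
    orthologs: dict,
    threshold: float = DEFAULT_THRESHOLD,
    per_element_threshold: dict = None,
) -> ScreenSummary:
    """Screen every catalog element against its supplied ortholog.

    ``orthologs`` maps element id -> sequence; elements without an entry
    are tallied as missing. ``per_element_threshold`` overrides the flat
    threshold for named elements (some catalogs define element-specific
    expected identity).
    """
    aligner = _make_aligner()
    per_element_threshold = per_element_threshold or {}
    rows, n_flagged, n_missing = [], 0, 0
    for rec in records:
        ortho = orthologs.get(rec.element_id)
        if ortho is None:
            n_missing += 1
            rows.append(
                {"element_id": rec.element_id, "status": "missing", "variation": None,
                 "mismatches": None, "gap_columns": None, "flagged": False}
            )
            continue
        thr = per_element_threshold.get(rec.element_id, threshold)
        res = variation_fraction(rec.sequence, ortho, thr, aligner, rec.element_id)
        n_flagged += res.flagged
        rows.append(
            {"element_id": rec.element_id, "status": "screened",
             "variation": res.variation, "mismatches": res.mismatches,
             "gap_columns": res.gap_columns, "flagged": res.flagged}
        )
    return ScreenSummary(
        n_screened=len(records) - n_missing,
        n_flagged=n_flagged,
        n_missing=n_missing,
        results=pd.DataFrame(rows),
    )
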