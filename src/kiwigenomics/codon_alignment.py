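"""In-frame codon alignments: container, FASTA IO, pre-filters, frequencies.

The alignment filters mirror a two-stage ortholog-screen design: a strict
pass keeping only alignments free of frameshift indels, and a rescue pass
extracting the longest clean block of at least 200 aligned bases.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetics import GeneticCode, UNIVERSAL_CODE

GAP = "-"
AMBIG = "N"


@dataclass
class CodonAlignment:
    """Aligned in-frame coding sequences over {A,C,G,T,N,-}.

    Every sequence has the same length, divisible by 3; frame-1 codons free
    of gaps must not be stop codons (internal stops disqualify coding
    alignments from selection analysis).
    """

    taxa: list
    sequences: list
    code: GeneticCode = field(default_factory=lambda: UNIVERSAL_CODE)

    def __post_init__(self):
        if len(self.taxa) != len(self.sequences):
            raise ValueError("taxa and sequences differ in number")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon names")
        self.sequences = [s.upper() for s in self.sequences]
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        if self.sequences and len(self.sequences[0]) % 3 != 0:
            raise ValueError("alignment length not divisible by 3")
        bad = set("".join(self.sequences)) - set("ACGTN" + GAP)
        if bad:
            raise ValueError(f"unexpected symbols in alignment: {sorted(bad)}")
        for name, seq in zip(self.taxa, self.sequences):
            for k in range(0, len(seq) - 3, 3):  # final codon may be a stop
                cod = seq[k : k + 3]
                if GAP in cod or AMBIG in cod:
                    continue
                if self.code.is_stop(cod):
                    raise ValueError(f"internal stop codon {cod} at position {k} in {name}")

    @property
    def n_codons(self) -> int:
        return len(self.sequences[0]) // 3 if self.sequences else 0

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def codon(self, taxon_idx: int, column: int) -> str:
        return self.sequences[taxon_idx][3 * column : 3 * column + 3]

    def complete_columns(self):
        """Indices of codon columns with no gap or N in any taxon."""
        keep = []
        for col in range(self.n_codons):
            if all(
                GAP not in self.codon(t, col) and AMBIG not in self.codon(t, col)
                for t in range(self.n_taxa)
            ):
                keep.append(col)
        return keep

    def state_matrix(self) -> np.ndarray:
        """(n_taxa, n_complete_columns) sense-codon state indices.

        Columns containing a gap or ambiguity in any taxon are excluded
        (complete-column analysis); terminal stop codons are likewise
        dropped since they are outside the sense-codon state space.
        """
        cols = []
        for col in self.complete_columns():
            codons = [self.codon(t, col) for t in range(self.n_taxa)]
            if any(self.code.is_stop(c) for c in codons):
                continue  # terminal stop column
            cols.append([self.code.index(c) for c in codons])
        if not cols:
            return np.empty((self.n_taxa, 0), dtype=np.intp)
        return np.asarray(cols, dtype=np.intp).T

    def subset_columns(self, start: int, end: int) -> "CodonAlignment":
        """New alignment over codon columns [start, end)."""
        return CodonAlignment(
            list(self.taxa), [s[3 * start : 3 * end] for s in self.sequences], self.code
        )

    @classmethod
    def from_fasta(cls, path, code: GeneticCode = UNIVERSAL_CODE) -> "CodonAlignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        return cls([r.id for r in records], [str(r.seq) for r in records], code)

    def to_fasta(self, path) -> None:
        SeqIO.write(
            (SeqRecord(Seq(s), id=t, description="") for t, s in zip(self.taxa, self.sequences)),
            str(path),
            "fasta",
        )


def filter_set1(aln: CodonAlignment) -> bool:
    """Strict alignment filter: no frameshift indel in any sequence.

    True iff every gap run in every sequence has length divisible by 3
    (indels preserve the reading frame). Internal stops are already
    rejected by the container invariant.
    """
    for seq in aln.sequences:
        for m in re.finditer(rf"{GAP}+", seq):
            if (m.end() - m.start()) % 3 != 0:
                return False
    return True


def longest_clean_block(
    aln: CodonAlignment, min_len: int = 200, unresolved_chars=frozenset({AMBIG})
):
    """Longest run of aligned bases free of gaps and unresolved characters.

    Scans nucleotide columns; a column is clean when no sequence carries a
    gap or an unresolved symbol there. The maximal clean run is trimmed
    inward to codon boundaries and returned as ``(start, end)`` nucleotide
    coordinates (0-based, half-open) if its trimmed length is at least
    ``min_len``; ties broken by leftmost start. Returns None when no block
    qualifies — absence is a legitimate outcome, not an error.
    """
    if aln.n_codons == 0:
        return None
    bad_syms = set(unresolved_chars) | {GAP}
    ncols = len(aln.sequences[0])
    clean = np.ones(ncols, dtype=bool)
    for seq in aln.sequences:
        for i, ch in enumerate(seq):
            if ch in bad_syms:
                clean[i] = False
    best = None
    i = 0
    while i < ncols:
        if not clean[i]:
            i += 1
            continue
        j = i
        while j < ncols and clean[j]:
            j += 1
        # trim inward to codon boundaries
        start = -(-i // 3) * 3
        end = (j // 3) * 3
        if end - start >= min_len and (best is None or end - start > best[1] - best[0]):
            best = (start, end)
        i = j
    return best


def f3x4_frequencies(aln: CodonAlignment) -> np.ndarray:
    """Equilibrium sense-codon frequencies from position-specific
    nucleotide counts (the F3x4 estimator).

    Nucleotide frequencies are tallied separately at the three codon
    positions over all taxa (gaps and Ns skipped); each sense codon's
    frequency is the product of its positional frequencies, renormalized
    over the sense codons.
    """
    counts = np.zeros((3, 4))
    order = {n: k for k, n in enumerate("TCAG")}
    for seq in aln.sequences:
        for i, ch in enumerate(seq):
            if ch in order:
                counts[i % 3, order[ch]] += 1
    if counts.sum() == 0:
        raise ValueError("empty alignment: cannot estimate frequencies")
    # guard empty positions with a flat pseudocount
    counts += 1e-6
    freqs = counts / counts.sum(axis=1, keepdims=True)
    code = aln.code
    pi = np.array(
        [freqs[0, order[c[0]]] * freqs[1, order[c[1]]] * freqs[2, order[c[2]]]
         for c in code.sense_codons]
    )
    return pi / pi.sum()
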