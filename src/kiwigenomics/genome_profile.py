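"""k-mer-spectrum genome-size estimation and assembly summary statistics.

A read set sequenced at depth c from a genome of size G yields a k-mer
multiplicity histogram whose main peak sits at the effective k-mer depth
c_k = c * (L - k + 1) / L for read length L. Total k-mers above the
low-multiplicity error spike divided by the peak depth estimates G. The
estimator models a single peak only (no heterozygosity or repeat peaks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class KmerHistogram:
    """Multiplicity -> count of distinct k-mers observed that many times."""

    k: int
    entries: dict

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if any(m < 1 for m in self.entries):
            raise ValueError("multiplicities must be >= 1")
        if any(c < 0 for c in self.entries.values()):
            raise ValueError("counts must be >= 0")

    def as_arrays(self):
        """(multiplicity, count) dense arrays from 1 to the max multiplicity."""
        mmax = max(self.entries) if self.entries else 0
        counts = np.zeros(mmax + 1)
        for m, c in self.entries.items():
            counts[m] = c
        return np.arange(mmax + 1), counts

    @classmethod
    def from_tsv(cls, path, k: int) -> "KmerHistogram":
        df = pd.read_csv(path, sep="\t", header=None, names=["multiplicity", "count"])
        return cls(k=k, entries=dict(zip(df["multiplicity"].astype(int), df["count"].astype(int))))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for m in sorted(self.entries):
                fh.write(f"{m}\t{self.entries[m]}\n")


@dataclass
class GenomeSizeEstimate:
    """Genome size from a k-mer spectrum.

    ``size_bp`` divides by the raw peak depth c_k; ``size_bp_corrected``
    (when the read length is known) divides by the per-base coverage
    c = c_k * L / (L - k + 1) instead, i.e. multiplies by (L - k + 1) / L.
    """

    k: int
    error_cutoff: int
    peak_depth: int
    total_kmers: float
    size_bp: float
    size_bp_corrected: float = None


def kmer_histogram(reads, k: int) -> KmerHistogram:
    """Canonical k-mer multiplicity histogram of a read set.

    Each k-mer is counted as the lexicographic minimum of itself and its
    reverse complement (strand-collapsed); k-mers containing N are skipped.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = {}
    any_long_enough = False
    for read in reads:
        read = read.upper()
        if len(read) < k:
            continue
        any_long_enough = True
        for i in range(len(read) - k + 1):
            kmer = read[i : i + k]
            if "N" in kmer:
                continue
            rc = reverse_complement(kmer)
            canon = kmer if kmer <= rc else rc
            counts[canon] = counts.get(canon, 0) + 1
    if not any_long_enough:
        raise ValueError(f"k={k} exceeds every read length")
    hist = {}
    for m in counts.values():
        hist[m] = hist.get(m, 0) + 1
    return KmerHistogram(k=k, entries=hist)


def estimate_genome_size(hist: KmerHistogram, read_length: int = None) -> GenomeSizeEstimate:
    """Genome size = total k-mers above the error cutoff / peak depth.

    The error cutoff is the trough of the count curve — the multiplicity
    where it first turns upward, separating the sequencing-error spike at
    low multiplicity from the main coverage peak; the peak depth is the
    count argmax above the cutoff.
    """
    m, counts = hist.as_arrays()
    if len(m) < 2 or counts.sum() == 0:
        raise ValueError("empty k-mer histogram")
    # cutoff = the multiplicity where the count curve first turns upward,
    # i.e. the trough between the error spike and the coverage peak (with
    # no error spike this is just the left edge of the peak)
    cutoff = None
    for i in range(1, len(counts) - 1):
        if counts[i + 1] > counts[i]:
            cutoff = i
            break
    if cutoff is None:
        raise ValueError(
            "k-mer spectrum never turns upward: error spike and coverage "
            "peak are not separable (histogram is monotone)"
        )
    above = counts[cutoff + 1 :]
    if above.size == 0 or above.max() == 0:
        raise ValueError("no k-mers above the error cutoff")
    peak = int(cutoff + 1 + np.argmax(above))
    total = float((m[cutoff + 1 :] * counts[cutoff + 1 :]).sum())
    size = total / peak
    corrected = None
    if read_length is not None:
        if read_length <= hist.k:
            raise ValueError("read length must exceed k")
        corrected = size * (read_length - hist.k + 1) / read_length
    return GenomeSizeEstimate(
        k=hist.k,
        error_cutoff=cutoff,
        peak_depth=peak,
        total_kmers=total,
        size_bp=size,
        size_bp_corrected=corrected,
    )


def n50(lengths) -> int:
    """Smallest piece length such that pieces at least that long hold
    >= half the total bases."""
    arr = np.asarray(list(lengths))
    if arr.size == 0:
        raise ValueError("empty length list")
    if np.any(arr <= 0):
        raise ValueError("lengths must be positive")
    srt = np.sort(arr)[::-1]
    cum = np.cumsum(srt)
    return int(srt[np.searchsorted(cum, cum[-1] / 2.0)])
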