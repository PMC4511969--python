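"""Genetic code tables and the 61-state sense-codon space.

Codons are ordered lexicographically over T, C, A, G (the PAML convention),
so state indices line up with CODEML-style output when cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

NUCLEOTIDES = "TCAG"

# Universal (standard) genetic code, one-letter amino acids, '*' = stop.
_UNIVERSAL = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a->b is a transition."""
    return (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES)


@dataclass(frozen=True, eq=False)
class GeneticCode:
    """A genetic code over the 64 codons with a fixed sense-codon ordering.

    Attributes
    ----------
    table : dict
        codon -> one-letter amino acid, with '*' marking stops.
    sense_codons : tuple
        The non-stop codons in lexicographic TCAG order (61 for the
        universal code); their positions define the model's state indices.
    """

    table: dict = field(default_factory=lambda: dict(_UNIVERSAL))

    def __post_init__(self):
        if len(self.table) != 64:
            raise ValueError(f"genetic code must cover all 64 codons, got {len(self.table)}")

    @property
    def sense_codons(self) -> tuple:
        return self._sense()

    @lru_cache(maxsize=None)
    def _sense(self) -> tuple:
        order = {n: i for i, n in enumerate(NUCLEOTIDES)}
        key = lambda c: tuple(order[x] for x in c)
        return tuple(sorted((c for c, aa in self.table.items() if aa != "*"), key=key))

    @property
    def n_states(self) -> int:
        return len(self.sense_codons)

    def index(self, codon: str) -> int:
        """State index of a sense codon; raises on stops or unknown symbols."""
        try:
            return self._index_map()[codon.upper()]
        except KeyError:
            raise ValueError(f"not a sense codon: {codon!r}")

    @lru_cache(maxsize=None)
    def _index_map(self) -> dict:
        return {c: i for i, c in enumerate(self.sense_codons)}

    def is_stop(self, codon: str) -> bool:
        try:
            return self.table[codon.upper()] == "*"
        except KeyError:
            raise ValueError(f"unknown codon: {codon!r}")

    def translate(self, codon: str) -> str:
        return self.table[codon.upper()]

    @lru_cache(maxsize=None)
    def neighbor_table(self):
        """Single-step codon pairs as flat index arrays.

        Returns (i, j, transition, nonsynonymous): each one-dimensional
        numpy array over all ordered sense-codon pairs differing at exactly
        one position. Pairs differing at >1 position have zero instantaneous
        rate and are omitted.
        """
        codons = self.sense_codons
        ii, jj, ts, ns = [], [], [], []
        for i, ci in enumerate(codons):
            for j, cj in enumerate(codons):
                if i == j:
                    continue
                diffs = [p for p in range(3) if ci[p] != cj[p]]
                if len(diffs) != 1:
                    continue
                p = diffs[0]
                ii.append(i)
                jj.append(j)
                ts.append(is_transition(ci[p], cj[p]))
                ns.append(self.table[ci] != self.table[cj])
        return (
            np.asarray(ii, dtype=np.intp),
            np.asarray(jj, dtype=np.intp),
            np.asarray(ts, dtype=bool),
            np.asarray(ns, dtype=bool),
        )


UNIVERSAL_CODE = GeneticCode()
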