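"""Genetic-code bookkeeping for the 61-state sense-codon alphabet.

The codon substitution machinery works on the 61 sense codons of the
standard nuclear genetic code, indexed in fixed lexicographic order
(A < C < G < T), with stop codons excluded from the state space.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
MISSING = -1

#: Purine/pyrimidine classes used to tell transitions from transversions.
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a->b is a transition."""
    return (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES)


@dataclass(frozen=True)
class GeneticCode:
    """Standard nuclear genetic code with a fixed sense-codon ordering.

    Attributes
    ----------
    table:
        Mapping codon -> one-letter amino acid, or ``"*"`` for stops.
    sense_codons:
        The 61 non-stop codons in lexicographic order; their positions
        define the state indices used throughout the likelihood engine.
    """

    table: dict[str, str] = field(default_factory=dict)
    sense_codons: tuple[str, ...] = ()

    @classmethod
    def standard(cls) -> "GeneticCode":
        bio = CodonTable.unambiguous_dna_by_id[1]
        table = dict(bio.forward_table)
        for stop in bio.stop_codons:
            table[stop] = "*"
        sense = tuple(
            c for c in ("".join(p) for p in itertools.product(NUCLEOTIDES, repeat=3))
            if table[c] != "*"
        )
        return cls(table=table, sense_codons=sense)

    def __post_init__(self) -> None:
        if self.sense_codons:
            stops = [c for c, aa in self.table.items() if aa == "*"]
            if len(stops) != 3 or len(self.sense_codons) != 61:
                raise ValueError("standard code must have 3 stops and 61 sense codons")

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(sorted(c for c, aa in self.table.items() if aa == "*"))

    def index(self, codon: str) -> int:
        """State index of a sense codon (raises KeyError for stops)."""
        return self._index_map()[codon]

    def _index_map(self) -> dict[str, int]:
        # cached on the instance despite frozen dataclass
        m = getattr(self, "_idx", None)
        if m is None:
            m = {c: i for i, c in enumerate(self.sense_codons)}
            object.__setattr__(self, "_idx", m)
        return m

    def is_stop(self, codon: str) -> bool:
        return self.table.get(codon) == "*"

    def translate_codon(self, codon: str) -> str:
        """One-letter amino acid, ``*`` for stop, ``X`` if ambiguous/gapped."""
        return self.table.get(codon, "X")

    def is_synonymous(self, i: int, j: int) -> bool:
        ci, cj = self.sense_codons[i], self.sense_codons[j]
        return self.table[ci] == self.table[cj]


STANDARD_CODE = GeneticCode.standard()
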