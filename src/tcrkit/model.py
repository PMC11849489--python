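"""Canonical in-memory model: a Repertoire is an ordered list of Clonotypes.

A clonotype is one (CDR3 amino-acid sequence, V gene, J gene) rearrangement
with an abundance (read/clone count).  Frequencies are always derived from
counts and renormalized whenever the clonotype list changes, so that the
frequency vector of a finalized repertoire sums to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

#: The 20 standard amino acids, alphabetical one-letter code.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AA_ALPHABET)

#: Characters tolerated before QC in addition to the 20 standard letters.
#: '*' marks a stop codon, '_' an out-of-frame junction in caller exports.
PRE_QC_EXTRA = frozenset("*_")


@dataclass
class Clonotype:
    """One CDR3 rearrangement with its abundance.

    ``frequency`` is count / total repertoire count and is maintained by the
    owning :class:`Repertoire`; a free-standing clonotype carries 0.0.
    """

    cdr3_aa: str
    v_gene: str = ""
    j_gene: str = ""
    count: int = 1
    frequency: float = 0.0

    def key(self) -> tuple[str, str, str]:
        return (self.cdr3_aa, self.v_gene, self.j_gene)


@dataclass
class Repertoire:
    """An ordered collection of clonotypes for one sample."""

    sample_id: str
    clonotypes: list[Clonotype] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.recompute_frequencies()

    def __len__(self) -> int:
        return len(self.clonotypes)

    def __iter__(self) -> Iterator[Clonotype]:
        return iter(self.clonotypes)

    @property
    def total_count(self) -> int:
        return int(sum(c.count for c in self.clonotypes))

    @property
    def sequences(self) -> list[str]:
        return [c.cdr3_aa for c in self.clonotypes]

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([c.frequency for c in self.clonotypes], dtype=float)

    @property
    def counts(self) -> np.ndarray:
        return np.array([c.count for c in self.clonotypes], dtype=np.int64)

    def recompute_frequencies(self) -> None:
        total = self.total_count
        if total > 0:
            for c in self.clonotypes:
                c.frequency = c.count / total
        else:
            for c in self.clonotypes:
                c.frequency = 0.0

    def with_clonotypes(self, clonotypes: list[Clonotype]) -> "Repertoire":
        """A copy of this repertoire carrying a new clonotype list."""
        rep = Repertoire(
            sample_id=self.sample_id,
            clonotypes=[replace(c) for c in clonotypes],
            metadata=dict(self.metadata),
        )
        return rep

    def sorted_by_frequency(self) -> list[Clonotype]:
        """Clonotypes ordered by decreasing frequency, ties broken by CDR3."""
        return sorted(self.clonotypes, key=lambda c: (-c.frequency, c.cdr3_aa))
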