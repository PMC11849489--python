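"""General repertoire statistics.

Diversity is measured with the one-parameter Renyi entropy family

.. math::

    H_\\alpha = \\frac{1}{1-\\alpha} \\log_b \\sum_{i=1}^{N} P_i^{\\alpha}

where :math:`P_i` is the clone-mass frequency of sequence *i*, *N* the
number of unique sequences and *b* the logarithm base (default 2, i.e.
bits).  :math:`\\alpha` tunes the sensitivity to abundant clones: at
:math:`\\alpha=0` the entropy is the log richness :math:`\\log_b N`,
at :math:`\\alpha\\to 1` it is the Shannon entropy, and at
:math:`\\alpha\\to\\infty` it is :math:`-\\log_b \\max_i P_i`, driven by the
single most expanded clone.  A profile over an :math:`\\alpha` grid shows
the balance of rare versus expanded clones in one curve.

Clonality is the complement of Pielou evenness,
:math:`1 - H_1 / \\log_b N`: zero for a maximally even repertoire,
approaching one under strong clonal dominance.  A single-clonotype
repertoire is assigned clonality 1 (the evenness ratio is 0/0 there, and a
lone clone is maximal dominance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import EmptyInputError, MissingAnnotationError
from .model import AA_ALPHABET, Repertoire

#: Default alpha grid spanning the conventional Renyi curve display.
DEFAULT_ALPHAS: tuple[float, ...] = (0, 0.25, 0.5, 1, 2, 4, 8, 16, 32, np.inf)


def _check_freqs(freqs: np.ndarray) -> np.ndarray:
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size == 0:
        raise EmptyInputError("empty frequency vector")
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be strictly positive")
    if abs(freqs.sum() - 1.0) > 1e-6:
        raise ValueError(f"frequencies sum to {freqs.sum():.8f}, not 1")
    return freqs


def renyi_entropy(freqs, alpha: float, base: float = 2.0) -> float:
    """Renyi entropy of order ``alpha`` in log-``base`` units.

    Exact special cases: ``alpha=0`` returns log richness, ``alpha=1`` the
    Shannon entropy, ``alpha=inf`` the min-entropy.  Evaluation goes through
    log-space so large orders do not underflow.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    if base <= 1:
        raise ValueError("log base must exceed 1")
    p = _check_freqs(freqs)
    log_b = np.log(base)
    if alpha == 0:
        return float(np.log(p.size) / log_b)
    if alpha == 1:
        return float(-(p * np.log(p)).sum() / log_b)
    if np.isinf(alpha):
        return float(-np.log(p.max()) / log_b)
    return float(logsumexp(alpha * np.log(p)) / (1.0 - alpha) / log_b)


@dataclass
class DiversityProfile:
    """Renyi entropies evaluated over an alpha grid for one repertoire."""

    alphas: tuple[float, ...]
    entropies: tuple[float, ...]
    base: float = 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"alpha": self.alphas, "renyi_entropy": self.entropies})


def _repertoire_freqs(rep: Repertoire, weighted: bool = True) -> np.ndarray:
    if len(rep) == 0:
        raise EmptyInputError(f"repertoire {rep.sample_id} has no clonotypes")
    if weighted:
        counts = rep.counts.astype(float)
        return counts / counts.sum()
    return np.full(len(rep), 1.0 / len(rep))


def diversity_profile(
    rep: Repertoire,
    alphas=DEFAULT_ALPHAS,
    base: float = 2.0,
    weighted: bool = True,
) -> DiversityProfile:
    """Evaluate the Renyi curve over ``alphas``.

    ``weighted=True`` (default) uses clone-mass frequencies; ``False`` gives
    every unique sequence equal weight, which flattens the curve to
    :math:`\\log_b N`.
    """
    p = _repertoire_freqs(rep, weighted)
    ent = tuple(renyi_entropy(p, a, base) for a in alphas)
    return DiversityProfile(alphas=tuple(alphas), entropies=ent, base=base)


def clonality(rep: Repertoire, base: float = 2.0, weighted: bool = True) -> float:
    """Clonality score ``1 - Pielou evenness`` in ``[0, 1]``."""
    p = _repertoire_freqs(rep, weighted)
    n = p.size
    if n == 1:
        return 1.0
    shannon = renyi_entropy(p, 1.0, base)
    return float(1.0 - shannon / (np.log(n) / np.log(base)))


def length_distribution(rep: Repertoire, weighted: bool = False) -> dict[int, float]:
    """CDR3 length spectrum: unique-sequence counts or clone-mass shares."""
    table: dict[int, float] = {}
    for c in rep.clonotypes:
        val = c.frequency if weighted else 1.0
        table[len(c.cdr3_aa)] = table.get(len(c.cdr3_aa), 0.0) + val
    return dict(sorted(table.items()))


def gene_usage(
    rep: Repertoire, segment: str = "V", weighted: bool = False
) -> dict[str, float]:
    """Per-gene share of unique sequences or of clone mass; shares sum to 1."""
    if segment not in ("V", "J"):
        raise ValueError("segment must be 'V' or 'J'")
    genes = [c.v_gene if segment == "V" else c.j_gene for c in rep.clonotypes]
    if not any(genes):
        raise MissingAnnotationError(f"no {segment} gene calls in {rep.sample_id}")
    table: dict[str, float] = {}
    for c, g in zip(rep.clonotypes, genes):
        val = c.count if weighted else 1.0
        table[g] = table.get(g, 0.0) + val
    total = sum(table.values())
    return {g: v / total for g, v in sorted(table.items())}


def vj_pairing(rep: Repertoire, weighted: bool = False) -> pd.DataFrame:
    """V x J matrix of pair shares; the grand total is 1.

    Row sums reproduce ``gene_usage(segment='V')`` and column sums
    ``gene_usage(segment='J')``.
    """
    v_usage = gene_usage(rep, "V", weighted)  # raises if unannotated
    j_usage = gene_usage(rep, "J", weighted)
    mat = pd.DataFrame(
        0.0, index=sorted(v_usage), columns=sorted(j_usage), dtype=float
    )
    for c in rep.clonotypes:
        mat.loc[c.v_gene, c.j_gene] += c.count if weighted else 1.0
    return mat / mat.to_numpy().sum()


@dataclass
class ClonalComposition:
    """Top clones by frequency with the remaining mass pooled as 'other'."""

    top_clones: list[tuple[str, float]]
    other_frequency: float

    def to_frame(self) -> pd.DataFrame:
        rows = list(self.top_clones) + [("other", self.other_frequency)]
        return pd.DataFrame(rows, columns=["cdr3_aa", "frequency"])


def clonal_composition(rep: Repertoire, top_n: int = 10) -> ClonalComposition:
    if len(rep) == 0:
        raise EmptyInputError(f"repertoire {rep.sample_id} has no clonotypes")
    ranked = rep.sorted_by_frequency()
    top = [(c.cdr3_aa, c.frequency) for c in ranked[:top_n]]
    other = float(sum(c.frequency for c in ranked[top_n:]))
    return ClonalComposition(top_clones=top, other_frequency=other)


@dataclass
class PositionWeightMatrix:
    """Per-position amino-acid probabilities for equal-length sequences.

    ``probs`` is an L x 20 table over the standard alphabet with rows
    summing to 1 (pseudocount 0); ``support`` is the number of sequences
    summarized.
    """

    probs: pd.DataFrame
    support: int

    @property
    def length(self) -> int:
        return len(self.probs)

    def to_tsv(self, path) -> None:
        self.probs.to_csv(path, sep="\t", index_label="position")

    def conserved_positions(self, threshold: float = 1.0 - 1e-9) -> list[int]:
        return [
            i for i in range(self.length) if self.probs.iloc[i].max() >= threshold
        ]


def pwm_from_sequences(
    sequences: list[str], weights=None
) -> PositionWeightMatrix:
    """Build a PWM from equal-length sequences, optionally weighted."""
    if not sequences:
        raise EmptyInputError("no sequences for PWM")
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise ValueError("PWM requires equal-length sequences")
    if weights is None:
        weights = np.ones(len(sequences))
    weights = np.asarray(weights, dtype=float)
    counts = np.zeros((length, len(AA_ALPHABET)))
    idx = {a: i for i, a in enumerate(AA_ALPHABET)}
    for s, w in zip(sequences, weights):
        for pos, ch in enumerate(s):
            counts[pos, idx[ch]] += w
    probs = counts / counts.sum(axis=1, keepdims=True)
    return PositionWeightMatrix(
        probs=pd.DataFrame(probs, columns=list(AA_ALPHABET)),
        support=len(sequences),
    )


def logos_by_length(rep: Repertoire, top_n: int = 100) -> dict[int, PositionWeightMatrix]:
    """PWMs of the ``top_n`` most frequent sequences, one per CDR3 length.

    Variable-length sequences are never force-aligned; each length group
    gets its own unweighted PWM.
    """
    if len(rep) == 0:
        raise EmptyInputError(f"repertoire {rep.sample_id} has no clonotypes")
    top = [c.cdr3_aa for c in rep.sorted_by_frequency()[:top_n]]
    groups: dict[int, list[str]] = {}
    for s in top:
        groups.setdefault(len(s), []).append(s)
    return {length: pwm_from_sequences(seqs) for length, seqs in sorted(groups.items())}


def top_logo(rep: Repertoire, top_n: int = 100) -> PositionWeightMatrix:
    """PWM of the modal-length group among the ``top_n`` most frequent CDR3s.

    Ties on group size go to the shorter length.
    """
    groups = logos_by_length(rep, top_n)
    modal = max(groups, key=lambda length: (groups[length].support, -length))
    return groups[modal]
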