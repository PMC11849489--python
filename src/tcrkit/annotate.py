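"""Fuzzy annotation of query CDR3s against a labelled reference.

Queries are matched to reference sequences within edit distance 1
(Levenshtein by default, so one substitution, insertion, or deletion; a
substitutions-only mode restricts matching to Hamming distance 1).  The
index uses the symmetric-deletion scheme: every sequence is keyed by
itself and by each of its single-character-deletion variants, which makes
distance-1 candidate retrieval a handful of dictionary lookups instead of
a full scan; every candidate is then verified, so results are exactly the
brute-force neighbour set.

Only the most frequent clonotypes of a repertoire are annotated (default
top 3000 by frequency): disease-associated sequences tend to be clonally
expanded, and the cap keeps batch searches predictable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import EmptyInputError
from .model import Repertoire
from .qc import validate_cdr3

logger = logging.getLogger(__name__)

REFERENCE_COLUMNS = (
    "cdr3_aa",
    "v_gene",
    "j_gene",
    "condition",
    "cell_type",
    "cell_source",
    "provenance",
)


@dataclass(frozen=True)
class ReferenceRecord:
    """One annotated reference CDR3."""

    cdr3_aa: str
    v_gene: str = ""
    j_gene: str = ""
    condition: str = ""
    cell_type: str = ""
    cell_source: str = ""
    provenance: str = ""


@dataclass(frozen=True)
class AnnotationHit:
    """One (query, reference record) match within the mismatch budget."""

    query_cdr3: str
    matched_cdr3: str
    edit_distance: int
    record: ReferenceRecord
    query_frequency: float = 0.0


def within_one_edit(a: str, b: str) -> bool:
    """True iff Levenshtein distance(a, b) <= 1."""
    la, lb = len(a), len(b)
    if abs(la - lb) > 1:
        return False
    if la == lb:
        return sum(x != y for x, y in zip(a, b)) <= 1
    if la > lb:
        a, b, la, lb = b, a, lb, la
    # a is shorter by one: allow a single gap in a
    i = 0
    while i < la and a[i] == b[i]:
        i += 1
    return a[i:] == b[i + 1 :]


def _deletion_keys(seq: str) -> set[str]:
    return {seq} | {seq[:i] + seq[i + 1 :] for i in range(len(seq))}


@dataclass
class AnnotationIndex:
    """Deletion-variant index over a reference record list."""

    records: list[ReferenceRecord]
    _exact: dict[str, list[int]] = field(default_factory=dict, repr=False)
    _deletions: dict[str, list[int]] = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.records)


def build_reference_index(records: list[ReferenceRecord]) -> AnnotationIndex:
    """Build the distance-<=1 lookup index; construction is deterministic.

    Duplicate CDR3s with different annotations are retained as separate
    records.  Records failing the CDR3 sequence rules are rejected.
    """
    if not records:
        raise EmptyInputError("reference record list is empty")
    index = AnnotationIndex(records=list(records))
    for i, rec in enumerate(index.records):
        verdict = validate_cdr3(rec.cdr3_aa)
        if not verdict.passed:
            raise ValueError(
                f"reference record {i} ({rec.cdr3_aa!r}) fails CDR3 rules: "
                f"{','.join(verdict.reasons)}"
            )
        index._exact.setdefault(rec.cdr3_aa, []).append(i)
        for key in _deletion_keys(rec.cdr3_aa):
            index._deletions.setdefault(key, []).append(i)
    return index


def fuzzy_search(
    index: AnnotationIndex,
    query: str,
    max_mismatch: int = 1,
    substitutions_only: bool = False,
    query_frequency: float = 0.0,
) -> list[AnnotationHit]:
    """All reference records within ``max_mismatch`` edits of ``query``.

    ``max_mismatch`` may be 0 (exact) or 1.  Hits are sorted by
    (distance, matched sequence, record order); an empty list means no
    match.
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    query = query.upper()
    hits: list[AnnotationHit] = []
    if max_mismatch == 0:
        candidate_ids = list(index._exact.get(query, []))
    else:
        seen: set[int] = set()
        candidate_ids = []
        for key in sorted(_deletion_keys(query)):
            for i in index._deletions.get(key, []):
                if i not in seen:
                    seen.add(i)
                    candidate_ids.append(i)
    for i in sorted(candidate_ids):
        rec = index.records[i]
        if rec.cdr3_aa == query:
            dist = 0
        elif substitutions_only:
            if len(rec.cdr3_aa) != len(query):
                continue
            if sum(x != y for x, y in zip(rec.cdr3_aa, query)) != 1:
                continue
            dist = 1
        elif within_one_edit(rec.cdr3_aa, query):
            dist = 1
        else:
            continue
        if dist > max_mismatch:
            continue
        hits.append(
            AnnotationHit(
                query_cdr3=query,
                matched_cdr3=rec.cdr3_aa,
                edit_distance=dist,
                record=rec,
                query_frequency=query_frequency,
            )
        )
    hits.sort(key=lambda h: (h.edit_distance, h.matched_cdr3))
    return hits


def annotate_repertoire(
    rep: Repertoire,
    index: AnnotationIndex,
    top_n: int = 3000,
    max_mismatch: int = 1,
    substitutions_only: bool = False,
) -> pd.DataFrame:
    """Annotate the ``top_n`` most frequent clonotypes of a repertoire.

    Frequency ties at the cutoff are broken lexicographically.  The result
    has one row per (query, hit) pair; queries without any hit appear once
    with ``annotated=False``.
    """
    if len(rep) == 0:
        raise EmptyInputError(f"repertoire {rep.sample_id} has no clonotypes")
    ranked = rep.sorted_by_frequency()[:top_n]
    rows = []
    for c in ranked:
        hits = fuzzy_search(
            index,
            c.cdr3_aa,
            max_mismatch=max_mismatch,
            substitutions_only=substitutions_only,
            query_frequency=c.frequency,
        )
        if not hits:
            rows.append(
                {
                    "query_cdr3": c.cdr3_aa,
                    "query_frequency": c.frequency,
                    "annotated": False,
                    "matched_cdr3": "",
                    "edit_distance": -1,
                    "condition": "",
                    "cell_type": "",
                    "cell_source": "",
                    "provenance": "",
                }
            )
            continue
        for h in hits:
            rows.append(
                {
                    "query_cdr3": h.query_cdr3,
                    "query_frequency": h.query_frequency,
                    "annotated": True,
                    "matched_cdr3": h.matched_cdr3,
                    "edit_distance": h.edit_distance,
                    "condition": h.record.condition,
                    "cell_type": h.record.cell_type,
                    "cell_source": h.record.cell_source,
                    "provenance": h.record.provenance,
                }
            )
    return pd.DataFrame(rows)


def enrichment_summary(table: pd.DataFrame, field: str = "condition") -> pd.DataFrame:
    """Unique annotated query sequences per label of ``field``.

    A query annotated with several labels counts once under each; hitting
    the same label through several records still counts once.
    """
    if field not in ("condition", "cell_type", "cell_source"):
        raise ValueError("field must be condition, cell_type, or cell_source")
    annotated = table[table["annotated"]]
    if annotated.empty:
        return pd.DataFrame(columns=[field, "unique_sequences"])
    summary = (
        annotated.groupby(field)["query_cdr3"]
        .nunique()
        .reset_index(name="unique_sequences")
        .sort_values(["unique_sequences", field], ascending=[False, True])
        .reset_index(drop=True)
    )
    return summary


def read_reference_tsv(path: str | Path) -> list[ReferenceRecord]:
    """Load reference records from a TSV in the standard schema."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "cdr3_aa" not in df.columns:
        raise ValueError(f"{path}: reference TSV needs a 'cdr3_aa' column")
    return [
        ReferenceRecord(
            cdr3_aa=str(r.get("cdr3_aa", "")).upper(),
            v_gene=r.get("v_gene", ""),
            j_gene=r.get("j_gene", ""),
            condition=r.get("condition", ""),
            cell_type=r.get("cell_type", ""),
            cell_source=r.get("cell_source", ""),
            provenance=r.get("provenance", ""),
        )
        for r in df.to_dict("records")
    ]


def write_reference_tsv(records: list[ReferenceRecord], path: str | Path) -> None:
    df = pd.DataFrame([vars(r) for r in records], columns=list(REFERENCE_COLUMNS))
    df.to_csv(path, sep="\t", index=False)
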