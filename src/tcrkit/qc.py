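"""Quality control producing a reliable TRB CDR3 repertoire.

Five rules are applied, in a fixed order chosen so that allele collapse
precedes duplicate merging (otherwise identical-CDR3 records that differ
only in allele suffix would be undercounted):

1. V/J allele suffixes (``*NN``) are stripped, keeping the gene symbol.
2. Records lacking a V or J call are dropped (optional, for sequence-only
   inputs).
3. CDR3 sequences must follow the IMGT junction convention: start with
   cysteine, end with phenylalanine or tryptophan, contain no stop codon or
   frame-shift marker, and use only the 20 standard amino acids.
4. CDR3 lengths outside 8..24 amino acids are removed.
5. Identical CDR3 sequences with different V/J genes are merged into one
   clonotype that keeps the gene pair of the most abundant contributing
   record (count ties broken by lexicographically smallest symbol) and the
   summed count, preserving clone-abundance mass for diversity statistics.

The operation is idempotent and reports per-rule bookkeeping.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

from .model import AA_SET, Clonotype, Repertoire

MIN_CDR3_LENGTH = 8
MAX_CDR3_LENGTH = 24


@dataclass(frozen=True)
class ValidationVerdict:
    """Outcome of the CDR3 sequence rules, with machine-readable reasons."""

    passed: bool
    reasons: tuple[str, ...] = ()


@dataclass
class QCReport:
    """Per-rule bookkeeping for one QC run.

    ``output_records = input_records - dropped_missing_vj -
    dropped_invalid_cdr3 - dropped_length - merged_duplicates``.
    """

    input_records: int = 0
    merged_duplicates: int = 0
    dropped_missing_vj: int = 0
    dropped_invalid_cdr3: int = 0
    dropped_length: int = 0
    output_records: int = 0
    dropped_records: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)


def strip_allele(gene: str) -> str:
    """Drop the allele suffix of a gene symbol: ``TRBV12-3*01 -> TRBV12-3``."""
    star = gene.find("*")
    return gene if star < 0 else gene[:star]


def collapse_alleles(rep: Repertoire) -> Repertoire:
    """Merge alleles of the same V/J gene by stripping ``*NN`` suffixes.

    Records made identical by the collapse are left for
    :func:`merge_duplicate_cdr3` to absorb.
    """
    clonotypes = [
        replace(c, v_gene=strip_allele(c.v_gene), j_gene=strip_allele(c.j_gene))
        for c in rep.clonotypes
    ]
    return rep.with_clonotypes(clonotypes)


def validate_cdr3(seq: str) -> ValidationVerdict:
    """Check one CDR3 amino-acid sequence against the junction rules.

    Reason codes: ``stop_codon``, ``invalid_letter``, ``start_anchor``,
    ``end_anchor``, ``length``.
    """
    reasons: list[str] = []
    if not seq:
        return ValidationVerdict(False, ("invalid_letter",))
    if "*" in seq or "_" in seq:
        reasons.append("stop_codon")
    if any(ch not in AA_SET and ch not in "*_" for ch in seq):
        reasons.append("invalid_letter")
    if seq[0] != "C":
        reasons.append("start_anchor")
    if seq[-1] not in "FW":
        reasons.append("end_anchor")
    if not (MIN_CDR3_LENGTH <= len(seq) <= MAX_CDR3_LENGTH):
        reasons.append("length")
    return ValidationVerdict(not reasons, tuple(reasons))


def merge_duplicate_cdr3(rep: Repertoire) -> Repertoire:
    """Collapse records sharing one CDR3 into a single clonotype.

    The merged clonotype sums the counts and keeps the V/J pair of the
    largest contributing record; count ties go to the lexicographically
    smallest gene symbols.  Allele collapse is applied first so that allele
    variants of one gene are never treated as competing gene calls.
    """
    rep = collapse_alleles(rep)
    order: list[str] = []
    groups: dict[str, list[Clonotype]] = {}
    for c in rep.clonotypes:
        if c.cdr3_aa not in groups:
            groups[c.cdr3_aa] = []
            order.append(c.cdr3_aa)
        groups[c.cdr3_aa].append(c)
    merged = []
    for seq in order:
        members = groups[seq]
        total = sum(c.count for c in members)
        best = min(members, key=lambda c: (-c.count, c.v_gene, c.j_gene))
        merged.append(
            Clonotype(cdr3_aa=seq, v_gene=best.v_gene, j_gene=best.j_gene, count=total)
        )
    return rep.with_clonotypes(merged)


def apply_qc(
    rep: Repertoire, require_vj: bool = True, keep_dropped: bool = False
) -> tuple[Repertoire, QCReport]:
    """Run the full rule set and return the clean repertoire plus a report.

    ``require_vj=False`` skips the V/J-presence rule, which sequence-only
    inputs (``cdr3_list``) cannot satisfy.  An input whose every record is
    removed yields a valid zero-clonotype repertoire, not an error.
    """
    report = QCReport(input_records=len(rep.clonotypes))
    if keep_dropped:
        report.dropped_records = {
            "missing_vj": [],
            "invalid_cdr3": [],
            "length": [],
        }

    rep = collapse_alleles(rep)

    kept: list[Clonotype] = []
    for c in rep.clonotypes:
        if require_vj and (not c.v_gene or not c.j_gene):
            report.dropped_missing_vj += 1
            if keep_dropped:
                report.dropped_records["missing_vj"].append(c.cdr3_aa)
            continue
        verdict = validate_cdr3(c.cdr3_aa)
        if not verdict.passed:
            # a record failing both sequence and length rules is booked under
            # the sequence-rule bucket; length is the sole-reason bucket
            if verdict.reasons == ("length",):
                report.dropped_length += 1
                if keep_dropped:
                    report.dropped_records["length"].append(c.cdr3_aa)
            else:
                report.dropped_invalid_cdr3 += 1
                if keep_dropped:
                    report.dropped_records["invalid_cdr3"].append(c.cdr3_aa)
            continue
        kept.append(c)

    merged_rep = merge_duplicate_cdr3(rep.with_clonotypes(kept))
    report.merged_duplicates = len(kept) - len(merged_rep.clonotypes)
    report.output_records = len(merged_rep.clonotypes)
    return merged_rep, report
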