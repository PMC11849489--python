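"""Readers and writers for the four supported clonotype-table dialects.

Supported input dialects:

``airr``
    AIRR Rearrangement TSV with the standard column names ``junction_aa``,
    ``v_call``, ``j_call``, ``duplicate_count``.
``caller_tsv``
    V(D)J-caller export TSV (MiXCR-like), recognized through column aliases
    such as ``cloneCount``/``aaSeqCDR3``.
``cdr3_list``
    Plain text, one CDR3 amino-acid sequence per line, no header.
``csv``
    Generic comma-separated table with a user-supplied column map.

The canonical on-disk output is an AIRR-style TSV; ``read(write(R)) == R``
on the canonical fields for any QC-passed repertoire.
"""

from __future__ import annotations

import csv as _csv
import logging
import re
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import EmptyInputError, FormatError, SchemaError
from .model import Clonotype, Repertoire

logger = logging.getLogger(__name__)

FORMATS = ("caller_tsv", "cdr3_list", "airr", "csv")

# Column aliases for caller exports; first match wins.
CALLER_COUNT_ALIASES = ("cloneCount", "count", "reads", "duplicate_count")
CALLER_CDR3_ALIASES = ("aaSeqCDR3", "cdr3aa", "CDR3.aa", "cdr3_aa", "junction_aa")
CALLER_V_ALIASES = ("bestVGene", "vGene", "v_gene", "v_call", "V.name", "v")
CALLER_J_ALIASES = ("bestJGene", "jGene", "j_gene", "j_call", "J.name", "j")

_SEQ_RE = re.compile(r"^[A-Za-z*_]+$")


def _first_alias(columns: Sequence[str], aliases: Sequence[str]) -> str | None:
    for a in aliases:
        if a in columns:
            return a
    return None


def _read_header(path: Path) -> str:
    try:
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if line.strip():
                    return line.rstrip("\n")
    except UnicodeDecodeError as exc:
        raise FormatError(f"{path} is not a decodable text file") from exc
    raise EmptyInputError(f"{path} is empty")


def detect_format(path: str | Path) -> str:
    """Guess the dialect of a clonotype table from its first line.

    AIRR is detected by a ``junction_aa`` header; a single bare-sequence
    column means ``cdr3_list``; a tab-delimited header carrying both a count
    and a CDR3 alias means ``caller_tsv``; anything else falls back to
    ``csv``.
    """
    path = Path(path)
    header = _read_header(path)
    if "\t" in header:
        cols = header.split("\t")
        if "junction_aa" in cols:
            return "airr"
        if _first_alias(cols, CALLER_COUNT_ALIASES) and _first_alias(
            cols, CALLER_CDR3_ALIASES
        ):
            return "caller_tsv"
        return "csv"
    if "," not in header and _SEQ_RE.match(header.strip()):
        return "cdr3_list"
    return "csv"


def _records_to_repertoire(
    rows: list[tuple[str, str, str, int]], sample_id: str
) -> Repertoire:
    clonotypes = []
    for cdr3, v, j, count in rows:
        if not cdr3 or str(cdr3).lower() in ("nan", "none"):
            logger.warning("dropping row with missing CDR3 in sample %s", sample_id)
            continue
        try:
            count = int(float(count))
        except (TypeError, ValueError):
            count = 1
        if count < 1:
            count = 1
        clonotypes.append(
            Clonotype(
                cdr3_aa=str(cdr3).strip().upper(),
                v_gene=("" if pd.isna(v) else str(v).strip()),
                j_gene=("" if pd.isna(j) else str(j).strip()),
                count=count,
            )
        )
    if not clonotypes:
        raise EmptyInputError(f"no parsable clonotype rows for sample {sample_id}")
    return Repertoire(sample_id=sample_id, clonotypes=clonotypes)


def _read_table(path: Path, sep: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=True)
    except OSError:
        raise
    except Exception as exc:  # malformed tables
        raise SchemaError(f"could not parse {path}: {exc}") from exc
    return df


def read_repertoire(
    path: str | Path,
    format: str | None = None,
    column_map: Mapping[str, str] | None = None,
    sample_id: str | None = None,
) -> Repertoire:
    """Read one clonotype table into a :class:`Repertoire`.

    No QC is applied; one clonotype is created per input row, in file order.
    Records without a count column default to count 1, so frequency-based
    statistics stay defined.

    Parameters
    ----------
    path:
        Input file.
    format:
        One of ``caller_tsv``, ``cdr3_list``, ``airr``, ``csv``; autodetected
        when omitted.
    column_map:
        For ``csv`` inputs, maps the canonical keys ``cdr3`` (required),
        ``count``, ``v``, ``j`` to column names in the file.
    sample_id:
        Defaults to the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or detect_format(path)
    if fmt not in FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {FORMATS}")
    sid = sample_id or path.stem

    if fmt == "cdr3_list":
        with open(path, encoding="utf-8") as fh:
            rows = [
                (line.strip(), "", "", 1) for line in fh if line.strip()
            ]
        if not rows:
            raise EmptyInputError(f"{path} contains no sequences")
        return _records_to_repertoire(rows, sid)

    if fmt == "airr":
        df = _read_table(path, "\t")
        if "junction_aa" not in df.columns:
            raise SchemaError(f"{path}: AIRR input lacks column 'junction_aa'")
        count_col = "duplicate_count" if "duplicate_count" in df.columns else None
        rows = [
            (
                r.get("junction_aa"),
                r.get("v_call", ""),
                r.get("j_call", ""),
                r.get(count_col) if count_col else 1,
            )
            for r in df.to_dict("records")
        ]
        return _records_to_repertoire(rows, sid)

    if fmt == "caller_tsv":
        df = _read_table(path, "\t")
        cdr3_col = _first_alias(df.columns, CALLER_CDR3_ALIASES)
        if cdr3_col is None:
            raise SchemaError(
                f"{path}: no CDR3 column among aliases {CALLER_CDR3_ALIASES}"
            )
        count_col = _first_alias(df.columns, CALLER_COUNT_ALIASES)
        v_col = _first_alias(df.columns, CALLER_V_ALIASES)
        j_col = _first_alias(df.columns, CALLER_J_ALIASES)
        rows = [
            (
                r.get(cdr3_col),
                r.get(v_col, "") if v_col else "",
                r.get(j_col, "") if j_col else "",
                r.get(count_col) if count_col else 1,
            )
            for r in df.to_dict("records")
        ]
        return _records_to_repertoire(rows, sid)

    # generic csv
    column_map = dict(column_map or {})
    df = _read_table(path, ",")
    cdr3_col = column_map.get("cdr3")
    if cdr3_col is None:
        raise SchemaError("csv input requires a column_map naming the 'cdr3' column")
    if cdr3_col not in df.columns:
        raise SchemaError(f"{path}: mapped CDR3 column {cdr3_col!r} not found")
    count_col = column_map.get("count")
    if count_col is not None and count_col not in df.columns:
        raise SchemaError(f"{path}: mapped count column {count_col!r} not found")
    v_col = column_map.get("v")
    j_col = column_map.get("j")
    rows = [
        (
            r.get(cdr3_col),
            r.get(v_col, "") if v_col else "",
            r.get(j_col, "") if j_col else "",
            r.get(count_col) if count_col else 1,
        )
        for r in df.to_dict("records")
    ]
    return _records_to_repertoire(rows, sid)


def write_repertoire(rep: Repertoire, path: str | Path, format: str = "airr") -> None:
    """Write a repertoire to disk.

    The canonical output dialect is an AIRR-style TSV with columns
    ``junction_aa``, ``v_call``, ``j_call``, ``duplicate_count``,
    ``frequency``; missing gene calls are written as empty cells.  The other
    dialects are provided so the simulator can emit round-trip fixtures; the
    ``cdr3_list`` dialect drops counts and gene calls by construction.
    """
    path = Path(path)
    if format == "cdr3_list":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for c in rep.clonotypes:
                fh.write(c.cdr3_aa + "\n")
        return
    if format == "airr":
        cols = ["junction_aa", "v_call", "j_call", "duplicate_count", "frequency"]
        rows = [
            [c.cdr3_aa, c.v_gene, c.j_gene, c.count, f"{c.frequency:.10g}"]
            for c in rep.clonotypes
        ]
        sep = "\t"
    elif format == "caller_tsv":
        cols = ["cloneCount", "aaSeqCDR3", "bestVGene", "bestJGene"]
        rows = [[c.count, c.cdr3_aa, c.v_gene, c.j_gene] for c in rep.clonotypes]
        sep = "\t"
    elif format == "csv":
        cols = ["cdr3_aa", "count", "v_gene", "j_gene"]
        rows = [[c.cdr3_aa, c.count, c.v_gene, c.j_gene] for c in rep.clonotypes]
        sep = ","
    else:
        raise ValueError(f"unknown format {format!r}")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = _csv.writer(fh, delimiter=sep, lineterminator="\n")
        writer.writerow(cols)
        writer.writerows(rows)


#: column_map that reads back the generic csv written by write_repertoire.
CSV_ROUNDTRIP_MAP = {"cdr3": "cdr3_aa", "count": "count", "v": "v_gene", "j": "j_gene"}
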