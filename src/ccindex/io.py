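"""Readers and writers: delimited expression tables, GMT gene sets, reports.

Expression tables are genes-in-rows delimited text (TSV by default): first
column gene identifiers, header row sample identifiers. Gene sets are GMT
(name TAB description TAB gene...) or plain one-gene-per-line lists. Reports
are TSV or JSON with '#'-prefixed metadata header lines.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneModule
from .exceptions import TableFormatError

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression_table",
    "write_expression_table",
    "read_gene_sets",
    "write_report",
]

#: fixed numeric precision for diffable text output
FLOAT_FMT = "%.6g"


def read_expression_table(
    path,
    delimiter: str = "\t",
    orientation: str = "genes_in_rows",
    log2_transform: bool = False,
    duplicate_policy: str = "error",
) -> ExpressionMatrix:
    """Read a delimited expression table into an :class:`ExpressionMatrix`.

    Parameters
    ----------
    path : path-like
    delimiter : str
        Field separator; "\\t" (default) or ",".
    orientation : {"genes_in_rows", "genes_in_columns"}
        The table is transposed after reading if genes are in columns.
    log2_transform : bool
        Apply log2(x + 1) after ingestion. Off by default: the concordance
        statistics are applied to the matrix as given.
    duplicate_policy : {"error", "first"}
        Duplicate gene identifiers abort by default; "first" keeps the first
        occurrence of each.
    """
    path = Path(path)
    if not path.exists():
        raise TableFormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0)
    except Exception as exc:
        raise TableFormatError(f"{path}: failed to parse table: {exc}") from exc
    if df.empty:
        raise TableFormatError(f"{path}: empty table")
    if orientation == "genes_in_columns":
        df = df.T
    elif orientation != "genes_in_rows":
        raise TableFormatError(f"unknown orientation {orientation!r}")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        if duplicate_policy == "first":
            logger.warning("%s: keeping first occurrence of %d duplicate id(s)", path, len(dups))
            df = df[~df.index.duplicated(keep="first")]
        else:
            raise TableFormatError(
                f"{path}: duplicate gene id(s): {', '.join(map(str, dups[:5]))}"
            )
    non_numeric = df.columns[
        [not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]
    ].tolist()
    if non_numeric:
        # locate one offending cell for the error message
        col = non_numeric[0]
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad_rows = df.index[coerced.isna() & df[col].notna()].tolist()
        where = f" (e.g. gene {bad_rows[0]!r})" if bad_rows else ""
        raise TableFormatError(f"{path}: non-numeric values in column {col!r}{where}")
    if df.isna().any().any():
        gene = df.index[df.isna().any(axis=1)][0]
        raise TableFormatError(f"{path}: missing value(s), e.g. in gene {gene!r}")
    values = df.to_numpy(dtype=float)
    if log2_transform:
        if (values < 0).any():
            raise TableFormatError(f"{path}: negative values, cannot log2(x+1)-transform")
        values = np.log2(values + 1.0)
    return ExpressionMatrix(values, list(df.index), list(df.columns))


def write_expression_table(expr: ExpressionMatrix, path, delimiter: str = "\t") -> None:
    expr.to_dataframe().to_csv(path, sep=delimiter, index_label="gene")


def read_gene_sets(path) -> list[GeneModule]:
    """Read gene modules from a GMT file or a plain one-gene-per-line list.

    Files ending in ``.gmt`` (or whose lines carry >= 3 tab-separated fields)
    are parsed as GMT: name, description, then genes. Anything else is one
    module named after the file. Duplicate genes within a module are dropped
    with a warning; an empty file yields an empty list.
    """
    path = Path(path)
    if not path.exists():
        raise TableFormatError(f"no such file: {path}")
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines()]
    lines = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
    if not lines:
        return []
    is_gmt = path.suffix.lower() == ".gmt" or all(len(ln.split("\t")) >= 3 for ln in lines)
    modules: list[GeneModule] = []
    if is_gmt:
        for lineno, ln in enumerate(lines, start=1):
            fields = ln.split("\t")
            if len(fields) < 3:
                raise TableFormatError(
                    f"{path}:{lineno}: GMT line needs name, description and >= 1 gene"
                )
            name, genes = fields[0], [g for g in fields[2:] if g.strip()]
            if not genes:
                raise TableFormatError(f"{path}:{lineno}: module {name!r} has no genes")
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                logger.warning(
                    "%s:%d: module %s: %d duplicate gene(s) removed",
                    path, lineno, name, len(genes) - len(deduped),
                )
            modules.append(GeneModule(name=name, genes=tuple(deduped)))
    else:
        genes = [ln.strip() for ln in lines]
        deduped = list(dict.fromkeys(genes))
        if len(deduped) < len(genes):
            logger.warning("%s: %d duplicate gene(s) removed", path, len(genes) - len(deduped))
        modules.append(GeneModule(name=path.stem, genes=tuple(deduped)))
    return modules


def _record_to_dict(rec) -> dict:
    if dataclasses.is_dataclass(rec) and not isinstance(rec, type):
        return dataclasses.asdict(rec)
    return dict(rec)


def _fmt(v):
    if isinstance(v, float):
        return FLOAT_FMT % v
    return "" if v is None else str(v)


def write_report(records, path, fmt: str = "tsv", metadata: dict | None = None) -> None:
    """Write a list of records (dataclasses or dicts) as TSV or JSON.

    Column order follows the first record; metadata (seed, config, version)
    goes into '#'-prefixed header lines (TSV) or a "metadata" object (JSON).
    Floats are formatted at 6 significant digits for diffability.
    """
    if fmt not in ("tsv", "json"):
        raise TableFormatError(f"format must be 'tsv' or 'json', got {fmt!r}")
    rows = [_record_to_dict(r) for r in records]
    meta = metadata or {}
    path = Path(path)
    if fmt == "json":
        payload = {
            "metadata": meta,
            "records": [
                {k: (float(FLOAT_FMT % v) if isinstance(v, float) else v) for k, v in r.items()}
                for r in rows
            ],
        }
        path.write_text(json.dumps(payload, indent=1, default=str) + "\n")
        return
    with path.open("w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        if rows:
            cols = list(rows[0])
            fh.write("\t".join(cols) + "\n")
            for r in rows:
                fh.write("\t".join(_fmt(r.get(c)) for c in cols) + "\n")
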