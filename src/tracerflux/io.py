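"""CSV/TSV I/O with embedded metadata headers.

Every output table starts with ``#``-prefixed ``key = value`` lines (package
version, seed, isotope constants, config hash) followed by an ordinary CSV
body, so a result file is self-describing and reproducible.  Readers skip
the header transparently.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
from pathlib import Path

import pandas as pd

from .errors import SchemaError

FLOAT_FORMAT = "%.10g"


def config_hash(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, metadata: dict | None = None,
                sep: str = ",", timestamp: bool = True) -> None:
    """Write a table with a ``#`` metadata header.

    The optional ``created`` timestamp is the only non-deterministic line;
    disable it (or strip lines starting with ``# created``) when comparing
    outputs byte-for-byte.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = []
    if timestamp:
        lines.append(f"# created = {_dt.datetime.now().isoformat()}")
    for k, v in (metadata or {}).items():
        lines.append(f"# {k} = {v}")
    body = df.to_csv(index=False, sep=sep, float_format=FLOAT_FORMAT)
    path.write_text("\n".join(lines) + ("\n" if lines else "") + body)


def read_table(path, sep: str = ",") -> tuple[pd.DataFrame, dict]:
    """Read a table written by :func:`write_table`; returns (df, metadata)."""
    path = Path(path)
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            stripped = line[1:].strip()
            if "=" in stripped:
                k, v = stripped.split("=", 1)
                meta[k.strip()] = v.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep=sep)
    return df, meta


def require_columns(df: pd.DataFrame, columns, path=None) -> None:
    for c in columns:
        if c not in df.columns:
            raise SchemaError("missing required column", path=str(path),
                              column=c)


def check_numeric(df: pd.DataFrame, column: str, path=None,
                  minimum=None) -> None:
    """Validate a numeric column, reporting the first offending data row."""
    vals = pd.to_numeric(df[column], errors="coerce")
    bad = vals.isna() & df[column].notna()
    if bad.any():
        raise SchemaError("non-numeric value", path=str(path), column=column,
                          row=int(bad.idxmax()) + 1)
    if minimum is not None:
        low = vals < minimum
        if low.any():
            raise SchemaError(f"value below {minimum}", path=str(path),
                              column=column, row=int(low.idxmax()) + 1)
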