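"""Per-cytosine methylation count tables.

The site count table is the RRBS analysis substrate: one row per covered
cytosine with methylated (non-converted) and unmethylated (converted) read
counts.  Columns: chrom, pos (1-based), strand, meth_count, unmeth_count,
context.  The ``bismark`` dialect accepts the Bismark cytosine-report column
order (same first six columns, headerless, with a trailing trinucleotide
column that is ignored).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["SITE_COLUMNS", "read_site_counts", "write_site_counts", "validate_site_table"]

SITE_COLUMNS = ["chrom", "pos", "strand", "meth_count", "unmeth_count", "context"]


def validate_site_table(df: pd.DataFrame, name: str = "table") -> pd.DataFrame:
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{name}: missing columns {missing}")
    df = df[SITE_COLUMNS].copy()
    if (df["meth_count"] < 0).any() or (df["unmeth_count"] < 0).any():
        raise ValueError(f"{name}: negative counts")
    if df.duplicated(subset=["chrom", "pos", "strand"]).any():
        raise ValueError(f"{name}: duplicate (chrom, pos, strand) rows")
    return df


def read_site_counts(path: str | Path, dialect: str = "native") -> pd.DataFrame:
    """Read a site count table.  ``dialect='bismark'`` reads a headerless
    Bismark-style cytosine report (extra columns ignored)."""
    if dialect == "native":
        df = pd.read_csv(path, sep="\t", comment="#",
                         names=SITE_COLUMNS, dtype={"chrom": str})
    elif dialect == "bismark":
        df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
        df = df.iloc[:, :6]
        df.columns = SITE_COLUMNS
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df["pos"] = df["pos"].astype(int)
    df["meth_count"] = df["meth_count"].astype(int)
    df["unmeth_count"] = df["unmeth_count"].astype(int)
    return validate_site_table(df, str(path))


def write_site_counts(df: pd.DataFrame, path: str | Path) -> None:
    df = validate_site_table(df)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(SITE_COLUMNS) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)
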