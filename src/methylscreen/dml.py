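"""RRBS gene-body differential methylation via a two-proportion z-test.

The procedure: (1) keep only cytosines covered ≥ ``min_cov`` in BOTH
conditions; (2) pool retained sites per gene body, summing conversions
(unmethylated reads) and non-conversions (methylated reads) into one
per-gene bisulfite conversion rate per condition; (3) test the conversion
ratio for change between conditions with a pooled two-proportion z-test,

    z = (p̂₁ − p̂₂) / sqrt( p̂(1−p̂)(1/n₁ + 1/n₂) ),   p̂ = (x₁+x₂)/(n₁+n₂),

where x is the converted (unmethylated) read count and n the total; the
two-sided p-value is 2·(1−Φ(|z|)).  z² equals the Pearson chi-square
statistic of the 2×2 table without continuity correction.  Degenerate pooled
proportions (0 or 1) return z = 0, p = 1 by convention.  No multiple-testing
correction is applied by default (a raw p threshold of 1e-4 flags
significance); Benjamini–Hochberg is available behind a flag.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .counts import validate_site_table
from .genes import GeneModel

__all__ = [
    "filter_covered",
    "pool_by_gene",
    "two_proportion_ztest",
    "ztest_frame",
    "report_dml",
]

DEFAULT_ALPHA_METH = 1e-4  # raw-p significance threshold for methylation change


def _sum_replicates(tables: pd.DataFrame | Sequence[pd.DataFrame], name: str) -> pd.DataFrame:
    """Sum replicate count tables for one condition by coordinate."""
    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    frames = [validate_site_table(t, name) for t in tables]
    df = pd.concat(frames, ignore_index=True)
    grouped = (df.groupby(["chrom", "pos", "strand"], as_index=False)
                 .agg(meth_count=("meth_count", "sum"),
                      unmeth_count=("unmeth_count", "sum"),
                      context=("context", "first")))
    return grouped


def filter_covered(
    table_a: pd.DataFrame | Sequence[pd.DataFrame],
    table_b: pd.DataFrame | Sequence[pd.DataFrame],
    min_cov: int = 10,
) -> pd.DataFrame:
    """Dual-condition coverage filter.

    Replicate tables per condition are summed first.  A site survives iff its
    total coverage (meth+unmeth) is ≥ ``min_cov`` in BOTH conditions
    (boundary inclusive); sites absent from either condition are dropped.
    The same (chrom, pos) reported on different strands in the two conditions
    is a hard error.  Returns one merged frame with _a/_b count columns.
    """
    a = _sum_replicates(table_a, "condition A")
    b = _sum_replicates(table_b, "condition B")
    clash = pd.merge(a[["chrom", "pos", "strand"]], b[["chrom", "pos", "strand"]],
                     on=["chrom", "pos"], how="inner", suffixes=("_a", "_b"))
    bad = clash[clash["strand_a"] != clash["strand_b"]]
    if len(bad):
        first = bad.iloc[0]
        raise ValueError(
            f"inconsistent strand at {first['chrom']}:{first['pos']} "
            f"({first['strand_a']} vs {first['strand_b']})")
    merged = pd.merge(a, b, on=["chrom", "pos", "strand"], suffixes=("_a", "_b"))
    cov_a = merged["meth_count_a"] + merged["unmeth_count_a"]
    cov_b = merged["meth_count_b"] + merged["unmeth_count_b"]
    out = merged[(cov_a >= min_cov) & (cov_b >= min_cov)].reset_index(drop=True)
    return out


def pool_by_gene(filtered: pd.DataFrame, gene_bodies: Sequence[GeneModel]) -> pd.DataFrame:
    """Pool filtered sites per gene body into (x₁, n₁, x₂, n₂).

    x = summed converted (unmethylated) reads, n = summed total reads over
    all retained sites inside the gene body (tx_start..tx_end, strand
    agnostic; table positions are 1-based).  Genes with n = 0 in either
    condition are excluded.  A site inside two overlapping gene bodies
    contributes to both.
    """
    trees: dict[str, IntervalTree] = {}
    for gm in gene_bodies:
        trees.setdefault(gm.chrom, IntervalTree()).addi(gm.tx_start, gm.tx_end, gm.gene_id)
    acc: dict[str, np.ndarray] = {gm.gene_id: np.zeros(4, dtype=np.int64)
                                  for gm in gene_bodies}
    for row in filtered.itertuples():
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        pos0 = row.pos - 1
        for iv in tree.at(pos0):
            a = acc[iv.data]
            a[0] += row.unmeth_count_a
            a[1] += row.meth_count_a + row.unmeth_count_a
            a[2] += row.unmeth_count_b
            a[3] += row.meth_count_b + row.unmeth_count_b
    rows = [(gid, *v) for gid, v in acc.items() if v[1] > 0 and v[3] > 0]
    return pd.DataFrame(rows, columns=["gene_id", "x1", "n1", "x2", "n2"])


def two_proportion_ztest(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z-test; returns (z, two-sided p).

    Degenerate pooled proportion (all converted or none) → (0.0, 1.0).
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("n must be >= 1 in both groups")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("x out of range")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled <= 0.0 or pooled >= 1.0:
        return 0.0, 1.0
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (x1 / n1 - x2 / n2) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def ztest_frame(pooled: pd.DataFrame) -> pd.DataFrame:
    """Vectorised z-test over a pooled per-gene frame (columns x1,n1,x2,n2).

    Adds conversion ratios, methylated fractions, z, p_value and the
    methylation change descriptors (delta and fold change on the methylated
    fraction, condition B relative to A).
    """
    df = pooled.copy()
    x1 = df["x1"].to_numpy(float)
    n1 = df["n1"].to_numpy(float)
    x2 = df["x2"].to_numpy(float)
    n2 = df["n2"].to_numpy(float)
    p1 = x1 / n1
    p2 = x2 / n2
    pooled_p = (x1 + x2) / (n1 + n2)
    ok = (pooled_p > 0.0) & (pooled_p < 1.0)
    se = np.sqrt(np.where(ok, pooled_p * (1 - pooled_p) * (1 / n1 + 1 / n2), 1.0))
    z = np.where(ok, (p1 - p2) / se, 0.0)
    p = np.where(ok, np.minimum(2.0 * stats.norm.sf(np.abs(z)), 1.0), 1.0)
    df["conv_ratio_a"] = p1
    df["conv_ratio_b"] = p2
    df["meth_frac_a"] = 1.0 - p1
    df["meth_frac_b"] = 1.0 - p2
    df["delta_meth"] = df["meth_frac_b"] - df["meth_frac_a"]
    with np.errstate(divide="ignore", invalid="ignore"):
        df["meth_fold_change"] = np.where(
            df["meth_frac_a"] > 0, df["meth_frac_b"] / df["meth_frac_a"], np.nan)
    df["z"] = z
    df["p_value"] = p
    return df


def report_dml(
    results: pd.DataFrame,
    alpha_meth: float = DEFAULT_ALPHA_METH,
    fdr: bool = False,
) -> pd.DataFrame:
    """Rank tested genes and flag significant methylation changes.

    Sorted by p then |Δ conversion ratio| (descending); ``significant`` is
    raw p < ``alpha_meth`` (or Benjamini–Hochberg q < alpha when ``fdr``).
    """
    if results.empty:
        out = results.copy()
        out["significant"] = pd.Series(dtype=bool)
        out.attrs["status"] = "no genes tested (empty input)"
        return out
    df = results.copy()
    df["abs_delta_conv"] = (df["conv_ratio_a"] - df["conv_ratio_b"]).abs()
    if fdr:
        df["q_value"] = _benjamini_hochberg(df["p_value"].to_numpy())
        df["significant"] = df["q_value"] < alpha_meth
    else:
        df["significant"] = df["p_value"] < alpha_meth
    df = df.sort_values(["p_value", "abs_delta_conv"],
                        ascending=[True, False], kind="mergesort")
    df.attrs["status"] = f"{int(df['significant'].sum())} of {len(df)} genes significant"
    return df.reset_index(drop=True)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out
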