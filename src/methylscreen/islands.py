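"""CpG-island detection and gene-body classification.

A CpG island is detected with the classic Gardiner-Garden & Frommer criteria:
span ≥ 200 bp, GC fraction ≥ 0.5, and observed/expected CpG ratio ≥ 0.6,
where Obs/Exp = count(CG)·N / (count(C)·count(G)) over the evaluated span.
Qualifying fixed-size windows are merged and the merged span is re-tested,
trimming symmetrically (one base off each end per round, Takai–Jones style)
until it qualifies or falls below the minimum length.

Islands overlapping a gene body (the transcribed span: 5'UTR, exons, introns,
3'UTR) by at least ``min_overlap`` bp are classified as gene-body islands;
the rest (promoter/5' or intergenic) are flagged separately.  Gene-body
islands are the screening target: intragenic methylation is associated with
active transcription, unlike promoter methylation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .genes import GeneModel

__all__ = [
    "CpGIsland",
    "IslandCall",
    "find_islands",
    "classify_islands",
    "span_stats",
    "write_islands_bed",
]


@dataclass(frozen=True)
class CpGIsland:
    """A detected CpG island, 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    gc_fraction: float
    obs_exp_cpg: float
    n_cpg: int

    @property
    def length(self) -> int:
        return self.end - self.start


def span_stats(seq: str, start: int = 0, end: int | None = None) -> tuple[float, float, int]:
    """(gc_fraction, obs_exp_cpg, n_cpg) of ``seq[start:end]``.

    CG dinucleotides are counted only when fully inside the span.
    Obs/Exp is 0 when the span contains no C or no G.
    """
    sub = seq[start:end if end is not None else len(seq)]
    width = len(sub)
    if width == 0:
        return 0.0, 0.0, 0
    c = sub.count("C")
    g = sub.count("G")
    cg = sub.count("CG")
    gc = (c + g) / width
    oe = cg * width / (c * g) if c and g else 0.0
    return gc, oe, cg


class _SeqStats:
    """Cumulative base/dinucleotide counts for O(1) window statistics."""

    def __init__(self, seq: str):
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        self.n = arr.size
        is_c = arr == ord("C")
        is_g = arr == ord("G")
        is_n = ~np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
        is_cg = np.zeros(self.n, dtype=bool)
        if self.n > 1:
            is_cg[:-1] = is_c[:-1] & is_g[1:]
        z = np.zeros(1, dtype=np.int64)
        self.cum_c = np.concatenate([z, np.cumsum(is_c)])
        self.cum_g = np.concatenate([z, np.cumsum(is_g)])
        self.cum_n = np.concatenate([z, np.cumsum(is_n)])
        self.cum_cg = np.concatenate([z, np.cumsum(is_cg)])

    def counts(self, a: int, b: int) -> tuple[int, int, int, int]:
        c = int(self.cum_c[b] - self.cum_c[a])
        g = int(self.cum_g[b] - self.cum_g[a])
        nn = int(self.cum_n[b] - self.cum_n[a])
        cg = int(self.cum_cg[b - 1] - self.cum_cg[a]) if b - a >= 2 else 0
        return c, g, nn, cg


def _qualifies(c: int, g: int, cg: int, width: int, gc_min: float, oe_min: float) -> bool:
    gc = (c + g) / width
    oe = cg * width / (c * g) if c and g else 0.0
    return gc >= gc_min and oe >= oe_min


def find_islands(
    sequence: str,
    chrom: str = "region",
    *,
    min_length: int = 200,
    gc_min: float = 0.5,
    oe_min: float = 0.6,
    window: int = 200,
    step: int = 1,
) -> list[CpGIsland]:
    """Scan ``sequence`` for CpG islands.

    Every window of ``window`` bp (advanced by ``step``) containing no N and
    meeting both the GC and Obs/Exp thresholds is a candidate; overlapping or
    adjacent candidates merge.  Each merged span is re-tested on its exact
    extent and trimmed one base off both ends per round until it qualifies;
    spans that shrink below ``min_length`` are discarded.  Every emitted
    island therefore satisfies all three thresholds when recomputed on its
    exact span.
    """
    sequence = sequence.upper()
    n = len(sequence)
    if n < window:
        return []
    stats = _SeqStats(sequence)
    starts = np.arange(0, n - window + 1, step)
    c = stats.cum_c[starts + window] - stats.cum_c[starts]
    g = stats.cum_g[starts + window] - stats.cum_g[starts]
    nn = stats.cum_n[starts + window] - stats.cum_n[starts]
    cg = stats.cum_cg[starts + window - 1] - stats.cum_cg[starts]
    with np.errstate(divide="ignore", invalid="ignore"):
        gc = (c + g) / window
        oe = np.where((c > 0) & (g > 0), cg * window / np.maximum(c * g, 1), 0.0)
    good = (nn == 0) & (gc >= gc_min) & (oe >= oe_min)
    good_starts = starts[good]
    if good_starts.size == 0:
        return []
    # merge overlapping/adjacent qualifying windows
    spans: list[list[int]] = []
    for s in good_starts:
        s = int(s)
        if spans and s <= spans[-1][1]:
            spans[-1][1] = max(spans[-1][1], s + window)
        else:
            spans.append([s, s + window])
    islands = []
    for a, b in spans:
        while b - a >= min_length:
            cc, gg, _, ccg = stats.counts(a, b)
            if _qualifies(cc, gg, ccg, b - a, gc_min, oe_min):
                width = b - a
                gc_f = (cc + gg) / width
                oe_f = ccg * width / (cc * gg) if cc and gg else 0.0
                islands.append(CpGIsland(chrom, a, b, gc_f, oe_f, ccg))
                break
            a += 1
            b -= 1
    return islands


# ---------------------------------------------------------------------------
# Gene-body classification


@dataclass(frozen=True)
class IslandCall:
    """Classification of one island against the gene-body set."""

    island: CpGIsland
    gene_ids: tuple[str, ...]
    is_gene_body: bool
    overlap_bp: Mapping[str, int]


def classify_islands(
    islands: Sequence[CpGIsland],
    gene_bodies: Sequence[GeneModel],
    *,
    min_overlap: int = 1,
) -> tuple[list[IslandCall], dict[str, int]]:
    """Assign each island gene-body status.

    An island is a gene-body island iff it overlaps at least ``min_overlap``
    bp of some gene's transcribed span.  Returns the per-island calls and a
    per-gene island count.  Islands on a chromosome absent from the gene
    models raise a hard error naming the known chromosomes.
    """
    trees: dict[str, IntervalTree] = {}
    for gm in gene_bodies:
        trees.setdefault(gm.chrom, IntervalTree()).addi(gm.tx_start, gm.tx_end, gm.gene_id)
    known = sorted(trees)
    calls = []
    per_gene = {gm.gene_id: 0 for gm in gene_bodies}
    for isl in islands:
        if isl.chrom not in trees:
            raise ValueError(
                f"island chromosome {isl.chrom!r} not in gene models; known: {known}")
        overlaps: dict[str, int] = {}
        for iv in trees[isl.chrom].overlap(isl.start, isl.end):
            bp = min(isl.end, iv.end) - max(isl.start, iv.begin)
            if bp >= min_overlap:
                overlaps[iv.data] = bp
        gene_ids = tuple(sorted(overlaps))
        for gid in gene_ids:
            per_gene[gid] += 1
        calls.append(IslandCall(isl, gene_ids, bool(gene_ids), overlaps))
    return calls, per_gene


def write_islands_bed(calls: Sequence[IslandCall], path: str | Path) -> None:
    """Write island calls as BED4 (name = comma-joined gene ids or 'intergenic')."""
    lines = []
    for call in calls:
        name = ",".join(call.gene_ids) if call.gene_ids else "intergenic"
        isl = call.island
        lines.append(f"{isl.chrom}\t{isl.start}\t{isl.end}\t{name}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
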