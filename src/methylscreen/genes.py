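"""Gene models and the one-gene-per-line tab format.

A gene model records the transcribed span, CDS limits and exon structure in
0-based half-open coordinates (UCSC genePred-like).  The gene body — the
screening unit for intragenic methylation — is the full transcribed span:
5'UTR, all exons and introns, and 3'UTR, i.e. ``[tx_start, tx_end)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

__all__ = ["GeneModel", "read_gene_models", "write_gene_models"]

_COLUMNS = ("gene_id", "chrom", "strand", "tx_start", "tx_end",
            "cds_start", "cds_end", "exon_starts", "exon_ends")


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise ValueError(f"{self.gene_id}: CDS outside transcript")
        if len(self.exon_starts) != len(self.exon_ends) or not self.exon_starts:
            raise ValueError(f"{self.gene_id}: malformed exon lists")
        if self.exon_starts[0] != self.tx_start or self.exon_ends[-1] != self.tx_end:
            raise ValueError(f"{self.gene_id}: exons do not span the transcript")
        for s, e in zip(self.exon_starts, self.exon_ends):
            if s >= e:
                raise ValueError(f"{self.gene_id}: empty exon [{s},{e})")

    @property
    def gene_body(self) -> tuple[int, int]:
        """The transcribed span [tx_start, tx_end): 5'UTR + exons + introns + 3'UTR."""
        return self.tx_start, self.tx_end

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple((e, s) for e, s in zip(self.exon_ends[:-1], self.exon_starts[1:]))

    def contains(self, pos: int) -> bool:
        """Whether a 0-based position falls in the gene body."""
        return self.tx_start <= pos < self.tx_end


def _fmt_ints(values: Sequence[int]) -> str:
    return ",".join(str(v) for v in values)


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    lines = ["#" + "\t".join(_COLUMNS)]
    for g in genes:
        lines.append("\t".join([
            g.gene_id, g.chrom, g.strand, str(g.tx_start), str(g.tx_end),
            str(g.cds_start), str(g.cds_end),
            _fmt_ints(g.exon_starts), _fmt_ints(g.exon_ends)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) != len(_COLUMNS):
            raise ValueError(f"expected {len(_COLUMNS)} columns, got {len(f)}: {line!r}")
        genes.append(GeneModel(
            gene_id=f[0], chrom=f[1], strand=f[2],
            tx_start=int(f[3]), tx_end=int(f[4]),
            cds_start=int(f[5]), cds_end=int(f[6]),
            exon_starts=tuple(int(x) for x in f[7].split(",") if x),
            exon_ends=tuple(int(x) for x in f[8].split(",") if x)))
    return genes
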