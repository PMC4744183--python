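"""Bisulfite clone methylation calling, QC and lollipop matrices.

Each Sanger-sequenced clone of a bisulfite PCR product is aligned globally to
the untreated reference region under bisulfite-aware scoring: a reference C
read as T is a match (conversion) and a reference C read as C is a match
(protection), so methylation status never penalises the alignment.  Per-CpG
calls follow from the clone base aligned to each reference CpG cytosine
(C → methylated, T → unmethylated, anything else → ambiguous).

QC mirrors common practice for clone bisulfite data: clones are retained only
if the conversion rate (fraction of non-CpG reference Cs read as T — a proxy
for complete bisulfite treatment) and the alignment identity both clear their
thresholds.  Retained clones form the lollipop matrix: filled circles for
methylated CpGs, open circles for unmethylated, dots for missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .bisulfite import reverse_complement

__all__ = [
    "AlignmentScoring",
    "CloneAlignment",
    "LollipopMatrix",
    "align_clone",
    "qc_filter",
    "build_lollipop",
]

METH, UNMETH, AMBIGUOUS = "METH", "UNMETH", "AMBIGUOUS"


@dataclass(frozen=True)
class AlignmentScoring:
    """Bisulfite-aware global alignment parameters.

    ``match`` also scores reference-C↔clone-T (conversion is not an error);
    clone C against reference T scores as a mismatch — a C appearing where
    the reference has none signals sequencing error, not methylation.
    """

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0


def _make_aligner(sc: AlignmentScoring) -> Align.PairwiseAligner:
    alphabet = "ACGTN"
    mat = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if "N" in (a, b):
                mat[a, b] = 0.0
            elif a == b or (a == "C" and b == "T"):  # rows: reference, cols: clone
                mat[a, b] = sc.match
            else:
                mat[a, b] = sc.mismatch
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = sc.gap_open
    aligner.extend_gap_score = sc.gap_extend
    return aligner


@dataclass
class CloneAlignment:
    """One clone aligned to the reference region, with per-CpG calls."""

    clone_id: str
    aligned_reference: str
    aligned_clone: str
    score: float
    reversed: bool
    identity_fraction: float
    conversion_rate: float
    #: {reference CpG position (0-based C) -> METH | UNMETH | AMBIGUOUS}
    calls: dict[int, str]


def _trim_end_gaps(ref: str, clone: str) -> tuple[int, int]:
    """Column range [i, j) excluding leading/trailing gap-only overhangs."""
    i, j = 0, len(ref)
    while i < j and (ref[i] == "-" or clone[i] == "-"):
        i += 1
    while j > i and (ref[j - 1] == "-" or clone[j - 1] == "-"):
        j -= 1
    return i, j


def align_clone(
    reference_region: str,
    clone_seq: str,
    clone_id: str = "clone",
    scoring: AlignmentScoring = AlignmentScoring(),
) -> CloneAlignment:
    """Globally align a clone to the untreated reference region and call CpGs.

    The clone is auto-reverse-complemented when that orientation scores
    higher (ties keep the forward orientation).  Identity counts
    reference-C↔clone-T as a match and is computed over aligned columns
    excluding end gaps; conversion_rate is the fraction of covered non-CpG
    reference Cs read as T (1.0 when no non-CpG C is covered).
    """
    reference_region = reference_region.upper()
    clone_seq = clone_seq.upper()
    if not reference_region or not clone_seq:
        raise ValueError("empty sequence")
    aligner = _make_aligner(scoring)
    fwd = aligner.align(reference_region, clone_seq)
    rev = aligner.align(reference_region, reverse_complement(clone_seq))
    use_rev = rev.score > fwd.score
    best = (rev if use_rev else fwd)[0]
    ref_aln, clone_aln = best[0], best[1]

    cpg_set = {i for i in range(len(reference_region) - 1)
               if reference_region[i] == "C" and reference_region[i + 1] == "G"}
    lo, hi = _trim_end_gaps(ref_aln, clone_aln)
    matches = cols = 0
    conv_t = conv_total = 0
    calls: dict[int, str] = {}
    ref_pos = -1
    for col, (r, c) in enumerate(zip(ref_aln, clone_aln)):
        if r != "-":
            ref_pos += 1
        if lo <= col < hi:
            cols += 1
            if r != "-" and c != "-" and (r == c or (r == "C" and c == "T")):
                matches += 1
        if r == "C":
            if ref_pos in cpg_set:
                if c == "C":
                    calls[ref_pos] = METH
                elif c == "T":
                    calls[ref_pos] = UNMETH
                else:
                    calls[ref_pos] = AMBIGUOUS
            elif c in ("C", "T"):
                conv_total += 1
                conv_t += c == "T"
    identity = matches / cols if cols else 0.0
    conversion = conv_t / conv_total if conv_total else 1.0
    return CloneAlignment(
        clone_id=clone_id, aligned_reference=ref_aln, aligned_clone=clone_aln,
        score=float(best.score), reversed=use_rev,
        identity_fraction=identity, conversion_rate=conversion, calls=calls)


# ---------------------------------------------------------------------------
# QC


def qc_filter(
    alignments: Sequence[CloneAlignment],
    min_conversion: float = 0.95,
    min_identity: float = 0.90,
) -> tuple[list[CloneAlignment], list[tuple[CloneAlignment, str]]]:
    """Split clones into retained and rejected (with reasons).

    A clone is retained iff conversion_rate ≥ ``min_conversion`` AND
    identity ≥ ``min_identity``.
    """
    for name, v in [("min_conversion", min_conversion), ("min_identity", min_identity)]:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0,1]")
    retained, rejected = [], []
    for aln in alignments:
        reasons = []
        if aln.conversion_rate < min_conversion:
            reasons.append(f"incomplete conversion ({aln.conversion_rate:.3f} < {min_conversion})")
        if aln.identity_fraction < min_identity:
            reasons.append(f"low identity ({aln.identity_fraction:.3f} < {min_identity})")
        if reasons:
            rejected.append((aln, "; ".join(reasons)))
        else:
            retained.append(aln)
    return retained, rejected


def qc_report_frame(retained: Sequence[CloneAlignment],
                    rejected: Sequence[tuple[CloneAlignment, str]]) -> pd.DataFrame:
    rows = [(a.clone_id, a.conversion_rate, a.identity_fraction, a.reversed, "retained", "")
            for a in retained]
    rows += [(a.clone_id, a.conversion_rate, a.identity_fraction, a.reversed, "rejected", why)
             for a, why in rejected]
    return pd.DataFrame(rows, columns=["clone_id", "conversion_rate", "identity",
                                       "reversed", "status", "reason"])


# ---------------------------------------------------------------------------
# Lollipop matrix


FILLED, OPEN, MISSING = "filled", "open", "missing"
_GLYPH = {FILLED: "●", OPEN: "○", MISSING: "·"}


@dataclass
class LollipopMatrix:
    """Clone × CpG methylation matrix plus per-CpG methylation fractions.

    ``matrix`` rows are retained clones (stable input order), columns are
    0-based reference CpG positions; cells are "filled" (methylated), "open"
    (unmethylated) or "missing" (uncovered / ambiguous).  Fractions are
    filled/(filled+open) per column, missing cells excluded.
    """

    matrix: pd.DataFrame
    fractions: pd.Series

    @property
    def n_clones(self) -> int:
        return len(self.matrix)

    def render_text(self) -> str:
        lines = []
        for clone_id, row in self.matrix.iterrows():
            lines.append(f"{clone_id}\t" + "".join(_GLYPH[v] for v in row))
        return "\n".join(lines)

    def write(self, out_dir: str | Path, label: str = "region") -> dict[str, str]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {"matrix": str(out / f"lollipop_{label}.tsv"),
                 "fractions": str(out / f"cpg_fractions_{label}.tsv"),
                 "text": str(out / f"lollipop_{label}.txt")}
        self.matrix.to_csv(paths["matrix"], sep="\t")
        self.fractions.rename("meth_fraction").to_csv(paths["fractions"], sep="\t")
        Path(paths["text"]).write_text(self.render_text() + "\n")
        return paths


def build_lollipop(retained: Sequence[CloneAlignment],
                   cpg_positions: Sequence[int] | None = None) -> LollipopMatrix:
    """Assemble the lollipop matrix from retained clone alignments.

    ``cpg_positions`` fixes the column set (reference CpG positions); by
    default it is the union of positions called in any clone.  Raises on an
    empty clone list so the caller can report the empty result explicitly.
    """
    if not retained:
        raise ValueError("no retained clones; nothing to plot")
    if cpg_positions is None:
        cols = sorted({p for a in retained for p in a.calls})
    else:
        cols = [int(p) for p in cpg_positions]
    data = []
    for aln in retained:
        row = []
        for p in cols:
            call = aln.calls.get(p)
            row.append(FILLED if call == METH else OPEN if call == UNMETH else MISSING)
        data.append(row)
    matrix = pd.DataFrame(data, index=[a.clone_id for a in retained], columns=cols)
    matrix.index.name = "clone_id"
    filled = (matrix == FILLED).sum(axis=0)
    informative = filled + (matrix == OPEN).sum(axis=0)
    with np.errstate(invalid="ignore"):
        fractions = (filled / informative.replace(0, np.nan)).astype(float)
    return LollipopMatrix(matrix=matrix, fractions=fractions)
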