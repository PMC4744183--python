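"""Methylation-aware in-silico bisulfite conversion and restriction-digest prediction.

Bisulfite treatment deaminates unmethylated cytosine to uracil (read as T by
sequencing) while 5-methylcytosine is protected.  Converting a template *in
silico* under the two extreme methylation states (fully methylated / fully
unmethylated) and predicting restriction-digest patterns on each converted
sequence identifies enzymes whose fragment patterns discriminate the two
states — the basis of COBRA (Combined Bisulfite Restriction Analysis).

Conventions
-----------
* Sequences are uppercase A/C/G/T/N strings; coordinates are 0-based.
* Methylation flags index the plus-strand C of a CpG (CG) dinucleotide.
* OT ("original top") conversion is C→T on the plus-strand view; OB
  ("original bottom") conversion appears as G→A on the plus-strand view.
* Digestion is evaluated on the given (plus) strand of the template only by
  default; bisulfite PCR amplicons are effectively single sequences.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "IUPAC",
    "MethylationState",
    "ALL_METHYLATED",
    "ALL_UNMETHYLATED",
    "RestrictionEnzyme",
    "DigestPattern",
    "CobraEnzymeResult",
    "DEFAULT_ENZYME_PANEL",
    "reverse_complement",
    "cpg_positions",
    "convert",
    "digest",
    "cobra_predict",
    "classify_from_observed",
    "read_enzyme_table",
    "write_enzyme_table",
]

#: IUPAC nucleotide codes mapped to the set of concrete bases they match.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"), "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

_A, _C, _G, _T, _N = (ord(b) for b in "ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _as_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def cpg_positions(seq: str) -> np.ndarray:
    """0-based positions of the plus-strand C of every CG dinucleotide."""
    arr = _as_bytes(seq)
    if arr.size < 2:
        return np.empty(0, dtype=np.int64)
    return np.nonzero((arr[:-1] == _C) & (arr[1:] == _G))[0]


# ---------------------------------------------------------------------------
# Methylation state


@dataclass(frozen=True)
class MethylationState:
    """Per-CpG methylation flags over a sequence, or a symbolic extreme state.

    ``methylated`` holds 0-based positions of methylated plus-strand CpG Cs.
    Flags at non-CpG positions are rejected unless ``allow_non_cpg`` is set
    (non-CpG methylation is not modelled by default).
    """

    kind: str = "explicit"  # "explicit" | "all_methylated" | "all_unmethylated"
    methylated: frozenset[int] = frozenset()
    allow_non_cpg: bool = False

    @classmethod
    def from_positions(cls, positions: Iterable[int], *, allow_non_cpg: bool = False) -> "MethylationState":
        return cls(kind="explicit", methylated=frozenset(int(p) for p in positions),
                   allow_non_cpg=allow_non_cpg)

    def methylated_on(self, seq: str) -> np.ndarray:
        """Resolve to concrete methylated CpG positions on ``seq``."""
        cpgs = cpg_positions(seq)
        if self.kind == "all_methylated":
            return cpgs
        if self.kind == "all_unmethylated":
            return np.empty(0, dtype=np.int64)
        pos = np.array(sorted(self.methylated), dtype=np.int64)
        if not self.allow_non_cpg and pos.size:
            bad = np.setdiff1d(pos, cpgs)
            if bad.size:
                raise ValueError(
                    f"methylation flags at non-CpG positions {bad[:5].tolist()}"
                    " (set allow_non_cpg=True to permit)")
        return pos


ALL_METHYLATED = MethylationState(kind="all_methylated")
ALL_UNMETHYLATED = MethylationState(kind="all_unmethylated")


# ---------------------------------------------------------------------------
# Conversion


def convert(
    seq: str,
    state: MethylationState,
    strand: str = "OT",
    failure_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    *,
    failure_at_cpg: bool = True,
) -> str:
    """Bisulfite-convert ``seq`` under a methylation state.

    OT: every C becomes T except Cs flagged methylated (and stochastic
    conversion failures at ``failure_rate``, which leave C unchanged).
    OB: the mirror-image rule on the plus-strand view — every G becomes A
    except the G paired with a methylated CpG C.  N passes through; length is
    preserved.

    ``failure_at_cpg=False`` restricts stochastic failures to non-CpG
    cytosines (used by the clone simulator, where CpG read states are drawn
    explicitly from the methylation profile).
    """
    if strand not in ("OT", "OB"):
        raise ValueError(f"strand must be 'OT' or 'OB', got {strand!r}")
    if failure_rate and rng is None:
        raise ValueError("failure_rate > 0 requires an rng")
    arr = _as_bytes(seq).copy()
    meth = state.methylated_on(seq)
    if strand == "OT":
        eligible = arr == _C
        protected = meth
    else:
        eligible = arr == _G
        protected = meth + 1  # G of the CpG pair
    protected = protected[protected < arr.size]
    if protected.size:
        eligible[protected] = False
    if failure_rate and rng is not None:
        candidates = eligible.copy()
        if not failure_at_cpg:
            cpgs = cpg_positions(seq)
            sites = cpgs if strand == "OT" else cpgs + 1
            if sites.size:
                candidates[sites] = False
        idx = np.nonzero(candidates)[0]
        fails = idx[rng.random(idx.size) < failure_rate]
        if fails.size:
            eligible[fails] = False
    arr[eligible] = _T if strand == "OT" else _A
    return arr.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Restriction digestion


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme: IUPAC recognition site and top-strand cut offset."""

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        site = self.recognition.upper()
        if not site:
            raise ValueError(f"{self.name}: empty recognition site")
        bad = set(site) - set(IUPAC)
        if bad:
            raise ValueError(f"{self.name}: invalid IUPAC codes {sorted(bad)}")
        if not 0 <= self.cut_offset <= len(site):
            raise ValueError(f"{self.name}: cut_offset {self.cut_offset} outside site")
        object.__setattr__(self, "recognition", site)


@dataclass(frozen=True)
class DigestPattern:
    """Cut positions and fragment lengths of one enzyme on one linear template."""

    template_label: str
    template_length: int
    cut_positions: tuple[int, ...]
    fragment_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        assert sum(self.fragment_lengths) == self.template_length
        assert len(self.fragment_lengths) == len(self.cut_positions) + 1


_IUPAC_BYTES = {code: np.frombuffer("".join(sorted(bases)).encode(), dtype=np.uint8)
                for code, bases in IUPAC.items()}


def digest(seq: str, enzyme: RestrictionEnzyme, label: str | None = None) -> DigestPattern:
    """Locate all (possibly overlapping) recognition matches on the plus strand
    and compute the fragment lengths of the linear template.

    Duplicate cut positions collapse; cuts at the template ends (offset 0 or
    ``len(seq)``) do not cleave a linear molecule and are dropped.  A template
    with no sites yields a single full-length fragment.
    """
    n = len(seq)
    site = enzyme.recognition
    L = len(site)
    cuts: np.ndarray
    if n < L:
        cuts = np.empty(0, dtype=np.int64)
    else:
        arr = _as_bytes(seq)
        match = np.ones(n - L + 1, dtype=bool)
        for j, code in enumerate(site):
            match &= np.isin(arr[j:n - L + 1 + j], _IUPAC_BYTES[code])
        starts = np.nonzero(match)[0]
        cuts = np.unique(starts + enzyme.cut_offset)
        cuts = cuts[(cuts > 0) & (cuts < n)]
    bounds = np.concatenate(([0], cuts, [n]))
    frags = tuple(int(x) for x in np.diff(bounds))
    return DigestPattern(label or enzyme.name, n, tuple(int(c) for c in cuts), frags)


#: Default COBRA screening panel.  TaqαI is an isoschizomer of TaqI; the panel
#: is extensible via an enzyme table file.
DEFAULT_ENZYME_PANEL: tuple[RestrictionEnzyme, ...] = (
    RestrictionEnzyme("TaqI", "TCGA", 1),
    RestrictionEnzyme("TaqaI", "TCGA", 1),
    RestrictionEnzyme("BstUI", "CGCG", 2),
    RestrictionEnzyme("HpyCH4IV", "ACGT", 1),
    RestrictionEnzyme("MspI", "CCGG", 1),
    RestrictionEnzyme("HhaI", "GCGC", 3),
    RestrictionEnzyme("MseI", "TTAA", 1),
)


def read_enzyme_table(path: str | Path) -> list[RestrictionEnzyme]:
    """Read a tab-delimited enzyme file: name, recognition, cut_offset."""
    enzymes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, recognition, offset = line.split("\t")
        enzymes.append(RestrictionEnzyme(name, recognition, int(offset)))
    if not enzymes:
        raise ValueError(f"no enzymes in {path}")
    return enzymes


def write_enzyme_table(enzymes: Sequence[RestrictionEnzyme], path: str | Path) -> None:
    lines = [f"{e.name}\t{e.recognition}\t{e.cut_offset}" for e in enzymes]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# COBRA informativeness


@dataclass(frozen=True)
class CobraEnzymeResult:
    """Digest predictions for one enzyme on the two extreme converted templates.

    ``informative`` is True iff the fragment-length multisets of the
    fully-methylated and fully-unmethylated conversions differ, i.e. gel
    electrophoresis of the digested bisulfite PCR product can distinguish the
    states.
    """

    enzyme: RestrictionEnzyme
    pattern_unconverted: DigestPattern
    pattern_methylated: DigestPattern
    pattern_unmethylated: DigestPattern
    informative: bool
    fragments_methylated_only: tuple[int, ...]
    fragments_unmethylated_only: tuple[int, ...]


def _multiset_diff(a: Sequence[int], b: Sequence[int]) -> tuple[int, ...]:
    diff = Counter(a) - Counter(b)
    return tuple(sorted(diff.elements()))


def cobra_predict(
    region: str,
    enzyme_panel: Sequence[RestrictionEnzyme] = DEFAULT_ENZYME_PANEL,
    *,
    strand: str = "OT",
    label: str = "region",
) -> list[CobraEnzymeResult]:
    """Predict per-enzyme COBRA informativeness for a bisulfite PCR region.

    The region is converted under the fully-methylated and fully-unmethylated
    states (no stochastic failures) and each enzyme is digested on both, plus
    the unconverted template for reference.  Conversion can both destroy sites
    (a C in the site converts away) and create them (a converted T completes a
    site), so patterns are compared as fragment-length multisets.
    """
    if not enzyme_panel:
        raise ValueError("enzyme panel is empty")
    conv_m = convert(region, ALL_METHYLATED, strand)
    conv_u = convert(region, ALL_UNMETHYLATED, strand)
    results = []
    for enz in enzyme_panel:
        pat_raw = digest(region, enz, f"{label}|unconverted")
        pat_m = digest(conv_m, enz, f"{label}|methylated")
        pat_u = digest(conv_u, enz, f"{label}|unmethylated")
        m_only = _multiset_diff(pat_m.fragment_lengths, pat_u.fragment_lengths)
        u_only = _multiset_diff(pat_u.fragment_lengths, pat_m.fragment_lengths)
        results.append(CobraEnzymeResult(
            enzyme=enz,
            pattern_unconverted=pat_raw,
            pattern_methylated=pat_m,
            pattern_unmethylated=pat_u,
            informative=bool(m_only or u_only),
            fragments_methylated_only=m_only,
            fragments_unmethylated_only=u_only,
        ))
    return results


def _matches_within(observed: Sequence[float], predicted: Sequence[int], tol: float) -> bool:
    if len(observed) != len(predicted):
        return False
    obs = sorted(observed)
    pred = sorted(predicted)
    return all(abs(o - p) <= tol * p for o, p in zip(obs, pred))


def classify_from_observed(
    observed_fragments: Sequence[float],
    result: CobraEnzymeResult,
    tolerance: float = 0.05,
) -> str:
    """Classify an observed gel fragment pattern against COBRA predictions.

    ``tolerance`` is the relative length tolerance (gel resolution) applied
    per fragment, default ±5%.  Returns ``"methylated"``, ``"unmethylated"``
    or ``"ambiguous"`` (pattern matches both predictions or neither).
    """
    if not observed_fragments:
        raise ValueError("observed fragment list is empty")
    hit_m = _matches_within(observed_fragments, result.pattern_methylated.fragment_lengths, tolerance)
    hit_u = _matches_within(observed_fragments, result.pattern_unmethylated.fragment_lengths, tolerance)
    if hit_m and not hit_u:
        return "methylated"
    if hit_u and not hit_m:
        return "unmethylated"
    return "ambiguous"
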