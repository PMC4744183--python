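"""Shared fixtures and independent test oracles.

The oracles here deliberately use naive per-base / per-window Python loops so
they stay independent of the vectorised implementation paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from methylscreen.bisulfite import IUPAC


def random_dna(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))


# ---------------------------------------------------------------------------
# Independent oracles


def convert_oracle(seq: str, methylated: set[int], strand: str = "OT") -> str:
    """Per-base bisulfite conversion rule applied independently at each base."""
    out = []
    for i, b in enumerate(seq):
        if strand == "OT" and b == "C" and i not in methylated:
            out.append("T")
        elif strand == "OB" and b == "G" and (i - 1) not in methylated:
            out.append("A")
        else:
            out.append(b)
    return "".join(out)


def digest_oracle(seq: str, recognition: str, cut_offset: int):
    """Regex-free sliding-window site search and fragment arithmetic."""
    n, L = len(seq), len(recognition)
    cuts = set()
    for i in range(n - L + 1):
        if all(seq[i + j] in IUPAC[c] for j, c in enumerate(recognition)):
            cut = i + cut_offset
            if 0 < cut < n:
                cuts.add(cut)
    cuts = sorted(cuts)
    frags = [b - a for a, b in zip([0] + cuts, cuts + [n])]
    return tuple(cuts), tuple(frags)


def island_oracle(seq: str, min_length=200, gc_min=0.5, oe_min=0.6, window=200, step=1):
    """Exhaustive all-windows scan + merge + symmetric trim, naive counting."""

    def stats(sub: str):
        c, g, cg = sub.count("C"), sub.count("G"), sub.count("CG")
        width = len(sub)
        gc = (c + g) / width
        oe = cg * width / (c * g) if c and g else 0.0
        return gc, oe, cg

    def qualifies(sub: str) -> bool:
        gc, oe, _ = stats(sub)
        return gc >= gc_min and oe >= oe_min

    n = len(seq)
    good = []
    for s in range(0, n - window + 1, step):
        win = seq[s:s + window]
        if any(b not in "ACGT" for b in win):
            continue
        if qualifies(win):
            good.append(s)
    spans = []
    for s in good:
        if spans and s <= spans[-1][1]:
            spans[-1][1] = max(spans[-1][1], s + window)
        else:
            spans.append([s, s + window])
    islands = []
    for a, b in spans:
        while b - a >= min_length:
            if qualifies(seq[a:b]):
                gc, oe, cg = stats(seq[a:b])
                islands.append((a, b, gc, oe, cg))
                break
            a += 1
            b -= 1
    return islands


def pearson_chi2(x1: int, n1: int, x2: int, n2: int) -> float:
    """Pearson chi-square of the 2x2 table, no continuity correction."""
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expected = rows * cols / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


# ---------------------------------------------------------------------------
# Fixtures


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def tiny_dataset():
    from methylscreen.simulate import SimulationConfig, generate_reference

    cfg = SimulationConfig(seed=11, n_genes=6)
    return generate_reference(cfg)
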