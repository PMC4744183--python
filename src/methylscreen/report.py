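"""Small reporting utilities for count summaries.

Covers the arithmetic that accompanies the screen's experimental readouts:
percentage of positive recipients among scored animals, and expected
genotype counts under Mendelian segregation from a heterozygote incross.
"""

from __future__ import annotations

from fractions import Fraction

__all__ = ["percent_positive", "expected_mendelian_count", "proportion_summary"]


def percent_positive(positive: int, total: int) -> int:
    """Nearest-integer percentage of positive counts (e.g. 17/30 → 57)."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= positive <= total:
        raise ValueError("positive count out of range")
    return round(100 * positive / total)


def expected_mendelian_count(n_scored: int, genotype_fraction: Fraction | float = Fraction(1, 4)) -> float:
    """Expected count of a genotype class among ``n_scored`` offspring.

    Default fraction 1/4: homozygotes from a heterozygote incross
    (e.g. 32 embryos → 8 expected homozygous mutants).
    """
    frac = float(genotype_fraction)
    if not 0.0 <= frac <= 1.0:
        raise ValueError("genotype fraction must be in [0,1]")
    if n_scored < 0:
        raise ValueError("n_scored must be nonnegative")
    return n_scored * frac


def proportion_summary(positive: int, total: int) -> str:
    """Human-readable 'k/n (p%)' summary string."""
    return f"{positive}/{total} ({percent_positive(positive, total)}%)"
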