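"""Degrees of freedom of the genetic code across reading frames.

Fix an ordered pair (A1, A2) of coding-frame symbols drawn from the 21
letters (20 amino acids plus stop).  Every di-codon (c1, c2) with
translate(c1) = A1 and translate(c2) = A2 determines one codon in each
alternative frame; the number of *distinct* symbols those frame codons
translate to (stop counting as its own symbol) measures how much freedom
the code leaves to encode information in that frame without touching the
coding-frame pair.  The per-frame mean over all 21 x 21 ordered pairs is
the summary statistic; it is smallest in frame -2.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .frames import ALTERNATIVE_FRAMES, extract_frame_codon
from .genetic_code import (
    CODONS64,
    GeneticCode,
    STANDARD_CODE,
    STOP_LABEL,
)


def _codons_for(symbol: str, code: GeneticCode) -> tuple[str, ...]:
    return tuple(c for c in CODONS64 if code.translate(c) == symbol)


def encodable_set(
    a1: str,
    a2: str,
    frame: str,
    code: GeneticCode = STANDARD_CODE,
    count_stop: bool = True,
) -> frozenset[str]:
    """Symbols encodable in ``frame`` while the coding frame reads (a1, a2).

    Enumerates every di-codon realizing the pair and translates the
    frame's sub-codon of the 6-nucleotide window.  ``count_stop=False``
    discards the stop label from the result (a documented variant; the
    default keeps it as a distinct 21st symbol).
    """
    if frame not in ALTERNATIVE_FRAMES:
        raise ValueError(f"frame must be one of {ALTERNATIVE_FRAMES}")
    symbols = set()
    for c1 in _codons_for(a1, code):
        for c2 in _codons_for(a2, code):
            symbols.add(code.translate(extract_frame_codon(c1 + c2, frame)))
    if not count_stop:
        symbols.discard(STOP_LABEL)
    return frozenset(symbols)


def round_half_up(x: float, digits: int = 2) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), for table comparisons."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def mean_degrees_of_freedom(
    frame: str,
    code: GeneticCode = STANDARD_CODE,
    include_stop_pairs: bool = True,
    count_stop: bool = True,
) -> float:
    """Mean |encodable_set| over all ordered symbol pairs.

    Defaults (pairs drawn from the 21-symbol alphabet, stop counted as an
    encodable symbol) define the canonical table; the flags expose the
    nearby enumeration variants.
    """
    alphabet = (
        code.symbols_with_stop if include_stop_pairs else code.amino_acids
    )
    sizes = [
        len(encodable_set(a1, a2, frame, code, count_stop))
        for a1 in alphabet
        for a2 in alphabet
    ]
    return sum(sizes) / len(sizes)


@dataclass(frozen=True)
class FreedomTable:
    """Per-frame mean degrees of freedom plus enumeration metadata."""

    means: dict[str, float]
    include_stop_pairs: bool
    count_stop: bool

    def rounded(self, digits: int = 2) -> dict[str, float]:
        return {f: round_half_up(m, digits) for f, m in self.means.items()}


def freedom_table(
    code: GeneticCode = STANDARD_CODE,
    include_stop_pairs: bool = True,
    count_stop: bool = True,
) -> FreedomTable:
    means = {
        f: mean_degrees_of_freedom(f, code, include_stop_pairs, count_stop)
        for f in ALTERNATIVE_FRAMES
    }
    return FreedomTable(means, include_stop_pairs, count_stop)
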