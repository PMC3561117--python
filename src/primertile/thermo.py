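"""Composition-based melting temperature and GC content for primers.

Degeneracy in this package is restricted to the IUPAC codes W (= A/T)
and S (= G/C).  Under a GC-fraction melting formula an A<->T or G<->C
substitution never changes Tm, which is exactly why W/S-only degenerate
primer pools can be annealed at a single temperature.  A nearest-neighbour
stacking model would break that neutrality, so the formula here is
deliberately composition-based:

    Tm = 64.9 + 41 * (nGC - 16.4) / N

where nGC counts G, C and S positions and N is the primer length.  The
constant set (64.9 / 41 / 16.4) is the conventional "Wallace-like" long
oligo parameterization; it is centralized below so it can be swapped in
one place if a different composition formula is preferred.
"""

from __future__ import annotations

import math

TM_INTERCEPT = 64.9
TM_SLOPE = 41.0
TM_GC_OFFSET = 16.4

#: the formula is not meaningful for very short oligos
MIN_TM_LENGTH = 14

_STRONG = frozenset("GCS")
_ALPHABET = frozenset("ACGTWS")


def _check_alphabet(seq: str) -> None:
    bad = set(seq) - _ALPHABET
    if bad:
        raise ValueError(f"sequence contains non-primer characters: {sorted(bad)}")


def gc_content(seq: str) -> float:
    """Fraction of strong (G/C/S) positions in an oligo.

    S counts as G/C and W as A/T, so degenerate primers have a single
    well-defined GC content.
    """
    if not seq:
        raise ValueError("gc_content of an empty sequence is undefined")
    _check_alphabet(seq)
    return sum(1 for b in seq if b in _STRONG) / len(seq)


def melting_temperature(seq: str) -> float:
    """Melting temperature in degrees centigrade of a (possibly W/S
    degenerate) oligo.

    All 2**w concrete expansions of a W/S degenerate oligo share this Tm
    exactly, because the formula depends only on the strong-base count
    and the length.
    """
    if len(seq) < MIN_TM_LENGTH:
        raise ValueError(
            f"melting_temperature requires length >= {MIN_TM_LENGTH}, got {len(seq)}"
        )
    _check_alphabet(seq)
    n_gc = sum(1 for b in seq if b in _STRONG)
    return TM_INTERCEPT + TM_SLOPE * (n_gc - TM_GC_OFFSET) / len(seq)


def round_half_up(x: float) -> int:
    """Deterministic half-up rounding (avoids banker's rounding ties)."""
    return int(math.floor(x + 0.5))


def rounded_tm(seq: str) -> int:
    """Integer target Tm class of an oligo: a primer "has" target Tm t
    when its formula Tm rounds (half-up) to t."""
    return round_half_up(melting_temperature(seq))


def tm_from_counts(n_gc: int, length: int) -> float:
    """Tm from a strong-base count and length (fast path for enumeration)."""
    return TM_INTERCEPT + TM_SLOPE * (n_gc - TM_GC_OFFSET) / length
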