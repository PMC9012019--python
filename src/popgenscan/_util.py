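"""Small shared helpers: coordinate conversion, rounding, seeding."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np

MISSING = -1  # genotype code for a missing diploid call


def to_zero_based_half_open(start_1based: int, end_1based: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open.

    All window arithmetic in this package happens on 1-based inclusive
    coordinates (the VCF convention); this is the single place where the
    BED-style convention is produced.
    """
    return start_1based - 1, end_1based


def to_one_based_inclusive(start_0based: int, end_half_open: int) -> tuple[int, int]:
    return start_0based + 1, end_half_open


def percent(numerator: float, denominator: float, decimals: int = 2) -> float:
    """Percentage rounded half-up to ``decimals`` places.

    Round-half-up (not banker's rounding) so that printed two-decimal
    percentages are reproducible from integer counts.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    q = Decimal(numerator) * 100 / Decimal(denominator)
    exp = Decimal(1).scaleb(-decimals)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


def child_seed(seed: int, *tags: int) -> int:
    """Derive a deterministic sub-stream seed below 2**31."""
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *[int(t) for t in tags]])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def rng_for(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, *tags))
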