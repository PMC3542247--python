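"""Closed-form genetic expectations used as references for the simulator.

Map functions translate map distance d (Morgan) into a recombination
fraction r: Haldane r = (1 - e^(-2d))/2 applies without chiasma
interference, Kosambi r = tanh(2d)/2 under moderate interference. The
quadrivalent-fraction formula follows from independent telomere pairing:
with preferential-pairing fraction p the matching pairing has probability
p + (1-p)/3 and each other pairing (1-p)/3; two bivalents form when both
telomeres draw the same pairing.
"""

from __future__ import annotations

import math

__all__ = [
    "HALDANE",
    "KOSAMBI",
    "haldane_r",
    "kosambi_r",
    "map_function_r",
    "expected_quadrivalent_fraction",
]

HALDANE = "HALDANE"
KOSAMBI = "KOSAMBI"


def haldane_r(d: float) -> float:
    """Haldane recombination fraction for map distance ``d`` in Morgan."""
    if d < 0:
        raise ValueError("map distance must be >= 0")
    return 0.5 * (1.0 - math.exp(-2.0 * d))


def kosambi_r(d: float) -> float:
    """Kosambi recombination fraction for map distance ``d`` in Morgan."""
    if d < 0:
        raise ValueError("map distance must be >= 0")
    return 0.5 * math.tanh(2.0 * d)


def map_function_r(d: float, kind: str) -> float:
    """Recombination fraction at distance ``d`` Morgan under ``kind``."""
    k = kind.upper()
    if k == HALDANE:
        return haldane_r(d)
    if k == KOSAMBI:
        return kosambi_r(d)
    raise ValueError(f"unknown map function {kind!r}; expected HALDANE or KOSAMBI")


def expected_quadrivalent_fraction(p: float) -> float:
    """Expected quadrivalent fraction under natural pairing at ``p``.

    1 - P(two bivalents) with
    P(two bivalents) = (p + (1-p)/3)^2 + 2((1-p)/3)^2; equals 2/3 at p = 0
    and 0 at p = 1.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("preferential-pairing fraction must be in [0, 1]")
    m = p + (1.0 - p) / 3.0
    o = (1.0 - p) / 3.0
    return 1.0 - (m * m + 2.0 * o * o)
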