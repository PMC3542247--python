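"""Chiasma generation and application.

Chiasmata (crossover events) are placed along a paired region by a renewal
process running from one telomere to the other. Without chiasma
interference the inter-chiasma distance is Exponential with mean 0.5 Morgan
per paired chromosome pair (two chiasmata per Morgan in a bivalent), which
yields Haldane-map recombination in bivalents. With interference the
distance is Gamma(shape 2.63) with the same mean, which closely follows the
Kosambi map function; the process is burnt in several Morgan before the
chromosome start so that it is stationary at the first marker.

No chromatid interference is modelled: each chiasma involves one uniformly
chosen chromatid of each paired chromosome, independently of other
chiasmata. A chiasma at position x exchanges all content at positions >= x
between the two chromatids (a tail swap), so successive chiasmata read
telomere-to-telomere reproduce the physical crossover mosaic.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from random import Random

from .genome import HaploStruct

__all__ = [
    "ChiasmaProcessConfig",
    "Chiasma",
    "sample_interchiasma_distance",
    "generate_chiasma_positions",
    "choose_chromatids",
    "apply_chiasma",
]

#: Gamma shape that reproduces Kosambi-level chiasma interference.
KOSAMBI_GAMMA_SHAPE = 2.63


@dataclass(frozen=True)
class ChiasmaProcessConfig:
    """Parameters of the chiasma renewal process.

    ``mean_distance`` is the mean inter-chiasma distance in Morgan along one
    paired structure: 0.5 for bivalents and each branch of a cross-type
    quadrivalent, 0.25 for a parallel quadrivalent (four paired chromosomes).
    ``gamma_shape`` only applies when ``interference`` is on;
    ``burnin_length`` (Morgan) is how far before the chromosome start the
    interference process is started to make it stationary.
    """

    interference: bool = False
    mean_distance: float = 0.5
    gamma_shape: float = KOSAMBI_GAMMA_SHAPE
    burnin_length: float = 10.0

    def __post_init__(self) -> None:
        if self.mean_distance <= 0:
            raise ValueError("mean_distance must be > 0 Morgan")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be > 0")
        if self.burnin_length < 5.0:
            raise ValueError("burnin_length must be >= 5 Morgan")


@dataclass(frozen=True)
class Chiasma:
    """A crossover: position (cM) plus the two involved chromatids."""

    position: float
    chromatid_a: object
    chromatid_b: object


def sample_interchiasma_distance(cfg: ChiasmaProcessConfig, rng: Random) -> float:
    """One inter-chiasma distance in Morgan.

    Exponential(mean) without interference; Gamma(shape, scale=mean/shape)
    with interference, so the mean distance is preserved.
    """
    if cfg.interference:
        return rng.gammavariate(cfg.gamma_shape, cfg.mean_distance / cfg.gamma_shape)
    return rng.expovariate(1.0 / cfg.mean_distance)


def generate_chiasma_positions(
    region_start: float,
    region_end: float,
    direction: int,
    cfg: ChiasmaProcessConfig,
    rng: Random,
) -> list[float]:
    """Sample chiasma positions (cM) inside ``(region_start, region_end)``.

    The renewal process enters the region at one end and proceeds to the
    other (``direction`` +1: from ``region_start``; -1: mirrored, from
    ``region_end``). Without interference the first gap past the entry point
    is a fresh Exponential draw (memorylessness makes burn-in unnecessary);
    with interference the process starts ``burnin_length`` Morgan outside
    the region with one Exponential draw followed by Gamma gaps, and only
    in-region positions are returned. Positions are returned ascending.
    Endpoints themselves are never returned (a swap at an endpoint would be
    a no-op).
    """
    if region_end <= region_start:
        return []
    mean_cm = cfg.mean_distance * 100.0
    span = region_end - region_start
    # Work in "distance from entry telomere"; mirror at the end if needed.
    positions: list[float] = []
    if cfg.interference:
        shape = cfg.gamma_shape
        scale = mean_cm / shape
        d = -cfg.burnin_length * 100.0 + rng.expovariate(1.0 / mean_cm)
        while d <= 0.0:
            d += rng.gammavariate(shape, scale)
        while d < span:
            positions.append(d)
            d += rng.gammavariate(shape, scale)
    else:
        rate = 1.0 / mean_cm
        d = rng.expovariate(rate)
        while d < span:
            positions.append(d)
            d += rng.expovariate(rate)
    if direction >= 0:
        return [region_start + d for d in positions]
    out = [region_end - d for d in positions]
    out.reverse()
    return out


def choose_chromatids(chrom_a_chromatids, chrom_b_chromatids, rng: Random):
    """Uniform choice of one chromatid per chromosome (4 combinations).

    Chromatid choices are independent between chiasmata: no chromatid
    interference.
    """
    return (
        chrom_a_chromatids[rng.getrandbits(1)],
        chrom_b_chromatids[rng.getrandbits(1)],
    )


def _splice(us, ua, vs, va, x):
    """Exchange content at positions >= x between two segment lists.

    Returns four new lists (u starts, u alleles, v starts, v alleles).
    Inputs must be canonical; outputs are canonical.
    """
    i = bisect_left(us, x)  # first u segment starting at or after x
    j = bisect_left(vs, x)
    # allele covering x on each chromatid
    au = ua[i] if i < len(us) and us[i] == x else ua[i - 1]
    av = va[j] if j < len(vs) and vs[j] == x else va[j - 1]
    i2 = i + 1 if i < len(us) and us[i] == x else i
    j2 = j + 1 if j < len(vs) and vs[j] == x else j
    nus = us[:i]
    nua = ua[:i]
    if nua[-1] != av:
        nus.append(x)
        nua.append(av)
    nus += vs[j2:]
    nua += va[j2:]
    nvs = vs[:j]
    nva = va[:j]
    if nva[-1] != au:
        nvs.append(x)
        nva.append(au)
    nvs += us[i2:]
    nva += ua[i2:]
    return nus, nua, nvs, nva


def apply_chiasma(
    u: HaploStruct,
    v: HaploStruct,
    x: float,
    length: float | None = None,
) -> tuple[HaploStruct, HaploStruct]:
    """Tail swap at position ``x``: contents at positions >= x exchanged.

    The boundary position itself takes the recombined allele (half-open
    convention). Applying the same swap twice restores the inputs.
    """
    if x <= 0.0 or (length is not None and x >= length):
        raise ValueError(f"chiasma position {x} outside the open chromosome interval")
    nus, nua, nvs, nva = _splice(u.starts, u.alleles, v.starts, v.alleles, x)
    return (
        HaploStruct.from_arrays(nus, nua, u.chromosome, validate=False),
        HaploStruct.from_arrays(nvs, nva, v.chromosome, validate=False),
    )
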