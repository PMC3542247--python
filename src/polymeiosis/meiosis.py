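"""Meiosis of one diploid or tetraploid individual.

The simulation follows the natural sequence per chromosome set:

1. *Pairing.* In a tetraploid, telomere pairing at both chromosome ends
   decides between two bivalents and one quadrivalent (cross-type or
   parallel). Pairing at each telomere is preferential with fraction p:
   the matching (same-subgenome) pairing has probability p + (1-p)/3, the
   other two pairings (1-p)/3 each. Identical pairings at both ends give
   two bivalents; different pairings give a cross-type quadrivalent whose
   branches realize the two pairings. The bivalent:quadrivalent ratio can
   instead be forced per chromosome.
2. *Recombination.* Chiasmata are generated along each paired structure by
   the renewal process in :mod:`polymeiosis.chiasma` and applied as tail
   swaps between uniformly chosen non-sister chromatids.
3. *First division.* Centromeres (each holding two chromatids) are
   partitioned over the two poles: one per pole from each bivalent; for
   quadrivalents a uniformly random partition of the four centromeres into
   two pairs (optionally, for cross-type, the partition that separates
   centromere-side pairing partners).
4. *Second division.* Each centromere splits; its two chromatids go to the
   two daughter gametes with independent random orientation.

Two pieces of strand bookkeeping make the four-strand accounting exact.
First, a chiasma at x swaps the chromatid tails distal to x, after which
the two strands have exchanged the chromosome *axis* their distal parts lie
on; chiasmata are applied in ascending position order and each one chooses
uniformly among the current occupants of its two paired axes. This is what
yields Haldane-map recombination per transmitted chromatid in a bivalent.
Second, chromatids stay attached to a physical centromere: a chiasma
proximal to the centromere moves the centromere region with the exchanged
tail, so the two strands also trade centromere membership; this is what
makes every tetraploid gamete receive its two chromatids from two
different parental centromeres (no double reduction at the centromere
itself).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from random import Random

from .chiasma import ChiasmaProcessConfig, _splice, generate_chiasma_positions
from .genome import (
    ChromosomeSpec,
    Gamete,
    HaploStruct,
    IndividualGenome,
    UnsupportedPloidyError,
)
from .theory import expected_quadrivalent_fraction  # noqa: F401  (re-export)

__all__ = [
    "PAIRINGS",
    "MATCHING",
    "Bivalent",
    "TwoBivalents",
    "CrossQuadrivalent",
    "ParallelQuadrivalent",
    "pair_telomere",
    "decide_configuration",
    "expected_quadrivalent_fraction",
    "do_bivalent",
    "build_cross_quadrivalent",
    "build_parallel_quadrivalent",
    "first_division",
    "second_division",
    "do_meiosis",
    "sample_gamete",
]

#: The three partitions of homolog slots {0,1,2,3} into telomere pairs.
#: Index 0 is the "matching" pairing: slots 0,1 form one subgenome and
#: slots 2,3 the other.
PAIRINGS: tuple[tuple[tuple[int, int], tuple[int, int]], ...] = (
    ((0, 1), (2, 3)),
    ((0, 2), (1, 3)),
    ((0, 3), (1, 2)),
)
MATCHING = 0

_CHROM_PAIRS6 = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


# ---------------------------------------------------------------------------
# configurations


@dataclass
class Bivalent:
    """Diploid configuration: the single bivalent of the two homologs."""

    kind = "bivalent"


@dataclass
class TwoBivalents:
    """Tetraploid configuration A: two separate bivalents."""

    pairing: int  # index into PAIRINGS
    kind = "bivalents"


@dataclass
class CrossQuadrivalent:
    """Tetraploid configuration B: cross-type quadrivalent.

    Two branches pair chromosome tops (per ``top`` pairing) and two pair
    bottoms (per ``bottom``); ``exchange_point`` is filled in when the
    quadrivalent is built.
    """

    top: int
    bottom: int
    exchange_point: float | None = None
    kind = "cross"

    def __post_init__(self) -> None:
        if self.top == self.bottom:
            raise ValueError("cross-type quadrivalent needs different top and bottom pairings")


@dataclass
class ParallelQuadrivalent:
    """Tetraploid configuration C: all four chromosomes paired in parallel."""

    kind = "parallel"


# ---------------------------------------------------------------------------
# Step 1: pairing


def pair_telomere(p: float, rng: Random) -> int:
    """Draw the pairing at one telomere under preferential pairing ``p``.

    Returns an index into :data:`PAIRINGS`; the matching pairing has
    probability ``p + (1-p)/3``, each other pairing ``(1-p)/3``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("preferential-pairing fraction must be in [0, 1]")
    r = rng.random()
    o = (1.0 - p) / 3.0
    if r < p + o:
        return 0
    return 1 if r < p + 2.0 * o else 2


def decide_configuration(spec: ChromosomeSpec, rng: Random, ploidy: int = 4):
    """Resolve the meiotic configuration for one chromosome set.

    Diploids always form the single bivalent. In natural mode the top and
    bottom telomere pairings are drawn independently; identical pairings
    give two bivalents, different ones a quadrivalent. In forced mode the
    configuration is a Bernoulli draw on the per-chromosome quadrivalent
    fraction, and pairing is performed within that constraint (bivalents:
    one telomere draw used at both ends; quadrivalent: the bottom pairing
    is drawn from the preferential distribution renormalized over the two
    pairings different from the top). A quadrivalent is parallel-type with
    probability ``spec.parallel_fraction``, else cross-type.
    """
    if ploidy == 2:
        return Bivalent()
    if ploidy != 4:
        raise UnsupportedPloidyError(f"ploidy must be 2 or 4, got {ploidy}")
    p = spec.pref_pairing
    if spec.natural_quadrivalents:
        top = pair_telomere(p, rng)
        bottom = pair_telomere(p, rng)
        if top == bottom:
            return TwoBivalents(top)
    else:
        if rng.random() < spec.quadrivalent_fraction:
            top = pair_telomere(p, rng)
            others = [q for q in (0, 1, 2) if q != top]
            m = p + (1.0 - p) / 3.0
            o = (1.0 - p) / 3.0
            w0 = m if others[0] == MATCHING else o
            w1 = m if others[1] == MATCHING else o
            total = w0 + w1
            if total <= 0.0:  # p == 1 and top == matching: uniform fallback
                bottom = others[rng.getrandbits(1)]
            else:
                bottom = others[0] if rng.random() < w0 / total else others[1]
        else:
            return TwoBivalents(pair_telomere(p, rng))
    if rng.random() < spec.parallel_fraction:
        return ParallelQuadrivalent()
    return CrossQuadrivalent(top, bottom)


# ---------------------------------------------------------------------------
# Step 2: recombination on chromatid bundles


class _Chromatid:
    """Mutable working chromatid: segment lists plus centromere membership.

    ``chrom`` is the original homolog slot (sister chromatids share it and
    never recombine with each other); ``unit`` identifies the parental
    centromere the chromatid is currently attached to.
    """

    __slots__ = ("starts", "alleles", "chrom", "unit")

    def __init__(self, hs: HaploStruct, chrom: int):
        self.starts = list(hs.starts)
        self.alleles = list(hs.alleles)
        self.chrom = chrom
        self.unit = chrom

    def to_haplostruct(self, chromosome: str | None) -> HaploStruct:
        return HaploStruct.from_arrays(self.starts, self.alleles, chromosome, validate=False)


def _swap_tails(u: _Chromatid, v: _Chromatid, x: float, centromere: float) -> None:
    u.starts, u.alleles, v.starts, v.alleles = _splice(
        u.starts, u.alleles, v.starts, v.alleles, x
    )
    if x < centromere:
        # The centromere region travelled with the swapped tails: the two
        # chromatids trade parental centromeres.
        u.unit, v.unit = v.unit, u.unit


def _duplicate(homologs: list[HaploStruct]) -> list[list[_Chromatid]]:
    return [[_Chromatid(h, i), _Chromatid(h, i)] for i, h in enumerate(homologs)]


def _cross_axes(axes, i, j, x, centromere, rng) -> None:
    """One chiasma between axes ``i`` and ``j`` at position ``x``.

    Chooses one current occupant of each axis uniformly, swaps their tails,
    and exchanges their axis occupancy: distal to the crossover, each
    strand continues along the other chromosome's axis, so later (more
    distal) chiasmata pick among the updated occupants.
    """
    bi = rng.getrandbits(1)
    bj = rng.getrandbits(1)
    u = axes[i][bi]
    v = axes[j][bj]
    _swap_tails(u, v, x, centromere)
    axes[i][bi] = v
    axes[j][bj] = u


def _recombine_bivalent(axes, i, j, length, centromere, cfg, rng) -> None:
    for x in generate_chiasma_positions(0.0, length, 1, cfg, rng):
        _cross_axes(axes, i, j, x, centromere, rng)


def _exchange_point_race(length: float, cfg, rng) -> float:
    """Locate the chromosome exchange point of a cross-type quadrivalent.

    Pairing proceeds inward from both chromosome ends at chiasma-sized
    steps: four virtual renewal streams (two per side) race toward the
    middle. Frontiers advance by accepting, over all open streams, the
    pending step closest to its own telomere; a pending step that would
    cross the opposite side's frontier closes its stream. The exchange
    point is the midpoint of the final gap between the top-side and
    bottom-side frontiers, which gives it a unimodal distribution peaked
    at the chromosome center. The virtual steps only locate the collision;
    the actual chiasmata are drawn afterwards so that the chiasma density
    inside each branch territory stays at the stationary rate (reusing the
    race's own steps would over-weight event-rich streams near the
    collision).
    """
    # stream: [side, positions (in processing order), next_index, frontier, open]
    streams = []
    for _ in range(2):
        streams.append([0, generate_chiasma_positions(0.0, length, 1, cfg, rng), 0, 0.0, True])
    for _ in range(2):
        pos = generate_chiasma_positions(0.0, length, -1, cfg, rng)
        pos.reverse()  # process from the bottom telomere inward
        streams.append([1, pos, 0, length, True])
    while True:
        best = None
        best_d = None
        for st in streams:
            if not st[4] or st[2] >= len(st[1]):
                continue
            x = st[1][st[2]]
            d = x if st[0] == 0 else length - x
            if best_d is None or d < best_d:
                best_d = d
                best = st
        if best is None:
            break
        x = best[1][best[2]]
        if best[0] == 0:
            if x >= min(st[3] for st in streams if st[0] == 1):
                best[4] = False
                continue
        else:
            if x <= max(st[3] for st in streams if st[0] == 0):
                best[4] = False
                continue
        best[2] += 1
        best[3] = x
    top_frontier = max(st[3] for st in streams if st[0] == 0)
    bottom_frontier = min(st[3] for st in streams if st[0] == 1)
    return 0.5 * (top_frontier + bottom_frontier)


def _recombine_cross(axes, top, bottom, spec, cfg, rng) -> float:
    """Cross-type quadrivalent recombination; returns the exchange point.

    The exchange point is located first (see :func:`_exchange_point_race`);
    the two top branches then pair chromosome tops over ``[0, exchange)``
    and the two bottom branches chromosome bottoms over ``(exchange,
    length]``, each with its own chiasma stream entering from its telomere
    at the bivalent rate. All chiasmata are applied in ascending order, so
    axis occupancy carries across the exchange point and recombinant
    chromatids can combine segments of three parental chromosomes.
    """
    length = spec.length
    cen = spec.centromere_pos
    exchange_point = _exchange_point_race(length, cfg, rng)
    chiasmata: list[tuple[float, tuple[int, int]]] = []
    for pair in PAIRINGS[top]:
        for x in generate_chiasma_positions(0.0, exchange_point, 1, cfg, rng):
            chiasmata.append((x, pair))
    for pair in PAIRINGS[bottom]:
        for x in generate_chiasma_positions(exchange_point, length, -1, cfg, rng):
            chiasmata.append((x, pair))
    chiasmata.sort(key=lambda t: t[0])
    for x, (i, j) in chiasmata:
        _cross_axes(axes, i, j, x, cen, rng)
    return exchange_point


def _recombine_parallel(axes, spec, cfg, rng) -> None:
    # Four paired chromosomes: twice the chiasma density of a bivalent so
    # the per-chromatid crossover rate stays one per Morgan.
    pcfg = replace(cfg, mean_distance=cfg.mean_distance * 0.5)
    cen = spec.centromere_pos
    for x in generate_chiasma_positions(0.0, spec.length, 1, pcfg, rng):
        i, j = _CHROM_PAIRS6[rng.randrange(6)]
        _cross_axes(axes, i, j, x, cen, rng)


def _collect_units(tids) -> list[list[_Chromatid]]:
    units: list[list[_Chromatid]] = [[] for _ in tids]
    for row in tids:
        for ct in row:
            units[ct.unit].append(ct)
    return units


def _units_to_haplostructs(units, chromosome):
    return [[ct.to_haplostruct(chromosome) for ct in unit] for unit in units]


# Public single-structure builders (mainly for direct testing/statistics).


def do_bivalent(
    hom_a: HaploStruct,
    hom_b: HaploStruct,
    spec: ChromosomeSpec,
    cfg: ChiasmaProcessConfig,
    rng: Random,
):
    """Recombine one bivalent; returns two centromere units of 2 chromatids.

    Unit k holds the chromatids attached to the parental centromere of
    homolog k after recombination.
    """
    tids = _duplicate([hom_a, hom_b])
    axes = [list(row) for row in tids]
    _recombine_bivalent(axes, 0, 1, spec.length, spec.centromere_pos, cfg, rng)
    return _units_to_haplostructs(_collect_units(tids), spec.name)


def build_cross_quadrivalent(
    homologs: list[HaploStruct],
    top: int,
    bottom: int,
    spec: ChromosomeSpec,
    cfg: ChiasmaProcessConfig,
    rng: Random,
):
    """Recombine a cross-type quadrivalent.

    Returns ``(units, exchange_point)``: four centromere units of two
    chromatids each, and the realized chromosome exchange point in cM.
    """
    if top == bottom:
        raise ValueError("cross-type quadrivalent needs different top and bottom pairings")
    tids = _duplicate(homologs)
    axes = [list(row) for row in tids]
    exchange_point = _recombine_cross(axes, top, bottom, spec, cfg, rng)
    return _units_to_haplostructs(_collect_units(tids), spec.name), exchange_point


def build_parallel_quadrivalent(
    homologs: list[HaploStruct],
    spec: ChromosomeSpec,
    cfg: ChiasmaProcessConfig,
    rng: Random,
):
    """Recombine a parallel quadrivalent; returns four centromere units.

    The chiasma stream runs at twice the bivalent density (mean gap
    ``cfg.mean_distance / 2``, i.e. 0.25 Morgan by default); each chiasma
    involves a uniform pair of the six chromosome pairs and then uniform
    non-sister chromatids, equivalent to a uniform choice among the 24
    non-sister chromatid pairs.
    """
    tids = _duplicate(homologs)
    axes = [list(row) for row in tids]
    _recombine_parallel(axes, spec, cfg, rng)
    return _units_to_haplostructs(_collect_units(tids), spec.name)


# ---------------------------------------------------------------------------
# Steps 3 and 4: the meiotic divisions

_PARTITIONS = PAIRINGS  # partitions of 4 centromeres into two pole pairs


def first_division(
    config,
    spec: ChromosomeSpec,
    rng: Random,
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Partition centromere units over the two poles (unit indices).

    Bivalent: one centromere per pole. Two bivalents: each splits
    independently. Quadrivalent (default): the four centromeres form two
    pairs uniformly over the three possible partitions. Cross-type with
    ``spec.paired_centromeres``: the two chromosomes paired on the
    centromere's side of the exchange point go to opposite poles; the two
    compatible partitions are equally likely.
    """
    kind = config.kind
    if kind == "bivalent":
        return ((0,), (1,)) if rng.getrandbits(1) else ((1,), (0,))
    if kind == "bivalents":
        pole0 = []
        pole1 = []
        for i, j in PAIRINGS[config.pairing]:
            if rng.getrandbits(1):
                i, j = j, i
            pole0.append(i)
            pole1.append(j)
        return tuple(pole0), tuple(pole1)
    if kind == "parallel" and spec.paired_centromeres:
        raise ValueError("paired_centromeres is defined for cross-type quadrivalents only")
    if kind == "cross" and spec.paired_centromeres:
        if config.exchange_point is None:
            raise ValueError("exchange point not set; build the quadrivalent first")
        pairing = (
            config.top if spec.centromere_pos < config.exchange_point else config.bottom
        )
        # Pole partitions separating both centromere-side partner pairs are
        # exactly the two partitions different from the pairing itself.
        compatible = [q for q in (0, 1, 2) if q != pairing]
        part = _PARTITIONS[compatible[rng.getrandbits(1)]]
    else:
        part = _PARTITIONS[rng.randrange(3)]
    pair0, pair1 = part
    if rng.getrandbits(1):
        pair0, pair1 = pair1, pair0
    return pair0, pair1


def second_division(pole_units, rng: Random):
    """Split each centromere at a pole over the two daughter gametes.

    ``pole_units`` is a list of units (two chromatids each); each unit's
    chromatids are dealt to the two daughters with independent random
    orientation. Returns two lists with one chromatid per unit.
    """
    daughter0 = []
    daughter1 = []
    for unit in pole_units:
        b = rng.getrandbits(1)
        daughter0.append(unit[b])
        daughter1.append(unit[1 - b])
    return daughter0, daughter1


# ---------------------------------------------------------------------------
# the full pipeline


def do_meiosis(
    parent: IndividualGenome,
    specs: list[ChromosomeSpec],
    cfg: ChiasmaProcessConfig,
    rng: Random,
    configs_out: dict | None = None,
) -> list[Gamete]:
    """One complete meiosis: four gametes.

    Pairing, recombination and both divisions run independently per
    chromosome set; pole-to-gamete assortment is therefore independent
    between chromosomes. When ``configs_out`` is given it is filled with
    the resolved configuration per chromosome name (the cross-type entries
    carry their realized exchange point).
    """
    ploidy = parent.ploidy
    gametes: list[dict[str, list[HaploStruct]]] = [{}, {}, {}, {}]
    for spec in specs:
        homologs = parent.homologs[spec.name]
        tids = _duplicate(homologs)
        axes = [list(row) for row in tids]
        config = decide_configuration(spec, rng, ploidy)
        kind = config.kind
        if kind == "bivalent":
            _recombine_bivalent(axes, 0, 1, spec.length, spec.centromere_pos, cfg, rng)
        elif kind == "bivalents":
            for i, j in PAIRINGS[config.pairing]:
                _recombine_bivalent(axes, i, j, spec.length, spec.centromere_pos, cfg, rng)
        elif kind == "cross":
            config.exchange_point = _recombine_cross(
                axes, config.top, config.bottom, spec, cfg, rng
            )
        else:
            _recombine_parallel(axes, spec, cfg, rng)
        if configs_out is not None:
            configs_out[spec.name] = config
        units = _collect_units(tids)
        pole0, pole1 = first_division(config, spec, rng)
        d0, d1 = second_division([units[i] for i in pole0], rng)
        d2, d3 = second_division([units[i] for i in pole1], rng)
        for g, chromatids in zip(gametes, (d0, d1, d2, d3)):
            g[spec.name] = [ct.to_haplostruct(spec.name) for ct in chromatids]
    return [Gamete(chromatids=g) for g in gametes]


def sample_gamete(gametes: list[Gamete], rng: Random) -> Gamete:
    """Uniformly select one of the four gametes of a meiosis."""
    if len(gametes) != 4:
        raise ValueError("a meiosis yields exactly 4 gametes")
    return gametes[rng.randrange(4)]
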