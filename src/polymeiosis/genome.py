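"""Core data types for simulated genomes.

Chromosomes are abstract linear genetic maps measured in centiMorgan (cM);
there is no sequence content. Every chromosome copy in the population is a
mosaic of *founder* chromosomes: a :class:`HaploStruct` stores an ordered
list of ``(start, founder_allele)`` segments with half-open extents
``[start, next_start)``. Founder individuals carry single-segment homologs
with globally unique integer founder-allele IDs (founder ``i`` of ploidy
``P`` owns IDs ``i*P .. i*P+P-1``), so any downstream chromosome can be
decoded back to its founder origin at every position.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

__all__ = [
    "NATURAL",
    "UnsupportedPloidyError",
    "MalformedHaploStructError",
    "PositionError",
    "AssignmentGapError",
    "ChromosomeSpec",
    "LocusDef",
    "HaploStruct",
    "IndividualGenome",
    "Gamete",
    "AlleleAssignment",
    "founder_genome",
    "allele_at",
    "canonicalize",
]

#: Sentinel for ``ChromosomeSpec.quadrivalent_fraction``: let the degree of
#: preferential telomere pairing determine the bivalent/quadrivalent ratio.
NATURAL = "natural"


class UnsupportedPloidyError(ValueError):
    """Raised for ploidy levels other than 2 or 4."""


class MalformedHaploStructError(ValueError):
    """Raised when segment starts are not strictly increasing from 0."""


class PositionError(ValueError):
    """Raised when a map position lies outside its chromosome."""


class AssignmentGapError(KeyError):
    """Raised when a founder allele has no observed allele at a locus."""


@dataclass(frozen=True)
class ChromosomeSpec:
    """Per-chromosome simulation parameters.

    Parameters
    ----------
    name
        Chromosome identifier.
    length
        Map length in cM (> 0).
    centromere_pos
        Centromere position in cM, within ``[0, length]``.
    pref_pairing
        Preferential-pairing fraction ``p`` in ``[0, 1]``: the tendency of
        each subgenome's two true homologues to pair at a telomere. 0 means
        fully random (autotetraploid), 1 exclusive pairing (allotetraploid).
    quadrivalent_fraction
        Fraction of meioses forming a quadrivalent, or :data:`NATURAL` to
        derive it from independent telomere pairing.
    parallel_fraction
        Fraction of quadrivalents that are parallel-type (the rest are
        cross-type).
    paired_centromeres
        Alternative first-division model for cross-type quadrivalents: the
        two chromosomes paired on the centromere's side of the exchange
        point always move to opposite poles.
    """

    name: str
    length: float
    centromere_pos: float
    pref_pairing: float = 0.0
    quadrivalent_fraction: float | str = NATURAL
    parallel_fraction: float = 0.0
    paired_centromeres: bool = False

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name!r}: length must be > 0")
        if not 0.0 <= self.centromere_pos <= self.length:
            raise ValueError(
                f"chromosome {self.name!r}: centromere {self.centromere_pos} "
                f"outside [0, {self.length}]"
            )
        if not 0.0 <= self.pref_pairing <= 1.0:
            raise ValueError(f"chromosome {self.name!r}: prefPairing outside [0, 1]")
        if not 0.0 <= self.parallel_fraction <= 1.0:
            raise ValueError(f"chromosome {self.name!r}: parallel fraction outside [0, 1]")
        qf = self.quadrivalent_fraction
        if qf != NATURAL and not (isinstance(qf, (int, float)) and 0.0 <= qf <= 1.0):
            raise ValueError(
                f"chromosome {self.name!r}: quadrivalent fraction must be "
                f"'{NATURAL}' or in [0, 1]"
            )

    @property
    def natural_quadrivalents(self) -> bool:
        return self.quadrivalent_fraction == NATURAL


@dataclass(frozen=True)
class LocusDef:
    """A marker locus on the genetic map."""

    name: str
    chromosome: str
    position: float


class HaploStruct:
    """One chromatid or homolog as a founder-segment mosaic.

    ``starts`` and ``alleles`` are parallel lists; segment ``k`` covers
    ``[starts[k], starts[k+1])`` (the last runs to the chromosome end) and
    carries founder allele ``alleles[k]``. The first start is always 0 and
    starts are strictly increasing. A HaploStruct is *canonical* when
    adjacent segments carry different alleles.
    """

    __slots__ = ("starts", "alleles", "chromosome")

    def __init__(self, segments, chromosome: str | None = None):
        starts: list[float] = []
        alleles: list[int] = []
        for start, allele in segments:
            starts.append(float(start))
            alleles.append(int(allele))
        _validate_starts(starts)
        self.starts = starts
        self.alleles = alleles
        self.chromosome = chromosome

    @classmethod
    def from_arrays(cls, starts, alleles, chromosome=None, validate=True):
        h = cls.__new__(cls)
        h.starts = list(starts)
        h.alleles = list(alleles)
        h.chromosome = chromosome
        if validate:
            _validate_starts(h.starts)
        return h

    @property
    def segments(self) -> list[tuple[float, int]]:
        return list(zip(self.starts, self.alleles))

    def allele_at(self, pos: float) -> int:
        if pos < self.starts[0]:
            raise PositionError(f"position {pos} before chromosome start")
        return self.alleles[bisect_right(self.starts, pos) - 1]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, HaploStruct)
            and self.starts == other.starts
            and self.alleles == other.alleles
        )

    def __hash__(self):
        return hash((tuple(self.starts), tuple(self.alleles)))

    def __repr__(self) -> str:
        return f"HaploStruct({self.segments!r}, chromosome={self.chromosome!r})"


def _validate_starts(starts: list[float]) -> None:
    if not starts:
        raise MalformedHaploStructError("HaploStruct needs at least one segment")
    if starts[0] != 0.0:
        raise MalformedHaploStructError("first segment must start at 0")
    for a, b in zip(starts, starts[1:]):
        if b <= a:
            raise MalformedHaploStructError("segment starts must be strictly increasing")


@dataclass
class IndividualGenome:
    """One individual: ``ploidy`` homologs per chromosome, in fixed slots.

    Slot order is meaningful: slots 0..ploidy/2-1 derive from the maternal
    gamete and the rest from the paternal gamete (founders: one subgenome
    per slot pair), which is what positional preferential pairing acts on.
    """

    name: str
    ploidy: int
    homologs: dict[str, list[HaploStruct]]

    def __post_init__(self) -> None:
        if self.ploidy not in (2, 4):
            raise UnsupportedPloidyError(f"ploidy must be 2 or 4, got {self.ploidy}")
        for chrom, homs in self.homologs.items():
            if len(homs) != self.ploidy:
                raise ValueError(
                    f"individual {self.name!r}, chromosome {chrom!r}: "
                    f"{len(homs)} homologs for ploidy {self.ploidy}"
                )


@dataclass
class Gamete:
    """Chromatids delivered to one spore: ploidy/2 per chromosome."""

    chromatids: dict[str, list[HaploStruct]]


@dataclass
class AlleleAssignment:
    """Observable alleles per founder allele at every locus.

    ``observed[locus][founder_allele]`` is the observed allele string;
    ``reference[locus]`` names the allele whose dosage (0..ploidy) is
    reported per individual.
    """

    observed: dict[str, dict[int, str]]
    reference: dict[str, str]

    def observed_allele(self, locus: str, founder_allele: int) -> str:
        try:
            return self.observed[locus][founder_allele]
        except KeyError:
            raise AssignmentGapError(
                f"no observed allele for founder allele {founder_allele} "
                f"at locus {locus!r}"
            ) from None


def founder_genome(
    founder_index: int,
    ploidy: int,
    chromosomes: list[ChromosomeSpec],
    name: str | None = None,
) -> IndividualGenome:
    """Create founder ``i`` with single-segment homologs.

    Homolog slot ``k`` carries founder allele ``i*ploidy + k`` over the full
    length of every chromosome, so allele IDs are globally unique and
    order-stable across founders.
    """
    if ploidy not in (2, 4):
        raise UnsupportedPloidyError(f"ploidy must be 2 or 4, got {ploidy}")
    if founder_index < 0:
        raise ValueError("founder_index must be >= 0")
    base = founder_index * ploidy
    homologs = {
        spec.name: [
            HaploStruct([(0.0, base + k)], chromosome=spec.name) for k in range(ploidy)
        ]
        for spec in chromosomes
    }
    return IndividualGenome(
        name=name if name is not None else f"founder{founder_index}",
        ploidy=ploidy,
        homologs=homologs,
    )


def allele_at(h: HaploStruct, pos: float) -> int:
    """Founder allele at ``pos`` (half-open segment convention)."""
    return h.allele_at(pos)


def canonicalize(h: HaploStruct) -> HaploStruct:
    """Merge adjacent equal-allele segments; ``allele_at`` is unchanged."""
    _validate_starts(h.starts)
    starts = [h.starts[0]]
    alleles = [h.alleles[0]]
    for s, a in zip(h.starts[1:], h.alleles[1:]):
        if a != alleles[-1]:
            starts.append(s)
            alleles.append(a)
    return HaploStruct.from_arrays(starts, alleles, h.chromosome, validate=False)
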