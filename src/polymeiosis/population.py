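"""Gene-dropping over a pedigree.

Founders receive labelled single-segment genomes; every other individual is
created by mating: one sampled gamete from each parent, with the maternal
gamete's chromatids filling homolog slots 0..ploidy/2-1 and the paternal
ones the remaining slots. Selfing (parent1 == parent2) runs two independent
meioses of the same parent. Observable marker genotypes and allele dosages
are then read off the founder-allele mosaics with an allele assignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from random import Random

import pandas as pd

from .chiasma import ChiasmaProcessConfig
from .genome import (
    AlleleAssignment,
    ChromosomeSpec,
    IndividualGenome,
    LocusDef,
    founder_genome,
)
from .meiosis import do_meiosis, sample_gamete

__all__ = [
    "PedigreeError",
    "PedigreeEntry",
    "RealizedGenotypes",
    "mate",
    "build_population",
    "realize_genotypes",
]


class PedigreeError(ValueError):
    """Raised for invalid pedigrees (missing parents, bad ordering, cycles)."""


@dataclass(frozen=True)
class PedigreeEntry:
    """One pedigree row; founders have both parents missing (None)."""

    name: str
    parent1: str | None = None
    parent2: str | None = None

    def __post_init__(self) -> None:
        if (self.parent1 is None) != (self.parent2 is None):
            raise PedigreeError(
                f"individual {self.name!r}: both parents must be given or both missing"
            )

    @property
    def is_founder(self) -> bool:
        return self.parent1 is None


@dataclass
class RealizedGenotypes:
    """Observable marker data for a population on a genetic map.

    ``founder[locus][individual]`` holds the ordered founder-allele IDs per
    homolog slot, ``observed`` the corresponding observed allele strings,
    and ``dosage`` is a loci x individuals DataFrame counting copies of the
    locus's reference allele (0..ploidy).
    """

    ploidy: int
    individuals: list[str]
    loci: list[LocusDef]
    founder: dict[str, dict[str, tuple[int, ...]]]
    observed: dict[str, dict[str, tuple[str, ...]]]
    dosage: pd.DataFrame


def mate(
    parent1: IndividualGenome,
    parent2: IndividualGenome,
    specs: list[ChromosomeSpec],
    cfg: ChiasmaProcessConfig,
    rng: Random,
    name: str = "offspring",
) -> IndividualGenome:
    """Produce one offspring from two (possibly identical) parents."""
    if parent1.ploidy != parent2.ploidy:
        raise ValueError(
            f"ploidy mismatch: {parent1.name!r} is {parent1.ploidy}x, "
            f"{parent2.name!r} is {parent2.ploidy}x"
        )
    g1 = sample_gamete(do_meiosis(parent1, specs, cfg, rng), rng)
    g2 = sample_gamete(do_meiosis(parent2, specs, cfg, rng), rng)
    homologs = {
        spec.name: list(g1.chromatids[spec.name]) + list(g2.chromatids[spec.name])
        for spec in specs
    }
    return IndividualGenome(name=name, ploidy=parent1.ploidy, homologs=homologs)


def build_population(
    pedigree: list[PedigreeEntry],
    specs: list[ChromosomeSpec],
    cfg: ChiasmaProcessConfig,
    seed: int | Random,
    ploidy: int,
) -> dict[str, IndividualGenome]:
    """Gene-drop founder alleles down a pedigree.

    The pedigree is processed in order; parents must be defined before
    their offspring (this also rules out cycles). Founders are numbered in
    order of appearance, fixing their founder-allele IDs. Reproducible:
    the same seed yields identical genomes.
    """
    rng = Random(seed) if isinstance(seed, int) else seed
    population: dict[str, IndividualGenome] = {}
    founder_count = 0
    for entry in pedigree:
        if entry.name in population:
            raise PedigreeError(f"duplicate individual {entry.name!r}")
        if entry.is_founder:
            population[entry.name] = founder_genome(
                founder_count, ploidy, specs, name=entry.name
            )
            founder_count += 1
            continue
        if entry.parent1 == entry.name or entry.parent2 == entry.name:
            raise PedigreeError(f"pedigree cycle: {entry.name!r} is its own parent")
        for parent in (entry.parent1, entry.parent2):
            if parent not in population:
                raise PedigreeError(
                    f"individual {entry.name!r}: parent {parent!r} not defined "
                    "before use"
                )
        population[entry.name] = mate(
            population[entry.parent1],
            population[entry.parent2],
            specs,
            cfg,
            rng,
            name=entry.name,
        )
    return population


def realize_genotypes(
    population: dict[str, IndividualGenome],
    genetic_map: list[LocusDef],
    assignment: AlleleAssignment,
) -> RealizedGenotypes:
    """Observable ordered genotypes and reference-allele dosages.

    The observed allele of homolog slot k at a locus is the assignment of
    the founder allele found at the locus position; the dosage counts the
    slots carrying the locus's reference allele. Distinct founder
    haplotypes may yield homozygous observed genotypes when they share an
    assigned allele.
    """
    individuals = list(population)
    ploidies = {ind.ploidy for ind in population.values()}
    if len(ploidies) != 1:
        raise ValueError("population mixes ploidy levels")
    ploidy = ploidies.pop()
    founder: dict[str, dict[str, tuple[int, ...]]] = {}
    observed: dict[str, dict[str, tuple[str, ...]]] = {}
    dosage_rows = []
    for locus in genetic_map:
        f_row: dict[str, tuple[int, ...]] = {}
        o_row: dict[str, tuple[str, ...]] = {}
        d_row = []
        ref = assignment.reference[locus.name]
        for name in individuals:
            homs = population[name].homologs[locus.chromosome]
            ids = tuple(h.allele_at(locus.position) for h in homs)
            obs = tuple(assignment.observed_allele(locus.name, i) for i in ids)
            f_row[name] = ids
            o_row[name] = obs
            d_row.append(sum(1 for a in obs if a == ref))
        founder[locus.name] = f_row
        observed[locus.name] = o_row
        dosage_rows.append(d_row)
    dosage = pd.DataFrame(
        dosage_rows, index=[l.name for l in genetic_map], columns=individuals, dtype=int
    )
    return RealizedGenotypes(
        ploidy=ploidy,
        individuals=individuals,
        loci=list(genetic_map),
        founder=founder,
        observed=observed,
        dosage=dosage,
    )
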