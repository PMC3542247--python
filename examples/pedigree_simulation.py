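"""Gene-dropping a tetraploid F1 cross and reading off marker dosages.

Builds a two-founder pedigree with ten F1 offspring on one 100 cM
chromosome, assigns SNP-like observed alleles to the founder haplotypes,
and prints the resulting allele-dosage matrix — the kind of input a
polyploid linkage-mapping or dosage-calling method consumes.
"""

from polymeiosis import (
    AlleleAssignment,
    ChiasmaProcessConfig,
    ChromosomeSpec,
    LocusDef,
    PedigreeEntry,
    build_population,
    realize_genotypes,
)

spec = ChromosomeSpec("1", length=100.0, centromere_pos=20.0)
loci = [LocusDef(f"m{i}", "1", pos) for i, pos in enumerate((0.0, 25.0, 50.0, 75.0, 100.0))]
pedigree = [PedigreeEntry("P1"), PedigreeEntry("P2")] + [
    PedigreeEntry(f"F1_{i:02d}", "P1", "P2") for i in range(10)
]

# P1 is duplex (AAaa) at every marker, P2 nulliplex (aaaa).
assignment = AlleleAssignment(
    observed={l.name: {i: ("A" if i in (0, 1) else "a") for i in range(8)} for l in loci},
    reference={l.name: "A" for l in loci},
)

population = build_population(pedigree, [spec], ChiasmaProcessConfig(), seed=42, ploidy=4)
realized = realize_genotypes(population, loci, assignment)

print("Dosage of allele A (rows: markers, columns: individuals):")
print(realized.dosage.to_string())
print(
    "\nP1 carries A on both homologs of one subgenome (dosage 2), P2 none;"
    "\neach F1 inherits 0-2 copies through its maternal gamete, so offspring"
    "\ndosages segregate between 0 and 2 with linked markers co-varying"
    "\nalong the chromosome."
)
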