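# polymeiosis

Simulation of meiosis in diploid and tetraploid organisms: bivalent and
quadrivalent pairing, chiasma interference, preferential pairing of
homoeologues, double reduction, and gene-dropping of marker genotypes over
arbitrary pedigrees.

## Why

Linkage mapping, haplotyping and QTL methods for tetraploid crops (potato,
rose, leek, alfalfa, ...) are hard to validate without populations whose
true inheritance model is known. Tetrasomic inheritance brings phenomena
that diploid simulators do not produce: four homologous chromosomes can
pair as two bivalents or as one quadrivalent, homoeologues may pair
preferentially with their own subgenome partner, allele dosages range from
0 to 4, and quadrivalents generate *double reduction* — gametes carrying
two copies of part of the same parental homolog. `polymeiosis` simulates
gamete formation mechanistically, step by step, and drops labelled founder
chromosomes down a pedigree to produce complete, error-free ordered marker
genotypes and allele dosages.

## The model

Each meiosis runs per chromosome set through four stages:

1. **Pairing.** Telomeres pair independently at both chromosome ends. With
   preferential-pairing fraction *p*, the matching (same-subgenome) pairing
   has probability *p* + (1−*p*)/3 and each of the other two pairings
   (1−*p*)/3. Identical pairings at both ends give two bivalents, different
   pairings a quadrivalent, so the expected quadrivalent fraction is
   1 − [(*p* + (1−*p*)/3)² + 2((1−*p*)/3)²] — 2/3 for an autotetraploid
   (*p* = 0), 0 for a strict allotetraploid (*p* = 1). The
   bivalent:quadrivalent ratio can instead be forced per chromosome, as can
   the share of "parallel" versus "cross-type" quadrivalents.
2. **Recombination.** Chiasmata are laid down along each paired structure
   by a renewal process from one telomere to the other: exponential
   inter-chiasma distances with mean 0.5 Morgan per paired chromosome pair
   (no interference, Haldane regime: r = (1 − e^(−2d))/2), or
   Gamma(shape 2.63) distances with the same mean (chiasma interference,
   closely following Kosambi: r = tanh(2d)/2), burnt in 10 Morgan before
   the chromosome start. Each chiasma involves one uniformly chosen
   chromatid of each paired chromosome — no chromatid interference — and
   exchanges the strand tails distal to the crossover. In a cross-type
   quadrivalent, two branches pair chromosome tops and two pair bottoms on
   either side of a chromosome exchange point whose position varies per
   meiosis (unimodal, peaked at the chromosome center); a parallel
   quadrivalent pairs all four chromosomes along their length with a
   0.25 Morgan mean chiasma spacing.
3. **First division.** Bivalents send one centromere to each pole;
   quadrivalent centromeres are partitioned into two uniform random pairs
   (optionally, centromere-side pairing partners always separate).
4. **Second division.** Each centromere splits, sending its two chromatids
   to the two daughter gametes with independent random orientation.

Chromosomes are founder-segment mosaics: founder *i* of ploidy *P* carries
founder alleles *iP* .. *iP*+*P*−1, one per homolog, and every descendant
chromosome is a list of (start position, founder allele) segments.
Observable marker genotypes are produced by assigning an observed allele to
every founder haplotype at every mapped locus.

## Worked example

`python examples/quadrivalent_pairing.py` prints:

```
    p  expected  simulated   (100000 pairing decisions each)
 0.00     0.667      0.667
 0.25     0.625      0.622
 0.50     0.500      0.501
 0.75     0.292      0.292
 1.00     0.000      0.000
```

i.e. the simulated share of meioses that form a quadrivalent matches the
closed form above for every degree of preferential pairing. The other
examples compare bivalent recombination with the Haldane/Kosambi map
functions, trace double reduction from 0 at the centromere to its 1/7
limit, and gene-drop a tetraploid F1 cross into a marker dosage matrix:

```python
from polymeiosis import (ChiasmaProcessConfig, ChromosomeSpec, LocusDef,
                         PedigreeEntry, build_population, realize_genotypes)

spec = ChromosomeSpec("1", length=100.0, centromere_pos=20.0)
pedigree = [PedigreeEntry("P1"), PedigreeEntry("P2"),
            PedigreeEntry("F1_01", "P1", "P2")]
population = build_population(pedigree, [spec], ChiasmaProcessConfig(),
                              seed=42, ploidy=4)
```

## Command line

For file-driven runs there is a thin CLI:

```
polymeiosis run.par [--seed N] [--test]
```

`run.par` is a `KEY = value` parameter file (PLOIDY, MAPFUNCTION =
HALDANE|KOSAMBI, CHROMFILE, MAPFILE, PEDFILE, FOUNDERFILE, OUTPUT, and
optional MISSING, SEED, TEST). All input and output files are plain
tab-delimited text with a header row; the missing code defaults to `NA`.
A simulation run writes four tables: `<prefix>_founderalleles.dat`,
`<prefix>_genotypes.dat`, `<prefix>_alleledose.dat` and
`<prefix>_haplostruct.dat` (the founder-segment mosaics; readable back
into memory losslessly). `--test` switches to the replicated-meiosis test
mode, which accumulates gamete statistics for one founder and writes
`<prefix>_testreport.dat` comparing them with closed-form references.
Runs with the same seed are byte-identical. The file dialects are
documented in `polymeiosis/io.py`.

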